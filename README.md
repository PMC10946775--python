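# aadpheno

Rule-based phenotyping of **asthma, atopic eczema and allergic rhinitis**
in children from longitudinal primary-care electronic health records
(EHR), for epidemiologists who define disease outcomes from CTV3-style
diagnosis codes and BNF-coded prescriptions rather than direct clinical
assessment.

Diagnosis codes in GP records are an imperfect proxy for disease: coding
practice varies between practices and doctors, early-childhood wheeze and
infant rashes are easily mislabelled, and hay-fever remedies are bought
over the counter so prescriptions undercount true use. The package
implements paired case definitions per outcome — one backed by
prescription evidence, one based on codes alone — and quantifies how well
prescriptions track codes.

## The rules and the statistic

Each child is classified under two definitions per outcome (ages are
completed years; an *age-year k* is the interval [k-th birthday, (k+1)-th
birthday)):

| Outcome | 1st definition | 2nd definition |
|---|---|---|
| Asthma | code at age ≥ 6, **or** code at age 3–5 **and** ≥ 3 prescriptions of bronchodilators / inhaled corticosteroids / leukotriene receptor antagonists (pooled) in ≥ 1 age-year from age 6 | code at age ≥ 3 |
| Atopic eczema | first code at age ≥ 1 **and** ≥ 2 eczema-related prescription items in [first code − 90 d, first code + 365 d] | code at age ≥ 1 |
| Allergic rhinitis | code at any age | code during hay fever season (1 Mar–31 Jul) **and** ≥ 1 seasonal antihistamine / intranasal corticosteroid prescription |

Concordance between codes and prescriptions is summarised per medication
class with the codes as reference standard. With a = code+/prescribed+,
b = code−/prescribed+, c = code+/prescribed−, d = code−/prescribed−:

```
PPV = a / (a + b)        NPV = d / (c + d)
```

with two-sided 95% binomial confidence intervals (Clopper–Pearson by
default, which remains informative at NPV = d/d = 1: the lower bound is
0.025^(1/n); Wilson and Wald are available).

The package also provides codelist construction by case-insensitive term
mining with audited include/exclude decisions, and a synthetic cohort
generator (no real patient data are required or included anywhere).

## Worked example

```python
from aadpheno import TwoByTwo, Outcome, MedClass
from aadpheno.concordance import table_row
from aadpheno.simulate import (FixtureSpec, TwoByTwo, default_class_map,
                               default_codelists, generate_exact_fixture)
from aadpheno.concordance import build_two_by_two, code_status

# a deterministic 13,044-child cohort hitting given 2x2 cell counts
fixture = generate_exact_fixture(FixtureSpec.single(
    Outcome.ASTHMA, MedClass.BRONCHODILATOR, TwoByTwo(883, 556, 420, 11185)))
status = code_status(fixture, default_codelists()[Outcome.ASTHMA], Outcome.ASTHMA)
t = build_two_by_two(fixture, status, Outcome.ASTHMA, MedClass.BRONCHODILATOR)
row = table_row(t, Outcome.ASTHMA, MedClass.BRONCHODILATOR)
print(t.a, t.b, t.c, t.d)        # 883 556 420 11185
print(row["ppv_fmt"])            # 0.61 (0.59, 0.64)
print(row["npv_fmt"])            # 0.96 (0.96, 0.97)
print(row["pct_code_yes_rx_yes"])  # 67.8  (883 of the 1,303 code-positive)
```

Reading: 61% of children ever meeting the bronchodilator exposure
criterion (≥ 3 items in one age-year from age 6) carry an asthma code —
prescription-only asthma drugs track the codes closely — while 96% of
children never meeting it carry no code.

The same numbers fall out of a stochastic cohort drawn with the default
calibration (2,000 children here):

```python
from aadpheno.simulate import SimulationConfig, generate_cohort
from aadpheno.concordance import predictive_value_table

cohort, truth = generate_cohort(SimulationConfig(n_children=2000), seed=7)
table = predictive_value_table(cohort, default_codelists())
print(table.loc[0, ["a", "b", "c", "d", "ppv_fmt", "npv_fmt"]].tolist())
# [143, 94, 54, 1709, '0.60 (0.54, 0.67)', '0.97 (0.96, 0.98)']
```

Or from the shell:

```bash
aadpheno simulate --seed 17 -o data/
aadpheno phenotype  --children data/children.csv --events data/events.csv \
    --prescriptions data/prescriptions.csv --classmap data/class_map.csv \
    --codelist-dir data/codelists -o status.csv
aadpheno concordance --status status.csv --children data/children.csv \
    --prescriptions data/prescriptions.csv --classmap data/class_map.csv \
    -o table2.csv --markdown table2.md
```

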