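"""Clinical codelist construction by term mining plus published codes.

A codelist operationally defines an outcome (asthma, atopic eczema, allergic
rhinitis) as a reviewed set of clinical codes.  Two sources feed it: codes
published in earlier validation studies, and codes found by case-insensitive
text mining of the term definitions that accompany each code in the local
code dictionary.  Mining is deliberately conservative plain-substring
matching (regex only behind an explicit flag), and every candidate keeps an
explicit include/exclude decision with a reason — terms like "Family history
of asthma" or "Asthma screening invite" match the disease word but describe
non-cases, so they are retained as documented exclusions rather than
silently filtered.  The exported CSV keeps the decision column editable so
the final human review step stays in the loop.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Outcome",
    "CodeDictionary",
    "CodelistEntry",
    "Codelist",
    "mine_terms",
    "merge_codelists",
    "read_codelist",
    "write_codelist",
]


class Outcome(str, Enum):
    ASTHMA = "asthma"
    ECZEMA = "eczema"
    ALLERGIC_RHINITIS = "allergic_rhinitis"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CodeDictionary:
    """Code → term-text dictionary (codes unique, case-sensitive)."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate codes in dictionary")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CodeDictionary":
        df = pd.read_csv(path, dtype=str).fillna("")
        if not {"code", "term"} <= set(df.columns):
            raise ValueError(f"{path}: dictionary needs columns code,term")
        return cls(tuple(zip(df["code"], df["term"])))


@dataclass(frozen=True)
class CodelistEntry:
    code: str
    term: str
    source: str  # "published", "mined" or "both"
    decision: str  # "include" or "exclude"
    reason: str = ""


@dataclass(frozen=True)
class Codelist:
    outcome: Outcome
    entries: tuple[CodelistEntry, ...] = ()

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate codes in codelist")
        for e in self.entries:
            if e.decision not in ("include", "exclude"):
                raise ValueError(f"bad decision {e.decision!r} for {e.code!r}")
            if e.decision == "exclude" and not e.reason:
                raise ValueError(f"excluded code {e.code!r} lacks a reason")

    def includes(self) -> frozenset[str]:
        """The codes that actively define the outcome."""
        return frozenset(e.code for e in self.entries if e.decision == "include")

    def __len__(self) -> int:
        return len(self.entries)


def _compile(patterns: Sequence[str], regex: bool) -> list[tuple[str, re.Pattern]]:
    out = []
    for p in patterns:
        src = p if regex else re.escape(p)
        out.append((p, re.compile(src, re.IGNORECASE)))
    return out


def mine_terms(
    dictionary: CodeDictionary,
    include_patterns: Sequence[str],
    exclude_patterns: Sequence[str] = (),
    outcome: Outcome = Outcome.ASTHMA,
    regex: bool = False,
) -> Codelist:
    """Mine the dictionary's term text for candidate outcome codes.

    An entry whose term matches any include pattern (case-insensitive
    substring; full regex with ``regex=True``) becomes a candidate; a
    candidate also matching an exclude pattern is kept with
    ``decision="exclude"`` and the matching pattern as reason, because
    exclusions must stay auditable.  Output is sorted by code, so the result
    does not depend on dictionary row order.
    """
    if not include_patterns:
        raise ValueError("at least one include pattern is required")
    if not dictionary.entries:
        warnings.warn("empty code dictionary: mined codelist is empty")
        return Codelist(outcome=outcome)

    inc = _compile(include_patterns, regex)
    exc = _compile(exclude_patterns, regex)
    entries: list[CodelistEntry] = []
    for code, term in dictionary.entries:
        hit = next((p for p, rx in inc if rx.search(term)), None)
        if hit is None:
            continue
        veto = next((p for p, rx in exc if rx.search(term)), None)
        if veto is not None:
            entries.append(
                CodelistEntry(
                    code, term, "mined", "exclude",
                    f"matched exclusion pattern {veto!r}",
                )
            )
        else:
            entries.append(
                CodelistEntry(
                    code, term, "mined", "include",
                    f"matched pattern {hit!r}",
                )
            )
    entries.sort(key=lambda e: e.code)
    return Codelist(outcome=outcome, entries=tuple(entries))


def merge_codelists(published: Codelist, mined: Codelist) -> Codelist:
    """Union two codelists for the same outcome, code by code.

    Where both lists carry the same code, the source becomes ``both`` and an
    explicit exclusion wins over an inclusion (mirroring the manual review
    step, where a vetoed term stays vetoed whatever list it came from);
    reasons are concatenated so the audit trail survives the merge.
    """
    if published.outcome != mined.outcome:
        raise ValueError(
            f"outcome mismatch: {published.outcome} vs {mined.outcome}"
        )
    by_code: dict[str, CodelistEntry] = {e.code: e for e in published.entries}
    for e in mined.entries:
        if e.code not in by_code:
            by_code[e.code] = e
            continue
        prev = by_code[e.code]
        decision = "exclude" if "exclude" in (prev.decision, e.decision) else "include"
        reason = "; ".join(r for r in (prev.reason, e.reason) if r)
        if decision == "exclude" and not reason:
            reason = "excluded on merge"
        by_code[e.code] = CodelistEntry(
            code=e.code,
            term=prev.term or e.term,
            source="both" if prev.source != e.source else prev.source,
            decision=decision,
            reason=reason,
        )
    entries = tuple(sorted(by_code.values(), key=lambda e: e.code))
    return Codelist(outcome=published.outcome, entries=entries)


def read_codelist(path: str | Path) -> Codelist:
    df = pd.read_csv(path, dtype=str).fillna("")
    needed = {"outcome", "code", "term", "source", "decision", "reason"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: codelist needs columns {sorted(needed)}")
    outcomes = set(df["outcome"])
    if len(outcomes) > 1:
        raise ValueError(f"{path}: mixed outcomes {sorted(outcomes)}")
    outcome = Outcome(next(iter(outcomes))) if outcomes else Outcome.ASTHMA
    entries = tuple(
        CodelistEntry(r.code, r.term, r.source, r.decision, r.reason)
        for r in df.itertuples(index=False)
    )
    return Codelist(outcome=outcome, entries=entries)


def write_codelist(codelist: Codelist, path: str | Path) -> None:
    rows = [
        {
            "outcome": codelist.outcome.value,
            "code": e.code,
            "term": e.term,
            "source": e.source,
            "decision": e.decision,
            "reason": e.reason,
        }
        for e in codelist.entries
    ]
    pd.DataFrame(
        rows, columns=["outcome", "code", "term", "source", "decision", "reason"]
    ).to_csv(path, index=False, lineterminator="\n")
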