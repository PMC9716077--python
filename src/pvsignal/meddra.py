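"""Preferred-term to SMQ-group mapping and indication-bias exclusion.

Adverse events arrive coded at the MedDRA preferred-term (PT) level; a
Standardized MedDRA Query (SMQ) groups PTs describing one medical condition.
Disproportionality against the treated disease's own manifestations is
indication bias, so indication-related PTs (or whole SMQs) can be excluded
before signal detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["SMQMap", "ExclusionList", "UNMAPPED", "load_smq_map", "load_exclusions",
           "assign_groups", "apply_exclusions"]

#: Sentinel group for PTs absent from the mapping.
UNMAPPED = "unmapped"


@dataclass
class SMQMap:
    """PT → SMQ-group mapping with insertion-ordered group list."""

    entries: dict[str, set[str]]
    groups: list[str]

    def lookup(self, pt: str) -> set[str]:
        return self.entries.get(pt, {UNMAPPED})


@dataclass
class ExclusionList:
    """Indication-related PTs and SMQ groups to drop before analysis."""

    excluded_pts: set[str] = field(default_factory=set)
    excluded_smqs: set[str] = field(default_factory=set)


def load_smq_map(path: str | Path) -> SMQMap:
    """Load a two-column TSV (pt, smq); duplicate rows collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("pt", "smq"):
        if col not in df.columns:
            raise ValueError(f"SMQ map missing mandatory column {col!r}")
    if df.empty:
        raise ValueError(f"SMQ map {path} is empty")
    entries: dict[str, set[str]] = {}
    groups: list[str] = []
    for pt, smq in zip(df["pt"], df["smq"]):
        entries.setdefault(pt, set()).add(smq)
        if smq not in groups:
            groups.append(smq)
    return SMQMap(entries=entries, groups=groups)


def load_exclusions(path: str | Path) -> ExclusionList:
    """Load an exclusion TSV with columns (name, kind), kind in {pt, smq}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("name", "kind"):
        if col not in df.columns:
            raise ValueError(f"exclusion list missing mandatory column {col!r}")
    excl = ExclusionList()
    for name, kind in zip(df["name"], df["kind"]):
        if kind == "pt":
            excl.excluded_pts.add(name)
        elif kind == "smq":
            excl.excluded_smqs.add(name)
        else:
            raise ValueError(f"exclusion kind must be 'pt' or 'smq', got {kind!r}")
    return excl


def assign_groups(events: list[str], smq_map: SMQMap) -> dict[str, set[str]]:
    """Map each PT to its SMQ groups; unmapped PTs get the ``unmapped`` sentinel."""
    return {pt: set(smq_map.lookup(pt)) for pt in events}


def apply_exclusions(events: list[str], smq_map: SMQMap, excl: ExclusionList) -> list[str]:
    """Drop excluded PTs, and PTs whose *every* group is excluded; order preserved.

    A PT mapped to both an excluded and a retained SMQ is retained: exclusion
    must be total, so borderline terms stay visible to signal detection.
    """
    out = []
    for pt in events:
        if pt in excl.excluded_pts:
            continue
        groups = smq_map.lookup(pt)
        if groups and groups <= excl.excluded_smqs:
            continue
        out.append(pt)
    return out
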