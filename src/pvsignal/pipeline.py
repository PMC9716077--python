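"""Workflow orchestration: reports → dedup → cohorts → signal tables.

Ties the stages together the way a published disproportionality study is
run: ingest, deduplicate, filter to each drug's primary-suspect cohort,
build all drug×event 2×2 tables against the whole-database background,
compute ROR and BCPNN IC, classify, and order the output by SMQ group and
descending IC−2SD.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .contingency import build_all_tables, round_half_up
from .meddra import ExclusionList, SMQMap, UNMAPPED, apply_exclusions
from .reports import ReportSet
from .stats import (
    BCPNNPriors,
    DEFAULT_PRIORS,
    DEFAULT_THRESHOLDS,
    SignalThresholds,
    bcpnn_ic,
    classify_signal,
    ror,
)

__all__ = ["signal_table", "format_signal_table"]


def signal_table(
    rs: ReportSet,
    lexicon: Mapping[str, str],
    drugs: Sequence[str],
    events: Sequence[str],
    smq_map: SMQMap | None = None,
    exclusions: ExclusionList | None = None,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
    priors: BCPNNPriors = DEFAULT_PRIORS,
) -> pd.DataFrame:
    """Full-statistics signal table for every (drug, event) pair.

    ``rs`` must be deduplicated.  When an SMQ map is given, each event row
    carries its group(s); events removed by the exclusion list are dropped
    before tabulation.  Rows are ordered by SMQ group (map order, unmapped
    last), then descending IC−2SD.
    """
    events = list(dict.fromkeys(events))
    if smq_map is not None and exclusions is not None:
        events = apply_exclusions(events, smq_map, exclusions)

    rows = []
    for drug, event, t in build_all_tables(rs, lexicon, drugs, events):
        r = ror(t, z=thresholds.z)
        i = bcpnn_ic(t, priors)
        cls = classify_signal(r, i, t.a, thresholds)
        groups = sorted(smq_map.lookup(event)) if smq_map is not None else [UNMAPPED]
        rows.append({
            "drug": drug,
            "event": event,
            "smq": "|".join(groups),
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": r.ror, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "ror_defined": r.defined,
            "ic": i.ic, "ic_minus_2sd": i.ic_minus_2sd, "ic_plus_2sd": i.ic_plus_2sd,
            "ror_positive": cls.ror_positive,
            "bcpnn_positive": cls.bcpnn_positive,
            "suspicious": cls.suspicious,
            "tier": cls.tier,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if smq_map is not None:
        order = {g: k for k, g in enumerate(smq_map.groups)}
        df["_g"] = df["smq"].map(lambda s: min(order.get(g, len(order)) for g in s.split("|")))
    else:
        df["_g"] = 0
    df = df.sort_values(["drug", "_g", "ic_minus_2sd"], ascending=[True, True, False])
    return df.drop(columns="_g").reset_index(drop=True)


def format_signal_table(df: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Display copy with statistics rounded half-up (printed-table convention)."""
    out = df.copy()
    for col in ("ror", "ci_low", "ci_high", "ic", "ic_minus_2sd", "ic_plus_2sd"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda x: None if x is None or pd.isna(x) else round_half_up(float(x), ndigits)
            )
    return out
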