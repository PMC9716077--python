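"""Cumulative information-component time scans.

A signal's stability is assessed by recomputing the BCPNN IC on the database
as it stood at the end of each successive quarter: for quarter q the 2×2
table is built from every report received up to and including q (the
background cells accumulate too), and the IC with its ±2SD credibility band
is recorded.  A stable association shows a steady or rising IC with a
narrowing band as reports accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .contingency import ContingencyTable
from .reports import ReportSet, normalize_drug_name, parse_quarter, quarter_key
from .stats import BCPNNPriors, DEFAULT_PRIORS, ICResult, bcpnn_ic

__all__ = ["TimeScanPoint", "TimeScanSeries", "ic_timescan", "bandwidth"]


@dataclass(frozen=True)
class TimeScanPoint:
    """IC state of one drug–event pair at the end of one quarter."""

    quarter: str
    a_cum: int
    ic: float
    band_low: float
    band_high: float
    no_reports: bool  # cumulative a == 0: IC is pure prior shrinkage


@dataclass
class TimeScanSeries:
    """Ordered cumulative-by-quarter IC series for one drug–event pair."""

    drug: str
    event: str
    points: list[TimeScanPoint]


def _quarter_range(start: str, end: str) -> list[str]:
    y0, q0 = parse_quarter(start)
    y1, q1 = parse_quarter(end)
    if (y0, q0) > (y1, q1):
        raise ValueError(f"empty quarter range {start}..{end}")
    out = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        out.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return out


def ic_timescan(
    rs: ReportSet,
    lexicon: Mapping[str, str],
    drug: str,
    event: str,
    start_quarter: str | None = None,
    end_quarter: str | None = None,
    priors: BCPNNPriors = DEFAULT_PRIORS,
) -> TimeScanSeries:
    """Cumulative IC series for one pair over a quarter range.

    Defaults: the range spans from the first quarter with any target-drug
    report to the last quarter present in the data.  The final point equals
    :func:`pvsignal.stats.bcpnn_ic` on the whole-period table.
    """
    if len(rs) == 0:
        raise ValueError("empty ReportSet")
    drug_n = normalize_drug_name(drug)

    # per-report flags, sorted by quarter for a single cumulative sweep
    flagged = sorted(
        (
            (quarter_key(r.receipt_quarter), drug_n in r.primary_suspects(lexicon), event in set(r.reactions))
            for r in rs
        ),
        key=lambda t: t[0],
    )
    if start_quarter is None:
        drug_keys = [k for k, is_d, _ in flagged if is_d]
        if not drug_keys:
            raise ValueError(f"no report has {drug!r} as primary suspect")
        k0 = min(drug_keys)
        start_quarter = f"{k0 // 4}Q{k0 % 4 + 1}"
    if end_quarter is None:
        k1 = flagged[-1][0]
        end_quarter = f"{k1 // 4}Q{k1 % 4 + 1}"
    quarters = _quarter_range(start_quarter, end_quarter)

    points: list[TimeScanPoint] = []
    i = 0
    a = cx = cy = n = 0
    for q in quarters:
        qk = quarter_key(q)
        while i < len(flagged) and flagged[i][0] <= qk:
            _, is_drug, has_event = flagged[i]
            n += 1
            if is_drug:
                cx += 1
            if has_event:
                cy += 1
            if is_drug and has_event:
                a += 1
            i += 1
        t = ContingencyTable(a, cx - a, cy - a, n - cx - cy + a)
        res: ICResult = bcpnn_ic(t, priors)
        points.append(
            TimeScanPoint(
                quarter=q,
                a_cum=a,
                ic=res.ic,
                band_low=res.ic_minus_2sd,
                band_high=res.ic_plus_2sd,
                no_reports=(a == 0),
            )
        )
    return TimeScanSeries(drug=drug, event=event, points=points)


def bandwidth(series: TimeScanSeries) -> list[tuple[str, float]]:
    """Credibility-band width (band_high − band_low) per quarter."""
    if not series.points:
        raise ValueError("empty series")
    return [(p.quarter, p.band_high - p.band_low) for p in series.points]
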