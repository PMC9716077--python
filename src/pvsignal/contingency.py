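"""2×2 contingency tables for drug–event pairs, and recovery from printed marginals.

Disproportionality analysis reduces a report database to one 2×2 table per
(drug, event) pair::

                     target event    other events    total
    target drug           a               b          a + b
    all other drugs       c               d          c + d

with margins C = a+b+c+d (whole database), Cx = a+b (drug cohort),
Cy = a+c (event total) and joint cell Cxy = a.  Reports are counted once per
cell: a report belongs to the drug row iff the drug is among its primary
suspects, and to the event column iff the PT appears anywhere in its reaction
list (a PT listed twice still counts once).
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

from .reports import ReportSet, normalize_drug_name

__all__ = [
    "ContingencyTable",
    "build_table",
    "build_all_tables",
    "recover_table_from_marginals",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how printed tables round."""
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Counts a, b, c, d of one drug–event 2×2 table; margins are derived."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))  # normalize numpy ints

    @property
    def C(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def Cx(self) -> int:
        return self.a + self.b

    @property
    def Cy(self) -> int:
        return self.a + self.c

    @property
    def Cxy(self) -> int:
        return self.a

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _report_flags(rs: ReportSet, lexicon: Mapping[str, str], drugs: Sequence[str],
                  events: Sequence[str]):
    """Per-report (primary-suspect generics ∩ drugs, reactions ∩ events)."""
    drug_set = {normalize_drug_name(d) for d in drugs}
    event_set = set(events)
    for r in rs:
        ps = r.primary_suspects(lexicon) & drug_set
        ev = set(r.reactions) & event_set
        yield ps, ev


def build_table(rs: ReportSet, lexicon: Mapping[str, str], drug: str, event: str) -> ContingencyTable:
    """Build the 2×2 table for one (drug, event) pair from a deduplicated ReportSet."""
    return build_all_tables(rs, lexicon, [drug], [event])[0][2]


def build_all_tables(
    rs: ReportSet, lexicon: Mapping[str, str], drugs: Sequence[str], events: Sequence[str]
) -> list[tuple[str, str, ContingencyTable]]:
    """All drug×event 2×2 tables in one pass over the reports.

    Element-wise identical to calling :func:`build_table` per pair.
    """
    drugs_n = [normalize_drug_name(d) for d in drugs]
    n = len(rs)
    # joint[i][j] counts reports with drug i as primary suspect and event j present
    joint = {(di, ej): 0 for di in drugs_n for ej in events}
    drug_tot = {di: 0 for di in drugs_n}
    event_tot = {ej: 0 for ej in events}
    for ps, ev in _report_flags(rs, lexicon, drugs_n, events):
        for di in ps:
            drug_tot[di] += 1
            for ej in ev:
                joint[(di, ej)] += 1
        for ej in ev:
            event_tot[ej] += 1
    out = []
    for orig_d, di in zip(drugs, drugs_n):
        for ej in events:
            a = joint[(di, ej)]
            b = drug_tot[di] - a
            c = event_tot[ej] - a
            d = n - a - b - c
            out.append((orig_d, ej, ContingencyTable(a, b, c, d)))
    return out


def recover_table_from_marginals(
    a: int,
    drug_total: int,
    grand_total: int,
    ror_printed: float | str,
    ndigits: int | None = None,
) -> tuple[ContingencyTable, bool]:
    """Reconstruct a 2×2 table from a published (a, Cx, C, ROR) quadruple.

    Published signal tables print the joint count ``a`` and the ROR but not
    the background cell ``c``.  Given the drug cohort total Cx and the grand
    total C, this searches the integer ``c`` in [1, C−Cx] whose exact
    ROR = a·d / (b·c) (with b = Cx−a, d = C−Cx−c) rounds half-up to the
    printed value, returning the candidate minimizing |exact − printed|
    (ties toward smaller c).

    Pass ``ror_printed`` as a string to preserve its printed precision, or
    set ``ndigits`` explicitly (default 2).

    Returns ``(table, ambiguous)`` where ``ambiguous`` flags that more than
    one ``c`` was rounding-consistent.  Raises ``ValueError`` when no ``c``
    reproduces the printed ROR (inconsistent marginals).
    """
    if isinstance(ror_printed, str):
        s = ror_printed.strip()
        if ndigits is None:
            ndigits = len(s.split(".")[1]) if "." in s else 0
        ror_val = float(s)
    else:
        ror_val = float(ror_printed)
        if ndigits is None:
            ndigits = 2
    if not (0 < a <= drug_total <= grand_total):
        raise ValueError("require 0 < a <= drug_total <= grand_total")
    if ror_val <= 0:
        raise ValueError("printed ROR must be positive")

    b = drug_total - a
    rest = grand_total - drug_total  # c + d
    if b <= 0 or rest < 2:
        raise ValueError("degenerate marginals: no room for b or c,d")

    # ROR(c) = a(rest−c)/(b·c) is strictly decreasing in c, so the
    # rounding-consistent set is a contiguous integer interval around the
    # analytic inversion c* = a·rest / (b·ror + a).
    half = 0.5 * 10 ** (-ndigits)
    lo_target, hi_target = ror_val - half, ror_val + half

    def inv(r: float) -> float:
        return a * rest / (b * r + a)

    c_lo = max(1, int(inv(hi_target)) - 2)
    c_hi = min(rest - 1, int(inv(max(lo_target, 1e-12))) + 2)
    candidates = []
    for c in range(c_lo, c_hi + 1):
        d = rest - c
        if d <= 0:
            continue
        exact = a * d / (b * c)
        if round_half_up(exact, ndigits) == round_half_up(ror_val, ndigits):
            candidates.append((abs(exact - ror_val), c))
    if not candidates:
        raise ValueError(
            f"no integer c in [1, {rest - 1}] reproduces ROR={ror_val} at {ndigits} dp; "
            "marginals are inconsistent with the printed statistic"
        )
    candidates.sort(key=lambda t: (t[0], t[1]))
    best_c = candidates[0][1]
    return ContingencyTable(a, b, best_c, rest - best_c), len(candidates) > 1
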