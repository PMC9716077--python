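"""Seeded generator of FAERS-like report sets with planted disproportionality.

Spontaneous-report databases cannot be redistributed, so every pipeline stage
is exercised against synthetic report streams instead.  The generator draws
independent reports: each report is assigned to one drug cohort (a target
drug, or the pooled background), then each monitored event is sampled with a
cohort-conditional probability solved from the event's background marginal
rate and the planted odds ratio — so the *population* 2×2 cell probabilities
satisfy the planted odds ratio exactly, and estimators can be checked for
parameter recovery.  Demographics are drawn independently of signal status,
duplicate case versions and multi-PT reports are injected at configurable
rates, and everything is a deterministic function of the seed.

Default rates mimic a large post-marketing ophthalmology cohort: a female
majority, most reports in the 50–79 and 80+ age bands with a large unknown
mass, USA as the dominant reporter country, and a minority of reports
carrying a serious outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contingency import ContingencyTable
from .reports import (
    AEReport,
    DrugEntry,
    ReportSet,
    config_hash,
    normalize_drug_name,
    parse_quarter,
)

__all__ = ["SyntheticConfig", "generate", "realize_table", "solve_joint_cell"]

_FILLER_PTS = (
    "Headache", "Nausea", "Fatigue", "Dizziness", "Pyrexia",
    "Arthralgia", "Rash", "Vision blurred", "Eye pain", "Malaise",
)
_BACKGROUND_DRUGS = (
    "metformin", "lisinopril", "atorvastatin", "omeprazole", "amlodipine",
    "levothyroxine", "ibuprofen", "sertraline", "warfarin", "prednisone",
)


def solve_joint_cell(px: float, py: float, psi: float) -> float:
    """Joint-cell probability p11 with margins (px, py) and odds ratio psi.

    Solves psi = p11·p00 / (p10·p01) for p11, taking the root in
    [max(0, px+py−1), min(px, py)] (the Plackett construction); psi = 1
    returns the independence product.
    """
    if psi <= 0:
        raise ValueError("odds ratio must be positive")
    if abs(psi - 1.0) < 1e-12:
        return px * py
    s = 1.0 + (px + py) * (psi - 1.0)
    disc = s * s - 4.0 * psi * (psi - 1.0) * px * py
    p11 = (s - math.sqrt(disc)) / (2.0 * (psi - 1.0))
    lo, hi = max(0.0, px + py - 1.0), min(px, py)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError(f"no feasible joint cell for margins ({px}, {py}) and OR {psi}")
    return min(max(p11, lo), hi)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic report stream.

    ``drugs`` maps target generic names to cohort fractions (reports whose
    primary suspect is that drug); the remaining mass is the background pool.
    ``events`` maps monitored PTs to their marginal background rates.
    ``planted_signals`` lists (drug, event, odds_ratio) triples; at most one
    drug may plant a signal on a given event, so the planted odds ratio
    against the pooled complement is exact.
    """

    seed: int = 0
    n_reports: int = 10_000
    drugs: dict[str, float] = field(default_factory=lambda: {"drugx": 0.05})
    events: dict[str, float] = field(default_factory=lambda: {"Event of interest": 0.01})
    planted_signals: list[tuple[str, str, float]] = field(default_factory=list)
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"female": 0.47, "male": 0.37, "unknown": 0.16}
    )
    age_band_probs: dict[str, float] = field(
        default_factory=lambda: {"<18": 0.002, "18-49": 0.015, "50-79": 0.23, ">=80": 0.20, "unknown": 0.553}
    )
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {
            "death": 0.24, "disability": 0.03, "life-threatening": 0.015,
            "hospitalization": 0.17, "other": 0.40,
        }
    )
    country_probs: dict[str, float] = field(
        default_factory=lambda: {"US": 0.36, "JP": 0.06, "DE": 0.03, "other": 0.55}
    )
    start_quarter: str = "2004Q1"
    end_quarter: str = "2021Q3"
    duplicate_case_rate: float = 0.0
    multi_pt_rate: float = 0.0
    concomitant_rate: float = 0.2
    filler_events: tuple[str, ...] = _FILLER_PTS
    background_drugs: tuple[str, ...] = _BACKGROUND_DRUGS

    def lexicon(self) -> dict[str, str]:
        """Identity drug-name lexicon covering the configured target drugs."""
        return {normalize_drug_name(d): normalize_drug_name(d) for d in self.drugs}

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        total = sum(self.drugs.values())
        if any(f < 0 for f in self.drugs.values()) or total > 1.0 + 1e-12:
            raise ValueError("drug cohort fractions must be non-negative and sum to <= 1")
        if any(not (0.0 <= r <= 1.0) for r in self.events.values()):
            raise ValueError("event rates must lie in [0, 1]")
        for p in (self.sex_probs, self.age_band_probs, self.country_probs):
            if abs(sum(p.values()) - 1.0) > 1e-9:
                raise ValueError("categorical probabilities must sum to 1")
        if not (0.0 <= self.duplicate_case_rate < 1.0):
            raise ValueError("duplicate_case_rate must lie in [0, 1)")
        parse_quarter(self.start_quarter)
        parse_quarter(self.end_quarter)
        seen_events: set[str] = set()
        for drug, event, psi in self.planted_signals:
            if drug not in self.drugs:
                raise ValueError(f"planted signal names unknown drug {drug!r}")
            if event not in self.events:
                raise ValueError(f"planted signal names unknown event {event!r}")
            if event in seen_events:
                raise ValueError(f"event {event!r} has more than one planted signal")
            seen_events.add(event)
            px, py = self.drugs[drug], self.events[event]
            # degenerate margins leave no room to tilt the joint cell
            if not (0.0 < px < 1.0 and 0.0 < py < 1.0):
                raise ValueError(
                    f"infeasible planted pair ({drug!r}, {event!r}, OR={psi}): "
                    f"margins ({px}, {py}) admit no cell probabilities in (0, 1)"
                )
            p11 = solve_joint_cell(px, py, psi)  # raises if infeasible
            if not (0.0 <= p11 / px <= 1.0) or not (0.0 <= (py - p11) / (1 - px) <= 1.0):
                raise ValueError(f"infeasible planted pair ({drug!r}, {event!r}, OR={psi})")


def _sample_categorical(rng: np.ndarray, probs: dict[str, float], n: int, rand) -> np.ndarray:
    names = list(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    p = p / p.sum()
    idx = rand.choice(len(names), size=n, p=p)
    return np.array(names, dtype=object)[idx]


_AGE_SAMPLERS = {
    "<18": (1.0, 17.0),
    "18-49": (18.0, 49.0),
    "50-79": (50.0, 79.0),
    ">=80": (80.0, 99.0),
}


def generate(cfg: SyntheticConfig) -> ReportSet:
    """Draw a synthetic ReportSet; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports

    drug_names = list(cfg.drugs)
    cohorts = drug_names + ["__background__"]
    fracs = np.array([cfg.drugs[d] for d in drug_names] + [1.0 - sum(cfg.drugs.values())])
    fracs = np.clip(fracs, 0.0, None)
    fracs = fracs / fracs.sum()
    cohort_idx = rng.choice(len(cohorts), size=n, p=fracs)

    planted = {event: (drug, psi) for drug, event, psi in cfg.planted_signals}
    event_names = list(cfg.events)
    has_event = np.zeros((n, len(event_names)), dtype=bool)
    for j, ev in enumerate(event_names):
        py = cfg.events[ev]
        rate = np.full(n, py)
        if ev in planted:
            drug, psi = planted[ev]
            px = cfg.drugs[drug]
            p11 = solve_joint_cell(px, py, psi)
            di = drug_names.index(drug)
            in_cohort = cohort_idx == di
            if px > 0:
                rate[in_cohort] = p11 / px
            if px < 1:
                rate[~in_cohort] = (py - p11) / (1.0 - px)
        has_event[:, j] = rng.random(n) < rate

    n_extra = rng.poisson(cfg.multi_pt_rate, size=n) if cfg.multi_pt_rate > 0 else np.zeros(n, dtype=int)
    # rows with no monitored event and no extras still need one PT
    need_filler = (~has_event.any(axis=1)) & (n_extra == 0)
    n_extra = n_extra + need_filler.astype(int)
    filler_idx = rng.integers(0, len(cfg.filler_events), size=int(n_extra.sum()))

    sex = _sample_categorical(rng, cfg.sex_probs, n, rng)
    bands = _sample_categorical(rng, cfg.age_band_probs, n, rng)
    age_u = rng.random(n)
    # vectorized age draw within band; None where the band is "unknown"
    lo = np.array([_AGE_SAMPLERS.get(b, (0.0, 0.0))[0] for b in bands])
    hi = np.array([_AGE_SAMPLERS.get(b, (0.0, 0.0))[1] for b in bands])
    ages_num = np.round(lo + age_u * (hi - lo), 1)
    ages = [None if b == "unknown" else float(a) for b, a in zip(bands, ages_num)]
    country = _sample_categorical(rng, cfg.country_probs, n, rng)
    # outcome combinations as a bitmask so frozensets are shared, not rebuilt
    outcome_names = list(cfg.outcome_probs)
    omask = np.zeros(n, dtype=np.int64)
    for j, (k, p) in enumerate(cfg.outcome_probs.items()):
        omask |= (rng.random(n) < p).astype(np.int64) << j
    outcome_cache = {
        m: frozenset(k for j, k in enumerate(outcome_names) if m >> j & 1)
        for m in np.unique(omask)
    }

    k0 = parse_quarter(cfg.start_quarter)
    k1 = parse_quarter(cfg.end_quarter)
    key0, key1 = k0[0] * 4 + k0[1] - 1, k1[0] * 4 + k1[1] - 1
    qkeys = rng.integers(key0, key1 + 1, size=n)
    quarters = [f"{k // 4}Q{k % 4 + 1}" for k in qkeys]

    bg_drug_idx = rng.integers(0, len(cfg.background_drugs), size=n)
    conc = rng.random(n) < cfg.concomitant_rate
    conc_idx = rng.integers(0, len(cfg.background_drugs), size=n)

    n_dup_cases = int(round(cfg.duplicate_case_rate * n))
    dup_cases = set(rng.choice(n, size=n_dup_cases, replace=False).tolist()) if n_dup_cases else set()
    dup_extra = rng.integers(1, 4, size=n)  # versions below the final one

    ps_entry = {
        name: DrugEntry(name, normalize_drug_name(name), "primary-suspect")
        for name in drug_names + list(cfg.background_drugs)
    }
    conc_entry = {
        name: DrugEntry(name, normalize_drug_name(name), "concomitant")
        for name in cfg.background_drugs
    }

    reports: list[AEReport] = []
    cohort_counts = {d: 0 for d in drug_names}
    fpos = 0
    ev_rows = has_event.tolist()
    n_drugs = len(drug_names)
    cohort_list = cohort_idx.tolist()
    conc_list = conc.tolist()
    extra_list = n_extra.tolist()
    sex_list = sex.tolist()
    country_list = country.tolist()
    omask_list = omask.tolist()
    for i in range(n):
        ci = cohort_list[i]
        if ci < n_drugs:
            ps_name = drug_names[ci]
            cohort_counts[ps_name] += 1
        else:
            ps_name = cfg.background_drugs[bg_drug_idx[i]]
        drugs = [ps_entry[ps_name]]
        if conc_list[i]:
            drugs.append(conc_entry[cfg.background_drugs[conc_idx[i]]])
        pts = [ev for ev, flag in zip(event_names, ev_rows[i]) if flag]
        for _ in range(extra_list[i]):
            pts.append(cfg.filler_events[filler_idx[fpos]])
            fpos += 1
        # dedupe within-report PT repeats, order-preserving
        pts = list(dict.fromkeys(pts))
        outcomes = outcome_cache[omask_list[i]]
        case_id = f"C{i:08d}"
        final_version = 1 + (int(dup_extra[i]) if i in dup_cases else 0)
        for ver in range(1, final_version + 1):
            reports.append(
                AEReport(
                    report_id=f"R{i:08d}.{ver}",
                    case_id=case_id,
                    case_version=ver,
                    receipt_quarter=quarters[i],
                    drugs=list(drugs),
                    reactions=list(pts),
                    sex=sex_list[i],
                    age_years=ages[i],
                    outcomes=outcomes,
                    country=country_list[i],
                )
            )

    return ReportSet(
        reports,
        provenance={
            "generator": "pvsignal.synth.generate",
            "config_hash": config_hash(cfg),
            "seed": cfg.seed,
            "n_cases": n,
            "n_reports_emitted": len(reports),
            "cohort_counts": cohort_counts,
        },
    )


def realize_table(
    t: ContingencyTable,
    drug: str = "drugx",
    event: str = "Event of interest",
    other_drug: str = "backgrounddrug",
    other_event: str = "Background event",
    quarter: str = "2020Q1",
) -> ReportSet:
    """Materialize a 2×2 table as exactly a+b+c+d single-PT reports.

    ``build_table`` on the result returns ``t`` cell-for-cell, which makes
    any published table an executable end-to-end fixture.
    """
    reports: list[AEReport] = []
    spec = [
        (t.a, drug, event),
        (t.b, drug, other_event),
        (t.c, other_drug, event),
        (t.d, other_drug, other_event),
    ]
    i = 0
    for count, dname, ename in spec:
        for _ in range(count):
            reports.append(
                AEReport(
                    report_id=f"R{i:08d}",
                    case_id=f"C{i:08d}",
                    case_version=1,
                    receipt_quarter=quarter,
                    drugs=[DrugEntry(dname, normalize_drug_name(dname), "primary-suspect")],
                    reactions=[ename],
                )
            )
            i += 1
    return ReportSet(reports, provenance={"generator": "pvsignal.synth.realize_table",
                                          "table": t.cells()})
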