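"""Cohort characterization: demographics, serious outcomes, reporter countries.

Summarizes one drug's deduplicated primary-suspect cohort the way published
pharmacovigilance descriptive tables do: counts and percentages by sex, age
band (<18, 18–49, 50–79, ≥80, unknown), serious outcome, and reporter
country.  Unknown sex/age/country are first-class categories, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .contingency import round_half_up
from .reports import ReportSet, filter_primary_suspect

__all__ = ["DemographicsSummary", "summarize", "AGE_BANDS", "SERIOUS_OUTCOMES"]

AGE_BANDS = ("<18", "18-49", "50-79", ">=80", "unknown")
SERIOUS_OUTCOMES = ("death", "disability", "life-threatening", "hospitalization")


def _age_band(age: float | None) -> str:
    if age is None:
        return "unknown"
    if age < 18:
        return "<18"
    if age < 50:
        return "18-49"
    if age < 80:
        return "50-79"
    return ">=80"


@dataclass
class DemographicsSummary:
    """Counts and percentages for one drug cohort, by category family.

    ``n_events`` is the number of *deduplicated reports* in the cohort (the
    denominator of every percentage).  Sex, age and country blocks each sum
    to ``n_events``.  A report is counted once per serious-outcome code it
    carries but once overall in ``serious_total`` (codes are not mutually
    exclusive).
    """

    drug: str
    n_events: int
    sex: dict[str, int] = field(default_factory=dict)
    age: dict[str, int] = field(default_factory=dict)
    outcomes: dict[str, int] = field(default_factory=dict)
    serious_total: int = 0
    country: dict[str, int] = field(default_factory=dict)

    def pct(self, count: int) -> float | None:
        """Percentage of the cohort, 1 dp half-up; None for an empty cohort."""
        if self.n_events == 0:
            return None
        return round_half_up(100.0 * count / self.n_events, 1)

    def as_dict(self) -> dict:
        def block(counts: Mapping[str, int]) -> dict:
            return {k: {"count": v, "pct": self.pct(v)} for k, v in counts.items()}

        return {
            "drug": self.drug,
            "n_events": self.n_events,
            "sex": block(self.sex),
            "age": block(self.age),
            "serious_outcomes": block(self.outcomes),
            "serious_total": {"count": self.serious_total, "pct": self.pct(self.serious_total)},
            "country": block(self.country),
        }


def summarize(rs: ReportSet, lexicon: Mapping[str, str], drug: str) -> DemographicsSummary:
    """Characterize the deduplicated primary-suspect cohort of ``drug``.

    ``rs`` should already be deduplicated; the primary-suspect filter is
    applied here (idempotent if already applied).
    """
    cohort = filter_primary_suspect(rs, lexicon, drug)
    s = DemographicsSummary(drug=drug, n_events=len(cohort))
    s.sex = {k: 0 for k in ("female", "male", "unknown")}
    s.age = {k: 0 for k in AGE_BANDS}
    s.outcomes = {k: 0 for k in SERIOUS_OUTCOMES}
    for r in cohort:
        s.sex[r.sex] += 1
        s.age[_age_band(r.age_years)] += 1
        serious = False
        for code in SERIOUS_OUTCOMES:
            if code in r.outcomes:
                s.outcomes[code] += 1
                serious = True
        if serious:
            s.serious_total += 1
        s.country[r.country] = s.country.get(r.country, 0) + 1
    return s
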