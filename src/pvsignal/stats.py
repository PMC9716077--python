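"""Disproportionality statistics: reporting odds ratio and BCPNN information component.

Two complementary detectors are computed per 2×2 table:

* **ROR** (reporting odds ratio), the frequentist detector:
  ROR = a·d / (b·c), with Wald 95% CI
  exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)), z = 1.96.
  Undefined when any cell is zero (no continuity correction is applied; the
  a ≥ 3 gate handles sparse pairs).

* **IC** (information component), the Bayesian shrinkage detector of the
  BCPNN: the posterior expectation of log₂ of the observed-to-expected joint
  reporting ratio under independent Dirichlet priors on the margins and the
  joint cell,

      E(IC) = log₂ [ (Cxy+γ₁₁)(C+α)(C+β) / ((C+γ)(Cx+α₁)(Cy+β₁)) ]
      γ     = γ₁₁ (C+α)(C+β) / ((Cx+α₁)(Cy+β₁))
      V(IC) = ln2⁻² [ (C−Cxy+γ−γ₁₁)/((Cxy+γ₁₁)(1+C+γ))
                    + (C−Cx+α−α₁)/((Cx+α₁)(1+C+α))
                    + (C−Cy+β−β₁)/((Cy+β₁)(1+C+β)) ]

  with the customary priors α₁=β₁=γ₁₁=1, α=β=2.  IC−2SD = E(IC) − 2√V(IC)
  is the lower credibility bound; it is finite for every non-negative table,
  including a = 0, because the priors regularize all cells.

A pair is a *suspicious signal* when both detectors fire (a ≥ 3, CI lower
bound > 1, IC−2SD > 0); IC−2SD ≥ 1.5 marks medium-to-strong strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .contingency import ContingencyTable

__all__ = [
    "BCPNNPriors",
    "RORResult",
    "ICResult",
    "SignalThresholds",
    "SignalClassification",
    "ror",
    "bcpnn_ic",
    "classify_signal",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class BCPNNPriors:
    """Dirichlet hyper-parameters of the BCPNN; defaults are the customary ones."""

    alpha1: float = 1.0
    alpha: float = 2.0
    beta1: float = 1.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha", "beta1", "beta", "gamma11"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior {name} must be positive")

    def gamma(self, C: float, Cx: float, Cy: float) -> float:
        """Joint-cell prior scaled so prior E(IC) is 0 at independence."""
        return self.gamma11 * (C + self.alpha) * (C + self.beta) / (
            (Cx + self.alpha1) * (Cy + self.beta1)
        )


DEFAULT_PRIORS = BCPNNPriors()


@dataclass(frozen=True)
class RORResult:
    """Reporting odds ratio with Wald 95% CI; ``defined`` is False on zero cells."""

    ror: float | None
    ci_low: float | None
    ci_high: float | None
    defined: bool


@dataclass(frozen=True)
class ICResult:
    """BCPNN information component (bits) with its ±2SD credibility bounds."""

    ic: float
    var_ic: float
    ic_minus_2sd: float
    ic_plus_2sd: float


@dataclass(frozen=True)
class SignalThresholds:
    """Decision thresholds for signal classification."""

    min_a: int = 3
    ci_low_gt: float = 1.0
    ic2sd_gt: float = 0.0
    tier_cut: float = 1.5
    z: float = 1.96


DEFAULT_THRESHOLDS = SignalThresholds()


@dataclass(frozen=True)
class SignalClassification:
    """Joint decision of the two detectors for one drug–event pair."""

    ror_positive: bool
    bcpnn_positive: bool
    suspicious: bool
    tier: str  # none | weak | medium-strong
    n_reports: int


def ror(t: ContingencyTable, z: float = 1.96) -> RORResult:
    """Reporting odds ratio a·d/(b·c) with Wald CI; undefined on any zero cell."""
    a, b, c, d = t.cells()
    if min(a, b, c, d) == 0:
        return RORResult(None, None, None, defined=False)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_est = math.log(est)
    return RORResult(
        ror=est,
        ci_low=math.exp(log_est - z * se),
        ci_high=math.exp(log_est + z * se),
        defined=True,
    )


def bcpnn_ic(t: ContingencyTable, priors: BCPNNPriors = DEFAULT_PRIORS) -> ICResult:
    """BCPNN expected information component and its variance, in bits."""
    a = t.Cxy
    C, Cx, Cy = t.C, t.Cx, t.Cy
    p = priors
    g = p.gamma(C, Cx, Cy)
    ic = math.log2(
        (a + p.gamma11) * (C + p.alpha) * (C + p.beta)
        / ((C + g) * (Cx + p.alpha1) * (Cy + p.beta1))
    )
    var = (1.0 / _LN2**2) * (
        (C - a + g - p.gamma11) / ((a + p.gamma11) * (1 + C + g))
        + (C - Cx + p.alpha - p.alpha1) / ((Cx + p.alpha1) * (1 + C + p.alpha))
        + (C - Cy + p.beta - p.beta1) / ((Cy + p.beta1) * (1 + C + p.beta))
    )
    sd2 = 2.0 * math.sqrt(var)
    return ICResult(ic=ic, var_ic=var, ic_minus_2sd=ic - sd2, ic_plus_2sd=ic + sd2)


def classify_signal(
    r: RORResult,
    i: ICResult,
    a: int,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
) -> SignalClassification:
    """Combine the two detectors into the suspicious-signal decision and strength tier."""
    th = thresholds
    ror_pos = a >= th.min_a and r.defined and r.ci_low > th.ci_low_gt
    bcpnn_pos = a >= th.min_a and i.ic_minus_2sd > th.ic2sd_gt
    if i.ic_minus_2sd >= th.tier_cut and bcpnn_pos:
        tier = "medium-strong"
    elif bcpnn_pos:
        tier = "weak"
    else:
        tier = "none"
    return SignalClassification(
        ror_positive=ror_pos,
        bcpnn_positive=bcpnn_pos,
        suspicious=ror_pos and bcpnn_pos,
        tier=tier,
        n_reports=a,
    )
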