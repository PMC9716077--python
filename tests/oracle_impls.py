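"""Independent high-precision re-implementations of the disproportionality
statistics, used only as test oracles.

These deliberately avoid the package's code paths: the ROR is formed with
exact rational arithmetic, and both the Wald interval and the BCPNN moments
are evaluated with 50-digit ``decimal`` arithmetic from first principles.
"""

from decimal import Decimal, getcontext
from fractions import Fraction

getcontext().prec = 50

_TWO = Decimal(2)
_LN2 = _TWO.ln()


def ror_exact(a: int, b: int, c: int, d: int) -> Fraction:
    return Fraction(a * d, b * c)


def ror_ci_decimal(a: int, b: int, c: int, d: int, z: str = "1.96"):
    """Wald 95% CI of the log odds ratio in 50-digit decimal arithmetic."""
    est = Decimal(a * d) / Decimal(b * c)
    se = (Decimal(1) / a + Decimal(1) / b + Decimal(1) / c + Decimal(1) / d).sqrt()
    zz = Decimal(z)
    lo = (est.ln() - zz * se).exp()
    hi = (est.ln() + zz * se).exp()
    return lo, hi


def bcpnn_decimal(a: int, b: int, c: int, d: int):
    """BCPNN E(IC), V(IC) and IC−2SD with default priors, 50-digit decimals."""
    C = Decimal(a + b + c + d)
    Cx = Decimal(a + b)
    Cy = Decimal(a + c)
    Cxy = Decimal(a)
    a1 = b1 = g11 = Decimal(1)
    al = be = Decimal(2)
    g = g11 * (C + al) * (C + be) / ((Cx + a1) * (Cy + b1))
    ic = ((Cxy + g11) * (C + al) * (C + be) / ((C + g) * (Cx + a1) * (Cy + b1))).ln() / _LN2
    v = (
        (C - Cxy + g - g11) / ((Cxy + g11) * (1 + C + g))
        + (C - Cx + al - a1) / ((Cx + a1) * (1 + C + al))
        + (C - Cy + be - b1) / ((Cy + b1) * (1 + C + be))
    ) / (_LN2 * _LN2)
    return ic, v, ic - _TWO * v.sqrt()


def agree_sig_digits(x: float, y, digits: int) -> bool:
    """True when x matches the reference y to at least `digits` significant digits."""
    y = float(y)
    if y == 0:
        return abs(x) < 10 ** (-digits)
    return abs(x - y) <= abs(y) * 10 ** (-digits)
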