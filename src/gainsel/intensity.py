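"""Truncation-selection intensity under a normal index distribution.

For truncation selection keeping the upper fraction p of a normally
distributed index, the selection intensity (standardised selection
differential) is the mean of the retained tail:

    i(p) = phi(z) / p,    z = upper-p quantile of N(0, 1),

the classical infinite-population result. i is strictly decreasing in p,
diverges as p -> 0 and vanishes as p -> 1, which makes the inverse map
(from a required intensity back to the fraction of candidates a breeder
may keep) well defined; it is computed here by bisection.

A finite-population correction (Burrows' approximation) is available for
comparing against small simulated populations; the infinite-population
formula is the default everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect
from scipy.stats import norm

_P_LO = 1e-15
_P_HI = 1.0 - 1e-13


@dataclass(frozen=True)
class TruncationPoint:
    """A consistent (p, z, i) triple for normal truncation selection."""

    p: float  # selected upper-tail fraction
    z: float  # truncation threshold on the standard normal
    i: float  # intensity = mean of the selected tail = phi(z)/p


def intensity_from_fraction(p: float, n_total: int | None = None) -> float:
    """Selection intensity for keeping the top fraction ``p``.

    With ``n_total`` the infinite-population intensity is adjusted by
    Burrows' finite-sample approximation, i - (1 - p) / (2 i p N); useful
    when comparing against small simulated populations, never needed for
    the analytical pipeline.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"selected fraction must be in (0, 1), got {p}")
    z = norm.isf(p)
    i = float(norm.pdf(z) / p)
    if n_total is not None:
        if n_total < 2:
            raise ValueError("finite-population correction needs n_total >= 2")
        i = i - (1.0 - p) / (2.0 * i * p * n_total)
    return i


def fraction_from_intensity(i: float) -> float:
    """Selected fraction p whose truncation intensity equals ``i``.

    Inverts intensity_from_fraction by bisection on p (valid by strict
    monotonicity) to |dp| < 1e-10. Intensities below the p -> 1 limit are
    clamped to p ~ 1 with a warning.
    """
    if i <= 0.0:
        raise ValueError(f"selection intensity must be positive, got {i}")
    if i <= intensity_from_fraction(_P_HI):
        warnings.warn(
            f"intensity {i:.3g} is below the everything-selected limit; returning p ~ 1",
            stacklevel=2,
        )
        return _P_HI
    if i >= intensity_from_fraction(_P_LO):
        raise ValueError(f"intensity {i:.3g} too extreme to invert (p < {_P_LO})")
    return float(
        bisect(lambda p: intensity_from_fraction(p) - i, _P_LO, _P_HI, xtol=1e-12)
    )


def truncation_point(
    p: float | None = None, i: float | None = None
) -> TruncationPoint:
    """Complete a (p, z, i) triple from either the fraction or the intensity."""
    if (p is None) == (i is None):
        raise ValueError("give exactly one of p or i")
    if p is None:
        p = fraction_from_intensity(float(i))
    p = float(p)
    z = float(norm.isf(p))
    return TruncationPoint(p=p, z=z, i=intensity_from_fraction(p))
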