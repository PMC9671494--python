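"""Native circular statistics.

Angles are handled in degrees throughout (the unit used everywhere else in
the package).  The module provides the circular mean / mean resultant
length, the Rayleigh uniformity test with the standard finite-n series
p-value approximation, and Holm-Bonferroni step-down correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "CircularSummary",
    "circular_mean",
    "resultant_length",
    "rayleigh_test",
    "holm_bonferroni",
]

#: Resultant lengths below this are treated as "no preferred direction";
#: the mean angle is then undefined (NaN).
UNDEFINED_RESULTANT = 1e-12


@dataclass(frozen=True)
class CircularSummary:
    """Summary of a circular sample.

    Attributes
    ----------
    n : int
        Number of angles.
    mean_angle : float
        Mean direction in degrees in [0, 360), NaN when undefined.
    resultant : float
        Mean resultant length, in [0, 1].
    rayleigh_z : float
        Rayleigh statistic, ``n * resultant**2``.
    p : float
        Rayleigh-test p-value in (0, 1].
    """

    n: int
    mean_angle: float
    resultant: float
    rayleigh_z: float
    p: float


def _to_radians(angles_deg) -> np.ndarray:
    a = np.asarray(angles_deg, dtype=float)
    if a.ndim != 1:
        a = a.ravel()
    if a.size == 0:
        raise ConfigError("angles: need at least one angle")
    if not np.all(np.isfinite(a)):
        raise ConfigError("angles: non-finite values present")
    return np.deg2rad(a)


def circular_mean(angles_deg, weights=None) -> tuple[float, float]:
    """Mean direction and mean resultant length of a set of angles.

    Parameters
    ----------
    angles_deg : array-like
        Angles in degrees.
    weights : array-like, optional
        Non-negative weights (defaults to equal weights).

    Returns
    -------
    (mean_angle, resultant)
        Mean angle in degrees in [0, 360) (NaN if the resultant length is
        below ``UNDEFINED_RESULTANT``) and the mean resultant length.
    """
    rad = _to_radians(angles_deg)
    if weights is None:
        c = np.cos(rad).mean()
        s = np.sin(rad).mean()
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != rad.shape or np.any(w < 0):
            raise ConfigError("weights: must be non-negative, same length as angles")
        tot = w.sum()
        if tot <= 0:
            raise ConfigError("weights: must not all be zero")
        c = float(np.cos(rad) @ w) / tot
        s = float(np.sin(rad) @ w) / tot
    resultant = float(np.hypot(c, s))
    if resultant < UNDEFINED_RESULTANT:
        return float("nan"), resultant
    mean = float(np.rad2deg(np.arctan2(s, c))) % 360.0
    if mean >= 360.0:  # guards the float edge case (-eps % 360 == 360.0)
        mean = 0.0
    return mean, resultant


def resultant_length(angles_deg) -> float:
    """Mean resultant length of a set of angles in degrees."""
    return circular_mean(angles_deg)[1]


def _rayleigh_p(n: int, z: float) -> float:
    # Finite-n series approximation (Zar-style correction of exp(-z)).
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(np.clip(p, np.nextafter(0.0, 1.0), 1.0))


def rayleigh_test(angles_deg=None, *, n: int | None = None,
                  resultant: float | None = None) -> CircularSummary:
    """Rayleigh test of circular uniformity.

    Either pass raw ``angles_deg``, or the sufficient statistics ``n`` and
    ``resultant`` (mean resultant length).  The statistic is
    ``z = n * resultant**2``; the p-value uses the standard finite-n series
    approximation, clipped to (0, 1].
    """
    if angles_deg is not None:
        rad = _to_radians(angles_deg)
        n = rad.size
        mean_angle, resultant = circular_mean(angles_deg)
    else:
        if n is None or resultant is None:
            raise ConfigError("rayleigh_test: need angles or both n and resultant")
        if not 0.0 <= resultant <= 1.0:
            raise ConfigError("resultant: must lie in [0, 1]")
        mean_angle = float("nan")
    if n < 2:
        raise ConfigError("n: Rayleigh test needs at least 2 angles")
    z = n * resultant**2
    return CircularSummary(n=int(n), mean_angle=mean_angle,
                           resultant=float(resultant),
                           rayleigh_z=float(z), p=_rayleigh_p(int(n), z))


def holm_bonferroni(pvalues, alpha: float = 0.05):
    """Holm-Bonferroni step-down adjustment.

    Returns ``(adjusted, reject)`` in the original order.  Adjusted p-values
    are monotone in the sorted order and capped at 1; ``reject`` flags use
    ``adjusted <= alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("pvalues: must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= alpha
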