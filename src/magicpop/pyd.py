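"""Protein-yield deviation (PYD).

Grain yield (GY) and grain protein content (GPC) trade off along a negative
trend. PYD quantifies how far each line sits off that trend: both traits are
Z-scored, a symmetric Theil-Sen line is fitted (median of pairwise segment
angles, so the fit is equivariant under exchanging the axes), and PYD is the
signed perpendicular distance of each line from the fitted trend — positive
above the line, i.e. more protein than the yield trade-off predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PydResult", "zscore", "theilsen_symmetric", "pyd_scores"]


@dataclass
class PydResult:
    slope: float
    intercept: float
    pyd: np.ndarray  # signed perpendicular deviation per line, sd units
    gy_z: np.ndarray
    gpc_z: np.ndarray


def zscore(v) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd, ddof=1)."""
    v = np.asarray(v, dtype=float)
    s = v.std(ddof=1)
    if s == 0:
        raise ValueError("constant vector cannot be Z-scored")
    return (v - v.mean()) / s


def _circular_median_halfpi(phi: np.ndarray) -> float:
    """Geodesic median of undirected angles on the half-circle [0, pi).

    Minimizes sum_i d(theta, phi_i) with d(a, b) = min(|a-b|, pi-|a-b|),
    the geodesic distance on a circle of circumference pi. The cost is
    piecewise linear with minima only at data angles, so all data angles are
    evaluated (vectorized with prefix sums); a flat valley (even counts) is
    resolved at its midpoint. Reflections of the circle are isometries, so
    the median of reflected angles is the reflected median — this is what
    makes the symmetric Theil-Sen fit exactly axis-exchange equivariant.
    """
    a = np.sort(np.mod(phi, np.pi))
    m = a.size
    S = np.concatenate([[0.0], np.cumsum(a)])
    c = a  # candidates
    # right side: points >= c; near if a_i - c <= pi/2
    k = np.arange(m)
    j_hi = np.searchsorted(a, c + np.pi / 2, side="right")
    # left side: points < c; near if c - a_i <= pi/2
    j_lo = np.searchsorted(a, c - np.pi / 2, side="left")
    sum_near_r = S[j_hi] - S[k]
    n_near_r = j_hi - k
    sum_far_r = S[m] - S[j_hi]
    n_far_r = m - j_hi
    sum_near_l = S[k] - S[j_lo]
    n_near_l = k - j_lo
    sum_far_l = S[j_lo]
    n_far_l = j_lo
    cost = (
        (sum_near_r - n_near_r * c)
        + (n_far_r * (np.pi + c) - sum_far_r)
        + (n_near_l * c - sum_near_l)
        + (n_far_l * (np.pi - c) + sum_far_l)
    )
    cmin = cost.min()
    winners = np.flatnonzero(cost <= cmin + 1e-9 * max(1.0, abs(cmin)))
    if winners.size == 1:
        return float(a[winners[0]])
    # flat valley: contiguous run of minimizers -> geodesic midpoint
    lo, hi = a[winners[0]], a[winners[-1]]
    if hi - lo <= np.pi / 2:
        return float((lo + hi) / 2)
    return float(np.mod((hi + lo + np.pi) / 2, np.pi))  # valley wraps around 0


def theilsen_symmetric(x, y):
    """Symmetric Theil-Sen line: tan of the median pairwise segment angle.

    For every point pair the segment angle atan2(dy, dx) is folded onto the
    half-circle of undirected line directions and the circular (geodesic)
    median angle taken; the slope is its tangent and the intercept is
    median(y - slope x). Because the circular median commutes with rotations
    and reflections of the direction circle, swapping the axes maps the
    fitted slope to its reciprocal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    ii, jj = np.triu_indices(x.size, k=1)
    dx = x[jj] - x[ii]
    dy = y[jj] - y[ii]
    keep = (dx != 0) | (dy != 0)
    if not keep.any():
        raise ValueError("all points coincide")
    theta = _circular_median_halfpi(np.arctan2(dy[keep], dx[keep]))
    slope = float(np.tan(theta))
    intercept = float(np.median(y - slope * x))
    return slope, intercept


def pyd_scores(gy, gpc) -> PydResult:
    """PYD for each line from raw GY and GPC vectors.

    Both traits are Z-scored, the symmetric Theil-Sen trend of GPC on GY is
    fitted, and PYD = (GPC_z - (a + b GY_z)) / sqrt(1 + b^2): the signed
    perpendicular distance, positive above the trend.
    """
    gy_z = zscore(gy)
    gpc_z = zscore(gpc)
    b, a = theilsen_symmetric(gy_z, gpc_z)
    pyd = (gpc_z - (a + b * gy_z)) / np.sqrt(1.0 + b * b)
    return PydResult(slope=b, intercept=a, pyd=pyd, gy_z=gy_z, gpc_z=gpc_z)
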