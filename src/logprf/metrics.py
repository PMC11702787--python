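"""Reliability and performance statistics.

Test-retest reliability of pRF estimates is quantified per parameter:
Spearman rank correlation for eccentricity and size, and — because polar
angle is circular — the Fisher & Lee (1983) T-linear circular correlation
coefficient. Correlations are normalized with the Fisher z (arctanh)
transform before any averaging or regression. Only units passing the
retention filters in BOTH sessions enter a reliability comparison.

Note the circular coefficient: several inequivalent "circular
correlations" exist in the literature (e.g., Jammalamadaka–SenGupta); the
one implemented here is Fisher–Lee, which is invariant to independent
rotations of either variable and equals -1 under reflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "spearman_reliability",
    "circular_correlation",
    "fisher_z",
    "behavioral_performance",
    "binned_summary",
    "ReliabilityReport",
    "reliability_report",
]


def _check_pair(a, b, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    return a, b


def spearman_reliability(a, b) -> float:
    """Spearman rank correlation (average ranks for ties).

    Constant input leaves the rank correlation undefined: returns NaN.
    """
    a, b = _check_pair(a, b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(spearmanr(a, b).statistic)


def circular_correlation(theta_a, theta_b) -> float:
    """Fisher–Lee T-linear association between two circular variables
    (radians).

    r = sum_{i<j} sin(a_i-a_j) sin(b_i-b_j)
        / sqrt( sum_{i<j} sin^2(a_i-a_j) * sum_{i<j} sin^2(b_i-b_j) )

    computed in O(n) via trigonometric moment identities. Invariant to
    adding a constant rotation to either input. Degenerate spreads (all
    pairwise sines zero) leave the coefficient undefined: returns NaN.
    """
    a, b = _check_pair(theta_a, theta_b)
    n = a.size

    def _abs2(z: complex) -> float:
        return float(np.abs(z) ** 2)

    e_minus = np.exp(1j * (a - b)).sum()
    e_plus = np.exp(1j * (a + b)).sum()
    num = 0.5 * (_abs2(e_minus) - _abs2(e_plus))
    denom_a = 0.5 * (n**2 - _abs2(np.exp(2j * a).sum()))
    denom_b = 0.5 * (n**2 - _abs2(np.exp(2j * b).sum()))
    if denom_a <= 0 or denom_b <= 0:
        return float("nan")
    return float(num / np.sqrt(denom_a * denom_b))


def fisher_z(r) -> float:
    """Fisher z transform, z = arctanh(r) = 0.5 log((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher z transform")
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def behavioral_performance(n_hit: int, n_false_alarms: int, n_total: int) -> float:
    """Detection performance in percent: (hits - false alarms) / total * 100.

    May be negative when false alarms exceed hits, as the formula dictates.
    """
    if n_hit < 0 or n_false_alarms < 0 or n_total < 0:
        raise ValueError("counts must be non-negative")
    if n_total == 0:
        raise ValueError("n_total must be positive")
    return (n_hit - n_false_alarms) / n_total * 100.0


def binned_summary(x, y, bins) -> pd.DataFrame:
    """Per-bin count, median, mean and standard deviation of ``y`` grouped
    by ``x`` into ``bins`` (edge array). Empty bins are reported with NaN
    summaries, never interpolated."""
    x, y = _check_pair(x, y, min_n=1)
    edges = np.asarray(bins, dtype=float)
    which = np.searchsorted(edges, x, side="right") - 1
    rows = []
    for b in range(edges.size - 1):
        sel = y[(which == b) | ((b == edges.size - 2) & (x == edges[-1]))]
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": sel.size,
                "median": np.median(sel) if sel.size else np.nan,
                "mean": np.mean(sel) if sel.size else np.nan,
                "sd": np.std(sel, ddof=1) if sel.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReliabilityReport:
    """Per-parameter session-1 vs session-2 reliability."""

    n_units: int
    polar_angle_r: float
    eccentricity_rho: float
    sigma_rho: float

    @property
    def polar_angle_z(self) -> float:
        return fisher_z(self.polar_angle_r)

    @property
    def eccentricity_z(self) -> float:
        return fisher_z(self.eccentricity_rho)

    @property
    def sigma_z(self) -> float:
        return fisher_z(self.sigma_rho)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": ["polar_angle", "eccentricity", "sigma"],
                "coefficient": [self.polar_angle_r, self.eccentricity_rho, self.sigma_rho],
                "fisher_z": [self.polar_angle_z, self.eccentricity_z, self.sigma_z],
                "n_units": self.n_units,
            }
        )


def reliability_report(
    session1: pd.DataFrame,
    session2: pd.DataFrame,
    ve_min: float = 0.10,
) -> ReliabilityReport:
    """Unit-by-unit intersession reliability from two estimate tables.

    The tables must carry columns polar_angle, eccentricity, sigma and
    variance_explained aligned unit-by-unit. Only units with variance
    explained above ``ve_min`` in BOTH sessions enter the correlations
    (intersection semantics).
    """
    if len(session1) != len(session2):
        raise ValueError("sessions must contain the same units, unit-by-unit")
    keep = (session1["variance_explained"].to_numpy() > ve_min) & (
        session2["variance_explained"].to_numpy() > ve_min
    )
    s1, s2 = session1[keep], session2[keep]
    if keep.sum() < 3:
        raise ValueError("fewer than 3 units pass retention in both sessions")
    return ReliabilityReport(
        n_units=int(keep.sum()),
        polar_angle_r=circular_correlation(s1["polar_angle"], s2["polar_angle"]),
        eccentricity_rho=spearman_reliability(s1["eccentricity"], s2["eccentricity"]),
        sigma_rho=spearman_reliability(s1["sigma"], s2["sigma"]),
    )
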