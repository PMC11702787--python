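"""Six-parameter double-gamma hemodynamic response function (HRF).

The BOLD impulse response is modeled as a difference of two gamma
densities with an onset delay:

    h(t) = g(t - delta; alpha1, beta1) - g(t - delta; alpha2, beta2) / ratio

where g(.; a, b) is the gamma density with shape a and rate b. The first
term is the positive response (peak near 5-6 s for canonical values), the
second the post-stimulus undershoot, and ``ratio`` sets peak-to-undershoot
amplitude. h(t) = 0 for t <= delta (causality).

Downstream fitting maximizes correlation, which is amplitude-free, so the
curve is normalized to unit peak for numerical conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = ["HRFParams", "evaluate_hrf", "default_hrf", "HRF_BOUNDS"]

#: Box bounds used when the six parameters are co-estimated from data:
#: wide intervals around the canonical values.
HRF_BOUNDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "alpha1": (1.0 + 1e-6, 12.0),
    "alpha2": (1.0 + 1e-6, 24.0),
    "beta1": (0.1, 4.0),
    "beta2": (0.1, 4.0),
    "ratio": (0.5, 24.0),
}


@dataclass(frozen=True)
class HRFParams:
    """delta: onset delay (s); alpha1/beta1: response shape/dispersion;
    alpha2/beta2: undershoot shape/dispersion; ratio: response-to-undershoot
    amplitude ratio (dimensionless)."""

    delta: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    ratio: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("onset delay delta must be >= 0")
        if self.alpha1 <= 1 or self.alpha2 <= 1:
            raise ValueError("gamma shapes alpha1, alpha2 must be > 1")
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError("dispersions beta1, beta2 must be > 0")
        if self.ratio <= 0:
            raise ValueError("response-to-undershoot ratio must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.delta, self.alpha1, self.alpha2, self.beta1, self.beta2, self.ratio]
        )

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_array(cls, a) -> "HRFParams":
        return cls(*(float(v) for v in a))


def default_hrf() -> HRFParams:
    """Canonical SPM parameterization: response peaking at ~5-6 s,
    undershoot near 16 s, unit dispersions, 6:1 amplitude ratio, no delay."""
    return HRFParams(delta=0.0, alpha1=6.0, alpha2=16.0, beta1=1.0, beta2=1.0, ratio=6.0)


def _raw_hrf(t: np.ndarray, p: HRFParams) -> np.ndarray:
    ts = t - p.delta
    out = np.zeros_like(ts, dtype=float)
    pos = ts > 0
    out[pos] = _gamma_dist.pdf(ts[pos], p.alpha1, scale=1.0 / p.beta1) - _gamma_dist.pdf(
        ts[pos], p.alpha2, scale=1.0 / p.beta2
    ) / p.ratio
    return out


def evaluate_hrf(t, params: HRFParams) -> np.ndarray:
    """Evaluate the HRF at times ``t`` (seconds, non-decreasing).

    Returns the double-gamma curve normalized to unit peak. The peak used
    for normalization is taken on a dense internal grid so the scale does
    not depend on the sampling of ``t``.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1:
        raise ValueError("t must be a 1-D vector of times")
    if np.any(np.diff(t) < 0):
        raise ValueError("t must be non-decreasing")
    dense = np.arange(0.0, params.delta + 50.0, 0.01)
    peak = _raw_hrf(dense, params).max()
    if peak <= 0:
        raise ValueError("HRF has non-positive peak; parameters are degenerate")
    return _raw_hrf(t, params) / peak
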