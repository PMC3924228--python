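"""Descriptive statistics for growth curves, uptake kinetics and density gradients.

Four small, self-contained analyses used on both measured and simulated
time courses:

* interval growth rates ``GR_t = ln(OD_t / OD_{t−1}) / Δt``;
* biomass-normalized substrate series and one-phase-decay fits
  ``y(t) = plateau + (y0 − plateau)·e^{−K·t}`` (K in hr⁻¹, half-life
  ``ln 2 / K``);
* GFP/OD promoter-activity ratios with induced/uninduced fold change;
* the cell-density distribution ``CDD_ρᵢ = OD_ρᵢ / Σᵢ OD_ρᵢ`` across an
  eight-layer density gradient (defaults 1.19 … 1.06 g·ml⁻¹).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import ttest_ind

__all__ = [
    "GrowthCurve",
    "GrowthRateSeries",
    "DecayFit",
    "DensityProfile",
    "growth_rate",
    "normalize_to_biomass",
    "fit_one_phase_decay",
    "promoter_activity",
    "fold_ratio",
    "cell_density_distribution",
    "two_sample_ttest",
    "DEFAULT_LAYER_DENSITIES",
]

#: step-gradient layer densities ρ₀ … ρ₇, g·ml⁻¹ (densest layer first)
DEFAULT_LAYER_DENSITIES = (1.19, 1.18, 1.16, 1.14, 1.12, 1.10, 1.08, 1.06)


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time course (times in hr, strictly increasing)."""

    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValueError("times and od600 must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)


@dataclass(frozen=True)
class GrowthRateSeries:
    times: np.ndarray  # right edge of each interval
    gr: np.ndarray  # hr⁻¹

    def peak(self) -> tuple[float, float]:
        i = int(np.argmax(self.gr))
        return float(self.times[i]), float(self.gr[i])


def growth_rate(curve: GrowthCurve, method: str = "log") -> GrowthRateSeries:
    """Per-interval growth rate from an OD curve.

    ``log`` (default): GR_t = ln(OD_t / OD_{t−1}) / Δt — the dimensionally
    consistent specific growth rate (hr⁻¹).  ``ratio`` exposes the raw
    (OD_t / OD_{t−1}) / Δt variant.  Non-positive OD values are rejected
    with the offending index named.
    """
    od = curve.od600
    bad = np.nonzero(od <= 0)[0]
    if len(bad):
        raise ValueError(f"non-positive OD600 at index {bad[0]}")
    if len(od) < 2:
        raise ValueError("need at least two points")
    dt = np.diff(curve.times)
    if method == "log":
        gr = np.log(od[1:] / od[:-1]) / dt
    elif method == "ratio":
        gr = (od[1:] / od[:-1]) / dt
    else:
        raise ValueError(f"unknown method {method!r}")
    return GrowthRateSeries(times=curve.times[1:], gr=gr)


def normalize_to_biomass(
    times,
    substrate,
    curve: GrowthCurve,
    rescale: bool = True,
    divide_by_final_od: bool = False,
) -> np.ndarray:
    """Substrate series divided pointwise by OD (linear-interpolated to the
    substrate grid), rescaled to start at 1.

    ``divide_by_final_od`` divides the whole series by the final OD instead
    of pointwise (alternative normalization convention).  No extrapolation:
    substrate times must lie within the OD curve's span.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(substrate, dtype=float)
    if t.min() < curve.times.min() - 1e-12 or t.max() > curve.times.max() + 1e-12:
        raise ValueError("substrate times outside the OD curve span (no extrapolation)")
    if divide_by_final_od:
        od = np.full_like(t, curve.od600[-1])
    else:
        od = np.interp(t, curve.times, curve.od600)
    if np.any(od <= 0):
        raise ValueError("zero or negative OD in normalization")
    norm = y / od
    if rescale:
        if norm[0] == 0:
            raise ValueError("cannot rescale: first normalized value is zero")
        norm = norm / norm[0]
    return norm


@dataclass(frozen=True)
class DecayFit:
    """One-phase-decay fit y(t) = plateau + (y0 − plateau)·e^{−K·t}."""

    y0: float
    plateau: float
    K: float  # hr⁻¹
    half_life: float  # hr; time to (y0 + plateau)/2, = ln2/K
    rss: float
    converged: bool

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.plateau + (self.y0 - self.plateau) * np.exp(-self.K * t)


def _decay(t, y0, plateau, K):
    return plateau + (y0 - plateau) * np.exp(-K * t)


def fit_one_phase_decay(t, y, fix_plateau_zero: bool = False) -> DecayFit:
    """Nonlinear least-squares one-phase-decay fit.

    Initial values come from a log-linear regression on y − min(y); the fit
    itself leaves K unbounded, and a non-positive fitted K (or optimizer
    failure) is reported via ``converged=False`` rather than raised.  A flat
    series is a ``no-decay`` error.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 points for a decay fit")
    if np.allclose(y, y[0]):
        raise ValueError("no-decay: response is constant")

    base = float(np.min(y))
    shifted = y - base + 1e-12 * max(1.0, abs(base))
    with np.errstate(divide="ignore"):
        slope, intercept = np.polyfit(t, np.log(np.maximum(shifted, 1e-300)), 1)
    k0 = max(-slope, 1e-3)
    p0 = [float(y[0]), base, k0]

    try:
        if fix_plateau_zero:
            popt, _ = curve_fit(lambda tt, y0, K: _decay(tt, y0, 0.0, K),
                                t, y, p0=[p0[0], p0[2]], maxfev=20000)
            y0_hat, k_hat = popt
            plateau_hat = 0.0
        else:
            popt, _ = curve_fit(_decay, t, y, p0=p0, maxfev=20000)
            y0_hat, plateau_hat, k_hat = popt
        ok = True
    except RuntimeError:
        y0_hat, plateau_hat, k_hat = p0
        ok = False

    resid = y - _decay(t, y0_hat, plateau_hat, k_hat)
    converged = bool(ok and k_hat > 0)
    half_life = math.log(2.0) / k_hat if k_hat > 0 else math.inf
    return DecayFit(
        y0=float(y0_hat),
        plateau=float(plateau_hat),
        K=float(k_hat),
        half_life=float(half_life),
        rss=float(np.sum(resid**2)),
        converged=converged,
    )


def promoter_activity(times, gfp, curve: GrowthCurve) -> np.ndarray:
    """Pointwise GFP/OD ratio on the GFP time grid (OD linearly interpolated)."""
    t = np.asarray(times, dtype=float)
    g = np.asarray(gfp, dtype=float)
    od = np.interp(t, curve.times, curve.od600)
    if np.any(od <= 0):
        raise ValueError("zero or negative OD in promoter activity")
    return g / od


def fold_ratio(induced: np.ndarray, uninduced: np.ndarray) -> np.ndarray:
    """Induced / uninduced promoter-activity ratio (elementwise)."""
    u = np.asarray(uninduced, dtype=float)
    if np.any(u <= 0):
        raise ValueError("uninduced activity must be positive")
    return np.asarray(induced, dtype=float) / u


@dataclass(frozen=True)
class DensityProfile:
    """Background-subtracted OD per gradient layer plus its normalized CDD."""

    layer_densities: tuple = DEFAULT_LAYER_DENSITIES
    layer_od: np.ndarray = field(default_factory=lambda: np.zeros(8))
    cdd: np.ndarray | None = None

    def __post_init__(self):
        od = np.asarray(self.layer_od, dtype=float)
        if len(od) != len(self.layer_densities):
            raise ValueError("layer_od length must match layer_densities")
        object.__setattr__(self, "layer_od", od)

    @property
    def modal_density(self) -> float:
        if self.cdd is None:
            raise ValueError("call cell_density_distribution first")
        return float(self.layer_densities[int(np.argmax(self.cdd))])

    @property
    def mean_density(self) -> float:
        if self.cdd is None:
            raise ValueError("call cell_density_distribution first")
        return float(np.dot(self.cdd, self.layer_densities))


def cell_density_distribution(
    profile: DensityProfile, blank_od=None
) -> DensityProfile:
    """Normalize layer ODs to the cell density distribution CDD_ρᵢ = OD_ρᵢ/ΣOD.

    ``blank_od`` (same length) is subtracted first; negative layer readings
    after subtraction are clipped to zero with a warning.  An all-zero
    profile is an ``empty-gradient`` error.
    """
    od = profile.layer_od.copy()
    if blank_od is not None:
        od = od - np.asarray(blank_od, dtype=float)
    if np.any(od < 0):
        warnings.warn("negative layer OD after background subtraction; clipping to 0")
        od = np.clip(od, 0.0, None)
    total = od.sum()
    if total <= 0:
        raise ValueError("empty-gradient: all layer ODs are zero")
    return DensityProfile(
        layer_densities=profile.layer_densities, layer_od=od, cdd=od / total
    )


def two_sample_ttest(a, b):
    """Plain two-sample t-test (convenience wrapper; returns (t, p))."""
    res = ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
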