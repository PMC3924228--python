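"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one class of bench measurement with known ground
truth, so recovery of that truth by the corresponding analysis operation is a
testable property:

* batch OD600 / substrate-concentration tables sampled every 30 min with
  multiplicative lognormal noise (plate-reader-like, default 2% CV);
* eight-layer density-gradient OD profiles (Gaussian cell-mass loading plus
  additive read noise and a blank column);
* paired induced/uninduced GFP + OD induction time courses.

Every call draws from a private stream derived from ``(seed, generator
name)``, so identical seeds reproduce tables byte-identically and adding new
generators never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import BatchTrajectory
from .kinetics import DEFAULT_LAYER_DENSITIES, DensityProfile

__all__ = [
    "GeneratorSpec",
    "DecayTruth",
    "BatchTruth",
    "generate_batch_observations",
    "generate_decay_series",
    "generate_gradient_profile",
    "generate_induction_timecourse",
]

#: default sampling interval of plate-reader time courses, hr
SAMPLING_INTERVAL = 0.5


def _stream(seed: int, name: str) -> np.random.Generator:
    # stable per-generator stream: (seed, crc-of-name), both < 2**31
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


@dataclass(frozen=True)
class GeneratorSpec:
    """Noise configuration shared by the generators.

    ``od_cv`` / ``conc_cv`` are coefficients of variation of multiplicative
    lognormal noise on OD and concentration readings; ``gradient_sd`` is the
    additive Gaussian read noise on gradient-layer ODs.
    """

    seed: int = 0
    od_cv: float = 0.02
    conc_cv: float = 0.02
    gradient_sd: float = 0.002

    def __post_init__(self):
        if min(self.od_cv, self.conc_cv, self.gradient_sd) < 0:
            raise ValueError("noise magnitudes must be >= 0")


def _lognoise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


@dataclass(frozen=True)
class DecayTruth:
    """Ground truth for one substrate's normalized uptake curve."""

    K: float  # hr⁻¹
    y0: float = 1.0
    plateau: float = 0.0
    initial_concentration: float = 2.0  # g/L

    def curve(self, t: np.ndarray) -> np.ndarray:
        return self.plateau + (self.y0 - self.plateau) * np.exp(-self.K * t)


@dataclass(frozen=True)
class BatchTruth:
    """Closed-form batch ground truth: logistic OD growth + per-substrate decay."""

    od0: float = 0.035
    od_capacity: float = 1.0
    growth_rate: float = 0.7  # hr⁻¹, early-exponential rate of the logistic
    substrates: dict[str, DecayTruth] = field(
        default_factory=lambda: {"glucose": DecayTruth(K=0.5)}
    )

    def od(self, t: np.ndarray) -> np.ndarray:
        a = (self.od_capacity - self.od0) / self.od0
        return self.od_capacity / (1.0 + a * np.exp(-self.growth_rate * t))


def generate_batch_observations(
    truth: BatchTruth | BatchTrajectory,
    spec: GeneratorSpec,
    t_end: float = 6.0,
    interval: float = SAMPLING_INTERVAL,
) -> tuple[pd.DataFrame, BatchTruth | BatchTrajectory]:
    """Noisy OD + substrate-concentration table sampled on a 30-min grid.

    Accepts either closed-form :class:`BatchTruth` or a simulated
    :class:`~ccrsim.batch.BatchTrajectory` (interpolated onto the grid).
    Substrate concentrations under ``BatchTruth`` follow the decay curve *in
    biomass-normalized space* (concentration = y(t)·OD(t)/OD(0)·C₀), so the
    normalize-then-fit pipeline recovers each K exactly at zero noise.
    Returns ``(table, truth)`` with columns ``time``, ``od600`` and one per
    substrate.
    """
    rng = _stream(spec.seed, "batch_observations")
    t = np.arange(0.0, t_end + 1e-9, interval)
    if isinstance(truth, BatchTrajectory):
        od = np.interp(t, truth.times, truth.od600)
        concs = {
            s: np.interp(t, truth.times, c) for s, c in truth.concentrations.items()
        }
    else:
        od = truth.od(t)
        concs = {
            s: d.curve(t) * od / od[0] * d.initial_concentration
            for s, d in truth.substrates.items()
        }
    table = {"time": t, "od600": od * _lognoise(rng, spec.od_cv, t.shape)}
    for s, c in concs.items():
        table[s] = c * _lognoise(rng, spec.conc_cv, t.shape)
    return pd.DataFrame(table), truth


def generate_decay_series(
    truth: DecayTruth,
    spec: GeneratorSpec,
    n_points: int = 20,
    t_end: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A bare normalized decay series (t, y) with multiplicative noise."""
    rng = _stream(spec.seed, "decay_series")
    t = np.linspace(0.0, t_end, n_points)
    y = truth.curve(t) * _lognoise(rng, spec.conc_cv, (n_points,))
    return t, y


def generate_gradient_profile(
    center: float,
    spread: float,
    spec: GeneratorSpec,
    layers=DEFAULT_LAYER_DENSITIES,
    total_od: float = 1.0,
    blank_level: float = 0.05,
) -> tuple[DensityProfile, np.ndarray]:
    """Gaussian cell-mass loading discretized onto the gradient layers.

    Layer signal ∝ exp(−(ρᵢ−center)²/2·spread²) scaled to ``total_od``, plus
    additive read noise; the returned profile contains raw (blank-inflated)
    ODs and the matching blank column so the analysis path exercises
    background subtraction.  ``center`` must lie within the layer range.
    """
    rho = np.asarray(layers, dtype=float)
    if not (rho.min() <= center <= rho.max()):
        raise ValueError(f"center {center} outside layer range [{rho.min()}, {rho.max()}]")
    rng = _stream(spec.seed, "gradient_profile")
    if spread <= 0:
        signal = np.zeros_like(rho)
        signal[int(np.argmin(np.abs(rho - center)))] = total_od
    else:
        w = np.exp(-0.5 * ((rho - center) / spread) ** 2)
        signal = total_od * w / w.sum()
    blank = np.full_like(rho, blank_level) + rng.normal(0.0, spec.gradient_sd, rho.shape)
    raw = signal + blank + rng.normal(0.0, spec.gradient_sd, rho.shape)
    return DensityProfile(layer_densities=tuple(rho), layer_od=raw), blank


def generate_induction_timecourse(
    fold: float,
    onset_hr: float,
    spec: GeneratorSpec,
    t_end: float = 6.0,
    interval: float = SAMPLING_INTERVAL,
    growth_rate: float = 0.5,
    od0: float = 0.035,
    gfp_per_od: float = 100.0,
) -> pd.DataFrame:
    """Paired induced/uninduced GFP + OD series with true post-onset fold-ratio.

    The uninduced culture expresses a constitutive baseline (GFP = c·OD);
    after ``onset_hr`` the induced culture's per-OD expression is ``fold``
    times the baseline.  ``fold`` must be ≥ 1.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = _stream(spec.seed, "induction_timecourse")
    t = np.arange(0.0, t_end + 1e-9, interval)
    od = od0 * np.exp(growth_rate * t)
    base = gfp_per_od * od
    induced = base * np.where(t >= onset_hr, fold, 1.0)
    return pd.DataFrame(
        {
            "time": t,
            "od600": od * _lognoise(rng, spec.od_cv, t.shape),
            "gfp_uninduced": base * _lognoise(rng, spec.od_cv, t.shape),
            "gfp_induced": induced * _lognoise(rng, spec.od_cv, t.shape),
        }
    )
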