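"""Growth rates, one-phase-decay fitting, promoter activity and the CDD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccrsim import (
    DecayTruth,
    DensityProfile,
    GeneratorSpec,
    GrowthCurve,
    cell_density_distribution,
    fit_one_phase_decay,
    fold_ratio,
    generate_decay_series,
    growth_rate,
    normalize_to_biomass,
    promoter_activity,
    two_sample_ttest,
)
from ccrsim.kinetics import DEFAULT_LAYER_DENSITIES


# ---------------------------------------------------------------------------
# growth rate


def test_constant_od_gives_zero_growth_rate():
    curve = GrowthCurve(np.arange(5.0), np.full(5, 0.7))
    assert np.allclose(growth_rate(curve).gr, 0.0)


def test_doubling_series_gives_ln2_per_interval():
    t = np.arange(0.0, 5.0)
    curve = GrowthCurve(t, 0.05 * 2.0**t)
    gr = growth_rate(curve).gr
    assert np.allclose(gr, math.log(2.0), atol=1e-10)


def test_exact_exponential_recovers_its_rate_on_uneven_grid():
    t = np.array([0.0, 0.4, 1.1, 1.5, 2.8])
    curve = GrowthCurve(t, 0.03 * np.exp(0.62 * t))
    assert np.allclose(growth_rate(curve).gr, 0.62, atol=1e-10)


def test_sigmoid_od_with_baseline_peaks_early_then_declines():
    """An OD curve with medium background + logistic cell signal has its
    specific growth rate peaking in early exponential phase, then falling."""
    t = np.arange(0.0, 10.0, 0.5)
    cells = 1.0 / (1.0 + (1.0 / 0.005 - 1) * np.exp(-1.5 * t))
    od = 0.05 + cells
    gr = growth_rate(GrowthCurve(t, od))
    peak_i = int(np.argmax(gr.gr))
    assert 0 < peak_i < len(gr.gr) // 2  # early-exponential peak
    assert gr.gr[-1] < gr.gr[peak_i] / 2


def test_non_positive_od_error_names_the_index():
    with pytest.raises(ValueError, match="index 2"):
        growth_rate(GrowthCurve(np.arange(4.0), np.array([0.1, 0.2, 0.0, 0.4])))


def test_ratio_method_exposed():
    curve = GrowthCurve(np.arange(3.0), np.array([0.1, 0.2, 0.4]))
    gr = growth_rate(curve, method="ratio")
    assert np.allclose(gr.gr, 2.0)


# ---------------------------------------------------------------------------
# normalization


def test_normalize_flat_substrate_flat_od_is_one():
    curve = GrowthCurve(np.arange(4.0), np.full(4, 0.5))
    norm = normalize_to_biomass(np.arange(4.0), np.full(4, 2.0), curve)
    assert np.allclose(norm, 1.0)


def test_normalize_halved_substrate_constant_od_ends_at_half():
    curve = GrowthCurve(np.arange(3.0), np.full(3, 0.5))
    norm = normalize_to_biomass(np.arange(3.0), np.array([2.0, 1.5, 1.0]), curve)
    assert norm[-1] == pytest.approx(0.5)


def test_normalize_refuses_extrapolation():
    curve = GrowthCurve(np.arange(3.0), np.full(3, 0.5))
    with pytest.raises(ValueError, match="extrapolation"):
        normalize_to_biomass(np.array([0.0, 5.0]), np.array([1.0, 1.0]), curve)


def test_final_od_normalization_flag():
    curve = GrowthCurve(np.arange(3.0), np.array([0.1, 0.2, 0.4]))
    sub = np.array([2.0, 2.0, 2.0])
    pointwise = normalize_to_biomass(np.arange(3.0), sub, curve)
    final = normalize_to_biomass(np.arange(3.0), sub, curve, divide_by_final_od=True)
    assert pointwise[-1] < pointwise[0]  # growing OD shrinks the pointwise series
    assert np.allclose(final, 1.0)


# ---------------------------------------------------------------------------
# one-phase decay


def test_noiseless_decay_recovered_exactly():
    t = np.linspace(0.0, 6.0, 20)
    y = 1.0 * np.exp(-0.5 * t)
    fit = fit_one_phase_decay(t, y)
    assert fit.converged
    assert fit.K == pytest.approx(0.5, abs=1e-8)
    assert fit.y0 == pytest.approx(1.0, abs=1e-8)
    assert fit.plateau == pytest.approx(0.0, abs=1e-8)
    assert fit.half_life == pytest.approx(math.log(2) / 0.5, abs=1e-8)


def test_nonzero_plateau_recovered_and_half_life_consistent():
    t = np.linspace(0.0, 8.0, 30)
    y = 0.2 + 0.8 * np.exp(-0.7 * t)
    fit = fit_one_phase_decay(t, y)
    assert fit.K == pytest.approx(0.7, abs=1e-6)
    assert fit.plateau == pytest.approx(0.2, abs=1e-6)
    # time at which the curve is halfway between y0 and plateau
    halfway = fit.predict(fit.half_life)
    assert halfway == pytest.approx((fit.y0 + fit.plateau) / 2, abs=1e-6)


def test_noisy_decay_recovery_within_five_percent_median():
    """200 seeded replicates at 2% multiplicative noise, n=20 over 6 hr."""
    errs = []
    for seed in range(200):
        t, y = generate_decay_series(
            DecayTruth(K=0.5), GeneratorSpec(seed=seed, conc_cv=0.02)
        )
        fit = fit_one_phase_decay(t, y)
        errs.append(abs(fit.K - 0.5) / 0.5)
    assert np.median(errs) <= 0.05


def test_flat_series_is_a_no_decay_error():
    with pytest.raises(ValueError, match="no-decay"):
        fit_one_phase_decay(np.arange(5.0), np.ones(5))


def test_growing_series_with_zero_plateau_reports_not_converged():
    # with the plateau pinned at zero only K < 0 can fit growth, so the fit
    # must flag itself as not converged rather than report a rate constant
    t = np.linspace(0.0, 5.0, 10)
    fit = fit_one_phase_decay(t, np.exp(0.4 * t), fix_plateau_zero=True)
    assert not fit.converged
    assert fit.K <= 0 or not np.isfinite(fit.half_life)


def test_fix_plateau_zero_forces_plateau():
    t = np.linspace(0.0, 6.0, 20)
    y = 0.1 + 0.9 * np.exp(-0.6 * t)
    fit = fit_one_phase_decay(t, y, fix_plateau_zero=True)
    assert fit.plateau == 0.0


@given(scale=st.floats(min_value=0.1, max_value=50.0))
@settings(max_examples=25, deadline=None)
def test_decay_fit_is_scale_equivariant(scale):
    t = np.linspace(0.0, 6.0, 15)
    y = 0.15 + 0.85 * np.exp(-0.8 * t)
    base = fit_one_phase_decay(t, y)
    scaled = fit_one_phase_decay(t, scale * y)
    assert scaled.K == pytest.approx(base.K, abs=1e-8)
    assert scaled.half_life == pytest.approx(base.half_life, abs=1e-8)
    assert scaled.y0 == pytest.approx(scale * base.y0, rel=1e-6)
    assert scaled.plateau == pytest.approx(scale * base.plateau, abs=1e-6 * scale)


# ---------------------------------------------------------------------------
# promoter activity


def test_gfp_equal_to_od_gives_unit_activity():
    curve = GrowthCurve(np.arange(4.0), np.array([0.1, 0.2, 0.4, 0.8]))
    act = promoter_activity(np.arange(4.0), curve.od600.copy(), curve)
    assert np.allclose(act, 1.0)


def test_twofold_induction_gives_fold_ratio_two():
    curve = GrowthCurve(np.arange(4.0), np.array([0.1, 0.2, 0.4, 0.8]))
    uninduced = promoter_activity(np.arange(4.0), 5.0 * curve.od600, curve)
    induced = promoter_activity(np.arange(4.0), 10.0 * curve.od600, curve)
    assert np.allclose(fold_ratio(induced, uninduced), 2.0)


# ---------------------------------------------------------------------------
# cell density distribution


def test_delta_profile_at_1p14_layer():
    od = np.zeros(8)
    od[3] = 2.5  # rho_3 = 1.14 g/ml
    prof = cell_density_distribution(DensityProfile(layer_od=od))
    assert np.allclose(prof.cdd, np.eye(8)[3])
    assert prof.modal_density == pytest.approx(1.14)
    assert prof.mean_density == pytest.approx(1.14)


def test_uniform_profile_gives_equal_eighths():
    prof = cell_density_distribution(DensityProfile(layer_od=np.ones(8)))
    assert np.allclose(prof.cdd, 0.125)


def test_background_subtraction_and_negative_clipping():
    od = np.array([0.2, 0.5, 1.0, 0.5, 0.2, 0.1, 0.1, 0.05])
    blank = np.full(8, 0.1)
    with pytest.warns(UserWarning, match="clipping"):
        prof = cell_density_distribution(DensityProfile(layer_od=od), blank_od=blank)
    assert np.min(prof.cdd) == 0.0
    assert prof.cdd.sum() == pytest.approx(1.0)


def test_empty_gradient_is_an_error():
    with pytest.raises(ValueError, match="empty-gradient"):
        cell_density_distribution(DensityProfile(layer_od=np.zeros(8)))


@given(
    od=st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=8, max_size=8).filter(
        lambda v: sum(v) > 1e-6
    )
)
@settings(max_examples=50, deadline=None)
def test_cdd_normalizes_to_one_on_any_nonzero_profile(od):
    prof = cell_density_distribution(DensityProfile(layer_od=np.array(od)))
    assert prof.cdd.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.min(prof.cdd) >= 0.0
    assert DEFAULT_LAYER_DENSITIES[0] >= prof.mean_density >= DEFAULT_LAYER_DENSITIES[-1]


def test_ttest_convenience_returns_statistic_and_pvalue():
    t, p = two_sample_ttest([1.0, 1.1, 0.9, 1.05], [2.0, 2.1, 1.9, 2.05])
    assert p < 0.01
    assert t < 0
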