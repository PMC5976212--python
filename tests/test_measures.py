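"""Response measures: RF geometry, area curves, tuning, temporal indices."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from edog import (
    DOGSpatial,
    RasterStimulus,
    SpaceTimeGrid,
    compute_response,
    excitatory_feedback_circuit,
    generate_synthetic_movie,
    inhibitory_feedback_circuit,
    mixed_feedback_circuit,
    no_feedback_circuit,
    spatial_irf,
)
from edog.measures import (
    AreaResponseCurve,
    area_response_curve,
    optimal_size,
    response_map,
    response_reduction,
    rf_characteristics,
    spatial_frequency_tuning,
    suppression_index,
    temporal_autocorrelation,
    temporal_frequency_tuning,
    temporal_irf_measures,
)

TABLE_DOG = DOGSpatial(A=1.0, a=0.62, B=0.85, b=1.26)


# -- receptive-field geometry -------------------------------------------------

def test_rf_size_matches_analytic_dog_zero(spatial_grid):
    X, Y = spatial_grid.spatial_meshgrid()
    field = TABLE_DOG.evaluate(np.hypot(X, Y))
    rc = rf_characteristics(field, spatial_grid)
    root = brentq(TABLE_DOG.evaluate, 0.3, 2.5)  # 1-D root-finding oracle
    assert rc.rf_size == pytest.approx(root, abs=2e-3)
    assert rc.center_excitation == pytest.approx(TABLE_DOG.evaluate(0.0))
    assert rc.surround_inhibition < 0


def test_rf_size_undefined_for_all_positive_field(spatial_grid):
    from edog import GaussianSpatial

    X, Y = spatial_grid.spatial_meshgrid()
    field = GaussianSpatial(1.0).evaluate(np.hypot(X, Y))
    rc = rf_characteristics(field, spatial_grid)
    assert not rc.size_defined
    assert rc.rf_size is None


def test_feedback_sign_shifts_center_excitation(spatial_grid):
    """Excitatory feedback raises, inhibitory feedback lowers, the center
    peak relative to no feedback (opposite-effect law)."""
    base = rf_characteristics(spatial_irf(no_feedback_circuit(), spatial_grid),
                              spatial_grid)
    up = rf_characteristics(
        spatial_irf(excitatory_feedback_circuit(0.5, 0.83), spatial_grid),
        spatial_grid,
    )
    down = rf_characteristics(
        spatial_irf(inhibitory_feedback_circuit(-0.5, 0.83), spatial_grid),
        spatial_grid,
    )
    assert up.center_excitation > base.center_excitation > down.center_excitation


# -- area-response curves -----------------------------------------------------

def test_static_spot_curve_shape_and_convergence(spatial_grid):
    diameters = np.linspace(0.25, 6.0, 24)
    curve = area_response_curve(
        no_feedback_circuit(), spatial_grid, diameters, kind="static_spot"
    )
    i_peak = int(np.argmax(curve.responses))
    assert 0 < i_peak < len(diameters) - 1  # rises then declines
    assert curve.responses[-1] < curve.r_max  # suppressed plateau
    # largest diameter response approaches the uniform-luminance value
    full = (
        no_feedback_circuit().static_transfer(0.0)
        * no_feedback_circuit().retinal_h0
    )
    assert curve.responses[-1] == pytest.approx(full, rel=0.02)


def test_tiny_spot_response_vanishes(spatial_grid):
    curve = area_response_curve(
        no_feedback_circuit(), spatial_grid, [0.11, 1.7], kind="static_spot"
    )
    assert abs(curve.responses[0]) < 0.05 * abs(curve.r_max)


def test_diameters_beyond_half_extent_rejected(spatial_grid):
    with pytest.raises(ValueError):
        area_response_curve(
            no_feedback_circuit(), spatial_grid, [spatial_grid.extent], "static_spot"
        )


def test_suppression_index_arithmetic():
    curve = AreaResponseCurve(np.arange(1, 11.0), np.array(
        [1, 4, 10, 8, 6, 5, 4.5, 4.2, 4.0, 4.0]))
    assert suppression_index(curve) == pytest.approx(0.6)


def test_suppression_index_zero_for_saturating_curve():
    d = np.linspace(0.5, 20, 40)
    curve = AreaResponseCurve(d, 1 - np.exp(-d))
    assert suppression_index(curve) < 0.01


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_suppression_index_scale_invariant(scale):
    d = np.linspace(1, 10, 20)
    r = 5 * d * np.exp(-d / 2) + 1
    base = suppression_index(AreaResponseCurve(d, r))
    scaled = suppression_index(AreaResponseCurve(d, r * scale))
    assert 0 <= base <= 1
    assert scaled == pytest.approx(base, rel=1e-9)


def test_optimal_size_recovers_parabola_vertex():
    d = np.linspace(0.5, 6.0, 23)
    vertex = 2.87
    curve = AreaResponseCurve(d, -((d - vertex) ** 2) + 10)
    assert optimal_size(curve) == pytest.approx(vertex, abs=1e-9)


def test_optimal_size_feedback_trends(spatial_grid):
    """Inhibitory feedback shrinks, excitatory feedback grows, the optimal
    stimulus diameter; trends are monotone in feedback weight."""
    diameters = np.linspace(0.25, 6.0, 24)

    def osize(circuit):
        return optimal_size(
            area_response_curve(circuit, spatial_grid, diameters, "static_spot")
        )

    inh = [osize(inhibitory_feedback_circuit(-w, 0.83)) for w in (1e-9, 0.5, 1.0)]
    exc = [osize(excitatory_feedback_circuit(w, 0.83)) for w in (1e-9, 0.4, 0.75)]
    assert np.all(np.diff(inh) < 0)
    assert np.all(np.diff(exc) > 0)


# -- frequency tuning ---------------------------------------------------------

def test_small_patch_lowpass_large_patch_bandpass():
    grid = SpaceTimeGrid(n_spatial=512, extent=8 * np.pi, n_time=8, duration=100.0)
    ks = np.linspace(0.0, 3.0, 13)
    small = spatial_frequency_tuning(no_feedback_circuit(), grid, 1.5, ks).responses
    large = spatial_frequency_tuning(no_feedback_circuit(), grid, 10.0, ks).responses
    assert np.all(np.diff(small) < 0)  # low-pass
    i = int(np.argmax(large))
    assert 0 < i < len(ks) - 1  # band-pass (interior maximum)


def test_response_reduction_identical_diameters_is_zero(spatial_grid):
    assert response_reduction(no_feedback_circuit(), spatial_grid,
                              k_pg=0.5, d_center=2.0, d_full=2.0) == 0.0


def test_response_reduction_orders_center_vs_surround():
    grid = SpaceTimeGrid(n_spatial=512, extent=8 * np.pi, n_time=8, duration=100.0)
    red = response_reduction(no_feedback_circuit(), grid, k_pg=0.25,
                             d_center=1.5, d_full=10.0)
    assert 0 < red < 100


def test_temporal_tuning_zero_frequency_consistency(mixed):
    curve = temporal_frequency_tuning(mixed, 1.0, [0.0, 0.1])
    expected = abs(mixed.static_transfer(1.0) * mixed.retinal_h0)
    assert curve.responses[0] == pytest.approx(expected, rel=1e-12)


def test_delayed_inhibition_sharpens_temporal_tuning():
    omegas = np.linspace(0, 2 * np.pi * 0.06, 40)  # 0-60 Hz

    def peak_to_mean(circuit):
        r = temporal_frequency_tuning(circuit, 1.0, omegas).responses
        return r.max() / r.mean()

    base = peak_to_mean(no_feedback_circuit())
    delayed_inh = peak_to_mean(mixed_feedback_circuit(1.0, delta_ex=5, delta_in=30))
    synchronized = peak_to_mean(mixed_feedback_circuit(1.0, delta_ex=15, delta_in=15))
    assert delayed_inh > 1.3 * base
    assert synchronized == pytest.approx(base, rel=0.1)


# -- temporal impulse-response measures ---------------------------------------

def test_biphasic_trace_recovers_definition():
    """The raw biphasic retinal filter itself has i_bp = B and t_peak = tau/2."""
    from edog import BiphasicTemporal

    dt = 0.05
    t = np.arange(0, 120, dt)
    trace = BiphasicTemporal(42.5, 0.38).evaluate(t)
    m = temporal_irf_measures(trace, dt)
    assert m.i_bp == pytest.approx(0.38, abs=1e-4)
    assert m.t_peak == pytest.approx(21.25, abs=dt)


def test_monophasic_trace_has_zero_index():
    t = np.arange(0, 100, 0.5)
    trace = np.exp(-((t - 30) ** 2) / 50)
    m = temporal_irf_measures(trace, 0.5)
    assert m.i_bp == 0.0
    assert m.t_peak == pytest.approx(30.0, abs=0.01)


def test_all_negative_trace_rejected():
    with pytest.raises(ValueError):
        temporal_irf_measures(-np.ones(50), 1.0)


def test_biphasic_estimator_on_synthetic_two_lobe_traces():
    """Constructed two-lobe traces with known amplitude ratios are recovered
    within the interpolation bound across 100 random amplitude pairs."""
    rng = np.random.default_rng(99)
    dt = 0.25
    t = np.arange(0, 100, dt)
    for _ in range(100):
        a1 = rng.uniform(0.5, 3.0)
        a2 = rng.uniform(0.05, 1.0) * a1
        lobe = np.sin(np.pi * np.clip(t, 0, 40) / 40)
        trace = a1 * np.where(t <= 40, lobe, 0.0)
        second = np.sin(np.pi * np.clip(t - 40, 0, 40) / 40)
        trace -= a2 * np.where((t > 40) & (t <= 80), second, 0.0)
        m = temporal_irf_measures(trace, dt)
        assert m.i_bp == pytest.approx(a2 / a1, abs=2 * dt / 40)
        assert m.t_peak == pytest.approx(20.0, abs=dt)


# -- autocorrelation ----------------------------------------------------------

def test_acf_lag_zero_is_one():
    rng = np.random.default_rng(1)
    field = rng.standard_normal((8, 8, 64))
    lags, mean, sd = temporal_autocorrelation(field, window=4, max_lag=5)
    assert mean[0] == 1.0 and sd[0] == 0.0


def test_white_noise_acf_is_small():
    rng = np.random.default_rng(2)
    field = rng.standard_normal((6, 6, 1024))
    _, mean, _ = temporal_autocorrelation(field, window=6, max_lag=5)
    assert np.abs(mean[1:]).max() < 4 / np.sqrt(1024)


def test_zero_variance_neurons_excluded():
    rng = np.random.default_rng(3)
    field = rng.standard_normal((4, 4, 64))
    field[0, 0, :] = 5.0
    with pytest.warns(RuntimeWarning, match="zero-variance"):
        lags, mean, sd = temporal_autocorrelation(field, window=4, max_lag=3)
    assert np.isfinite(mean).all()


def test_feedback_configuration_orders_short_lag_decorrelation():
    """Delayed inhibitory feedback decorrelates responses to a correlated
    movie; delayed excitatory feedback increases short-lag correlation."""
    grid = SpaceTimeGrid(n_spatial=64, extent=4 * np.pi, n_time=256, duration=1000.0)
    movie = generate_synthetic_movie(7, grid)

    def acf(circuit):
        f = compute_response(circuit, movie, grid)
        _, mean, _ = temporal_autocorrelation(f, window=16, max_lag=8)
        return mean

    base = acf(no_feedback_circuit())
    delayed_inh = acf(mixed_feedback_circuit(1.0, delta_ex=5, delta_in=30))
    delayed_exc = acf(mixed_feedback_circuit(1.0, delta_ex=30, delta_in=5))
    short = slice(2, 6)
    assert np.all(delayed_inh[short] < base[short])
    assert np.all(delayed_exc[short] > base[short])


# -- natural-image response maps ----------------------------------------------

def test_no_feedback_response_map_peaks_at_one(spatial_grid):
    rng = np.random.default_rng(4)
    img = rng.standard_normal((spatial_grid.n_spatial,) * 2)
    raster = RasterStimulus(img, spatial_grid.dx)
    m = response_map(no_feedback_circuit(), raster, spatial_grid)
    assert np.abs(m).max() == pytest.approx(1.0)


def test_mixed_feedback_enhances_edges_suppresses_flats(spatial_grid):
    n = spatial_grid.n_spatial
    img = np.zeros((n, n))
    img[:, n // 2:] = 1.0
    img -= img.mean()
    raster = RasterStimulus(img, spatial_grid.dx)
    base = response_map(no_feedback_circuit(), raster, spatial_grid)
    fed = response_map(mixed_feedback_circuit(1.8), raster, spatial_grid)
    c = n // 2
    edge = slice(c - 2, c + 3)
    flat = slice(c + 15, c + 30)
    assert np.abs(fed[:, edge]).max() > np.abs(base[:, edge]).max()
    assert np.abs(fed[:, flat]).mean() < np.abs(base[:, flat]).mean()


def test_feedback_off_equivalence_bit_for_bit(spatial_grid):
    """Zero-weight feedback reproduces the no-feedback measures exactly."""
    zeroed = mixed_feedback_circuit(0.0)
    base = no_feedback_circuit()
    d = np.linspace(0.25, 6.0, 12)
    c1 = area_response_curve(base, spatial_grid, d, "patch_grating", k_pg=1.0)
    c2 = area_response_curve(zeroed, spatial_grid, d, "patch_grating", k_pg=1.0)
    np.testing.assert_array_equal(c1.responses, c2.responses)
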