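"""Estimation primitives: reference signal, smoothing, mixture threshold,
binarization, transition detection, period recovery, budding index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from cyclesync import (ReferenceSignalParams, binarize, budding_index,
                       build_reference, detect_transitions,
                       estimate_nominal_periods, estimate_phase_cycling,
                       estimate_phase_noncycling, fit_threshold, smooth)
from cyclesync.estimation import (BinaryTraceSet, Transition,
                                  binarize_traces)

TWO_PI = 2 * math.pi


# --- reference signal -------------------------------------------------------


def test_reference_flat_then_raised_cosine():
    p = ReferenceSignalParams(T0=75, T_flat=30, dt=1.5)
    t, r = build_reference(p, n_periods=2)
    flat = r[t < 30]
    assert np.all(flat == 0.0)
    # trough of the raised cosine reaches 1 at T_flat + T0/2
    i = np.argmin(np.abs(t - (30 + 37.5)))
    assert r[i] == pytest.approx(1.0, abs=1e-9)
    # T-periodicity on the sampled grid
    n_per = int(round(p.T / p.dt))
    assert np.allclose(r[:n_per], r[n_per:2 * n_per], atol=1e-12)
    # continuity at the flat/cosine junction
    j = np.argmin(np.abs(t - 30.0))
    assert r[j] == pytest.approx(0.0, abs=1e-12)


def test_crosscorrelation_phase_mapping():
    """A window cut from the reference at position tau* maps back to
    theta = (2*pi/T0)(tau* - T_flat) + pi/2."""
    p = ReferenceSignalParams(T0=75, T_flat=30, dt=1.25)
    _, ref = build_reference(p, 1)
    n = p.window_len
    # tau* = 48.75 = T_flat + T0/4: start index (48.75-30)/1.25 = 15
    th, r = estimate_phase_noncycling(ref[15:15 + n], p)
    assert th == pytest.approx(math.pi, abs=1e-9)
    assert r == pytest.approx(1.0)
    # affine invariance of Pearson correlation
    th2, _ = estimate_phase_noncycling(3.0 * ref[15:15 + n] + 7.0, p)
    assert th2 == pytest.approx(th)


def test_flat_window_is_invalid():
    """A zero-variance (G1-arrested) window has no defined correlation."""
    p = ReferenceSignalParams(dt=2.0)
    th, _ = estimate_phase_noncycling(np.full(p.window_len, 3.3), p)
    assert th is None


def test_window_length_checked():
    p = ReferenceSignalParams(dt=2.0)
    with pytest.raises(ValueError):
        estimate_phase_noncycling(np.zeros(5), p)


# --- smoothing --------------------------------------------------------------


def test_smooth_preserves_constant_and_interior_ramp():
    assert np.allclose(smooth(np.full(20, 3.7)), 3.7)
    ramp = np.arange(30, dtype=float)
    out = smooth(ramp)
    assert np.allclose(out[3:-3], ramp[3:-3], atol=1e-12)


def test_smooth_impulse_spreads_mass_over_seven_samples():
    x = np.zeros(21)
    x[10] = 1.0
    out = smooth(x)
    nz = np.nonzero(out > 1e-15)[0]
    assert nz.min() == 7 and nz.max() == 13
    assert out.sum() == pytest.approx(1.0, abs=1e-12)
    # boxcar(5) * boxcar(3) kernel, computed by hand
    kernel = np.array([1, 2, 3, 3, 3, 2, 1]) / 15.0
    assert np.allclose(out[7:14], kernel, atol=1e-12)


# --- mixture threshold ------------------------------------------------------


def test_threshold_symmetric_mixture_midpoint():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(1, 0.3, 600), rng.normal(5, 0.3, 600)])
    tm = fit_threshold(x)
    assert tm.l == pytest.approx(3.0, abs=0.15)


def test_threshold_asymmetric_matches_analytic_root():
    """Unequal sds: the fitted intersection agrees with the brentq root of
    the weighted-density difference (independent oracle)."""
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(1, 0.5, 4000), rng.normal(5, 1.0, 4000)])
    tm = fit_threshold(x)
    (m1, m2), (s1, s2), (w1, w2) = tm.means, tm.sds, tm.weights

    def diff(v):
        return w1 * norm.pdf(v, m1, s1) - w2 * norm.pdf(v, m2, s2)

    root = brentq(diff, m1, m2)
    assert tm.l == pytest.approx(root, abs=1e-6)
    assert m1 < tm.l < m2


def test_threshold_tight_clusters_classifies_perfectly():
    rng = np.random.default_rng(2)
    lo = rng.normal(1, 0.05, 500)
    hi = rng.normal(5, 0.05, 500)
    tm = fit_threshold(np.concatenate([lo, hi]))
    assert 2.0 <= tm.l <= 4.0
    assert (lo < tm.l).all() and (hi >= tm.l).all()


def test_threshold_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fit_threshold(np.full(100, 2.0))


# --- binarization and transitions -------------------------------------------


def test_binarize_threshold_inclusive():
    assert binarize(np.array([3.0]), 3.0).tolist() == [1]
    assert binarize(np.array([1.0, 5.0, 1.0, 5.0]), 3.0).tolist() == [0, 1, 0, 1]
    assert binarize(np.array([1.0, 2.0]), 3.0).tolist() == [0, 0]


def test_transitions_clean_square_wave_all_accepted():
    t = np.arange(0, 420, 1.0)
    b = ((t % 105) >= 42).astype(int)   # off 42 min, on 63 min
    trs = detect_transitions(t, b)
    kinds = [x.kind for x in trs]
    assert kinds[0] == "off_to_on"
    assert all(a != b_ for a, b_ in zip(kinds[:-1], kinds[1:]))
    gaps = np.diff([x.time for x in trs])
    assert set(np.round(gaps, 6)) <= {42.0, 63.0}


def test_transitions_glitch_removed_with_partner():
    t = np.arange(0, 100, 2.0)
    b = np.ones_like(t, dtype=int)
    b[:10] = 0          # one genuine off->on edge at t=20
    b[25:26] = 0        # 2-min glitch inside the on segment
    trs = detect_transitions(t, b)
    assert [x.kind for x in trs] == ["off_to_on"]
    assert trs[0].time == pytest.approx(20.0)


def test_transitions_constant_trace_empty():
    t = np.arange(0, 50, 2.0)
    assert detect_transitions(t, np.ones_like(t, dtype=int)) == []


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=2, max_size=80))
def test_transitions_always_alternate_and_respect_refractory(bits):
    t = 2.0 * np.arange(len(bits))
    trs = detect_transitions(t, np.array(bits), min_gap=14.0)
    kinds = [x.kind for x in trs]
    for a, b in zip(kinds[:-1], kinds[1:]):
        assert a != b
    gaps = np.diff([x.time for x in trs])
    assert (gaps >= 14.0).all() if gaps.size else True


# --- phase from transitions -------------------------------------------------


def test_phase_cycling_elapsed_mapping():
    trs = [Transition(10.0, "on_to_off")]
    th = estimate_phase_cycling(trs, 31.0, 105.0, 4 * math.pi / 5)
    assert th == pytest.approx(2 * math.pi / 5)  # omega0 * 21 min
    trs = [Transition(10.0, "off_to_on")]
    assert estimate_phase_cycling(trs, 10.0, 105.0, 4 * math.pi / 5) \
        == pytest.approx(4 * math.pi / 5)
    assert estimate_phase_cycling([], 10.0, 105.0, 1.0) is None


def test_phase_cycling_clamps_at_segment_boundary():
    g1s = 4 * math.pi / 5
    trs = [Transition(0.0, "on_to_off")]
    th = estimate_phase_cycling(trs, 500.0, 105.0, g1s)
    assert th < g1s
    trs = [Transition(0.0, "off_to_on")]
    th = estimate_phase_cycling(trs, 500.0, 105.0, g1s)
    assert g1s < th < TWO_PI


# --- nominal period recovery ------------------------------------------------


def test_nominal_periods_from_clean_square_wave():
    t = np.arange(0, 630, 1.0)
    b = ((t % 105) >= 42).astype(int)
    bts = BinaryTraceSet(times=t, values=b[:, None],
                         transitions=[detect_transitions(t, b)])
    p = estimate_nominal_periods(bts)
    assert p.T_G1 == pytest.approx(42.0)
    assert p.T_SG2M == pytest.approx(63.0)
    assert p.T0 == pytest.approx(105.0)
    assert p.theta_G1S == pytest.approx(4 * math.pi / 5)


def test_nominal_periods_requires_complete_intervals():
    t = np.arange(0, 30, 2.0)
    bts = BinaryTraceSet(times=t, values=np.zeros((t.size, 1), dtype=int),
                         transitions=[[]])
    with pytest.raises(ValueError):
        estimate_nominal_periods(bts)


def test_binarize_smooth_idempotent_on_two_level_signal():
    """Level assignment survives the smoothing filters when plateaus are
    longer than the filter support."""
    t = np.arange(0, 420, 2.0)
    clean = np.where((t % 105) >= 42, 5.0, 1.0)
    b1 = binarize(clean, 3.0)
    b2 = binarize(smooth(clean), 3.0)
    # edges may shift by at most the half-width of the combined kernel
    assert np.abs(b1 - b2).sum() <= 3 * (np.abs(np.diff(b1)) != 0).sum()
    interior = (t % 105 > 8) & (t % 105 < 36) | \
               ((t % 105 > 50) & (t % 105 < 99))
    assert np.array_equal(b1[interior], b2[interior])


# --- budding index ----------------------------------------------------------


def test_budding_index_counts():
    flags = np.array([True] * 4 + [False] * 6)
    assert budding_index(flags) == pytest.approx(40.0)
    phases = np.full(5, 0.3)
    assert budding_index(phases, theta_G1S=1.0) == 0.0


def test_budding_index_uniform_phases_near_baseline():
    rng = np.random.default_rng(3)
    phases = rng.uniform(0, TWO_PI, 10_000)
    bi = budding_index(phases, theta_G1S=4 * math.pi / 5)
    assert bi == pytest.approx(60.0, abs=1.5)


def test_budding_index_empty_flagged():
    with pytest.raises(ValueError):
        budding_index(np.array([]))
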