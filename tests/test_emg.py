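"""EMG decoding: rectification, Butterworth envelope, Bayesian filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoloop.emg import (
    BayesParams,
    BayesPosterior,
    BayesianDecoder,
    DriveSignal,
    EMGTrace,
    InvalidInputError,
    InvalidParameterError,
    bayes_decode,
    bayes_init,
    bayes_measure,
    bayes_propagate,
    butterworth_envelope,
    calibrate_mv_scale,
    rectify,
    resample_drive,
)

from conftest import constant_drive_trace

# ---------------------------------------------------------------------------
# rectification and trace invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "samples, expected",
    [
        ([-1.0, 2.0, -3.0], [1.0, 2.0, 3.0]),
        ([0.0, 0.0, 0.0], [0.0, 0.0, 0.0]),
        ([0.5, 1.5, 2.5], [0.5, 1.5, 2.5]),  # already non-negative: identity
    ],
)
def test_rectify(samples, expected):
    out = rectify(EMGTrace(np.array(samples)))
    assert np.array_equal(out.samples, expected)
    assert out.fs == 2000.0


def test_trace_rejects_non_finite():
    with pytest.raises(InvalidInputError):
        EMGTrace(np.array([1.0, np.nan]))
    with pytest.raises(InvalidInputError):
        EMGTrace(np.array([1.0]), fs=0)


# ---------------------------------------------------------------------------
# Butterworth envelope
# ---------------------------------------------------------------------------


def test_butterworth_unit_dc_gain_and_zero_input():
    const = EMGTrace(np.full(20000, 0.4))
    out = butterworth_envelope(const)
    assert out.values[-1] == pytest.approx(0.4, rel=1e-4)
    zero = butterworth_envelope(EMGTrace(np.zeros(1000)))
    assert np.all(zero.values == 0)


def test_butterworth_rejects_cutoff_at_nyquist():
    with pytest.raises(InvalidParameterError):
        butterworth_envelope(EMGTrace(np.zeros(10), fs=100.0), cutoff_hz=50.0)


def _reference_lowpass_step_rise(order, cutoff_hz, fs, level=0.9):
    """Independent Butterworth design: analog prototype poles laid out on
    the unit circle, manual bilinear transform, direct difference-equation
    recursion on a unit step.  Returns the first sample index at ``level``.
    """
    n = order
    # analog low-pass prototype poles (unit cutoff), Butterworth layout
    k = np.arange(n)
    poles = np.exp(1j * np.pi * (2 * k + n + 1) / (2 * n))
    wc = 2 * fs * np.tan(np.pi * cutoff_hz / fs)  # pre-warped
    poles = poles * wc
    # H(s) = wc^n / prod(s - p); bilinear s = 2 fs (z-1)/(z+1)
    num_s = np.array([wc**n])
    den_s = np.real(np.poly(poles))
    c = 2.0 * fs
    # substitute: multiply through by (z+1)^n
    zp1 = np.array([1.0, 1.0])
    zm1 = np.array([1.0, -1.0])
    den_z = np.zeros(n + 1)
    for i, a in enumerate(den_s):  # a * s^(n-i)
        power = n - i
        term = np.array([a])
        for _ in range(power):
            term = np.convolve(term, c * zm1)
        for _ in range(n - power):
            term = np.convolve(term, zp1)
        den_z = np.polyadd(den_z, term)
    num_z = num_s[0] * np.ones(1)
    for _ in range(n):
        num_z = np.convolve(num_z, zp1)
    num_z = num_z / den_z[0]
    den_z = den_z / den_z[0]
    # direct-form recursion on a step input
    n_samp = int(3 * fs / cutoff_hz)
    x = np.ones(n_samp)
    y = np.zeros(n_samp)
    for t in range(n_samp):
        acc = sum(num_z[j] * x[t - j] for j in range(len(num_z)) if t - j >= 0)
        acc -= sum(den_z[j] * y[t - j] for j in range(1, len(den_z)) if t - j >= 0)
        y[t] = acc
    return int(np.argmax(y >= level))


def test_butterworth_step_rise_matches_independent_design():
    """90% rise of a unit step matches a from-scratch filter design."""
    fs, cutoff, order = 2000.0, 1.0, 3
    step = EMGTrace(np.ones(6000), fs)
    ours = butterworth_envelope(step, order, cutoff)
    ours_idx = int(np.argmax(ours.values >= 0.9))
    ref_idx = _reference_lowpass_step_rise(order, cutoff, fs)
    assert abs(ours_idx - ref_idx) <= 1


# ---------------------------------------------------------------------------
# Bayesian filter pieces
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n_levels", [4, 128])
def test_bayes_init_uniform(n_levels):
    post = bayes_init(BayesParams(n_levels=n_levels, x_floor=1.0 / n_levels))
    assert np.allclose(post.probs, 1.0 / n_levels)
    assert post.probs.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(post.levels) > 0)


def test_propagate_identity_and_uniform_limits():
    params = BayesParams(alpha=0.0, beta=0.0, n_levels=8, x_floor=0.1)
    post = bayes_init(params)
    delta = BayesPosterior(post.levels, np.eye(8)[3])
    assert np.array_equal(bayes_propagate(delta, params).probs, delta.probs)
    full_jump = BayesParams(alpha=0.0, beta=1.0, n_levels=8, x_floor=0.1)
    out = bayes_propagate(delta, full_jump)
    assert np.allclose(out.probs, 1.0 / 8)


def test_propagate_matches_hand_computed_four_bins():
    """Delta at bin 1, alpha=0.1: second-difference arithmetic by hand."""
    params = BayesParams(alpha=0.1, beta=0.0, n_levels=4, x_floor=0.25)
    post = BayesPosterior(np.array([0.25, 0.5, 0.75, 1.0]),
                          np.array([0.0, 1.0, 0.0, 0.0]))
    out = bayes_propagate(post, params)
    # lap = [p1-p0, p0-2p1+p2, p1-2p2+p3, p2-p3] = [1, -2, 1, 0]
    assert np.allclose(out.probs, [0.1, 0.8, 0.1, 0.0], atol=1e-15)


def test_propagate_rejects_unstable_alpha():
    with pytest.raises(InvalidParameterError):
        BayesParams(alpha=0.6)


def test_measure_single_support_invariance():
    params = BayesParams(n_levels=4, x_floor=0.25)
    levels = np.array([0.25, 0.5, 0.75, 1.0])
    delta = BayesPosterior(levels, np.eye(4)[2])
    out = bayes_measure(delta, 0.7)
    assert np.allclose(out.probs, delta.probs)


def test_measure_matches_hand_normalized_likelihood():
    """Uniform prior, e=0.5 on {0.25,0.5,0.75,1.0}: brute-force arithmetic."""
    levels = np.array([0.25, 0.5, 0.75, 1.0])
    post = BayesPosterior(levels, np.full(4, 0.25))
    out = bayes_measure(post, 0.5)
    lik = (1.0 / levels) * np.exp(-0.5 / levels)
    assert np.allclose(out.probs, lik / lik.sum(), atol=1e-12)


def test_measure_map_at_observation():
    """With a flat prior the exponential likelihood (1/x)exp(-e/x) peaks at
    x = e, so the MAP lands on the grid point nearest the observation."""
    params = BayesParams(alpha=0.0, beta=0.0, n_levels=256, x_floor=1 / 256)
    post = bayes_init(params)
    e = 0.37
    out = bayes_measure(post, e)
    nearest = post.levels[np.argmin(np.abs(post.levels - e))]
    assert out.map_level() == pytest.approx(nearest)


def test_measure_rejects_negative_sample():
    post = bayes_init(BayesParams(n_levels=4, x_floor=0.25))
    with pytest.raises(InvalidInputError):
        bayes_measure(post, -0.1)


# ---------------------------------------------------------------------------
# whole-filter behaviour
# ---------------------------------------------------------------------------


def test_decode_zero_trace_pinned_at_floor(bayes_params):
    out = bayes_decode(EMGTrace(np.zeros(500)), bayes_params)
    assert np.all(out.values == bayes_params.x_floor)


def test_streaming_decoder_matches_functional_recursion(bayes_params):
    """The fast streaming loop and the documented propagate/measure
    recursion are the same filter, sample for sample."""
    rng = np.random.default_rng(42)
    params = BayesParams(alpha=0.05, beta=1e-6, n_levels=16, x_floor=1 / 16)
    samples = np.abs(rng.normal(0, 0.4, size=50))
    dec = BayesianDecoder(params, mv_scale=1.0)
    fast = dec.process(samples)
    post = bayes_init(params)
    slow = []
    for e in samples:
        post = bayes_propagate(post, params)
        post = bayes_measure(post, e)
        slow.append(post.map_level())
    assert np.allclose(fast, slow, atol=1e-12)


@pytest.mark.parametrize("x_true, seed", [(0.2, 10), (0.5, 11), (0.8, 12)])
def test_constant_drive_recovery(x_true, seed, mv_scale):
    """MAP time-average over the final second recovers the latent drive to
    within 10% from 10 s of synthesized EMG."""
    trace = constant_drive_trace(x_true, n=20000, seed=seed)
    drive = bayes_decode(trace, mv_scale=mv_scale)
    est = drive.values[-2000:].mean()
    assert est == pytest.approx(x_true, rel=0.10)


def test_bayes_no_slower_than_butterworth_on_step(mv_scale):
    """On a 0.1->0.6 jump the Bayesian MAP reaches 90% of the step no later
    than the 1 Hz Butterworth envelope on the same trace."""
    from myoloop.subject import IntentTrace, synthesize_emg

    x = np.concatenate([np.full(4000, 0.1), np.full(8000, 0.6)])
    trace = synthesize_emg(IntentTrace(x), seed=5)
    bayes = bayes_decode(trace, mv_scale=mv_scale)
    lin = butterworth_envelope(rectify(trace), 3, 1.0, mv_scale)
    thr = 0.1 + 0.9 * 0.5

    def crossing(values):
        idx = np.flatnonzero(values[4000:] >= thr)
        return idx[0] if idx.size else np.inf

    assert crossing(bayes.values) <= crossing(lin.values)


@given(
    st.lists(st.floats(0.0, 2.0), min_size=5, max_size=30),
    st.floats(0.0, 0.5),
    st.floats(0.0, 1e-3),
)
@settings(max_examples=50, deadline=None)
def test_posterior_stays_normalized_and_nonnegative(samples, alpha, beta):
    """Mass conservation and non-negativity through arbitrary filtering."""
    params = BayesParams(alpha=alpha, beta=beta, n_levels=16, x_floor=1 / 16)
    post = bayes_init(params)
    for e in samples:
        post = bayes_propagate(post, params)
        post = bayes_measure(post, e)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(post.probs >= 0)
        assert params.x_floor <= post.map_level() <= 1.0


# ---------------------------------------------------------------------------
# calibration and resampling
# ---------------------------------------------------------------------------


def test_mv_scale_calibration_tracks_folded_gaussian_mean():
    trace = constant_drive_trace(1.0, n=40000, seed=2)
    assert calibrate_mv_scale(trace) == pytest.approx(
        np.sqrt(2 / np.pi), rel=0.02
    )
    assert calibrate_mv_scale(trace, "p95") > calibrate_mv_scale(trace)


def test_resample_constant_and_length():
    d = DriveSignal(np.full(2000, 0.4), 2000.0)
    out = resample_drive(d, 100.0)
    assert out.values.size == 100
    assert np.all(out.values == 0.4)
    assert out.fs == 100.0


def test_resample_ramp_matches_direct_indexing():
    ramp = DriveSignal(np.linspace(0, 1, 2000), 2000.0)
    out = resample_drive(ramp, 100.0)
    assert np.array_equal(out.values, ramp.values[19::20])
    assert out.values[-1] == ramp.values[-1]  # causal endpoint preserved


def test_resample_rejects_bad_rate():
    d = DriveSignal(np.zeros(10), 2000.0)
    with pytest.raises(InvalidParameterError):
        resample_drive(d, 0.0)
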