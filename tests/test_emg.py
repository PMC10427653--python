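"""EMG chain: filtering, rectification, baseline logic, synthetic ground truth."""

import math

import numpy as np
import pytest
from scipy import signal

from cadkit.emg import (
    BASELINE_DURATION,
    STIM_DURATION,
    EMGRecording,
    EMGSimConfig,
    condition_means,
    filter_rectify,
    preprocess,
    synthesize_emg,
)

CONDS = ("view_neu", "view_neg", "distraction", "distancing", "suppression")


def _flat_amplitudes(c_amp, l_amp):
    return {"corrugator": {c: c_amp for c in CONDS},
            "levator": {c: l_amp for c in CONDS}}


def test_zero_signal_gives_zero_activity():
    rec = EMGRecording(
        samples={"corrugator": np.zeros(20_000), "levator": np.zeros(20_000)},
        sampling_rate=1000.0,
        events=[(5_000, "view_neu"), (12_000, "view_neg")],
    )
    trials = preprocess(rec)
    assert len(trials) == 4  # 2 trials x 2 channels
    assert (trials.activity == 0).all()
    assert (trials.baseline == 0).all()


def test_mains_sinusoid_is_notched_out():
    """A pure 50 Hz component must be attenuated by well over 20 dB
    relative to its unfiltered rectified mean."""
    t = np.arange(60_000) / 1000.0
    sine = np.sin(2 * np.pi * 50.0 * t)
    rec = EMGRecording(
        samples={"corrugator": sine.copy(), "levator": sine.copy()},
        sampling_rate=1000.0,
        events=[(10_000, "view_neg"), (30_000, "view_neg")],
    )
    trials = preprocess(rec)
    stim_mean = (trials.activity + trials.baseline).abs().max()
    raw_rectified_mean = np.abs(sine).mean()
    assert 20 * np.log10(stim_mean / raw_rectified_mean) <= -20.0


def test_double_preprocessing_is_rejected():
    rec = synthesize_emg(EMGSimConfig(trials_per_block=1), seed=0)
    processed = filter_rectify(rec)
    with pytest.raises(TypeError):
        preprocess(processed)
    with pytest.raises(TypeError):
        filter_rectify(processed)


def test_sampling_rate_must_clear_nyquist():
    rec = EMGRecording(samples={"corrugator": np.zeros(1000), "levator": np.zeros(1000)},
                       sampling_rate=500.0, events=[])
    with pytest.raises(ValueError, match="sampling rate"):
        preprocess(rec)


def test_out_of_bounds_trial_dropped_with_warning():
    rec = EMGRecording(
        samples={"corrugator": np.zeros(10_000), "levator": np.zeros(10_000)},
        sampling_rate=1000.0,
        events=[(500, "view_neu"), (3_000, "view_neg")],  # first lacks 2 s baseline
    )
    with pytest.warns(UserWarning, match="dropped"):
        trials = preprocess(rec)
    assert set(trials.condition) == {"view_neg"}


def test_synthesis_is_deterministic():
    r1 = synthesize_emg(EMGSimConfig(trials_per_block=2), seed=42)
    r2 = synthesize_emg(EMGSimConfig(trials_per_block=2), seed=42)
    assert r1.events == r2.events
    for ch in r1.samples:
        np.testing.assert_array_equal(r1.samples[ch], r2.samples[ch])


def test_condition_ordering_recovered_from_known_amplitudes():
    amps = {"corrugator": {"view_neu": 0.1, "view_neg": 1.2, "distraction": 0.4,
                           "distancing": 0.7, "suppression": 0.25},
            "levator": {"view_neu": 0.1, "view_neg": 0.8, "distraction": 0.3,
                        "distancing": 0.5, "suppression": 0.2}}
    cfg = EMGSimConfig(trials_per_block=8, burst_amplitudes=amps)
    trials = preprocess(synthesize_emg(cfg, seed=6))
    means = condition_means(trials)
    for ch in ("corrugator", "levator"):
        got = means[means.channel == ch].set_index("condition")["mean_activity"]
        want_order = sorted(amps[ch], key=amps[ch].get)
        assert list(got.loc[want_order].sort_values().index) == want_order


def _chain_rms_gain(fs=1000.0):
    """Closed-form RMS gain of the zero-phase filter cascade over the
    band-limited carrier spectrum (no data involved)."""
    f = np.linspace(0.0, fs / 2, 20_001)
    _, h_bp = signal.sosfreqz(signal.butter(8, (20, 300), "bandpass", fs=fs,
                                            output="sos"), worN=f, fs=fs)
    _, h_hp = signal.sosfreqz(signal.butter(8, 20, "highpass", fs=fs,
                                            output="sos"), worN=f, fs=fs)
    _, h_lp = signal.sosfreqz(signal.butter(8, 300, "lowpass", fs=fs,
                                            output="sos"), worN=f, fs=fs)
    b, a = signal.iirnotch(50.0, 30.0, fs=fs)
    _, h_n = signal.freqz(b, a, worN=f, fs=fs)
    carrier_psd = np.abs(h_bp) ** 4  # zero-phase filtering squares |H|
    chain_power = (np.abs(h_hp) * np.abs(h_lp) * np.abs(h_n)) ** 4
    return math.sqrt(np.trapezoid(chain_power * carrier_psd, f)
                     / np.trapezoid(carrier_psd, f))


def test_recovered_activity_matches_closed_form_expectation():
    """Zero noise floor, known amplitude: activity equals the rectified-
    Gaussian expectation sqrt(2/pi)*a corrected for the cascade gain and
    the moving-average edge terms, within 1%."""
    amp_c, amp_l = 1.0, 0.5
    cfg = EMGSimConfig(trials_per_block=8, noise_floor=0.0,
                       burst_amplitudes=_flat_amplitudes(amp_c, amp_l))
    trials = preprocess(synthesize_emg(cfg, seed=1))
    g = _chain_rms_gain()
    smooth_w = 0.1
    edge = 1.0 - smooth_w / (4 * STIM_DURATION)  # ramp loss inside the window
    baseline_leak = smooth_w / (8 * BASELINE_DURATION)  # smoothing leaks into baseline
    for ch, amp in (("corrugator", amp_c), ("levator", amp_l)):
        expectation = amp * math.sqrt(2 / math.pi) * g * (edge - baseline_leak)
        got = trials.loc[trials.channel == ch, "activity"].mean()
        assert got == pytest.approx(expectation, rel=0.01)


def test_equal_amplitudes_give_indistinguishable_conditions():
    """With identical burst amplitude everywhere, no condition stands out:
    the between-condition spread stays within sampling noise of the
    per-trial activity distribution."""
    cfg = EMGSimConfig(trials_per_block=10, burst_amplitudes=_flat_amplitudes(0.5, 0.5))
    trials = preprocess(synthesize_emg(cfg, seed=9))
    for ch in ("corrugator", "levator"):
        sub = trials[trials.channel == ch]
        cond_means = sub.groupby("condition")["activity"].mean()
        se = sub["activity"].std(ddof=1) / np.sqrt(cfg.trials_per_block)
        assert cond_means.max() - cond_means.min() <= 6 * se
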