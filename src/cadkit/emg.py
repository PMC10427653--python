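"""Facial-EMG preprocessing and a synthetic-signal generator.

The preprocessing chain for the two recorded muscles (corrugator
supercilii, indexing negative valence; levator labii, indexing disgust)
is: band-pass filtering 20-300 Hz (Butterworth, order 8, zero-phase),
50 Hz mains notch, full-wave rectification, integration by moving-average
smoothing (100 ms default), downsampling to 100 Hz, then per-trial mean
activity over the 6 s picture window, baseline-corrected by subtracting
the mean of the 2 s window before stimulus onset.  Filter family, phase
handling and the integration window are configurable because only the
cutoffs and orders are fixed by the recording protocol.

The generator produces a band-limited noise carrier whose amplitude
during each 6 s stimulus window depends on the block condition, with
fixation gaps drawn uniformly from 3-5 s, so the chain can be validated
against known ground truth without any recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .strategies import ALL_CONDITIONS

CHANNELS = ("corrugator", "levator")

STIM_DURATION = 6.0  # s of picture presentation
BASELINE_DURATION = 2.0  # s before onset used for baseline correction


@dataclass
class EMGRecording:
    """Raw two-channel recording with stimulus-onset events.

    ``events`` is a list of ``(onset_sample, condition)`` pairs; each
    event needs at least 2 s of signal before the onset and 6 s after.
    """

    samples: dict  # channel -> 1-D float array, mV
    sampling_rate: float = 1000.0
    events: list = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(v) for v in self.samples.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have the same length")
        self.n_samples = lengths.pop()

    def validate(self, lowpass: float = 300.0) -> None:
        if self.sampling_rate <= 2 * lowpass:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz must exceed twice "
                f"the low-pass cutoff ({lowpass} Hz)"
            )


@dataclass
class ProcessedEMG:
    """Rectified, smoothed and downsampled signal; input to trial scoring.

    A distinct type from :class:`EMGRecording` so the filter chain cannot
    be applied twice by accident.
    """

    samples: dict
    sampling_rate: float
    events: list


def filter_rectify(
    recording: EMGRecording,
    *,
    highpass: float = 20.0,
    lowpass: float = 300.0,
    order: int = 8,
    notch: float = 50.0,
    notch_q: float = 30.0,
    smooth_window: float = 0.1,
    target_rate: float = 100.0,
) -> ProcessedEMG:
    """Filter, rectify, integrate and downsample a raw recording."""
    if not isinstance(recording, EMGRecording):
        raise TypeError("filter chain expects a raw EMGRecording")
    recording.validate(lowpass)
    fs = recording.sampling_rate
    sos_hp = signal.butter(order, highpass, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.butter(order, lowpass, btype="lowpass", fs=fs, output="sos")
    b_notch, a_notch = signal.iirnotch(notch, notch_q, fs=fs)
    win = max(1, int(round(smooth_window * fs)))
    kernel = np.ones(win) / win
    decim = int(round(fs / target_rate))
    out = {}
    for ch, x in recording.samples.items():
        y = signal.sosfiltfilt(sos_hp, np.asarray(x, dtype=float))
        y = signal.sosfiltfilt(sos_lp, y)
        y = signal.filtfilt(b_notch, a_notch, y)
        y = np.abs(y)  # full-wave rectification
        y = np.convolve(y, kernel, mode="same")  # moving-average integration
        out[ch] = y[::decim]
    new_rate = fs / decim
    events = [(int(onset // decim), cond) for onset, cond in recording.events]
    return ProcessedEMG(samples=out, sampling_rate=new_rate, events=events)


def trial_activity(
    processed: ProcessedEMG,
    *,
    stim_duration: float = STIM_DURATION,
    baseline_duration: float = BASELINE_DURATION,
) -> pd.DataFrame:
    """Per-trial baseline-corrected mean activity for each channel.

    Activity is the mean over the stimulus window minus the mean over
    the pre-onset baseline window, so the corrected pre-onset mean is
    zero by construction.  Trials whose windows fall outside the record
    are dropped with a warning.
    """
    fs = processed.sampling_rate
    n_stim = int(round(stim_duration * fs))
    n_base = int(round(baseline_duration * fs))
    n = len(next(iter(processed.samples.values())))
    rows = []
    for trial, (onset, condition) in enumerate(processed.events, start=1):
        if onset - n_base < 0 or onset + n_stim > n:
            warnings.warn(
                f"trial {trial} ({condition}) window exceeds the record; dropped",
                stacklevel=2,
            )
            continue
        for ch in processed.samples:
            x = processed.samples[ch]
            baseline = float(np.mean(x[onset - n_base : onset]))
            stim = float(np.mean(x[onset : onset + n_stim]))
            rows.append(
                {
                    "trial": trial,
                    "condition": condition,
                    "channel": ch,
                    "baseline": baseline,
                    "activity": stim - baseline,
                }
            )
    return pd.DataFrame(rows, columns=["trial", "condition", "channel", "baseline", "activity"])


def preprocess(recording: EMGRecording, **params) -> pd.DataFrame:
    """Full chain from raw recording to the per-trial activity table."""
    if isinstance(recording, ProcessedEMG):
        raise TypeError("recording has already been through the filter chain")
    stim = params.pop("stim_duration", STIM_DURATION)
    base = params.pop("baseline_duration", BASELINE_DURATION)
    processed = filter_rectify(recording, **params)
    return trial_activity(processed, stim_duration=stim, baseline_duration=base)


def condition_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Average per-trial activity per condition and channel."""
    return (
        trials.groupby(["condition", "channel"], as_index=False)["activity"]
        .mean()
        .rename(columns={"activity": "mean_activity"})
    )


# ---------------------------------------------------------------------------
# Synthetic generator


@dataclass
class EMGSimConfig:
    """Ground-truth layout for a synthetic recording.

    ``burst_amplitudes`` maps condition -> extra carrier amplitude (mV)
    during the 6 s stimulus window, added to the resting
    ``noise_floor``.  Defaults follow the per-condition activity scale
    of the study's condition table (non-negative part).
    """

    conditions: tuple = ALL_CONDITIONS
    trials_per_block: int = 20
    noise_floor: float = 1.0  # resting carrier amplitude, mV
    burst_amplitudes: dict = field(
        default_factory=lambda: {
            "corrugator": {
                "view_neu": 0.04,
                "view_neg": 1.03,
                "distraction": 0.0,
                "distancing": 0.25,
                "suppression": 0.07,
            },
            "levator": {
                "view_neu": 0.09,
                "view_neg": 0.58,
                "distraction": 0.0,
                "distancing": 0.01,
                "suppression": 0.0,
            },
        }
    )
    sampling_rate: float = 1000.0
    fixation_min: float = 3.0  # uniform fixation-cross gap, s
    fixation_max: float = 5.0
    carrier_band: tuple = (20.0, 300.0)


def synthesize_emg(config: EMGSimConfig | None = None, seed=0) -> EMGRecording:
    """Generate a raw two-channel recording with condition-tagged events.

    The carrier is Gaussian noise band-limited to the EMG band and
    scaled so its rectified mean at unit amplitude is sqrt(2/pi) mV;
    during each stimulus window the amplitude is
    ``noise_floor + burst_amplitudes[channel][condition]``.
    """
    config = config or EMGSimConfig()
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n_stim = int(round(STIM_DURATION * fs))

    # lay out the block design: fixation gap then 6 s picture, per trial
    events = []
    cursor = int(round(config.fixation_min * fs))  # leading padding
    for condition in config.conditions:
        for _ in range(config.trials_per_block):
            gap = rng.uniform(config.fixation_min, config.fixation_max)
            cursor += int(round(gap * fs))
            events.append((cursor, condition))
            cursor += n_stim
    n_total = cursor + int(round(BASELINE_DURATION * fs))

    # steep zero-phase band-limiting keeps essentially all carrier power
    # inside the EMG band, so downstream filtering leaves it unchanged
    sos = signal.butter(8, config.carrier_band, btype="bandpass", fs=fs, output="sos")
    samples = {}
    for ch in CHANNELS:
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n_total))
        sd = carrier.std()
        if sd > 0:
            carrier /= sd  # unit variance -> rectified mean sqrt(2/pi)
        amplitude = np.full(n_total, config.noise_floor)
        for onset, condition in events:
            amplitude[onset : onset + n_stim] = (
                config.noise_floor + config.burst_amplitudes[ch][condition]
            )
        samples[ch] = carrier * amplitude
    return EMGRecording(samples=samples, sampling_rate=fs, events=events)
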