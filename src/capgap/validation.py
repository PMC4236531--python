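"""EMG processing and rank-correlation validation of simulated activations.

The processing chain mirrors standard surface-EMG practice: zero-lag
band-pass 20-400 Hz, full-wave rectification, zero-lag low-pass 10 Hz,
amplitude normalization to the trial maximum, and resampling to the
trial's kinematic frames.  Validation compares the processed envelope
with the simulated muscle activation using a Spearman rank correlation
(rank-based, so the amplitude normalization cannot affect it) with a
seeded permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps
from scipy import stats

from .synth import SyntheticEMG

__all__ = ["EMGEnvelope", "SpearmanResult", "process_emg", "spearman_validation"]

BANDPASS_HZ = (20.0, 400.0)
LOWPASS_HZ = 10.0
FILTER_ORDER = 4  # Butterworth, applied forward-backward (zero lag)


@dataclass
class EMGEnvelope:
    """Normalized EMG amplitude envelope at trial frame times."""

    muscle: str
    time: np.ndarray
    envelope: np.ndarray

    def __post_init__(self):
        if np.any(self.envelope < -1e-12):
            raise ValueError("envelope must be non-negative")


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float


def process_emg(
    raw,
    fs: float | None = None,
    trial_time: np.ndarray | None = None,
    muscle: str = "",
) -> EMGEnvelope:
    """Band-pass, rectify, low-pass, normalize, resample — in that order.

    Accepts a :class:`~capgap.synth.SyntheticEMG` (carrying its own
    sampling rate and trial frame times) or a plain array with ``fs``
    and, optionally, target ``trial_time``.  The envelope is normalized
    to its own maximum; a signal whose band-passed content is
    numerically zero (e.g. a DC input) is left unnormalized so its
    envelope stays at zero.
    """
    if isinstance(raw, SyntheticEMG):
        signal = np.asarray(raw.raw, dtype=float)
        fs = raw.fs
        t = raw.time
        trial_time = raw.trial_time if trial_time is None else trial_time
        muscle = muscle or raw.muscle
    else:
        signal = np.asarray(raw, dtype=float)
        if fs is None:
            raise ValueError("fs is required for a plain signal array")
        t = np.arange(signal.shape[0]) / fs
    if fs < 2.0 * BANDPASS_HZ[1]:
        raise ValueError(
            f"sampling rate {fs} Hz is below 2x the {BANDPASS_HZ[1]} Hz band-pass edge"
        )
    if signal.shape[0] / fs < 1.0:
        raise ValueError("need at least 1 s of signal")

    sos_band = sps.butter(FILTER_ORDER, BANDPASS_HZ, btype="bandpass", fs=fs, output="sos")
    sos_low = sps.butter(FILTER_ORDER, LOWPASS_HZ, btype="low", fs=fs, output="sos")
    banded = sps.sosfiltfilt(sos_band, signal)
    env = sps.sosfiltfilt(sos_low, np.abs(banded))
    env = np.maximum(env, 0.0)  # zero-lag low-pass can ring slightly negative

    peak = float(np.max(env))
    floor = 1e-8 * max(float(np.max(np.abs(signal))), 1e-300)
    if peak > floor:
        env = env / peak

    if trial_time is not None:
        env = np.interp(trial_time, t, env)
        t = np.asarray(trial_time, dtype=float)
    return EMGEnvelope(muscle=muscle, time=t, envelope=env)


def spearman_validation(
    envelope,
    activation: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> SpearmanResult:
    """Spearman rank correlation between an envelope and an activation series.

    Ties get average ranks.  The p-value is a two-sided permutation test
    (ranks of one series shuffled ``n_permutations`` times, seeded).  A
    constant input series makes the correlation undefined and raises.
    """
    x = np.asarray(envelope.envelope if isinstance(envelope, EMGEnvelope) else envelope, float)
    y = np.asarray(activation, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input series: Spearman correlation undefined")

    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.shape[0]
    count = 0
    for _ in range(n_permutations):
        r = float(np.mean(rx[rng.permutation(n)] * ry))
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return SpearmanResult(rho=rho, p_value=p)
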