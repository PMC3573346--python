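"""Morlet-wavelet extraction of complex time-frequency coefficients and phases.

One complex coefficient per (trial, channel) at a single requested time and
frequency: the inner product of the zero-meaned signal with an L2-normalized
Gaussian-enveloped complex exponential. Only the phases feed the statistics
downstream, so the normalization is cosmetic (asserted by test); the
demodulation is referenced to absolute recording time so that a stationary
cosine cos(2*pi*f*t + phi) yields the coefficient phase phi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .circstats import AngleSample, wrap_angles
from .exceptions import EdgeEffectError, InvalidInputError, UndefinedPhaseError

__all__ = ["TrialArray", "TFCoefficients", "morlet_coefficients", "phase_differences"]

#: Gaussian envelope truncation, in units of the envelope sigma_t.
#: exp(-TRUNC_SIGMAS**2 / 2) ~ 3e-4, negligible for phase estimates.
TRUNC_SIGMAS = 4.0


@dataclass(frozen=True)
class TrialArray:
    """Real-valued recordings indexed (trial, channel, sample).

    Parameters
    ----------
    data
        Array of shape (n_trials, n_channels, n_samples).
    fs
        Sampling rate in Hz, > 0.
    t0
        Time of the first sample in seconds (default 0).
    channel_names
        Optional channel labels, one per channel.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    channel_names: Optional[tuple] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise InvalidInputError(f"data must be 3-d (trial, channel, sample), got ndim={d.ndim}")
        if d.shape[0] < 1 or d.shape[1] < 1 or d.shape[2] < 2:
            raise InvalidInputError(f"need >= 1 trial, >= 1 channel, >= 2 samples, got shape {d.shape}")
        if not np.all(np.isfinite(d)):
            raise InvalidInputError("data must be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        d.setflags(write=False)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "t0", float(self.t0))
        if self.channel_names is not None:
            names = tuple(str(c) for c in self.channel_names)
            if len(names) != d.shape[1]:
                raise InvalidInputError("channel_names length must match the channel axis")
            object.__setattr__(self, "channel_names", names)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.fs


@dataclass(frozen=True)
class TFCoefficients:
    """Complex Morlet coefficients indexed (trial, channel) at one (time, freq) point."""

    values: np.ndarray
    freq: float
    time: float
    bandwidth_spec: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 2:
            raise InvalidInputError("coefficient array must be 2-d (trial, channel)")
        if self.freq <= 0:
            raise InvalidInputError(f"frequency must be positive, got {self.freq}")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


def morlet_sigma_t(freq: float, cycles: float) -> float:
    """Gaussian envelope width sigma_t = cycles / (2*pi*freq), in seconds."""
    return cycles / (2.0 * np.pi * freq)


def morlet_coefficients(
    trials: TrialArray,
    freq: float,
    time: float,
    cycles: float = 7.0,
) -> TFCoefficients:
    """Complex Morlet coefficient per (trial, channel) at one time-frequency point.

    The wavelet is a Gaussian envelope of width sigma_t = cycles/(2*pi*freq)
    centered on ``time``, truncated at +/- 4 sigma_t, multiplying a complex
    exponential at ``freq``; signals are demeaned per trial and channel
    before projection. The evaluation time must keep the full truncated
    support inside the recording, otherwise an :class:`EdgeEffectError`
    reports the minimum margin.
    """
    if freq <= 0 or cycles <= 0:
        raise InvalidInputError("freq and cycles must be positive")
    sigma_t = morlet_sigma_t(freq, cycles)
    margin = TRUNC_SIGMAS * sigma_t
    t_start, t_end = trials.t0, trials.t0 + trials.duration
    if not (t_start + margin <= time <= t_end - margin):
        raise EdgeEffectError(
            f"evaluation time {time:.4f} s is too close to the recording edge "
            f"[{t_start:.4f}, {t_end:.4f}] s; the {cycles}-cycle wavelet at {freq} Hz "
            f"needs a margin of {margin:.4f} s on each side"
        )
    taus = trials.times
    lo = int(np.searchsorted(taus, time - margin, side="left"))
    hi = int(np.searchsorted(taus, time + margin, side="right"))
    seg_t = taus[lo:hi]
    envelope = np.exp(-0.5 * ((seg_t - time) / sigma_t) ** 2)
    wavelet = envelope * np.exp(1j * 2.0 * np.pi * freq * seg_t)
    wavelet /= np.linalg.norm(wavelet)
    demeaned = trials.data - trials.data.mean(axis=2, keepdims=True)
    values = demeaned[:, :, lo:hi] @ np.conj(wavelet)
    return TFCoefficients(
        values=values,
        freq=float(freq),
        time=float(time),
        bandwidth_spec=f"morlet cycles={cycles} (sigma_t={sigma_t:.6g} s)",
    )


def phase_differences(coeffs: TFCoefficients, chan_a: int, chan_b: int) -> AngleSample:
    """Per-trial phase difference arg(coef_a) - arg(coef_b), wrapped to [0, 2*pi)."""
    n_chan = coeffs.values.shape[1]
    for c in (chan_a, chan_b):
        if not (0 <= c < n_chan):
            raise InvalidInputError(f"channel index {c} out of range for {n_chan} channels")
    va = coeffs.values[:, chan_a]
    vb = coeffs.values[:, chan_b]
    for name, v in (("a", va), ("b", vb)):
        zero = np.flatnonzero(np.abs(v) == 0.0)
        if zero.size:
            raise UndefinedPhaseError(
                f"zero-magnitude coefficient on channel {name} at trial {int(zero[0])}: phase undefined"
            )
    return AngleSample(
        wrap_angles(np.angle(va) - np.angle(vb)),
        label=f"phase-diff ch{chan_a}-ch{chan_b} @ {coeffs.freq:g} Hz, {coeffs.time:g} s",
    )
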