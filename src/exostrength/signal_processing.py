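"""Torque / sEMG signal conditioning and repetition extraction.

The raw inputs are a hip-joint torque trace from the exoskeleton motors
and eight surface-EMG channels sampled at 2 kHz. This module turns them
into analysis-ready objects:

* mains-interference removal (notch) and 20–500 Hz band-pass for sEMG;
* a moving-RMS rectified envelope;
* MVIC normalization, ``(x - rest) / (max - rest)``, expressing sEMG as a
  fraction of the maximum voluntary isometric contraction reference;
* repetition-peak detection on either the torque trace or an sEMG
  envelope, yielding a :class:`RepetitionSeries` of peak times,
  flexion-to-flexion intervals and repetition speeds.

All filters are 4th-order IIR designs applied forward-backward
(zero phase), so burst centres and torque peaks are not shifted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .protocols import ExerciseProtocol

TRACE_KINDS = ("torque", "semg_raw", "semg_mvic", "envelope")


@dataclass
class SignalTrace:
    """One uniformly sampled channel.

    ``samples`` are Nm for torque, a.u. for raw sEMG and dimensionless
    after MVIC normalization; ``rate`` is the sampling rate in Hz.
    """

    samples: np.ndarray
    rate: float
    channel: str = ""
    kind: str = "semg_raw"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in channel {self.channel!r}")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass
class MvicReference:
    """Per-channel MVIC normalization reference.

    ``semg_max`` is the maximum envelope value over the 1RM / isometric
    reference recordings; ``semg_rest`` the resting envelope level.
    """

    semg_max: dict[str, float]
    semg_rest: dict[str, float]

    def __post_init__(self) -> None:
        for ch, mx in self.semg_max.items():
            rest = self.semg_rest.get(ch)
            if rest is None:
                raise ValueError(f"channel {ch!r} has max but no rest level")
            if not (mx > rest >= 0.0):
                raise ValueError(
                    f"channel {ch!r}: need semg_max > semg_rest >= 0, got {mx} / {rest}"
                )


@dataclass
class RepetitionSeries:
    """Ordered repetition-peak times with derived intervals and speeds."""

    peak_times: np.ndarray
    source: str = "torque"

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size >= 2 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak_times must be strictly ascending")

    def __len__(self) -> int:
        return int(self.peak_times.size)

    @property
    def intervals(self) -> np.ndarray:
        """Flexion-to-flexion intervals in seconds."""
        return np.diff(self.peak_times)

    @property
    def speeds_rpm(self) -> np.ndarray:
        return 60.0 / self.intervals

    @property
    def speeds_per10s(self) -> np.ndarray:
        return 10.0 / self.intervals


class EmptySeriesWarning(UserWarning):
    """No repetition peaks were found in a trace."""


def _zero_phase(sos_or_ba, x: np.ndarray, *, sos: bool) -> np.ndarray:
    if sos:
        return sps.sosfiltfilt(sos_or_ba, x)
    b, a = sos_or_ba
    return sps.filtfilt(b, a, x)


def notch_filter(trace: SignalTrace, mains_freq: float = 60.0, q: float = 30.0) -> SignalTrace:
    """Remove power-line interference with a zero-phase IIR notch.

    Raises if ``mains_freq`` is at or above the Nyquist frequency.
    """
    nyq = trace.rate / 2.0
    if not (0.0 < mains_freq < nyq):
        raise ValueError(f"mains_freq {mains_freq} Hz outside (0, Nyquist={nyq}) Hz")
    if q <= 0:
        raise ValueError("q must be > 0")
    b, a = sps.iirnotch(mains_freq, q, fs=trace.rate)
    return replace(trace, samples=_zero_phase((b, a), trace.samples, sos=False))


def bandpass_filter(trace: SignalTrace, low: float = 20.0, high: float = 500.0, order: int = 4) -> SignalTrace:
    """20–500 Hz zero-phase Butterworth band-pass (sEMG passband).

    The low edge doubles as the high-pass stage that removes slow
    mechanical/motion artefacts.
    """
    nyq = trace.rate / 2.0
    if not (0.0 < low < high):
        raise ValueError("need 0 < low < high")
    if high > nyq:
        raise ValueError(f"high edge {high} Hz exceeds Nyquist {nyq} Hz")
    # at high == Nyquist the band-pass degenerates to a high-pass
    if high == nyq:
        sos = sps.butter(order, low, btype="highpass", fs=trace.rate, output="sos")
    else:
        sos = sps.butter(order, [low, high], btype="bandpass", fs=trace.rate, output="sos")
    return replace(trace, samples=_zero_phase(sos, trace.samples, sos=True))


def rectified_envelope(trace: SignalTrace, window: float = 0.1) -> SignalTrace:
    """Moving-RMS envelope of the rectified signal (length preserved).

    ``window`` is the RMS window in seconds; edges are handled by
    reflect padding.
    """
    w = int(round(window * trace.rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > trace.samples.size:
        raise ValueError("window longer than trace")
    mean_sq = uniform_filter1d(trace.samples**2, size=w, mode="reflect")
    env = np.sqrt(np.maximum(mean_sq, 0.0))
    return replace(trace, samples=env, kind="envelope")


def mvic_normalize(trace: SignalTrace, ref: MvicReference) -> SignalTrace:
    """Express an sEMG envelope as a fraction of the MVIC reference.

    Applies ``(x - rest) / (max - rest)`` elementwise for the trace's
    channel; output lies in [0, 1] wherever rest <= x <= max.
    """
    ch = trace.channel
    if ch not in ref.semg_max:
        raise KeyError(f"no MVIC reference for channel {ch!r}")
    mx, rest = ref.semg_max[ch], ref.semg_rest[ch]
    if mx == rest:
        raise ZeroDivisionError(f"channel {ch!r}: semg_max equals semg_rest")
    out = (trace.samples - rest) / (mx - rest)
    return replace(trace, samples=out, kind="semg_mvic")


def detect_rep_peaks(
    trace: SignalTrace,
    protocol: ExerciseProtocol,
    *,
    min_distance_frac: float = 0.5,
    prominence_frac: float = 0.30,
    smooth_window: float = 0.05,
) -> RepetitionSeries:
    """Find one peak per repetition cycle.

    For torque this finds the positive flexion-phase peaks; for an sEMG
    envelope, the per-rep burst maxima. The protocol's expected pace sets
    the minimum inter-peak distance (``min_distance_frac`` of the expected
    interval); required prominence is ``prominence_frac`` of the trace's
    95th-percentile amplitude. Torque is pre-smoothed with a centred
    moving average of ``smooth_window`` s — symmetric, so the location of
    a symmetric lobe peak is unchanged while broadband measurement noise
    (which would jitter the flat lobe top) is suppressed. An empty result
    is returned with a warning rather than raised — zero detected
    repetitions is meaningful.
    """
    x = trace.samples
    if trace.kind == "torque" and smooth_window > 0:
        w = int(round(smooth_window * trace.rate)) | 1  # odd: no phase shift
        if 1 < w < x.size:
            x = uniform_filter1d(x, size=w, mode="reflect")
    distance = max(1, int(round(min_distance_frac * protocol.expected_interval_s * trace.rate)))
    scale = float(np.percentile(x, 95))
    prominence = prominence_frac * scale if scale > 0 else None
    idx, _ = sps.find_peaks(x, distance=distance, prominence=prominence)
    if idx.size == 0:
        warnings.warn(
            f"no repetition peaks found in {trace.channel or trace.kind}",
            EmptySeriesWarning,
            stacklevel=2,
        )
    source = "torque" if trace.kind == "torque" else "semg"
    return RepetitionSeries(idx / trace.rate, source=source)


def series_agreement(a: RepetitionSeries, b: RepetitionSeries, tol: float) -> float:
    """Fraction of peaks matched one-to-one within ``tol`` seconds.

    Symmetric in its arguments; the denominator is the larger peak count.
    Greedy in-order matching is optimal here because both series are
    sorted.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ta, tb = a.peak_times, b.peak_times
    if ta.size == 0 or tb.size == 0:
        return 0.0 if max(ta.size, tb.size) else 1.0
    i = j = matched = 0
    while i < ta.size and j < tb.size:
        dt = ta[i] - tb[j]
        if abs(dt) <= tol:
            matched += 1
            i += 1
            j += 1
        elif dt < 0:
            i += 1
        else:
            j += 1
    return matched / max(ta.size, tb.size)
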