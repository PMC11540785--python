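"""The 27 per-participant exercise performance metrics.

Five metric families over three exercises (squat, knee-up, reverse
lunge) and two conditions (self-paced ``Max``, metronome-paced
``Const``):

* **NR** — number of repetitions completed in the bout (both conditions);
* **IS** — initial speed: mean repetition rate over the opening window
  (10 reps for squat/lunge, 30 for knee-up), reported in reps per 10 s;
* **CZ** — constant-speed zone: repetitions completed before the paced
  interval deviates persistently from the metronome target (const only);
* **sEMG amp** — change in MVIC-normalized sEMG RMS amplitude between
  the first and last 10 s of the bout;
* **iEMG** — change in integrated (rectified, time-integrated)
  MVIC-normalized sEMG between the first and last 10 s.

That is 3 exercises x (2 NR + 2 IS + 2 amp + 2 iEMG) + 3 CZ = 27
columns. Undefined metrics (too few repetitions, too-short trace,
missing session) propagate as missing values, never as zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocols import PROTOCOLS, ExerciseProtocol
from .signal_processing import (
    MvicReference,
    RepetitionSeries,
    SignalTrace,
    bandpass_filter,
    detect_rep_peaks,
    mvic_normalize,
    notch_filter,
    rectified_envelope,
)

log = logging.getLogger(__name__)

_FAMILIES_PER_CONDITION = ("NR", "IS", "sEMG_amp", "iEMG")
_EX_LABEL = {"squat": "Squat", "kneeup": "Kneeup", "lunge": "Lunge"}


def metric_columns() -> list[str]:
    """The 27 metric column names, in a fixed order."""
    cols = []
    for ex in ("squat", "kneeup", "lunge"):
        lab = _EX_LABEL[ex]
        for fam in _FAMILIES_PER_CONDITION:
            for cond in ("Max", "Const"):
                cols.append(f"{lab}_{fam}_{cond}")
        cols.append(f"{lab}_CZ")
    return cols


@dataclass
class ZoneSegmentation:
    """Constant-speed-zone boundary for a paced repetition series."""

    constant_zone_end_index: int  # rep index where the zone ends
    constant_zone_reps: int  # repetitions inside the zone
    deviation_flags: np.ndarray  # per-interval: True where off-pace


def number_of_repetitions(series: RepetitionSeries) -> int:
    """Count of detected repetition peaks (0 for an empty series)."""
    return len(series)


def initial_speed(series: RepetitionSeries, window_reps: int) -> float:
    """Mean repetition speed (reps per 10 s) over the opening window.

    Averages the per-interval speeds of the first
    ``min(window_reps, available)`` intervals; NaN (undefined) with
    fewer than two peaks.
    """
    if len(series) < 2:
        return math.nan
    k = min(window_reps, series.intervals.size)
    return float(np.mean(series.speeds_per10s[:k]))


def constant_speed_zone(
    series: RepetitionSeries,
    target_rpm: float,
    rel_tol: float = 0.10,
    persistence: int = 3,
    min_zone_duration: float | None = None,
) -> ZoneSegmentation:
    """Locate the boundary between the constant- and variable-speed zones.

    An interval deviates when it differs from the metronome interval
    (60/target_rpm) by more than ``rel_tol`` relative tolerance. The
    zone ends at the first run of ``persistence`` consecutive deviating
    intervals; with no such run the zone spans the whole series. If the
    run starts at the very first interval the zone holds only the first
    peak (reps = 1). ``min_zone_duration`` (s), when set, extends the
    zone to at least that duration before a boundary is accepted.
    """
    if not (0.0 < rel_tol < 1.0):
        raise ValueError("rel_tol must be in (0, 1)")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if target_rpm <= 0:
        raise ValueError("target_rpm must be > 0")
    n = len(series)
    intervals = series.intervals
    target = 60.0 / target_rpm
    flags = np.abs(intervals - target) > rel_tol * target
    boundary = n  # default: whole series is the constant zone
    run = 0
    for i, dev in enumerate(flags):
        run = run + 1 if dev else 0
        if run >= persistence:
            start = i - persistence + 1
            if (
                min_zone_duration is not None
                and n > 0
                and series.peak_times[start] - series.peak_times[0] < min_zone_duration
            ):
                run = 0
                continue
            boundary = start + 1
            break
    return ZoneSegmentation(
        constant_zone_end_index=boundary,
        constant_zone_reps=min(boundary, n),
        deviation_flags=flags,
    )


def semg_amplitude_delta(envelope: SignalTrace, window: float = 10.0) -> float:
    """RMS over the final ``window`` s minus RMS over the initial one.

    NaN (undefined) when the trace is shorter than two windows.
    """
    nw = int(round(window * envelope.rate))
    x = envelope.samples
    if x.size < 2 * nw:
        return math.nan
    rms_initial = float(np.sqrt(np.mean(x[:nw] ** 2)))
    rms_final = float(np.sqrt(np.mean(x[-nw:] ** 2)))
    return rms_final - rms_initial


def iemg_delta(envelope: SignalTrace, window: float = 10.0) -> float:
    """Integrated rectified sEMG over the final window minus the initial.

    Trapezoidal integration in MVIC·s units; NaN when the trace is
    shorter than two windows.
    """
    nw = int(round(window * envelope.rate))
    x = np.abs(envelope.samples)
    if x.size < 2 * nw:
        return math.nan
    dx = 1.0 / envelope.rate
    return float(np.trapezoid(x[-nw:], dx=dx) - np.trapezoid(x[:nw], dx=dx))


def mvic_envelopes(
    semg: dict[str, SignalTrace],
    ref: MvicReference,
    *,
    mains_freq: float = 60.0,
    envelope_window: float = 0.1,
) -> dict[str, SignalTrace]:
    """Condition raw sEMG channels into MVIC-normalized envelopes.

    Pipeline per channel: notch at the mains frequency, 20–500 Hz
    band-pass, moving-RMS envelope, MVIC normalization.
    """
    out = {}
    for ch, trace in semg.items():
        clean = bandpass_filter(notch_filter(trace, mains_freq))
        env = rectified_envelope(clean, envelope_window)
        out[ch] = mvic_normalize(env, ref)
    return out


def build_mvic_reference(
    reference_semg: list[dict[str, SignalTrace]],
    rest_semg: dict[str, SignalTrace],
    *,
    mains_freq: float = 60.0,
    envelope_window: float = 0.1,
) -> MvicReference:
    """Construct the per-channel MVIC reference.

    ``semg_max`` is the maximum envelope value over the reference
    (maximal-contraction) recordings; ``semg_rest`` the median envelope
    of a rest recording (median for robustness to residual artefacts).
    """
    semg_max: dict[str, float] = {}
    semg_rest: dict[str, float] = {}
    for bundle in reference_semg:
        for ch, trace in bundle.items():
            env = rectified_envelope(
                bandpass_filter(notch_filter(trace, mains_freq)), envelope_window
            )
            peak = float(env.samples.max())
            semg_max[ch] = max(semg_max.get(ch, 0.0), peak)
    for ch, trace in rest_semg.items():
        env = rectified_envelope(
            bandpass_filter(notch_filter(trace, mains_freq)), envelope_window
        )
        semg_rest[ch] = float(np.median(env.samples))
    return MvicReference(semg_max=semg_max, semg_rest=semg_rest)


def session_metrics(
    torque_series: RepetitionSeries,
    envelopes: dict[str, SignalTrace],
    protocol: ExerciseProtocol,
    *,
    semg_window: float = 10.0,
    cz_rel_tol: float = 0.10,
    cz_persistence: int = 3,
    cz_min_zone_duration: float | None = None,
) -> dict[str, float]:
    """Metrics contributed by one session, keyed by metric column name."""
    lab = _EX_LABEL[protocol.exercise]
    cond = "Max" if protocol.condition == "max" else "Const"
    out: dict[str, float] = {
        f"{lab}_NR_{cond}": float(number_of_repetitions(torque_series)),
        f"{lab}_IS_{cond}": initial_speed(torque_series, protocol.initial_speed_window_reps),
    }
    if protocol.condition == "const":
        zone = constant_speed_zone(
            torque_series,
            protocol.target_rpm,
            rel_tol=cz_rel_tol,
            persistence=cz_persistence,
            min_zone_duration=cz_min_zone_duration,
        )
        out[f"{lab}_CZ"] = float(zone.constant_zone_reps)
    amps = [semg_amplitude_delta(env, semg_window) for env in envelopes.values()]
    iemgs = [iemg_delta(env, semg_window) for env in envelopes.values()]
    # unweighted mean across the 8 muscles
    out[f"{lab}_sEMG_amp_{cond}"] = float(np.mean(amps)) if amps else math.nan
    out[f"{lab}_iEMG_{cond}"] = float(np.mean(iemgs)) if iemgs else math.nan
    return out


def build_metric_table(
    sessions: dict[str, dict[str, "SessionInputs"]],
    *,
    semg_window: float = 10.0,
    cz_rel_tol: float = 0.10,
    cz_persistence: int = 3,
) -> pd.DataFrame:
    """Assemble the participants x 27 metric table.

    ``sessions`` maps participant id -> protocol key (``squat:max`` ...)
    -> a :class:`SessionInputs` with the torque repetition series and
    MVIC envelopes. Missing sessions leave their cells missing and log a
    warning; rows are never dropped here.
    """
    cols = metric_columns()
    rows = {}
    for pid, by_protocol in sessions.items():
        row: dict[str, float] = {c: math.nan for c in cols}
        for key, proto in PROTOCOLS.items():
            inputs = by_protocol.get(key)
            if inputs is None:
                log.warning("participant %s: missing session %s", pid, key)
                continue
            row.update(
                session_metrics(
                    inputs.torque_series,
                    inputs.envelopes,
                    proto,
                    semg_window=semg_window,
                    cz_rel_tol=cz_rel_tol,
                    cz_persistence=cz_persistence,
                )
            )
        rows[pid] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.index.name = "participant_id"
    return table


@dataclass
class SessionInputs:
    """Processed inputs one session contributes to the metric table."""

    torque_series: RepetitionSeries
    envelopes: dict[str, SignalTrace]


def extract_session_inputs(
    bundle,
    ref: MvicReference,
    *,
    mains_freq: float = 60.0,
    envelope_window: float = 0.1,
) -> SessionInputs:
    """Run the signal chain on a raw session bundle.

    Torque peaks come straight from the (already smooth) torque trace;
    sEMG channels are conditioned into MVIC-normalized envelopes.
    """
    series = detect_rep_peaks(bundle.torque, bundle.protocol)
    envs = mvic_envelopes(
        bundle.semg, ref, mains_freq=mains_freq, envelope_window=envelope_window
    )
    return SessionInputs(torque_series=series, envelopes=envs)
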