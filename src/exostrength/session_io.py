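"""Plain-text on-disk formats for sessions, cohorts and repetition series.

A session is one delimited text file: ``#``-prefixed ``key=value`` header
lines (sampling rate, exercise, condition, participant, channel order),
then one comma-separated row per sample with the torque column first and
the eight sEMG channels after it. Planted ground-truth repetition times
live in a sidecar CSV (``rep_index,peak_time_s``) next to the session
file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import get_protocol
from .signal_processing import RepetitionSeries, SignalTrace
from .synthetic_data import SessionBundle


def session_filename(participant_id: str, protocol_key: str) -> str:
    return f"{participant_id}_{protocol_key.replace(':', '_')}.csv"


def write_session(bundle: SessionBundle, directory: str | Path) -> Path:
    """Write one session (and its ground-truth sidecar) as text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / session_filename(bundle.participant_id, bundle.protocol.key)
    channels = ["torque"] + bundle.channels
    header = [
        f"# rate_hz={bundle.torque.rate:g}",
        f"# participant={bundle.participant_id}",
        f"# exercise={bundle.protocol.exercise}",
        f"# condition={bundle.protocol.condition}",
        f"# channels={','.join(channels)}",
    ]
    data = np.column_stack(
        [bundle.torque.samples] + [bundle.semg[ch].samples for ch in bundle.channels]
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, data, fmt="%.6g", delimiter=",")
    sidecar = path.with_suffix(".truth.csv")
    truth = pd.DataFrame(
        {"rep_index": np.arange(bundle.rep_times.size), "peak_time_s": bundle.rep_times}
    )
    truth.to_csv(sidecar, index=False)
    return path


def read_session(path: str | Path) -> SessionBundle:
    """Read a session file written by :func:`write_session`.

    The ground-truth sidecar is loaded when present; otherwise the
    bundle carries an empty planted-times array (real recordings have
    no planted truth).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    required = ("rate_hz", "exercise", "condition", "channels")
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(f"session file {path} missing header keys: {missing}")
    rate = float(meta["rate_hz"])
    channels = meta["channels"].split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=n_header)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] != len(channels):
        raise ValueError(
            f"{path}: {data.shape[1]} columns but {len(channels)} channel labels"
        )
    protocol = get_protocol(meta["exercise"], meta["condition"])
    torque = None
    semg: dict[str, SignalTrace] = {}
    for i, ch in enumerate(channels):
        if ch == "torque":
            torque = SignalTrace(data[:, i], rate, channel="torque", kind="torque")
        else:
            semg[ch] = SignalTrace(data[:, i], rate, channel=ch, kind="semg_raw")
    if torque is None:
        raise ValueError(f"{path}: no torque channel")
    sidecar = path.with_suffix(".truth.csv")
    if sidecar.exists():
        rep_times = pd.read_csv(sidecar)["peak_time_s"].to_numpy(dtype=float)
    else:
        rep_times = np.empty(0)
    return SessionBundle(
        participant_id=meta.get("participant", path.stem),
        protocol=protocol,
        torque=torque,
        semg=semg,
        rep_times=rep_times,
    )


def write_repetition_series(series: RepetitionSeries, path: str | Path) -> Path:
    """Persist a repetition series as CSV (peak_time_s,interval_s,speed_rpm).

    Interval and speed are attributed to the repetition that closes
    them, so the first row has them empty.
    """
    path = Path(path)
    n = len(series)
    intervals = np.full(n, np.nan)
    speeds = np.full(n, np.nan)
    if n >= 2:
        intervals[1:] = series.intervals
        speeds[1:] = series.speeds_rpm
    pd.DataFrame(
        {"peak_time_s": series.peak_times, "interval_s": intervals, "speed_rpm": speeds}
    ).to_csv(path, index=False)
    return path


def read_repetition_series(path: str | Path, source: str = "torque") -> RepetitionSeries:
    df = pd.read_csv(path)
    return RepetitionSeries(df["peak_time_s"].to_numpy(dtype=float), source=source)
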