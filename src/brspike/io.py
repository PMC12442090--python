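"""CSV/JSON readers and writers for the pipeline's external formats.

All floats are serialized with 6 significant digits so regression outputs
are bit-stable across runs; readers validate structure and report the first
offending line on malformed input.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .spikes import ChannelSummary, SpikeEvent
from .synthdata import Recording

RECORDING_COLUMNS = ["time_s", "channel", "condition", "group", "voltage_mv"]
EVENT_COLUMNS = ["channel", "onset_s", "peak_s", "offset_s", "amplitude_mv", "duration_s"]


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_recordings_csv(recordings: list[Recording], path: str | Path) -> None:
    """Long-format recording CSV: time_s,channel,condition,group,voltage_mv."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RECORDING_COLUMNS)
        for rec in recordings:
            for t, v in zip(rec.times, rec.voltages):
                w.writerow([_fmt(t), rec.channel_id, rec.condition, rec.group, _fmt(v)])


def read_recordings_csv(path: str | Path) -> list[Recording]:
    """Read a long-format recording CSV back into Recording objects.

    Round trip: ``read(write(x))`` equals ``x`` to the 6-significant-digit
    print precision.  Missing columns, empty files and non-monotone time
    within a channel raise, naming the first offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty input file") from None
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    if df.empty:
        raise InputError(f"{path}: no data rows")
    out: list[Recording] = []
    for (channel, cond, group), sub in df.groupby(["channel", "condition", "group"],
                                                  sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = int(sub.index[bad[0] + 1]) + 2  # +1 header, +1 one-based
            raise InputError(f"{path}: non-monotone time at line {line} "
                             f"(channel {channel})")
        out.append(Recording(channel_id=str(channel), condition=str(cond),
                             group=str(group), times=t,
                             voltages=sub["voltage_mv"].to_numpy(dtype=float)))
    return out


def write_events_csv(events_by_channel: dict[str, list[SpikeEvent]],
                     path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for channel, events in events_by_channel.items():
            for e in events:
                w.writerow([channel, _fmt(e.onset), _fmt(e.peak_time),
                            _fmt(e.offset), _fmt(e.amplitude), _fmt(e.duration)])


def write_summary_csv(summaries: list[ChannelSummary], path: str | Path) -> None:
    """Per-channel summary CSV mirroring the published table columns."""
    rows = []
    for s in summaries:
        rows.append({
            "channel": s.channel_id, "n_events": s.n_events,
            "amplitude_mean_mv": _fmt(s.amplitude_mean),
            "amplitude_sd_mv": _fmt(s.amplitude_sd),
            "amplitude_min_mv": _fmt(s.amplitude_min),
            "amplitude_max_mv": _fmt(s.amplitude_max),
            "amplitude_median_mv": _fmt(s.amplitude_median),
            "period_mean_s": "" if s.period_mean is None else _fmt(s.period_mean),
            "period_sd_s": "" if s.period_sd is None else _fmt(s.period_sd),
            "period_min_s": "" if s.period_min is None else _fmt(s.period_min),
            "period_max_s": "" if s.period_max is None else _fmt(s.period_max),
            "period_median_s": "" if s.period_median is None else _fmt(s.period_median),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth_table_csv(rows, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["green", "blue", "yellow", "red", "optimal_light"])
        for g, b, y, r, label in rows:
            w.writerow([g, b, y, r, label])


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return [float(_fmt(v)) for v in o]
        if isinstance(o, (np.floating, float)):
            return float(_fmt(float(o)))
        if isinstance(o, (np.integer,)):
            return int(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, default=default, sort_keys=True)
        fh.write("\n")
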