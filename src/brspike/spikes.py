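"""Oscillation/spike event detection and amplitude/period summary statistics.

An "event" is one oscillation excursion above the slow baseline.  Its
amplitude is the peak voltage minus the local baseline (a rolling median,
which tracks drift slower than the oscillation without attenuating it), its
duration runs from the last baseline crossing before the peak to the first
one after, and the period is defined onset-to-onset between consecutive
events — the same convention the summary tables use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .exceptions import InputError, InsufficientEventsError, ParameterError
from .synthdata import Recording

#: Default rolling-median baseline window, seconds.
DEFAULT_BASELINE_WINDOW_S = 3000.0


@dataclass(frozen=True)
class SpikeEvent:
    onset: float  # s
    offset: float  # s
    peak_time: float  # s
    amplitude: float  # mV, peak minus local baseline
    duration: float  # s, offset - onset

    def __post_init__(self) -> None:
        if not (self.onset < self.peak_time <= self.offset):
            raise ParameterError(
                f"require onset < peak_time <= offset, got "
                f"({self.onset}, {self.peak_time}, {self.offset})")
        if self.amplitude <= 0:
            raise ParameterError(f"amplitude must be > 0, got {self.amplitude}")


@dataclass(frozen=True)
class ChannelSummary:
    """Per-channel event statistics in the published table layout."""

    channel_id: str
    n_events: int
    amplitude_mean: float
    amplitude_sd: float
    amplitude_min: float
    amplitude_max: float
    amplitude_median: float
    period_mean: float | None
    period_sd: float | None
    period_min: float | None
    period_max: float | None
    period_median: float | None


@dataclass(frozen=True)
class GroupSummary:
    """Statistics pooled over all events of a group of channels.

    mean/SD and range pool every event; ``*_median_range`` is the (min, max)
    of the per-channel medians.
    """

    group: str
    n_channels: int
    n_events: int
    amplitude_mean: float
    amplitude_sd: float
    amplitude_range: tuple[float, float]
    amplitude_median_range: tuple[float, float]
    period_mean: float | None
    period_sd: float | None
    period_range: tuple[float, float] | None
    period_median_range: tuple[float, float] | None


def rolling_baseline(rec: Recording, window_s: float = DEFAULT_BASELINE_WINDOW_S) -> np.ndarray:
    """Centered rolling-median baseline of the trace (mV)."""
    w = max(3, int(round(window_s * rec.sampling_rate)) | 1)  # odd window
    s = pd.Series(rec.voltages)
    return s.rolling(w, center=True, min_periods=1).median().to_numpy()


def robust_noise_sd(rec: Recording) -> float:
    """Robust noise SD from the first-difference MAD: 1.4826 * median|dV| / sqrt(2).

    Differencing removes the slow oscillation (whose sample-to-sample change
    is tiny at 1 Hz) so the estimate reflects the additive noise floor, not
    the signal amplitude.
    """
    dv = np.diff(rec.voltages)
    return 1.4826 * float(np.median(np.abs(dv - np.median(dv)))) / np.sqrt(2.0)


def _estimate_period(rec: Recording) -> float | None:
    """Quick dominant-period estimate (plain rfft argmax, DC excluded)."""
    n = rec.times.size
    if n < 64:
        return None
    x = rec.voltages - np.mean(rec.voltages)
    if np.allclose(x, 0.0):
        return None
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=rec.dt)
    searchable = freqs > 1.0 / rec.duration
    if not np.any(searchable):
        return None
    k = int(np.argmax(np.where(searchable, power, -np.inf)))
    return 1.0 / float(freqs[k])


def detect_spikes(rec: Recording, min_prominence: float | None = None,
                  min_separation: float | None = None,
                  baseline_window_s: float | None = None,
                  smooth_window: int | None = None) -> list[SpikeEvent]:
    """Detect oscillation events as prominent local maxima of the detrended trace.

    Parameters
    ----------
    rec
        Uniformly sampled recording.
    min_prominence
        Minimum peak prominence in mV.  Default: 3x the robust noise SD
        (first-difference MAD estimator), floored at a small positive value.
    min_separation
        Minimum separation between peaks in seconds; must be at least two
        sample intervals.  Default: half the estimated dominant period (one
        event per oscillation cycle), else 2 sample intervals.
    baseline_window_s
        Rolling-median window used both as amplitude reference and for
        onset/offset (baseline-crossing) localisation.  Default: 5x the
        dominant period estimated from the spectrum (a window spanning an
        integer number of cycles makes the oscillation's median vanish),
        falling back to 3000 s when no period is estimable.
    smooth_window
        Odd sample count of a quadratic Savitzky-Golay filter applied to the
        detrended trace before peak extraction; 1 disables smoothing.
        Default: ~1/10 of the estimated dominant period.  A broad oscillation
        peak passes a quadratic fit essentially unchanged while the noise
        that would otherwise bias the per-cycle maximum upward is suppressed.

    Returns
    -------
    Events sorted by onset.  A constant or empty trace yields ``[]``.
    Peaks within half a baseline window of either trace edge are discarded:
    the centered rolling median is computed over a partial window there and
    the amplitude reference is biased.
    """
    if rec.times.size < 2:
        raise InputError("recording must contain at least 2 samples")
    dt = rec.dt
    if np.allclose(rec.voltages, rec.voltages[0]):
        return []
    period = _estimate_period(rec)
    if min_separation is None:
        min_separation = max(0.5 * period, 2 * dt) if period else 2 * dt
    if min_separation < 2 * dt:
        raise ParameterError(f"min_separation must be >= 2 sample intervals ({2 * dt} s)")
    if baseline_window_s is None:
        baseline_window_s = 5.0 * period if period else DEFAULT_BASELINE_WINDOW_S
    if min_prominence is None:
        min_prominence = 3.0 * robust_noise_sd(rec)
        if min_prominence <= 0:
            min_prominence = 1e-9
    if min_prominence <= 0:
        raise ParameterError(f"min_prominence must be > 0, got {min_prominence}")

    detr = rec.voltages - rolling_baseline(rec, baseline_window_s)
    if smooth_window is None:
        if period is not None:
            w_s = int(round(period * rec.sampling_rate / 10)) | 1
            smooth_window = int(np.clip(w_s, 1, max(1, rec.times.size // 10) | 1))
        else:
            smooth_window = 1
    if smooth_window > 2:
        detr = savgol_filter(detr, smooth_window, 2)
    distance = max(1, int(round(min_separation / dt)))
    # find_peaks marks the left edge of plateaus via peak_plateaus handling:
    # with default arguments the reported index of a flat peak is its midpoint,
    # so ask for plateau info and take the left edge to honor the leftmost-tie rule.
    peaks, props = find_peaks(detr, prominence=min_prominence, distance=distance,
                              plateau_size=(None, None))
    if peaks.size == 0:
        return []
    left_edges = props.get("left_edges", peaks)

    w = max(3, int(round(baseline_window_s * rec.sampling_rate)) | 1)
    margin = w // 2
    if rec.times.size > 2 * margin + 1:
        keep = (peaks >= margin) & (peaks < rec.times.size - margin)
        peaks, left_edges = peaks[keep], left_edges[keep]

    events: list[SpikeEvent] = []
    below = detr <= 0
    for peak, left_edge in zip(peaks, left_edges):
        idx = int(left_edge)  # leftmost sample of a plateau maximum
        # onset: nearest preceding baseline crossing (last sample at/below 0)
        pre = np.nonzero(below[:idx])[0]
        onset_i = int(pre[-1]) if pre.size else 0
        post = np.nonzero(below[idx + 1:])[0]
        offset_i = int(post[0]) + idx + 1 if post.size else len(detr) - 1
        amp = float(detr[idx])
        if amp <= 0:
            continue
        onset_t = float(rec.times[onset_i])
        offset_t = float(rec.times[offset_i])
        peak_t = float(rec.times[idx])
        if not (onset_t < peak_t <= offset_t):
            # peak at trace edge with no surrounding crossing; skip
            continue
        events.append(SpikeEvent(onset=onset_t, offset=offset_t, peak_time=peak_t,
                                 amplitude=amp, duration=offset_t - onset_t))
    events.sort(key=lambda e: e.onset)
    return events


def period_series(events: list[SpikeEvent]) -> np.ndarray:
    """Onset-to-onset intervals between consecutive events (seconds)."""
    if len(events) < 2:
        raise InsufficientEventsError(
            f"need >= 2 events for periods, got {len(events)}")
    onsets = np.array([e.onset for e in events], dtype=float)
    periods = np.diff(onsets)
    if np.any(periods <= 0):
        raise InputError("events must have strictly increasing onsets")
    return periods


def summarize_channel(events: list[SpikeEvent], channel_id: str = "") -> ChannelSummary:
    """Sample statistics (SD with n-1 denominator) of one channel's events.

    Period statistics require >= 2 events; with a single event they are None.
    """
    if not events:
        raise InsufficientEventsError("no events to summarize")
    amps = np.array([e.amplitude for e in events], dtype=float)
    a_sd = float(np.std(amps, ddof=1)) if amps.size > 1 else 0.0
    if len(events) >= 2:
        per = period_series(events)
        p_stats = dict(period_mean=float(np.mean(per)),
                       period_sd=float(np.std(per, ddof=1)) if per.size > 1 else 0.0,
                       period_min=float(np.min(per)), period_max=float(np.max(per)),
                       period_median=float(np.median(per)))
    else:
        p_stats = dict(period_mean=None, period_sd=None, period_min=None,
                       period_max=None, period_median=None)
    return ChannelSummary(
        channel_id=channel_id, n_events=len(events),
        amplitude_mean=float(np.mean(amps)), amplitude_sd=a_sd,
        amplitude_min=float(np.min(amps)), amplitude_max=float(np.max(amps)),
        amplitude_median=float(np.median(amps)), **p_stats)


def summarize_group(group: str, event_lists: list[list[SpikeEvent]],
                    channel_ids: list[str] | None = None) -> GroupSummary:
    """Pool all events across channels of one group.

    mean +/- SD and range are over the pooled event list; the median-range is
    the (min, max) of per-channel medians — the row structure of the
    published per-condition tables.
    """
    if not event_lists or all(len(ev) == 0 for ev in event_lists):
        raise InsufficientEventsError("no events in any channel")
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(len(event_lists))]
    summaries = [summarize_channel(ev, cid)
                 for ev, cid in zip(event_lists, channel_ids) if ev]

    amps = np.concatenate([[e.amplitude for e in ev] for ev in event_lists if ev])
    a_medians = [s.amplitude_median for s in summaries]

    period_lists = [period_series(ev) for ev in event_lists if len(ev) >= 2]
    if period_lists:
        pers = np.concatenate(period_lists)
        p_medians = [s.period_median for s in summaries if s.period_median is not None]
        p_stats = dict(
            period_mean=float(np.mean(pers)),
            period_sd=float(np.std(pers, ddof=1)) if pers.size > 1 else 0.0,
            period_range=(float(np.min(pers)), float(np.max(pers))),
            period_median_range=(float(np.min(p_medians)), float(np.max(p_medians))))
    else:
        p_stats = dict(period_mean=None, period_sd=None,
                       period_range=None, period_median_range=None)

    return GroupSummary(
        group=group, n_channels=len(summaries), n_events=int(amps.size),
        amplitude_mean=float(np.mean(amps)),
        amplitude_sd=float(np.std(amps, ddof=1)) if amps.size > 1 else 0.0,
        amplitude_range=(float(np.min(amps)), float(np.max(amps))),
        amplitude_median_range=(float(np.min(a_medians)), float(np.max(a_medians))),
        **p_stats)


def dvdt(rec: Recording) -> np.ndarray:
    """Voltage rate of change dV/dt (mV/s) on the uniform grid.

    Central differences in the interior, one-sided at the ends; output has
    the same length as the trace.
    """
    if rec.times.size < 2:
        raise InputError("need >= 2 samples for dV/dt")
    return np.gradient(rec.voltages, rec.times)
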