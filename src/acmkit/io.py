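"""Device-log input/output and preprocessing onto the common 10-min grid.

Two plain-text export dialects are supported:

* wrist temperature (WT): an optional ``#``-prefixed or free-text preamble,
  then a ``datetime,temperature_C`` header and one sample per row at a
  nominal 10-min cadence (Thermochron iButton style);
* tilt: a ``datetime,angle_deg`` header and one sample per row at a nominal
  30-s cadence (HOBO Pendant G style), where the angle is measured between
  the logger's X axis (along the humerus) and the horizontal plane.  A
  converter accepts raw ``datetime,ax,ay,az`` gravity rows instead.

Malformed rows are counted and skipped with a log entry; a file with no
parseable rows is a format error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import RegularSeries

logger = logging.getLogger(__name__)

WT_HEADER = "datetime,temperature_C"
TILT_HEADER = "datetime,angle_deg"
TILT_XYZ_HEADER = "datetime,ax,ay,az"

#: default off-wrist / ambient plausibility range for wrist temperature, degC
WT_RANGE = (20.0, 40.0)
#: default isolated-spike threshold, degC per 10-min step
WT_SPIKE_DELTA = 2.0


class FormatError(ValueError):
    """Raised when a device log yields no parseable samples."""


@dataclass
class RawSamples:
    """Irregularly timestamped samples from one channel.

    ``mask`` is ``True`` where the sample is valid; filtering only ever
    flips mask bits, values are never altered.
    """

    time: pd.DatetimeIndex
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    units: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.size, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.time.size == self.values.size == self.mask.size):
            raise ValueError("time, values and mask must have equal length")
        if self.time.size > 1 and not (np.diff(self.time.asi8) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    @property
    def masked_fraction(self) -> float:
        return float(1.0 - self.mask.mean()) if self.values.size else 0.0


@dataclass
class AcmRecording:
    """One subject's multichannel week: raw WT and tilt plus metadata."""

    subject_id: str
    wt_raw: RawSamples
    tilt_raw: RawSamples
    metadata: dict = field(default_factory=dict)


def _read_log(path, header: str, n_fields: int) -> tuple[pd.DatetimeIndex, np.ndarray, int]:
    rows: list[tuple[pd.Timestamp, tuple[float, ...]]] = []
    n_skipped = 0
    in_body = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not in_body:
                if line == header:
                    in_body = True
                continue
            if not line:
                continue
            parts = line.split(",")
            try:
                if len(parts) != n_fields:
                    raise ValueError("wrong field count")
                ts = pd.Timestamp(parts[0])
                vals = tuple(float(p) for p in parts[1:])
                if ts is pd.NaT or any(not np.isfinite(v) for v in vals):
                    raise ValueError("non-finite")
            except (ValueError, TypeError):
                n_skipped += 1
                logger.warning("%s:%d: skipping malformed row %r", path, lineno, line)
                continue
            rows.append((ts, vals))
    if not rows:
        raise FormatError(f"{path}: no parseable rows (expected header {header!r})")
    times = pd.DatetimeIndex([r[0] for r in rows])
    values = np.array([r[1] for r in rows])
    return times, values, n_skipped


def read_wt_log(path) -> RawSamples:
    """Read a wrist-temperature log; returns ordered (timestamp, degC) samples."""
    times, values, n_skipped = _read_log(path, WT_HEADER, 2)
    return RawSamples(times, values[:, 0], units="degC", n_skipped=n_skipped)


def read_tilt_log(path) -> RawSamples:
    """Read a tilt-angle log; returns ordered (timestamp, degrees) samples.

    Angles are clamped into [0, 90] degrees from horizontal.
    """
    times, values, n_skipped = _read_log(path, TILT_HEADER, 2)
    angles = np.clip(values[:, 0], 0.0, 90.0)
    return RawSamples(times, angles, units="deg", n_skipped=n_skipped)


def read_tilt_xyz_log(path) -> RawSamples:
    """Read a 3-axis gravity log and derive the X-axis-to-horizontal angle.

    For a static logger the acceleration vector is gravity in the device
    frame, so the elevation of the X axis above the horizontal plane is
    ``asin(|ax| / ||a||)``.
    """
    times, values, n_skipped = _read_log(path, TILT_XYZ_HEADER, 4)
    norm = np.linalg.norm(values, axis=1)
    if (norm == 0).any():
        raise FormatError(f"{path}: zero-magnitude acceleration row")
    angles = np.degrees(np.arcsin(np.abs(values[:, 0]) / norm))
    return RawSamples(times, np.clip(angles, 0.0, 90.0), units="deg", n_skipped=n_skipped)


def write_wt_log(path, samples: RawSamples, preamble: str = "iButton wrist temperature export") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {preamble}\n{WT_HEADER}\n")
        for t, v in zip(samples.time, samples.values):
            fh.write(f"{t.isoformat()},{v:.3f}\n")


def write_tilt_log(path, samples: RawSamples, preamble: str = "Pendant G tilt export") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {preamble}\n{TILT_HEADER}\n")
        for t, v in zip(samples.time, samples.values):
            fh.write(f"{t.isoformat()},{v:.3f}\n")


def derive_activity_position(tilt_raw: RawSamples) -> tuple[RawSamples, RawSamples]:
    """Split a tilt log into motor activity and body position channels.

    Activity is the absolute rate of change of the tilt angle in degrees per
    minute, ``|angle_i - angle_{i-1}| / dt_minutes``; the first sample has no
    predecessor and is masked.  Position is the tilt angle itself.
    """
    if tilt_raw.values.size < 2:
        raise ValueError("need at least 2 tilt samples to derive activity")
    dt_min = np.diff(tilt_raw.time.asi8) / 60e9
    activity = np.empty_like(tilt_raw.values)
    activity[0] = 0.0
    activity[1:] = np.abs(np.diff(tilt_raw.values)) / dt_min
    act_mask = tilt_raw.mask.copy()
    act_mask[0] = False
    act_mask[1:] &= tilt_raw.mask[:-1]
    activity_s = RawSamples(tilt_raw.time, activity, act_mask, units="deg/min")
    position_s = RawSamples(tilt_raw.time, tilt_raw.values.copy(), tilt_raw.mask.copy(), units="deg")
    return activity_s, position_s


def filter_wt(
    samples: RawSamples,
    wt_range: tuple[float, float] = WT_RANGE,
    spike_delta: float = WT_SPIKE_DELTA,
) -> RawSamples:
    """Mask implausible wrist-temperature samples.

    Two rules: values outside ``wt_range`` (off-wrist or ambient exposure)
    are masked; isolated excursions that jump by more than ``spike_delta``
    from the previous valid value and return to within ``spike_delta`` of it
    within two samples are masked.  Filtering is total: it never raises.
    """
    lo, hi = wt_range
    x = samples.values
    mask = samples.mask & (x >= lo) & (x <= hi)
    for i in range(1, x.size):
        if not (mask[i] and mask[i - 1]):
            continue
        if abs(x[i] - x[i - 1]) <= spike_delta:
            continue
        for j in (i + 1, i + 2):
            if j < x.size and mask[j] and abs(x[j] - x[i - 1]) <= spike_delta:
                mask[i:j] = False
                break
    out = RawSamples(samples.time, x.copy(), mask, units=samples.units)
    logger.info("filter_wt: masked fraction %.3f", out.masked_fraction)
    return out


def regularize(samples: RawSamples, bin_minutes: int = 10) -> RegularSeries:
    """Average samples into fixed 10-min bins and trim to whole days.

    Each bin ``[t, t + bin_minutes)`` holds the arithmetic mean of the valid
    samples falling in it; empty bins are masked.  Partial leading and
    trailing days are trimmed so the result spans whole days from midnight.
    """
    t = samples.time[samples.mask]
    v = samples.values[samples.mask]
    if t.size == 0:
        raise FormatError("no valid samples to regularize")
    first_bin = t[0].floor(f"{bin_minutes}min")
    day0 = first_bin.ceil("D")
    day_end = (t[-1].floor(f"{bin_minutes}min") + pd.Timedelta(minutes=bin_minutes)).floor("D")
    if day_end <= day0:
        raise ValueError("fewer than one whole day of data after trimming")
    n_bins = int((day_end - day0) / pd.Timedelta(minutes=bin_minutes))
    idx = ((t.asi8 - day0.value) // (bin_minutes * 60_000_000_000)).astype(np.int64)
    keep = (idx >= 0) & (idx < n_bins)
    idx, v = idx[keep], v[keep]
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    mask = counts > 0
    values = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=values, where=mask)
    return RegularSeries(day0, values, mask, units=samples.units, bin_minutes=bin_minutes)


def regularize_recording(
    rec: AcmRecording,
    bin_minutes: int = 10,
    wt_range: tuple[float, float] = WT_RANGE,
    spike_delta: float = WT_SPIKE_DELTA,
) -> dict[str, RegularSeries]:
    """Filter and regularize all channels of a recording onto one grid.

    Returns the dict ``{"wt", "activity", "position"}`` of aligned
    :class:`RegularSeries`, cropped to their common whole-day span.
    """
    wt = regularize(filter_wt(rec.wt_raw, wt_range, spike_delta), bin_minutes)
    activity_raw, position_raw = derive_activity_position(rec.tilt_raw)
    activity = regularize(activity_raw, bin_minutes)
    position = regularize(position_raw, bin_minutes)
    channels = {"wt": wt, "activity": activity, "position": position}
    start = max(s.start for s in channels.values())
    end = min(s.start + pd.Timedelta(minutes=bin_minutes) * s.n_bins for s in channels.values())
    if end <= start:
        raise ValueError("channels share no whole day")
    for name, s in channels.items():
        i0 = int((start - s.start) / pd.Timedelta(minutes=bin_minutes))
        i1 = int((end - s.start) / pd.Timedelta(minutes=bin_minutes))
        channels[name] = RegularSeries(
            start, s.values[i0:i1], s.mask[i0:i1], units=s.units, bin_minutes=bin_minutes
        )
    return channels


def write_tidy_csv(path, subject_id: str, channels: dict[str, RegularSeries]) -> None:
    """Write channels as long-format tidy CSV: subject_id,channel,datetime,value,mask."""
    frames = []
    for name, s in channels.items():
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "channel": name,
                    "datetime": s.times(),
                    "value": s.values,
                    "mask": s.mask.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
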