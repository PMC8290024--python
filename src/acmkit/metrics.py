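"""Non-parametric circadian rhythm analysis.

Implements the classical non-parametric suite on a regular binned series:

* ``IS`` — interdaily stability, the constancy of the 24-h pattern over
  days: ``IS = [N * sum_b (xbar_b - xbar)^2] / [p * sum_i (x_i - xbar)^2]``
  with ``p`` time-of-day bins, ``N`` valid samples, ``xbar_b`` the mean over
  days at time-of-day bin ``b``.  IS is 1 iff every day is identical and
  tends to ``1/n_days`` in expectation for white noise.
* ``IV`` — intradaily variability, rhythm fragmentation from consecutive
  differences: ``IV = [N * sum (x_i - x_{i-1})^2] / [m * (N-1)/m ... ]``;
  in the complete-data case ``IV = [N * sum diff^2] / [(N-1) * sum dev^2]``.
  With gaps, differences never straddle a masked bin and the pair count
  replaces ``N - 1``.  Smooth slow signals give IV near 0; strict
  alternation between extremes gives IV near 4.
* ``RA`` — relative amplitude ``(M10 - L5) / (M10 + L5)`` where M10 / L5
  are the means of the 10 consecutive hours of highest and the 5
  consecutive hours of lowest values of the mean daily waveform, searched
  circularly over all onsets; their onset clock times are the phase markers
  TM10 and TL5.
* ``CFI`` — circadian function index, the [0, 1] composite
  ``(IS + (2 - min(IV, 2)) / 2 + RA) / 3`` (IS, inverted-rescaled IV and RA
  each contribute a third; IV is clipped at 2, its white-noise ceiling).

Statistics that are undefined (zero overall variance, M10 + L5 = 0) raise
:class:`UndefinedStatistic` rather than silently returning 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import numpy as np

from .series import DailyWaveform, RegularSeries

M10_HOURS = 10
L5_HOURS = 5


class UndefinedStatistic(ValueError):
    """A non-parametric statistic has no defined value for this input."""


@dataclass
class NonParametricSummary:
    """Per-subject, per-channel block of non-parametric circadian parameters."""

    IS: float
    IV: float
    RA: float
    CFI: float
    M10: float
    L5: float
    TM10: time
    TL5: time
    n_days: int
    masked_fraction: float

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["TM10"] = self.TM10.strftime("%H:%M")
        d["TL5"] = self.TL5.strftime("%H:%M")
        return d


def _day_arrays(series: RegularSeries) -> tuple[np.ndarray, np.ndarray]:
    if not series.is_whole_days():
        raise ValueError("non-parametric analysis requires whole days from midnight")
    return series.day_matrix()


def mean_waveform(series: RegularSeries) -> DailyWaveform:
    """Mean daily pattern: per time-of-day bin, the mean over days of valid values."""
    vals, mask = _day_arrays(series)
    counts = mask.sum(axis=0)
    if not counts.any():
        raise ValueError("all bins masked; no waveform")
    sums = np.where(mask, vals, 0.0).sum(axis=0)
    out = np.full(series.bins_per_day, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    return DailyWaveform(out, counts, units=series.units, bin_minutes=series.bin_minutes)


def interdaily_stability(series: RegularSeries) -> float:
    """IS in [0, 1]; 1 iff all days are identical, undefined at zero variance."""
    vals, mask = _day_arrays(series)
    if vals.shape[0] < 2:
        raise ValueError("IS requires at least 2 whole days")
    x = vals[mask]
    n = x.size
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise UndefinedStatistic("IS undefined: zero overall variance")
    counts = mask.sum(axis=0)
    bin_means = np.where(counts > 0, np.where(mask, vals, 0.0).sum(axis=0) / np.maximum(counts, 1), np.nan)
    valid_bins = counts > 0
    p = int(valid_bins.sum())
    ss_bins = ((bin_means[valid_bins] - grand) ** 2).sum()
    return float((n * ss_bins) / (p * ss_total))


def intradaily_variability(series: RegularSeries) -> float:
    """IV >= 0; consecutive squared differences never straddle masked gaps."""
    x = series.values
    mask = series.mask
    pair = mask[1:] & mask[:-1]
    m = int(pair.sum())
    if m < 1:
        raise ValueError("IV requires at least 2 consecutive valid samples")
    xv = x[mask]
    n = xv.size
    ss_total = ((xv - xv.mean()) ** 2).sum()
    if ss_total == 0:
        raise UndefinedStatistic("IV undefined: zero overall variance")
    diffs = (x[1:] - x[:-1])[pair]
    return float((n * (diffs**2).sum()) / (m * ss_total))


def find_m10_l5(waveform: DailyWaveform) -> tuple[float, time, float, time]:
    """Locate the M10 and L5 windows of a daily waveform.

    Windows of 10 h (M10) and 5 h (L5) of consecutive bins are searched
    circularly over all onsets, wrapping across midnight.  Window means are
    weighted by each bin's contributing-day count; bins with no contributing
    days are excluded.  Ties go to the earliest onset.  Returns
    ``(M10, TM10, L5, TL5)`` with the timings as onset clock times.
    """
    bpd = waveform.bins_per_day
    valid = waveform.mask
    if int(valid.sum()) < (M10_HOURS * 60) // waveform.bin_minutes:
        raise ValueError("fewer valid bins than the M10 window length")
    w = np.where(valid, waveform.counts, 0).astype(float)
    v = np.where(valid, waveform.values, 0.0)

    def window_means(width_bins: int) -> np.ndarray:
        v2, w2 = np.tile(v, 2), np.tile(w, 2)
        csum_v = np.concatenate([[0.0], np.cumsum(v2 * w2)])
        csum_w = np.concatenate([[0.0], np.cumsum(w2)])
        tot_v = csum_v[width_bins:] - csum_v[:-width_bins]
        tot_w = csum_w[width_bins:] - csum_w[:-width_bins]
        means = np.full(2 * bpd - width_bins + 1, np.nan)
        np.divide(tot_v, tot_w, out=means, where=tot_w > 0)
        return means[:bpd]

    def onset_time(b: int) -> time:
        minutes = b * waveform.bin_minutes
        return time(minutes // 60, minutes % 60)

    m10_means = window_means((M10_HOURS * 60) // waveform.bin_minutes)
    l5_means = window_means((L5_HOURS * 60) // waveform.bin_minutes)
    if np.isnan(m10_means).all() or np.isnan(l5_means).all():
        raise ValueError("no window contains a valid bin")
    b_m10 = int(np.nanargmax(m10_means))
    b_l5 = int(np.nanargmin(l5_means))
    return (
        float(m10_means[b_m10]),
        onset_time(b_m10),
        float(l5_means[b_l5]),
        onset_time(b_l5),
    )


def relative_amplitude(m10: float, l5: float) -> float:
    """RA = (M10 - L5) / (M10 + L5), for daytime-acrophase variables."""
    if m10 < l5:
        raise ValueError("M10 must be >= L5")
    if l5 < 0:
        raise ValueError("RA requires non-negative L5")
    if m10 + l5 == 0:
        raise UndefinedStatistic("RA undefined: M10 + L5 = 0")
    return float((m10 - l5) / (m10 + l5))


def circadian_function_index(is_: float, iv: float, ra: float) -> float:
    """CFI = (IS + (2 - min(IV, 2)) / 2 + RA) / 3, in [0, 1].

    0 means absence of circadian rhythmicity, 1 a fully robust rhythm.
    Linear in each argument on IV in [0, 2]; IV above 2 is clipped.
    """
    if not (0.0 <= is_ <= 1.0 and 0.0 <= ra <= 1.0):
        raise ValueError("IS and RA must lie in [0, 1]")
    if iv < 0:
        raise ValueError("IV must be non-negative")
    return float((is_ + (2.0 - min(iv, 2.0)) / 2.0 + ra) / 3.0)


def summarize(
    series: RegularSeries,
    min_days: int = 6,
    np_bin_minutes: int | None = None,
) -> NonParametricSummary:
    """Full non-parametric block for one series.

    ``np_bin_minutes`` selects the bin width for IS/IV (default: the
    series' own grid; 60 gives the classical hourly variant).  M10/L5 and
    the waveform always use the native grid.  Requires at least ``min_days``
    whole days (6 is the accepted minimum for a reliable analysis).
    """
    vals, _ = _day_arrays(series)
    n_days = vals.shape[0]
    if n_days < min_days:
        raise ValueError(f"need >= {min_days} whole days, got {n_days}")
    np_series = series if not np_bin_minutes else series.rebin(np_bin_minutes)
    is_ = interdaily_stability(np_series)
    iv = intradaily_variability(np_series)
    m10, tm10, l5, tl5 = find_m10_l5(mean_waveform(series))
    ra = relative_amplitude(m10, l5)
    cfi = circadian_function_index(min(is_, 1.0), iv, ra)
    return NonParametricSummary(
        IS=is_,
        IV=iv,
        RA=ra,
        CFI=cfi,
        M10=m10,
        L5=l5,
        TM10=tm10,
        TL5=tl5,
        n_days=n_days,
        masked_fraction=series.masked_fraction,
    )
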