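import numpy as np
import pandas as pd
import pytest

from acmkit.series import RegularSeries

EPOCH = pd.Timestamp("2022-03-07 00:00:00")


def make_series(values, mask=None, bin_minutes=10, units="", start=EPOCH):
    """RegularSeries from a flat value array starting at midnight."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.size, dtype=bool)
    return RegularSeries(start, values, np.asarray(mask, bool), units=units, bin_minutes=bin_minutes)


def day_series(day_rows, mask=None, bin_minutes=None, **kw):
    """RegularSeries from a (days, bins_per_day) array; bin width inferred."""
    arr = np.asarray(day_rows, dtype=float)
    if bin_minutes is None:
        bin_minutes = 1440 // arr.shape[1]
    flat_mask = None if mask is None else np.asarray(mask, bool).ravel()
    return make_series(arr.ravel(), flat_mask, bin_minutes=bin_minutes, **kw)


@pytest.fixture
def square_wave_week():
    """7 identical days: high for 16 h (08:00-24:00), zero for 8 h."""
    day = np.zeros(144)
    day[48:] = 100.0
    return day_series(np.tile(day, (7, 1)))


def brute_force_window(values, counts, width_bins, maximize):
    """Independent exhaustive circular window search (oracle for M10/L5)."""
    p = len(values)
    best_onset, best_mean = None, None
    for onset in range(p):
        idx = (onset + np.arange(width_bins)) % p
        w = counts[idx].astype(float)
        if w.sum() == 0:
            continue
        mean = float((values[idx] * w).sum() / w.sum())
        better = best_mean is None or (mean > best_mean if maximize else mean < best_mean)
        if better:
            best_onset, best_mean = onset, mean
    return best_mean, best_onset
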