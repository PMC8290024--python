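"""Regular 10-minute-binned time series, the common currency of all metrics.

Every analysis operation in this package runs on a :class:`RegularSeries`:
a value per fixed-width time-of-day bin with an explicit validity mask.
Bins are half-open intervals ``[t, t + bin_minutes)`` and bin 0 of each day
starts at local midnight.  Timestamps are local wall-clock with no DST
adjustment (week-long windows rarely span a transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440


@dataclass
class RegularSeries:
    """A value per fixed-width bin with a per-bin validity mask.

    Parameters
    ----------
    start
        Timestamp of the first bin's left edge; must be aligned to a bin
        boundary counted from midnight.
    values
        One float per bin.  Values at invalid bins carry no semantics.
    mask
        Boolean per bin, ``True`` where the bin holds a valid value.
    units
        Channel units (e.g. ``"degC"``, ``"deg/min"``, ``"deg"``, ``"a.u."``).
    bin_minutes
        Bin width; the default 10 minutes matches the wrist-temperature
        logger cadence that the other channels are averaged onto.
    """

    start: pd.Timestamp
    values: np.ndarray
    mask: np.ndarray
    units: str = ""
    bin_minutes: int = 10

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 1 or self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be 1-d arrays of equal length")
        if MINUTES_PER_DAY % self.bin_minutes:
            raise ValueError("bin_minutes must divide a day")
        offset = (self.start - self.start.normalize()) / pd.Timedelta(minutes=1)
        if offset % self.bin_minutes:
            raise ValueError("start must be aligned to a bin boundary")

    @property
    def bins_per_day(self) -> int:
        return MINUTES_PER_DAY // self.bin_minutes

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def n_days(self) -> float:
        return self.n_bins / self.bins_per_day

    @property
    def masked_fraction(self) -> float:
        """Fraction of bins that are invalid."""
        return float(1.0 - self.mask.mean()) if self.n_bins else 0.0

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=self.n_bins, freq=pd.Timedelta(minutes=self.bin_minutes)
        )

    def is_whole_days(self) -> bool:
        midnight_aligned = self.start == self.start.normalize()
        return midnight_aligned and self.n_bins % self.bins_per_day == 0

    def day_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Reshape to (days, bins_per_day); requires whole days from midnight."""
        if not self.is_whole_days():
            raise ValueError("series does not span whole days starting at midnight")
        shape = (int(self.n_days), self.bins_per_day)
        return self.values.reshape(shape), self.mask.reshape(shape)

    def rebin(self, bin_minutes: int) -> "RegularSeries":
        """Average into coarser bins (e.g. 10 min -> 60 min).

        A coarse bin is valid if at least one constituent fine bin is valid;
        its value is the mean of the valid fine bins.
        """
        if bin_minutes == self.bin_minutes:
            return self
        if bin_minutes % self.bin_minutes:
            raise ValueError("coarse bin width must be a multiple of the fine width")
        k = bin_minutes // self.bin_minutes
        if self.n_bins % k:
            raise ValueError("series length must be a multiple of the rebin factor")
        vals = np.where(self.mask, self.values, 0.0).reshape(-1, k)
        counts = self.mask.reshape(-1, k).sum(axis=1)
        mask = counts > 0
        out = np.full(vals.shape[0], np.nan)
        np.divide(vals.sum(axis=1), counts, out=out, where=mask)
        return RegularSeries(self.start, out, mask, units=self.units, bin_minutes=bin_minutes)

    def shifted(self, days: int) -> "RegularSeries":
        """Same data relabelled `days` later; analysis results are unchanged."""
        return RegularSeries(
            self.start + pd.Timedelta(days=days),
            self.values.copy(),
            self.mask.copy(),
            units=self.units,
            bin_minutes=self.bin_minutes,
        )


@dataclass
class DailyWaveform:
    """Mean daily pattern: one value per time-of-day bin plus contributing-day counts."""

    values: np.ndarray
    counts: np.ndarray
    units: str = ""
    bin_minutes: int = 10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        expected = MINUTES_PER_DAY // self.bin_minutes
        if self.values.size != expected or self.counts.size != expected:
            raise ValueError(f"waveform must have exactly {expected} bins")

    @property
    def bins_per_day(self) -> int:
        return self.values.size

    @property
    def mask(self) -> np.ndarray:
        """Valid where at least one day contributed."""
        return self.counts > 0


@dataclass
class TapSeries(RegularSeries):
    """Integrated TAP series: unitless values in [0, 1] on the common grid.

    ``provenance`` records which normalized channels were averaged.
    """

    provenance: tuple[str, ...] = field(default=("wt", "activity", "position"))
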