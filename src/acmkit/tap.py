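"""TAP integration: normalize channels to [0, 1] and average them.

TAP combines wrist Temperature (inverted), motor Activity and body
Position, each normalized per subject to [0, 1] and averaged bin-wise.
A TAP value of 1 corresponds to the lowest wrist temperatures, highest
activity and a standing position (wake); 0 to the highest temperatures,
lowest activity and a horizontal position (sleep).

Normalization clips each channel to its per-subject 5th-95th percentile
range by default (robust to burst outliers) before the linear map; plain
min-max is the (0, 100) special case.
"""

from __future__ import annotations

import numpy as np

from .series import RegularSeries, TapSeries

DEFAULT_PCT = (5.0, 95.0)


def normalize_channel(
    series: RegularSeries,
    invert: bool = False,
    lo_pct: float = DEFAULT_PCT[0],
    hi_pct: float = DEFAULT_PCT[1],
) -> RegularSeries:
    """Map a channel into [0, 1] via percentile clipping, optionally inverted.

    Values are clipped to the [lo_pct, hi_pct] percentile range of the
    subject's valid samples and mapped linearly onto [0, 1]; with ``invert``
    the result is ``1 - mapped`` (used for wrist temperature, whose rhythm
    is antiphase to activity).  A constant channel has no defined
    normalization and raises ``ValueError``.
    """
    if not 0.0 <= lo_pct < hi_pct <= 100.0:
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    valid = series.values[series.mask]
    if valid.size < 2 or np.unique(valid).size < 2:
        raise ValueError("normalization undefined for a constant channel")
    lo, hi = np.percentile(valid, [lo_pct, hi_pct])
    if hi == lo:
        raise ValueError("normalization undefined: degenerate percentile range")
    mapped = (np.clip(series.values, lo, hi) - lo) / (hi - lo)
    if invert:
        mapped = 1.0 - mapped
    return RegularSeries(
        series.start, mapped, series.mask.copy(), units="a.u.", bin_minutes=series.bin_minutes
    )


def integrate_tap(
    wt_n: RegularSeries,
    act_n: RegularSeries,
    pos_n: RegularSeries,
    missing: str = "mask",
) -> TapSeries:
    """Average three aligned normalized channels into the TAP series.

    ``wt_n`` must already be inverted-normalized so the mean is pure.
    ``missing`` policy: ``"mask"`` (default) masks a bin if any channel is
    masked there; ``"available"`` averages whichever channels remain.
    """
    channels = (wt_n, act_n, pos_n)
    ref = channels[0]
    for s in channels[1:]:
        if (
            s.start != ref.start
            or s.n_bins != ref.n_bins
            or s.bin_minutes != ref.bin_minutes
        ):
            raise ValueError("channels must share the same grid")
    for s in channels:
        v = s.values[s.mask]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("channels must be normalized into [0, 1]")
    if missing not in ("mask", "available"):
        raise ValueError(f"unknown missing policy {missing!r}")
    masks = np.stack([s.mask for s in channels])
    values = np.stack([s.values for s in channels])
    if missing == "mask":
        mask = masks.all(axis=0)
        tap = values.mean(axis=0)
    else:
        counts = masks.sum(axis=0)
        mask = counts > 0
        tap = np.full(ref.n_bins, np.nan)
        np.divide(
            np.where(masks, values, 0.0).sum(axis=0), counts, out=tap, where=mask
        )
    tap = np.clip(tap, 0.0, 1.0)
    return TapSeries(
        ref.start,
        tap,
        mask,
        units="a.u.",
        bin_minutes=ref.bin_minutes,
        provenance=("wt", "activity", "position"),
    )
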