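"""Epoch-level preprocessing: aggregation, day exclusion, folded profiles.

The processing chain mirrors standard wearable temperature workflows: 30-s
temperature epochs are aggregated into 15-min bins by arithmetic means, any
calendar day (midnight to midnight) containing a non-wear epoch is excluded
in full, subjects must retain a minimum number of complete days (2 for the
primary rule, 5 for the sensitivity rule), and retained days are folded
into an average 24-h profile for the non-parametric metrics and plots.
"""

from __future__ import annotations

import numpy as np

from .exceptions import AlignmentError, ConfigurationError, InsufficientDataError
from .types import DailyProfile, EpochSeries

__all__ = [
    "aggregate_to_bins",
    "exclude_nonwear_days",
    "require_min_days",
    "count_complete_days",
    "fold_average_profile",
    "flag_low_temperature",
]


def aggregate_to_bins(raw: EpochSeries, bin_minutes: int = 15) -> EpochSeries:
    """Aggregate a fine-grained series into fixed bins by arithmetic means.

    Each output epoch is the mean of its constituent input epochs; a bin
    containing any non-wear input epoch is flagged non-wear.  The input grid
    must divide the bin evenly and start on a bin boundary; a trailing
    partial bin is dropped.
    """
    if len(raw) == 0:
        return raw.copy()
    bin_s = bin_minutes * 60
    epoch_s = raw.epoch_s
    if epoch_s == 0:
        raise AlignmentError("cannot aggregate a single-epoch series")
    if bin_s % epoch_s:
        raise AlignmentError(
            f"epoch length {epoch_s}s does not divide the {bin_minutes}-min bin evenly"
        )
    start = raw.timestamps[0]
    offset_s = int((start - start.normalize()).total_seconds())
    if offset_s % bin_s:
        raise AlignmentError("series does not start on a bin boundary")
    # bin id of each epoch, robust to day gaps left by exclusion
    sec = (raw.timestamps.asi8 - raw.timestamps[0].normalize().value) // 1_000_000_000
    bin_id = sec // bin_s
    k = bin_s // epoch_s
    # keep only complete bins (k epochs present)
    uniq, inverse, counts = np.unique(bin_id, return_inverse=True, return_counts=True)
    keep = (counts == k)[inverse]
    if not keep.any():
        return EpochSeries(raw.timestamps[:0], raw.values[:0], raw.wear[:0])
    sub = raw.select(keep)
    sec = (sub.timestamps.asi8 - sub.timestamps[0].normalize().value) // 1_000_000_000
    order = np.argsort(sec, kind="stable")
    vals = sub.values[order].reshape(-1, k)
    wear = sub.wear[order].reshape(-1, k)
    ts = sub.timestamps[order][::k]
    return EpochSeries(ts, vals.mean(axis=1), wear.all(axis=1))


def exclude_nonwear_days(series: EpochSeries, drop_incomplete: bool = True) -> EpochSeries:
    """Remove entire calendar days containing any non-wear epoch.

    With ``drop_incomplete`` (the default), partial days — e.g. a device
    started or stopped mid-day — are removed as well, so the survivors are
    complete midnight-to-midnight days.  May return an empty series.
    """
    if len(series) == 0:
        return series.copy()
    ppd = series.epochs_per_day
    days = series.day_index
    keep = np.ones(len(series), dtype=bool)
    for d in np.unique(days):
        m = days == d
        bad = (~series.wear[m]).any()
        if drop_incomplete and m.sum() != ppd:
            bad = True
        if bad:
            keep[m] = False
    return series.select(keep)


def count_complete_days(series: EpochSeries) -> int:
    """Number of calendar days with a full complement of epochs, all worn."""
    if len(series) == 0:
        return 0
    ppd = series.epochs_per_day
    days = series.day_index
    n = 0
    for d in np.unique(days):
        m = days == d
        if m.sum() == ppd and series.wear[m].all():
            n += 1
    return n


def require_min_days(series: EpochSeries, min_days: int = 2) -> bool:
    """Inclusion rule: True iff the series retains >= ``min_days`` complete days.

    ``min_days=2`` is the primary inclusion rule; ``min_days=5`` the
    sensitivity rule.
    """
    if min_days < 1:
        raise ConfigurationError("min_days must be >= 1")
    return count_complete_days(series) >= min_days


def fold_average_profile(series: EpochSeries, bin_minutes: int | None = None) -> DailyProfile:
    """Fold a multi-day series into an average 24-h profile.

    Values are averaged across days at each bin of the day.  ``bin_minutes``
    defaults to the series' own epoch length; a coarser value re-bins first.
    The fold is invariant to the order of days.
    """
    if len(series) == 0:
        raise InsufficientDataError("cannot fold an empty series")
    epoch_min = series.epoch_s // 60 if series.epoch_s >= 60 else None
    if bin_minutes is None:
        if epoch_min is None:
            raise AlignmentError("specify bin_minutes for sub-minute epochs")
        bin_minutes = epoch_min
    work = series
    if bin_minutes * 60 != series.epoch_s:
        work = aggregate_to_bins(series, bin_minutes)
    if len(work) == 0:
        raise InsufficientDataError("no complete bins to fold")
    minute = work.minute_of_day
    grid = np.arange(0, 1440, bin_minutes)
    sums = np.zeros(len(grid))
    counts = np.zeros(len(grid), dtype=int)
    pos = minute // bin_minutes
    np.add.at(sums, pos, work.values)
    np.add.at(counts, pos, 1)
    if (counts == 0).any():
        raise InsufficientDataError("profile has empty bins; need >= 1 complete day")
    return DailyProfile(
        bin_start_minute=grid,
        mean_value=sums / counts,
        n_days_contributing=counts,
        bin_minutes=bin_minutes,
    )


def flag_low_temperature(
    series: EpochSeries, floor_c: float = 20.0, min_consecutive_bins: int = 3
) -> EpochSeries:
    """Optional naive non-wear heuristic: flag runs of implausibly low readings.

    Marks as non-wear any run of >= ``min_consecutive_bins`` consecutive
    epochs below ``floor_c``.  Off by default in the pipeline — wear flags
    normally arrive from the generator or an upstream device pipeline.
    """
    out = series.copy()
    low = out.values < floor_c
    n = len(out)
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= min_consecutive_bins:
                out.wear[i:j] = False
            i = j
        else:
            i += 1
    return out
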