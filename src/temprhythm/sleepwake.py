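"""Sleep-wake and activity summaries, and the temperature-sleep phase angle.

Sleep metrics are computed from epoch-level sleep/wake states (1 = sleep)
and nightly sleep windows: efficiency is the percentage of in-window epochs
asleep (averaged over nights), duration the mean asleep hours per night,
and the sleep midpoint the circular mean of nightly window midpoints
(circular so that 23:00 and 01:00 average to midnight, not noon).

The Sleep Regularity Index compares epoch states exactly 24 h apart:
SRI = -100 + 200*P, with P the fraction of matching pairs, so identical
days score 100 and day-inverted schedules -100.  At least 5 overlapping
days are required; otherwise the metric is withheld.

Activity summaries: M10 onset (start clock time of the most active 10-h
circular window of the folded activity profile), MVPA minutes/day (1-min
epochs strictly above 100 mg) and total activity per day.

The phase angle is acrotime minus sleep midpoint wrapped to (-12, 12] h and
expressed in radians (x 2*pi/24): positive values mean the temperature peak
comes after mid-sleep.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError, InsufficientDataError
from .preprocess import fold_average_profile
from .types import DailyProfile, EpochSeries, SleepWindow

__all__ = [
    "sleep_metrics",
    "sleep_regularity_index",
    "m10_onset",
    "mvpa_minutes",
    "total_activity",
    "phase_angle",
    "circular_mean_hours",
]


def circular_mean_hours(hours: np.ndarray, period: float = 24.0) -> float:
    """Circular mean of clock hours on a ``period``-hour dial."""
    hours = np.asarray(hours, dtype=float)
    if len(hours) == 0:
        return float("nan")
    ang = hours * 2.0 * np.pi / period
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean_ang * period / (2.0 * np.pi)) % period)


def sleep_metrics(
    windows: list[SleepWindow], states: EpochSeries
) -> tuple[float, float, float]:
    """Per-night sleep efficiency (%), circular-mean midpoint (clock hours)
    and mean asleep duration (hours per 24 h).

    Efficiency for a night is 100 x (asleep epochs) / (in-window epochs);
    nights whose window has no state epochs are skipped.
    """
    if not windows:
        raise InsufficientDataError("no sleep windows")
    ts = states.timestamps
    eff, mids, durs = [], [], []
    epoch_h = states.epoch_s / 3600.0
    for w in windows:
        mask = (ts >= w.onset) & (ts < w.offset)
        n_win = int(mask.sum())
        if n_win == 0:
            continue
        n_sleep = int((states.values[mask] == 1).sum())
        eff.append(100.0 * n_sleep / n_win)
        durs.append(n_sleep * epoch_h)
        mid = w.midpoint
        mids.append((mid - mid.normalize()).total_seconds() / 3600.0)
    if not eff:
        raise InsufficientDataError("no state epochs fall inside the sleep windows")
    return float(np.mean(eff)), circular_mean_hours(np.asarray(mids)), float(np.mean(durs))


def sleep_regularity_index(states: EpochSeries, min_overlap_days: int = 5) -> float:
    """Sleep Regularity Index in [-100, 100] from epoch pairs 24 h apart.

    Pairs are formed between identical clock epochs on consecutive calendar
    days; pairs spanning a missing day are skipped.  Raises
    :class:`InsufficientDataError` when fewer than ``min_overlap_days``
    distinct days contribute pairs (the metric is withheld, not guessed).
    """
    if len(states) == 0:
        raise InsufficientDataError("empty state series")
    ppd = states.epochs_per_day
    days = states.day_index
    sec = (states.timestamps.asi8 - states.timestamps.normalize().asi8) // 1_000_000_000
    pos = (sec // states.epoch_s).astype(int)
    n_span = int(days.max()) + 1
    grid = np.full((n_span, ppd), np.nan)
    grid[days, pos] = states.values
    a, b = grid[:-1], grid[1:]
    valid = ~np.isnan(a) & ~np.isnan(b)
    day_has_pair = valid.any(axis=1)
    involved = np.zeros(n_span, dtype=bool)
    involved[:-1] |= day_has_pair
    involved[1:] |= day_has_pair
    if int(involved.sum()) < min_overlap_days:
        raise InsufficientDataError(
            f"SRI requires >= {min_overlap_days} overlapping days "
            f"(have {int(involved.sum())})"
        )
    agree = (a == b) & valid
    p_hat = float(agree.sum()) / float(valid.sum())
    return -100.0 + 200.0 * p_hat


def _window_scan(profile: DailyProfile, width_h: float) -> tuple[int, bool, np.ndarray]:
    w = int(round(width_h * 60 / profile.bin_minutes))
    v = profile.mean_value
    ext = np.concatenate([v, v[: w - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    means = (csum[w:] - csum[:-w]) / w
    j = int(np.argmax(means))
    tied = bool(np.sum(np.isclose(means, means[j], rtol=0, atol=1e-12)) > 1)
    return j, tied, means


def m10_onset(
    data: EpochSeries | DailyProfile, with_tie: bool = False
) -> float | tuple[float, bool]:
    """Onset clock time (hours) of the most active 10-h circular window.

    Accepts a raw activity series (folded internally on its own epoch grid)
    or a pre-folded profile.  Ties are broken by the earliest clock time;
    pass ``with_tie=True`` to also learn whether the maximum was tied.
    """
    profile = data if isinstance(data, DailyProfile) else fold_average_profile(data)
    j, tied, _ = _window_scan(profile, 10.0)
    onset = float(profile.bin_start_minute[j] / 60.0)
    return (onset, tied) if with_tie else onset


def mvpa_minutes(activity: EpochSeries, threshold_mg: float = 100.0) -> float:
    """Minutes/day of moderate-to-vigorous activity: 1-min epochs strictly
    above ``threshold_mg``."""
    if activity.epoch_s != 60:
        raise ConfigurationError(
            f"MVPA needs 1-min epochs (got {activity.epoch_s}s)"
        )
    if len(activity) == 0:
        raise InsufficientDataError("empty activity series")
    n_days = len(np.unique(activity.day_index))
    return float((activity.values > threshold_mg).sum()) / n_days


def total_activity(activity: EpochSeries) -> float:
    """Total activity per day: epoch values summed over complete days,
    divided by the number of complete days."""
    if len(activity) == 0:
        raise InsufficientDataError("empty activity series")
    ppd = activity.epochs_per_day
    days = activity.day_index
    total = 0.0
    n_complete = 0
    for d in np.unique(days):
        m = days == d
        if m.sum() == ppd:
            total += float(activity.values[m].sum())
            n_complete += 1
    if n_complete == 0:
        raise InsufficientDataError("total activity needs >= 1 complete day")
    return total / n_complete


def phase_angle(acrotime: float, sleep_midpoint: float) -> float:
    """Temperature-sleep phase angle in radians, (-pi, pi].

    Acrotime minus sleep midpoint, wrapped to (-12, 12] hours and converted
    at 2*pi/24 rad per hour; positive = temperature peak after mid-sleep.
    NaN inputs (undefined acrophase) propagate.
    """
    if not (np.isfinite(acrotime) and np.isfinite(sleep_midpoint)):
        return float("nan")
    dh = (acrotime - sleep_midpoint) % 24.0
    if dh > 12.0:
        dh -= 24.0
    return dh * 2.0 * np.pi / 24.0
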