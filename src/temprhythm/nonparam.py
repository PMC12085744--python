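"""Non-parametric circadian metrics: IS, IV, M5/L10 and relative amplitude.

Inter-daily stability (IS) is the variance-ratio statistic

    IS = ( sum_h (xbar_h - xbar)^2 / p ) / ( sum_i (x_i - xbar)^2 / n )

over bins of the day (p bins/day, default hourly), where xbar_h is the
across-day mean at bin-of-day h: the fraction of the total variance
explained by the average 24-h pattern (0..1, higher = more stable).

Intra-daily variability (IV) is the normalized mean squared successive
difference

    IV = ( sum_pairs (x_i - x_prev)^2 / m ) / ( sum_i (x_i - xbar)^2 / n )

computed over consecutive bins in recorded order.  Successive differences
are taken within each contiguous block of retained whole days — pairs that
would span an excluded day are skipped — and each block is closed
circularly (its last bin is also differenced against its first, which is
clock-adjacent for whole-day blocks).  The circular closure makes IV exact
on periodic signals: a noiseless hourly-sampled 24-h cosine gives
IV = 4*sin^2(pi/24) and an alternating series gives IV = 4; white noise
still tends to 2.  Note IV is not mathematically bounded by 2 — the often
quoted 0-2 range is empirical.

M5 and L10 are the highest 5-h and lowest 10-h circular moving means of the
folded 24-h profile; relative amplitude RA = (M5 - L10)/(M5 + L10).
"""

from __future__ import annotations

import numpy as np

from .exceptions import InsufficientDataError
from .preprocess import aggregate_to_bins, fold_average_profile
from .types import DailyProfile, EpochSeries, NonparamMetrics

__all__ = [
    "interdaily_stability",
    "intradaily_variability",
    "m5_l10",
    "relative_amplitude",
    "compute_nonparam",
]


def _binned(series: EpochSeries, bin_minutes: int) -> EpochSeries:
    if series.epoch_s == bin_minutes * 60:
        return series
    return aggregate_to_bins(series, bin_minutes)


def interdaily_stability(series: EpochSeries, bin_minutes: int = 60) -> float:
    """Inter-daily stability of the rhythm across days (0..1).

    Needs >= 2 complete days.  A constant series has no variance to
    stabilize and returns NaN (undefined).
    """
    work = _binned(series, bin_minutes)
    if len(work) == 0:
        raise InsufficientDataError("empty series")
    p = 1440 // bin_minutes
    days = work.day_index
    uniq = np.unique(days)
    if len(uniq) < 2:
        raise InsufficientDataError("interdaily stability needs >= 2 complete days")
    pos = work.minute_of_day // bin_minutes
    x = work.values
    xbar = x.mean()
    sums = np.zeros(p)
    counts = np.zeros(p, dtype=int)
    np.add.at(sums, pos, x)
    np.add.at(counts, pos, 1)
    if (counts == 0).any():
        raise InsufficientDataError("days are incomplete at this bin width")
    hour_means = sums / counts
    denom = float(np.sum((x - xbar) ** 2)) / len(x)
    if denom == 0:
        return float("nan")
    num = float(np.sum((hour_means - xbar) ** 2)) / p
    return num / denom


def intradaily_variability(series: EpochSeries, bin_minutes: int = 60) -> float:
    """Intra-daily variability (rhythm fragmentation).

    Successive differences are taken within contiguous blocks of retained
    days (circularly closed per block); a constant series returns NaN.
    """
    work = _binned(series, bin_minutes)
    if len(work) < 2:
        raise InsufficientDataError("intradaily variability needs >= 2 bins")
    x = work.values
    xbar = x.mean()
    denom = float(np.sum((x - xbar) ** 2)) / len(x)
    if denom == 0:
        return float("nan")
    days = work.day_index
    uniq = np.unique(days)
    # contiguous runs of calendar days
    breaks = np.where(np.diff(uniq) != 1)[0]
    run_edges = np.concatenate([[0], breaks + 1, [len(uniq)]])
    sq_sum = 0.0
    m = 0
    for r0, r1 in zip(run_edges[:-1], run_edges[1:]):
        block_days = uniq[r0:r1]
        mask = np.isin(days, block_days)
        xb = x[mask]
        if len(xb) < 2:
            continue
        d = np.diff(xb)
        sq_sum += float(np.sum(d**2)) + float((xb[0] - xb[-1]) ** 2)
        m += len(xb)
    if m == 0:
        return float("nan")
    return (sq_sum / m) / denom


def _circular_window_means(values: np.ndarray, width: int) -> np.ndarray:
    ext = np.concatenate([values, values[: width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    return (csum[width:] - csum[:-width]) / width


def m5_l10(
    profile: DailyProfile, m_hours: float = 5.0, l_hours: float = 10.0
) -> tuple[float, float, float, float]:
    """Highest 5-h and lowest 10-h circular moving means of a folded profile.

    Returns ``(m5, l10, m5_midpoint, l10_midpoint)`` with midpoints as clock
    hours of the window centers.  Windows wrap across midnight; ties are
    broken by the earliest clock start.
    """
    wm = int(round(m_hours * 60 / profile.bin_minutes))
    wl = int(round(l_hours * 60 / profile.bin_minutes))
    if wm < 1 or wl < 1 or wm > len(profile) or wl > len(profile):
        raise InsufficientDataError("window widths incompatible with profile grid")
    v = profile.mean_value
    means_m = _circular_window_means(v, wm)
    means_l = _circular_window_means(v, wl)
    jm = int(np.argmax(means_m))
    jl = int(np.argmin(means_l))
    m5 = float(means_m[jm])
    l10 = float(means_l[jl])
    m5_mid = ((profile.bin_start_minute[jm] + wm * profile.bin_minutes / 2.0) / 60.0) % 24.0
    l10_mid = ((profile.bin_start_minute[jl] + wl * profile.bin_minutes / 2.0) / 60.0) % 24.0
    return m5, l10, float(m5_mid), float(l10_mid)


def relative_amplitude(m5: float, l10: float) -> float:
    """RA = (M5 - L10)/(M5 + L10); NaN when M5 + L10 <= 0 (undefined for °C)."""
    if m5 < l10 - 1e-12:
        raise ValueError("M5 must be >= L10")
    s = m5 + l10
    if s <= 0:
        return float("nan")
    return (m5 - l10) / s


def compute_nonparam(
    series: EpochSeries,
    profile: DailyProfile | None = None,
    is_iv_bin_minutes: int = 60,
    profile_bin_minutes: int = 15,
) -> NonparamMetrics:
    """All non-parametric metrics for one subject's retained temperature days."""
    if profile is None:
        profile = fold_average_profile(series, profile_bin_minutes)
    m5, l10, m5_mid, l10_mid = m5_l10(profile)
    return NonparamMetrics(
        is_value=interdaily_stability(series, is_iv_bin_minutes),
        iv_value=intradaily_variability(series, is_iv_bin_minutes),
        m5=m5,
        l10=l10,
        ra=relative_amplitude(m5, l10),
        m5_midpoint=m5_mid,
        l10_midpoint=l10_mid,
    )
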