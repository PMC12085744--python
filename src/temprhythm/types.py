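"""Core data containers.

The analysis operates on regular-grid epoch channels (wrist skin temperature
at 30-s epochs, gross motor activity and sleep/wake state at 1-min epochs).
An :class:`EpochSeries` wraps one channel: timestamps on a regular grid, the
epoch values and a per-epoch wear flag.  After whole-day exclusion the grid
may contain day-sized gaps, so the invariant is "strictly increasing
timestamps whose spacings are positive multiples of the epoch length" rather
than strict contiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "DailyProfile",
    "SleepWindow",
    "SubjectRecording",
    "CosinorFit",
    "GroupCosinorModel",
    "NonparamMetrics",
    "SleepWakeMetrics",
    "GroupComparison",
    "AgreementResult",
]


@dataclass
class EpochSeries:
    """A single regular-grid channel with per-epoch wear flags.

    Parameters
    ----------
    timestamps
        Epoch start times, strictly increasing, spaced by integer multiples
        of ``epoch_s`` seconds (gaps from excluded days are allowed).
    values
        Epoch values (°C for temperature, mg for activity, 0/1 for sleep).
    wear
        True where the device was worn.  Defaults to all-True.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    wear: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if self.wear is None:
            self.wear = np.ones(len(self.values), dtype=bool)
        else:
            self.wear = np.asarray(self.wear, dtype=bool)
        if not (len(self.timestamps) == len(self.values) == len(self.wear)):
            raise ValueError("timestamps, values and wear must have equal length")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)  # ns
            if np.any(deltas <= 0):
                raise ValueError("timestamps must be strictly increasing")
            step = int(self.epoch_s * 1_000_000_000)
            if np.any(deltas % step != 0):
                raise ValueError(
                    "timestamps must lie on a regular grid of the epoch length"
                )

    @property
    def epoch_s(self) -> int:
        """Epoch length in seconds (smallest spacing on the grid)."""
        if len(self.timestamps) < 2:
            return 0
        return int(np.min(np.diff(self.timestamps.asi8)) // 1_000_000_000)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_s

    @property
    def day_index(self) -> np.ndarray:
        """Calendar-day index (midnight-to-midnight) relative to the first day."""
        first_midnight = self.timestamps[0].normalize().value
        return (self.timestamps.asi8 - first_midnight) // 86_400_000_000_000

    @property
    def minute_of_day(self) -> np.ndarray:
        return (self.timestamps.hour * 60 + self.timestamps.minute).to_numpy()

    @property
    def hour_of_day(self) -> np.ndarray:
        """Clock hour of each epoch as a float in [0, 24)."""
        ns = self.timestamps.asi8 - self.timestamps.normalize().asi8
        return ns / 3.6e12

    @property
    def hours_since_start_midnight(self) -> np.ndarray:
        """Hours since midnight of the first recorded day (monotone time axis)."""
        t0 = self.timestamps[0].normalize().value
        return (self.timestamps.asi8 - t0) / 3.6e12

    def select(self, mask: np.ndarray) -> "EpochSeries":
        return EpochSeries(self.timestamps[mask], self.values[mask], self.wear[mask])

    def copy(self) -> "EpochSeries":
        return EpochSeries(self.timestamps.copy(), self.values.copy(), self.wear.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "value": self.values,
                "wear": self.wear,
            }
        )


@dataclass
class DailyProfile:
    """A folded 24-h average profile on a fixed bin grid.

    ``mean_value[i]`` is the across-day mean of the channel in the bin
    starting at ``bin_start_minute[i]``; ``n_days_contributing[i]`` counts the
    days entering that mean.  Covers exactly 24 h with constant bin width.
    """

    bin_start_minute: np.ndarray
    mean_value: np.ndarray
    n_days_contributing: np.ndarray
    bin_minutes: int

    def __post_init__(self) -> None:
        self.bin_start_minute = np.asarray(self.bin_start_minute, dtype=int)
        self.mean_value = np.asarray(self.mean_value, dtype=float)
        self.n_days_contributing = np.asarray(self.n_days_contributing, dtype=int)
        expected = np.arange(0, 1440, self.bin_minutes)
        if len(self.bin_start_minute) != len(expected) or np.any(
            self.bin_start_minute != expected
        ):
            raise ValueError("profile must cover exactly 24 h on a constant-width grid")

    def __len__(self) -> int:
        return len(self.mean_value)

    @property
    def bin_center_hours(self) -> np.ndarray:
        """Clock hour of each bin center."""
        return (self.bin_start_minute + self.bin_minutes / 2.0) / 60.0


@dataclass(frozen=True)
class SleepWindow:
    """One night's sleep window (onset to final wake)."""

    night_index: int
    onset: pd.Timestamp
    offset: pd.Timestamp

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("sleep window offset must be after onset")

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.onset + (self.offset - self.onset) / 2

    @property
    def duration_h(self) -> float:
        return (self.offset - self.onset).total_seconds() / 3600.0


@dataclass
class SubjectRecording:
    """All channels plus nightly sleep windows and metadata for one subject."""

    subject_id: str
    temperature: EpochSeries
    activity: EpochSeries
    sleep_state: EpochSeries
    sleep_windows: list[SleepWindow]
    metadata: dict = field(default_factory=dict)


@dataclass
class CosinorFit:
    """Single-cosinor fit of a 24-h rhythm.

    ``acrophase`` follows the convention Y(t) = M + A·cos(2πt/24 + φ) with φ
    wrapped to (−2π, 0], so a peak after midnight has negative φ;
    ``acrotime`` is the corresponding peak clock time in hours,
    acrotime = ((−φ) mod 2π)·24/(2π).  ``acrophase`` is NaN when the
    amplitude is indistinguishable from zero (phase undefined).
    """

    mesor: float
    amplitude: float
    acrophase: float
    acrotime: float
    r2: float
    rmse: float
    mae: float
    n_days: int
    period_h: float = 24.0

    @property
    def phase_defined(self) -> bool:
        return np.isfinite(self.acrophase)

    def predict(self, t_hours: np.ndarray) -> np.ndarray:
        """Model prediction at times ``t_hours`` (hours; any origin sharing
        the fit's clock)."""
        t = np.asarray(t_hours, dtype=float)
        if not self.phase_defined:
            return np.full_like(t, self.mesor)
        omega = 2.0 * np.pi / self.period_h
        return self.mesor + self.amplitude * np.cos(omega * t + self.acrophase)


@dataclass
class GroupCosinorModel:
    """Mixed-effects cosinor with group-specific parameters.

    ``groups`` maps each group label to a dict with keys ``mesor``,
    ``amplitude``, ``acrophase``, ``acrotime`` and their standard errors
    (``se_mesor``, ``se_amplitude``, ``se_acrophase``).  ``contrasts`` holds
    pairwise differences (second minus first label) with delta-method SEs.
    """

    groups: dict
    contrasts: dict
    random_intercept_var: float
    r2: float
    rmse: float
    mae: float
    n_subjects: int
    n_obs: int
    converged: bool


@dataclass
class NonparamMetrics:
    """Non-parametric circadian metrics for one subject."""

    is_value: float
    iv_value: float
    m5: float
    l10: float
    ra: float
    m5_midpoint: float
    l10_midpoint: float


@dataclass
class SleepWakeMetrics:
    """Sleep-wake and activity summaries for one subject.

    ``sri_reason`` explains a withheld (NaN) Sleep Regularity Index.
    """

    efficiency: float
    midpoint: float
    duration_h: float
    sri: float
    m10_onset: float
    mvpa_min: float
    tac: float
    phase_angle: float
    sri_reason: Optional[str] = None


@dataclass
class GroupComparison:
    """Covariate-adjusted group contrast for one outcome (ANCOVA)."""

    outcome: str
    groups: list
    f_stat: float
    df: tuple
    p_value: float
    emmeans: dict            # label -> (estimated marginal mean, SE), analysis scale
    raw_means: dict          # label -> unadjusted raw-scale mean
    posthoc: dict            # (label_a, label_b) -> Bonferroni-adjusted p
    posthoc_unadjusted: dict
    boxcox_lambda: Optional[float] = None
    boxcox_shift: float = 0.0
    n_used: int = 0


@dataclass
class AgreementResult:
    """Bland-Altman device agreement: bias and 95% limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def series_replace(series: EpochSeries, **kwargs) -> EpochSeries:
    """Shallow functional update helper for EpochSeries."""
    return replace(series, **kwargs)
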