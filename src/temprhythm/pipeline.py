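"""End-to-end orchestration: recordings -> subject metrics -> group contrasts.

One pipeline run takes a directory of per-subject channel CSVs (or a
simulation preset), applies the preprocessing rules (15-min aggregation,
whole-day non-wear exclusion, minimum complete days), computes every
subject-level rhythm metric (cosinor, non-parametric, sleep-wake), runs the
covariate-adjusted group comparisons for each grouping (cohort, illness
subtype, clinical stage), optionally fits the mixed-effects group cosinor,
and writes summary tables, 24-h mean/fitted curves, an exclusions report
and a reproducibility manifest.  Identical config + seed give byte-identical
summary CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cosinor import fit_cosinor, fit_goodness, fit_group_cosinor
from .exceptions import ConfigurationError, InsufficientDataError, TempRhythmError
from .nonparam import compute_nonparam
from .preprocess import (
    aggregate_to_bins,
    count_complete_days,
    exclude_nonwear_days,
    fold_average_profile,
)
from .sleepwake import (
    circular_mean_hours,
    m10_onset,
    mvpa_minutes,
    phase_angle,
    sleep_metrics,
    sleep_regularity_index,
    total_activity,
)
from .stats import ancova_compare
from .synthetic import (
    generate_cohort,
    mood_cohort_preset,
    null_cohort_preset,
    preset_from_yaml,
    read_cohort_csvs,
    write_cohort_csvs,
)
from .types import GroupCosinorModel, SubjectRecording

__all__ = [
    "RunConfig",
    "CohortResults",
    "DEFAULT_OUTCOMES",
    "process_subject",
    "analyze_cohort",
    "run_pipeline",
]

log = logging.getLogger("temprhythm")

DEFAULT_OUTCOMES = (
    "mesor",
    "amplitude",
    "acrophase",
    "is_value",
    "iv_value",
    "ra",
    "efficiency",
    "midpoint",
    "duration_h",
    "sri",
    "m10_onset",
    "mvpa_min",
    "tac",
    "phase_angle",
)


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold carries the analysis default
    (15-min bins, >= 2 complete days, hourly IS/IV bins, 100 mg MVPA
    threshold, >= 5 overlapping days for the SRI, age + sex covariates)."""

    input_dir: Optional[str] = None
    preset: Optional[str] = None          # "mood", "null", or a YAML path
    n_control: int = 50
    n_case: int = 50
    out_dir: Optional[str] = None
    seed: int = 0
    bin_minutes: int = 15
    min_days: int = 2
    is_iv_bin_minutes: int = 60
    mvpa_threshold_mg: float = 100.0
    sri_min_days: int = 5
    covariates: tuple = ("age", "sex")
    boxcox: object = "auto"
    groupings: tuple = ("cohort", "subtype", "stage")
    outcomes: tuple = DEFAULT_OUTCOMES
    group_model: bool = True
    make_plots: bool = False
    write_inputs: bool = False            # also dump the simulated channel CSVs
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "groupings", "outcomes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("covariates", "groupings", "outcomes"):
            d[key] = list(d[key])
        return d


@dataclass
class CohortResults:
    summary: pd.DataFrame
    exclusions: pd.DataFrame
    comparisons: dict                       # grouping -> {outcome: GroupComparison}
    group_model: Optional[GroupCosinorModel]
    curves: Optional[pd.DataFrame]
    group_acrotime: dict                    # grouping -> {label: circular-mean acrotime}
    config: RunConfig


def process_subject(rec: SubjectRecording, cfg: RunConfig):
    """Compute all subject-level metrics; returns ``(row, None)`` or
    ``(None, exclusion_reason)`` when the subject fails the inclusion rule."""
    temp_bins = aggregate_to_bins(rec.temperature, cfg.bin_minutes)
    clean = exclude_nonwear_days(temp_bins)
    n_days = count_complete_days(clean)
    if n_days < cfg.min_days:
        return None, (
            f"{n_days} complete temperature day(s) after non-wear exclusion "
            f"(< {cfg.min_days})"
        )
    profile = fold_average_profile(clean, cfg.bin_minutes)
    fit = fit_cosinor(profile)
    r2, rmse, mae = fit_goodness(fit, clean)
    npm = compute_nonparam(
        clean, profile,
        is_iv_bin_minutes=cfg.is_iv_bin_minutes,
        profile_bin_minutes=cfg.bin_minutes,
    )

    try:
        eff, midpoint, duration_h = sleep_metrics(rec.sleep_windows, rec.sleep_state)
    except InsufficientDataError:
        eff = midpoint = duration_h = float("nan")
    sri = float("nan")
    sri_reason = ""
    try:
        sri = sleep_regularity_index(rec.sleep_state, cfg.sri_min_days)
    except InsufficientDataError as exc:
        sri_reason = str(exc)
    try:
        m10 = m10_onset(rec.activity)
        mvpa = mvpa_minutes(rec.activity, cfg.mvpa_threshold_mg)
        tac = total_activity(rec.activity)
    except (InsufficientDataError, TempRhythmError):
        m10 = mvpa = tac = float("nan")
    pa = phase_angle(fit.acrotime, midpoint)

    meta = rec.metadata or {}
    row = {
        "subject_id": rec.subject_id,
        "cohort": meta.get("cohort", ""),
        "subtype": meta.get("subtype", ""),
        "stage": meta.get("stage", ""),
        "age": meta.get("age", np.nan),
        "sex": meta.get("sex", ""),
        "bmi": meta.get("bmi", np.nan),
        "mesor": fit.mesor,
        "amplitude": fit.amplitude,
        "acrophase": fit.acrophase,
        "acrotime_h": fit.acrotime,
        "acrotime_hhmm": _hhmm(fit.acrotime),
        "r2": r2,
        "rmse": rmse,
        "mae": mae,
        "n_days": n_days,
        "is_value": npm.is_value,
        "iv_value": npm.iv_value,
        "m5": npm.m5,
        "l10": npm.l10,
        "ra": npm.ra,
        "m5_midpoint": npm.m5_midpoint,
        "l10_midpoint": npm.l10_midpoint,
        "efficiency": eff,
        "midpoint": midpoint,
        "midpoint_hhmm": _hhmm(midpoint),
        "duration_h": duration_h,
        "sri": sri,
        "sri_reason": sri_reason,
        "m10_onset": m10,
        "m10_hhmm": _hhmm(m10),
        "mvpa_min": mvpa,
        "tac": tac,
        "phase_angle": pa,
        "phase_angle_min": pa * 24 * 60 / (2 * np.pi) if np.isfinite(pa) else np.nan,
    }
    return row, None


def _hhmm(hours: float) -> str:
    if not np.isfinite(hours):
        return ""
    total = int(round((hours % 24.0) * 60))
    return f"{(total // 60) % 24:02d}{total % 60:02d}"


def analyze_cohort(
    records: Sequence[SubjectRecording],
    metadata: Optional[pd.DataFrame],
    cfg: Optional[RunConfig] = None,
) -> CohortResults:
    """Run the full analysis on in-memory recordings.

    ``metadata`` may be None when every recording carries its own metadata.
    Excluded subjects are reported, never silently dropped.
    """
    cfg = cfg or RunConfig()
    rows, excl = [], []
    for rec in records:
        row, reason = process_subject(rec, cfg)
        if row is None:
            excl.append({"subject_id": rec.subject_id, "reason": reason})
            log.info("excluded %s: %s", rec.subject_id, reason)
        else:
            rows.append(row)
    summary = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excl, columns=["subject_id", "reason"])

    comparisons: dict = {}
    group_acrotime: dict = {}
    if len(summary):
        for grouping in cfg.groupings:
            if grouping not in summary.columns:
                continue
            sub = summary[summary[grouping].astype(str) != ""]
            if sub[grouping].nunique() < 2:
                continue
            per_outcome = {}
            for outcome in cfg.outcomes:
                if outcome not in sub.columns:
                    continue
                try:
                    per_outcome[outcome] = ancova_compare(
                        sub, outcome, group=grouping,
                        covariates=list(cfg.covariates), boxcox=cfg.boxcox,
                    )
                except (InsufficientDataError, TempRhythmError) as exc:
                    log.warning("ANCOVA skipped for %s by %s: %s",
                                outcome, grouping, exc)
            comparisons[grouping] = per_outcome
            group_acrotime[grouping] = {
                g: circular_mean_hours(
                    gdf.loc[np.isfinite(gdf["acrotime_h"]), "acrotime_h"].to_numpy()
                )
                for g, gdf in sub.groupby(grouping)
            }

    group_model = None
    curves = None
    if cfg.group_model and len(summary) and "cohort" in summary.columns:
        try:
            frame, curves = _group_frame_and_curves(records, summary, cfg)
            if frame is not None:
                group_model = fit_group_cosinor(frame)
                curves = _add_fitted_curves(curves, group_model)
        except TempRhythmError as exc:
            log.warning("group cosinor model skipped: %s", exc)

    return CohortResults(
        summary=summary,
        exclusions=exclusions,
        comparisons=comparisons,
        group_model=group_model,
        curves=curves,
        group_acrotime=group_acrotime,
        config=cfg,
    )


def _group_frame_and_curves(records, summary, cfg):
    """Long frame of per-subject folded 15-min profiles for the mixed model,
    plus per-group observed mean 24-h curves."""
    kept = set(summary["subject_id"])
    label_of = dict(zip(summary["subject_id"], summary["cohort"].astype(str)))
    parts = []
    for rec in records:
        if rec.subject_id not in kept:
            continue
        g = label_of[rec.subject_id]
        if not g:
            continue
        clean = exclude_nonwear_days(aggregate_to_bins(rec.temperature, cfg.bin_minutes))
        if count_complete_days(clean) < cfg.min_days:
            continue
        prof = fold_average_profile(clean, cfg.bin_minutes)
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "group": g,
                    "t_hours": prof.bin_center_hours,
                    "value": prof.mean_value,
                }
            )
        )
    if not parts:
        return None, None
    frame = pd.concat(parts, ignore_index=True)
    n_per_group = frame.groupby("group")["subject_id"].nunique()
    if len(n_per_group) < 2 or (n_per_group < 2).any():
        return None, None
    curves = (
        frame.groupby(["group", "t_hours"])["value"]
        .mean()
        .rename("mean_temp")
        .reset_index()
    )
    return frame, curves


def _add_fitted_curves(curves, model: GroupCosinorModel):
    fitted = []
    omega = 2 * np.pi / 24.0
    for _, row in curves.iterrows():
        g = model.groups[row["group"]]
        fitted.append(
            g["mesor"] + g["amplitude"] * np.cos(omega * row["t_hours"] + g["acrophase"])
            if np.isfinite(g["acrophase"])
            else g["mesor"]
        )
    curves = curves.copy()
    curves["fitted_temp"] = fitted
    return curves


def comparisons_table(comparisons: dict) -> pd.DataFrame:
    """Flatten ANCOVA results into a table mirroring the per-outcome layout:
    outcome, group, estimated mean (SE), F(df), p."""
    rows = []
    for grouping, per_outcome in comparisons.items():
        for outcome, gc in per_outcome.items():
            for g in gc.groups:
                est, se = gc.emmeans[g]
                rows.append(
                    {
                        "grouping": grouping,
                        "outcome": outcome,
                        "group": g,
                        "emmean": est,
                        "se": se,
                        "raw_mean": gc.raw_means.get(g, np.nan),
                        "f_stat": gc.f_stat,
                        "df1": gc.df[0],
                        "df2": gc.df[1],
                        "p_value": gc.p_value,
                        "boxcox_lambda": (
                            np.nan if gc.boxcox_lambda is None else gc.boxcox_lambda
                        ),
                        "n_used": gc.n_used,
                    }
                )
    return pd.DataFrame(rows)


def _load_records(cfg: RunConfig):
    if cfg.input_dir:
        return read_cohort_csvs(cfg.input_dir)
    if cfg.preset:
        if cfg.preset == "mood":
            preset = mood_cohort_preset(cfg.n_control, cfg.n_case)
        elif cfg.preset == "null":
            preset = null_cohort_preset(cfg.n_control)
        else:
            preset = preset_from_yaml(cfg.preset)
        return generate_cohort(preset, seed=cfg.seed)
    raise ConfigurationError("config must set either input_dir or preset")


def run_pipeline(cfg: RunConfig) -> CohortResults:
    """Execute a full run and (when ``out_dir`` is set) write all outputs:
    subject summary, exclusions report, group-comparison tables, 24-h mean
    and fitted curves (CSV and optional PNG), and a manifest sufficient to
    reproduce the run."""
    logging.basicConfig(level=getattr(logging, str(cfg.log_level).upper(), logging.INFO))
    records, metadata = _load_records(cfg)
    log.info("loaded %d subjects", len(records))
    results = analyze_cohort(records, metadata, cfg)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if cfg.write_inputs and cfg.preset:
            write_cohort_csvs(records, metadata, out / "inputs")
        results.summary.to_csv(out / "subject_summary.csv", index=False)
        results.exclusions.to_csv(out / "exclusions.csv", index=False)
        comparisons_table(results.comparisons).to_csv(
            out / "group_comparisons.csv", index=False
        )
        if results.curves is not None:
            results.curves.to_csv(out / "curves_24h.csv", index=False)
            if cfg.make_plots:
                _plot_curves(results.curves, out / "curves_24h.png")
        manifest = {
            "config": cfg.to_dict(),
            "seed": cfg.seed,
            "n_subjects_in": len(records),
            "n_subjects_analyzed": int(len(results.summary)),
            "n_excluded": int(len(results.exclusions)),
            "versions": _versions(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("outputs written to %s", out)
    return results


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "temprhythm": _pkg_version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _plot_curves(curves: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for g, gdf in curves.groupby("group"):
        axes[0].plot(gdf["t_hours"], gdf["mean_temp"], label=str(g))
        if "fitted_temp" in gdf:
            axes[1].plot(gdf["t_hours"], gdf["fitted_temp"], label=str(g))
    axes[0].set_title("Mean 24-h skin temperature")
    axes[1].set_title("Fitted cosinor curves")
    for ax in axes:
        ax.set_xlabel("Clock time (h)")
        ax.legend()
    axes[0].set_ylabel("Temperature (°C)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
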