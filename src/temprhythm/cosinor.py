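"""Single-cosinor and mixed-effects group cosinor fitting.

The 24-h rhythm model is

    Y(t) = M + A*cos(2*pi*t/24 + phi)

with mesor M, amplitude A >= 0 and acrophase phi.  The fit uses the standard
linearization Y = M + beta*cos(omega*t) + gamma*sin(omega*t) with
omega = 2*pi/period, estimated by ordinary least squares; then
A = sqrt(beta^2 + gamma^2) and phi = atan2(-gamma, beta), wrapped to
(-2*pi, 0] so that a peak after midnight carries a negative acrophase
(phi = -1.45 corresponds to a ~05:33 peak).  Acrotime converts the phase
to peak clock hours: acrotime = ((-phi) mod 2*pi) * period / (2*pi).

The group model adds group-specific cosinor parameters and a subject-level
random intercept:

    Y_ij(t) = M_g(i) + beta_g(i)*cos(omega*t) + gamma_g(i)*sin(omega*t) + u_i + e_ij

fitted by restricted maximum likelihood (statsmodels MixedLM).  Per-group
amplitude/acrophase and their contrasts are derived from (beta, gamma) with
delta-method standard errors.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, InsufficientDataError, RankDeficiencyError
from .types import CosinorFit, DailyProfile, EpochSeries, GroupCosinorModel

__all__ = [
    "fit_cosinor",
    "acrophase_to_acrotime",
    "fit_goodness",
    "fit_group_cosinor",
]

_AMP_TOL = 1e-8  # below this the phase is numerically undefined


def _wrap_acrophase(phi: float) -> float:
    """Wrap a phase into (-2*pi, 0]."""
    phi = float(np.arctan2(np.sin(phi), np.cos(phi)))  # (-pi, pi]
    if phi > 0:
        phi -= 2.0 * np.pi
    if phi <= -2.0 * np.pi + 1e-9:  # snap the -2*pi ~ 0 boundary to 0
        phi += 2.0 * np.pi
    return phi


def acrophase_to_acrotime(phi: float, period_h: float = 24.0) -> float:
    """Convert an acrophase (radians) to peak clock time in hours [0, period).

    NaN (undefined phase at zero amplitude) propagates.
    """
    if not np.isfinite(phi):
        return float("nan")
    return float((((-phi) % (2.0 * np.pi)) * period_h / (2.0 * np.pi)) % period_h)


def _design(t: np.ndarray, period_h: float) -> np.ndarray:
    omega = 2.0 * np.pi / period_h
    return np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])


def _fit_ty(t: np.ndarray, y: np.ndarray, period_h: float, n_days: int) -> CosinorFit:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("t and y must have equal length")
    if len(np.unique(np.mod(t, period_h))) < 3:
        raise RankDeficiencyError(
            "cosinor fit needs >= 3 distinct sampling times within the period"
        )
    X = _design(t, period_h)
    if np.linalg.matrix_rank(X) < 3:
        raise RankDeficiencyError("degenerate sampling times: design matrix is singular")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = coef
    amplitude = float(np.hypot(beta, gamma))
    if amplitude < _AMP_TOL:
        amplitude = max(amplitude, 0.0)
        acrophase = float("nan")
    else:
        acrophase = _wrap_acrophase(np.arctan2(-gamma, beta))
    resid = y - X @ coef
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    return CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase=acrophase,
        acrotime=acrophase_to_acrotime(acrophase, period_h),
        r2=r2,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        n_days=n_days,
        period_h=period_h,
    )


def fit_cosinor(
    data: Union[EpochSeries, DailyProfile, tuple],
    period_h: float = 24.0,
) -> CosinorFit:
    """Least-squares cosinor fit of a series, a folded profile, or ``(t, y)``.

    For an :class:`EpochSeries`, time is hours since the first day's
    midnight (clock-anchored, so the acrophase is a clock phase).  For a
    :class:`DailyProfile`, bin centers are used as sampling times.  A
    constant signal yields amplitude 0 with the acrophase flagged undefined
    (NaN).
    """
    if isinstance(data, EpochSeries):
        if len(data) == 0:
            raise InsufficientDataError("empty series")
        t = data.hours_since_start_midnight
        n_days = int(len(np.unique(data.day_index)))
        return _fit_ty(t, data.values, period_h, n_days)
    if isinstance(data, DailyProfile):
        n_days = int(np.max(data.n_days_contributing, initial=0))
        return _fit_ty(data.bin_center_hours, data.mean_value, period_h, n_days)
    t, y = data
    t = np.asarray(t, dtype=float)
    n_days = max(1, int(np.ceil((t.max() - t.min()) / period_h))) if len(t) else 0
    return _fit_ty(t, y, period_h, n_days)


def fit_goodness(
    fit: CosinorFit, data: Union[EpochSeries, DailyProfile, tuple]
) -> tuple[float, float, float]:
    """Goodness of fit (R^2, RMSE, MAE) of a cosinor fit against data.

    R^2 = 1 - SSres/SStot on the given observations; NaN for a
    zero-variance series.  Units of RMSE/MAE follow the data (°C for
    temperature).
    """
    if isinstance(data, EpochSeries):
        t, y = data.hours_since_start_midnight, data.values
    elif isinstance(data, DailyProfile):
        t, y = data.bin_center_hours, data.mean_value
    else:
        t, y = np.asarray(data[0], float), np.asarray(data[1], float)
    pred = fit.predict(t)
    resid = y - pred
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    return r2, float(np.sqrt(np.mean(resid**2))), float(np.mean(np.abs(resid)))


# ---------------------------------------------------------------------------
# Mixed-effects group cosinor
# ---------------------------------------------------------------------------

def _derived_with_se(beta, gamma, cov_bg):
    """Amplitude and acrophase with delta-method SEs from (beta, gamma)."""
    A = float(np.hypot(beta, gamma))
    if A < _AMP_TOL:
        return A, float("nan"), float("nan"), float("nan")
    gA = np.array([beta / A, gamma / A])
    se_A = float(np.sqrt(gA @ cov_bg @ gA))
    phi = _wrap_acrophase(np.arctan2(-gamma, beta))
    gphi = np.array([gamma / A**2, -beta / A**2])
    se_phi = float(np.sqrt(gphi @ cov_bg @ gphi))
    return A, se_A, phi, se_phi


def fit_group_cosinor(
    frame: pd.DataFrame,
    period_h: float = 24.0,
    value_col: str = "value",
    time_col: str = "t_hours",
    group_col: str = "group",
    subject_col: str = "subject_id",
) -> GroupCosinorModel:
    """Mixed-effects cosinor with group-specific (M, A, phi).

    ``frame`` is a tidy table with one row per observation carrying the
    subject id, group label, time in hours and the measured value.  Fits a
    subject random intercept; per-group parameters reduce to pooled
    single-group cosinor fits when the random-effect variance is zero.
    Requires >= 2 groups with >= 2 subjects each.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    labels = sorted(frame[group_col].unique().tolist())
    if len(labels) < 2:
        raise InsufficientDataError("group cosinor needs >= 2 groups")
    for g in labels:
        if frame.loc[frame[group_col] == g, subject_col].nunique() < 2:
            raise InsufficientDataError(f"group '{g}' needs >= 2 subjects")

    omega = 2.0 * np.pi / period_h
    t = frame[time_col].to_numpy(float)
    y = frame[value_col].to_numpy(float)
    cos_t, sin_t = np.cos(omega * t), np.sin(omega * t)
    cols, names = [], []
    for g in labels:
        ind = (frame[group_col] == g).to_numpy().astype(float)
        cols += [ind, ind * cos_t, ind * sin_t]
        names += [f"{g}:mesor", f"{g}:cos", f"{g}:sin"]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("singular group cosinor design")

    # L-BFGS is fastest but degenerates when the random-effect variance hits
    # the zero boundary (infinite llf, fixed effects collapse); fall back.
    import warnings

    res = None
    last_exc: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            model = MixedLM(y, X, groups=frame[subject_col].to_numpy())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            continue
        if np.isfinite(cand.llf) and np.all(np.isfinite(cand.fe_params)):
            res = cand
            break
    if res is None:
        raise ConvergenceError(f"mixed cosinor fit failed: {last_exc}")

    fe = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(fe), : len(fe)]
    groups_out: dict = {}
    for i, g in enumerate(labels):
        j = 3 * i
        M, beta, gamma = fe[j], fe[j + 1], fe[j + 2]
        cov_bg = cov[j + 1 : j + 3, j + 1 : j + 3]
        A, se_A, phi, se_phi = _derived_with_se(beta, gamma, cov_bg)
        groups_out[g] = {
            "mesor": float(M),
            "se_mesor": float(np.sqrt(cov[j, j])),
            "amplitude": A,
            "se_amplitude": se_A,
            "acrophase": phi,
            "se_acrophase": se_phi,
            "acrotime": acrophase_to_acrotime(phi, period_h),
            "beta": float(beta),
            "gamma": float(gamma),
        }

    contrasts: dict = {}
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            a, b = labels[a_i], labels[b_i]
            ja, jb = 3 * a_i, 3 * b_i
            d_mesor = fe[jb] - fe[ja]
            se_mesor = float(
                np.sqrt(cov[ja, ja] + cov[jb, jb] - 2 * cov[ja, jb])
            )
            # delta method on (beta_a, gamma_a, beta_b, gamma_b)
            idx = [ja + 1, ja + 2, jb + 1, jb + 2]
            sub = cov[np.ix_(idx, idx)]
            ba, ga_ = fe[ja + 1], fe[ja + 2]
            bb, gb = fe[jb + 1], fe[jb + 2]
            Aa, Ab = np.hypot(ba, ga_), np.hypot(bb, gb)
            if min(Aa, Ab) < _AMP_TOL:
                d_amp = float(Ab - Aa)
                se_amp = float("nan")
                d_phi = float("nan")
                se_phi = float("nan")
            else:
                gvecA = np.array([-ba / Aa, -ga_ / Aa, bb / Ab, gb / Ab])
                d_amp = float(Ab - Aa)
                se_amp = float(np.sqrt(gvecA @ sub @ gvecA))
                phi_a = np.arctan2(-ga_, ba)
                phi_b = np.arctan2(-gb, bb)
                d_phi = float(np.arctan2(np.sin(phi_b - phi_a), np.cos(phi_b - phi_a)))
                gvecP = np.array(
                    [-ga_ / Aa**2, ba / Aa**2, gb / Ab**2, -bb / Ab**2]
                )
                se_phi = float(np.sqrt(gvecP @ sub @ gvecP))
            contrasts[(a, b)] = {
                "d_mesor": float(d_mesor),
                "se_mesor": se_mesor,
                "d_amplitude": d_amp,
                "se_amplitude": se_amp,
                "d_acrophase": d_phi,
                "se_acrophase": se_phi,
            }

    # goodness of fit including subject random intercepts (zero when the
    # random-effect covariance collapses to the boundary)
    try:
        re_map = {
            k: float(np.asarray(v).ravel()[0]) for k, v in res.random_effects.items()
        }
        re_vec = frame[subject_col].map(re_map).to_numpy(float)
    except (ValueError, np.linalg.LinAlgError):
        re_vec = np.zeros(len(frame))
    fitted = X @ fe + re_vec
    resid = y - fitted
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    return GroupCosinorModel(
        groups=groups_out,
        contrasts=contrasts,
        random_intercept_var=float(np.asarray(res.cov_re).ravel()[0]),
        r2=r2,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        n_subjects=int(frame[subject_col].nunique()),
        n_obs=int(len(frame)),
        converged=bool(getattr(res, "converged", True)),
    )
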