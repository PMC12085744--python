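"""Group-level inference: ANCOVA with covariates, Box-Cox, Bland-Altman.

Each wearable-derived metric is compared between groups with an analysis of
covariance (linear model ``outcome ~ group + age + sex``), reporting the
F test for the group factor, estimated marginal means (predictive margins
at the observed covariate distribution) with standard errors, and
Bonferroni-adjusted pairwise post hoc contrasts.  Outcomes whose model
residuals fail a Shapiro-Wilk normality screen are Box-Cox transformed
(maximum-likelihood lambda) before the ANCOVA; the transform is monotone,
so contrast directions are preserved.

Bland-Altman agreement between two paired device series reports the mean
paired difference (bias) and the 95% limits of agreement bias +/- 1.96*SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import InsufficientDataError, PairingError, RankDeficiencyError
from .types import AgreementResult, GroupComparison

__all__ = [
    "BoxCoxResult",
    "boxcox_transform",
    "ancova_compare",
    "bland_altman",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_test",
]


@dataclass
class BoxCoxResult:
    """Box-Cox transform output; ``skipped`` marks degenerate (constant) input."""

    values: np.ndarray
    lam: Optional[float]
    shift: float
    skipped: bool


def boxcox_transform(x: Union[np.ndarray, Sequence[float]]) -> BoxCoxResult:
    """Maximum-likelihood Box-Cox transform, shifting non-positive data.

    y = (x^lam - 1)/lam (log x at lam = 0).  When any x <= 0 a positive
    shift is applied first and recorded in the result.  Constant input is
    returned untransformed with ``skipped=True``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.allclose(x, x[0]):
        return BoxCoxResult(values=x.copy(), lam=None, shift=0.0, skipped=True)
    shift = 0.0
    xmin = x.min()
    if xmin <= 0:
        rng_ = x.max() - xmin
        shift = -xmin + 1e-3 * (rng_ if rng_ > 0 else 1.0)
    y, lam = scipy.stats.boxcox(x + shift)
    return BoxCoxResult(values=y, lam=float(lam), shift=float(shift), skipped=False)


def _is_categorical(s: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(s)


def ancova_compare(
    table: pd.DataFrame,
    outcome: str,
    group: str = "cohort",
    covariates: Sequence[str] = ("age", "sex"),
    boxcox: Union[bool, str] = "auto",
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Covariate-adjusted comparison of one outcome between groups.

    ``boxcox`` may be True (always transform), False (never), or ``"auto"``
    (transform when the Shapiro-Wilk test on model residuals rejects at
    ``alpha_normality``).  Estimated marginal means are predictive margins:
    every subject's covariates with the group set counterfactually, averaged.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from patsy import build_design_matrices

    cols = [outcome, group, *covariates]
    df = table[cols].dropna().copy()
    df = df[df[group].astype(str) != ""]
    labels = sorted(df[group].astype(str).unique().tolist())
    if len(labels) < 2:
        raise InsufficientDataError(f"'{outcome}': need >= 2 groups")
    sizes = df.groupby(df[group].astype(str))[outcome].count()
    if (sizes < 3).any():
        raise InsufficientDataError(
            f"'{outcome}': every group needs >= 3 subjects (have {dict(sizes)})"
        )

    df["_y"] = df[outcome].astype(float)
    df["_g"] = df[group].astype(str)
    terms = ["C(_g)"]
    for c in covariates:
        terms.append(f"C(Q('{c}'))" if _is_categorical(df[c]) else f"Q('{c}')")
    formula = "_y ~ " + " + ".join(terms)

    def _fit(frame):
        model = smf.ols(formula, data=frame)
        if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
            raise RankDeficiencyError(
                f"collinear ANCOVA design for '{outcome}': columns "
                f"{list(model.exog_names)}"
            )
        return model.fit()

    res = _fit(df)
    lam: Optional[float] = None
    shift = 0.0
    if boxcox is True or (
        boxcox == "auto"
        and len(res.resid) >= 3
        and np.ptp(res.resid) > 0
        and scipy.stats.shapiro(res.resid)[1] < alpha_normality
    ):
        bc = boxcox_transform(df["_y"].to_numpy())
        if not bc.skipped:
            df["_y"] = bc.values
            lam, shift = bc.lam, bc.shift
            res = _fit(df)

    aov = sm.stats.anova_lm(res, typ=2)
    grow = aov.loc["C(_g)"]
    f_stat = float(grow["F"])
    p_value = float(grow["PR(>F)"])
    df_num = int(grow["df"])
    df_den = int(aov.loc["Residual", "df"])

    design_info = res.model.data.design_info
    params = res.params.to_numpy()
    cov = res.cov_params().to_numpy()
    L = {}
    for g in labels:
        cf = df.copy()
        cf["_g"] = g
        (X,) = build_design_matrices([design_info], cf)
        L[g] = np.asarray(X).mean(axis=0)
    emmeans = {}
    for g in labels:
        est = float(L[g] @ params)
        se = float(np.sqrt(L[g] @ cov @ L[g]))
        emmeans[g] = (est, se)

    raw_means = df.groupby("_g")[outcome].mean().astype(float).to_dict()

    pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    m = len(pairs)
    posthoc, posthoc_raw = {}, {}
    for a, b in pairs:
        c = L[b] - L[a]
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        tval = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2 * scipy.stats.t.sf(abs(tval), df_den))
        posthoc_raw[(a, b)] = p
        posthoc[(a, b)] = min(1.0, m * p)

    return GroupComparison(
        outcome=outcome,
        groups=labels,
        f_stat=f_stat,
        df=(df_num, df_den),
        p_value=p_value,
        emmeans=emmeans,
        raw_means=raw_means,
        posthoc=posthoc,
        posthoc_unadjusted=posthoc_raw,
        boxcox_lambda=lam,
        boxcox_shift=shift,
        n_used=int(len(df)),
    )


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement of two simultaneous paired series.

    Differences d = a - b; bias = mean(d); limits of agreement
    bias +/- 1.96*SD(d).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise PairingError(f"paired series differ in shape: {a.shape} vs {b.shape}")
    if len(a) == 0:
        raise InsufficientDataError("empty paired series")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return AgreementResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        sd_diff=sd, n=len(d),
    )


# ---------------------------------------------------------------------------
# Demographic pass-throughs (routine tests, delegated to scipy)
# ---------------------------------------------------------------------------

def mann_whitney(x, y):
    """Mann-Whitney U test (two-sided); returns (U, p)."""
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*samples):
    """Kruskal-Wallis rank sum test; returns (H, p)."""
    res = scipy.stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def dunn_test(samples: dict) -> dict:
    """Dunn's post hoc pairwise z tests on pooled ranks, Bonferroni-adjusted.

    ``samples`` maps group label -> 1-D array.  Returns
    {(a, b): adjusted p}.  Provided as a demographics convenience.
    """
    labels = sorted(samples)
    pooled = np.concatenate([np.asarray(samples[k], float) for k in labels])
    ranks = scipy.stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank, start = {}, 0
    for k in labels:
        n_k = len(samples[k])
        mean_rank[k] = ranks[start : start + n_k].mean()
        start += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt(var_base * (1.0 / len(samples[a]) + 1.0 / len(samples[b])))
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2 * scipy.stats.norm.sf(abs(z))
            out[(a, b)] = min(1.0, m * p)
    return out
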