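"""Evaluation metrics, bootstrap uncertainty and mixed-effects slope analysis.

The ordering task is scored with the tie-aware rank AUC and a percentile
bootstrap CI (1,000 resamples of the test set with replacement); resamples
missing a class are redrawn.  Regression tasks report RMSE/MAE/R^2 against
a naive baseline that always predicts zero change (the target mean for
symmetrically oriented pairs), plus the Pearson correlation on
chronologically ordered pairs.

Subject-level trends are analysed with a no-intercept linear mixed-effects
model on changes anchored at each subject's first timepoint (where the
change is identically zero, hence no intercept):

    change_ij = (beta + gamma * group_i + b_i) * t_ij + eps_ij,
    b_i ~ N(0, sigma_b^2)

fitted by maximum likelihood.  Individual variability is tested by a
likelihood-ratio test against the model without the random slope, using the
0.5*chi2_0 + 0.5*chi2_1 boundary mixture for the null; the group effect by
an LRT against the model without the group term (chi2_1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvalReport",
    "RegressionMetrics",
    "LMEResult",
    "auc",
    "bootstrap_auc_ci",
    "regression_metrics",
    "naive_zero_metrics",
    "pearson",
    "evaluate_ordering",
    "evaluate_regression",
    "lme_fit",
    "format_pvalue",
]


@dataclass
class RegressionMetrics:
    rmse: float
    mae: float
    r2: float


@dataclass
class EvalReport:
    """Task metrics next to the matching naive baseline."""

    task: str
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    naive_auc: float | None = None
    rmse: float | None = None
    mae: float | None = None
    r2: float | None = None
    naive_rmse: float | None = None
    naive_mae: float | None = None
    pcc: float | None = None
    pcc_p: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        d = {"task": self.task, "n": self.n}
        for k in ("auc", "naive_auc", "rmse", "mae", "r2",
                  "naive_rmse", "naive_mae", "pcc", "pcc_p"):
            v = getattr(self, k)
            if v is not None:
                d[k] = float(v)
        if self.auc_ci is not None:
            d["auc_ci"] = [float(self.auc_ci[0]), float(self.auc_ci[1])]
        return d


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Tie-aware rank AUC (Mann-Whitney with half-credit for tied scores)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes to be present")
    scores = np.asarray(scores, float)
    if np.ptp(scores) == 0:
        return 0.5  # constant scorer: every positive-negative pair ties
    return float(roc_auc_score(labels, scores))


def bootstrap_auc_ci(labels: np.ndarray, scores: np.ndarray,
                     n_boot: int = 1000, level: float = 0.95,
                     seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC (test set resampled with
    replacement; single-class resamples are redrawn)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes to be present")
    rng = np.random.default_rng(seed)
    n = len(labels)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if len(np.unique(labels[idx])) == 2:
                break
        vals[b] = auc(labels[idx], scores[idx])
    alpha = (1 - level) / 2
    return (float(np.quantile(vals, alpha)), float(np.quantile(vals, 1 - alpha)))


def regression_metrics(y: np.ndarray, y_hat: np.ndarray) -> RegressionMetrics:
    """RMSE, MAE and R^2 (relative to the mean of y)."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if y.size < 2:
        raise ValueError("R^2 requires at least two observations")
    err = y - y_hat
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    ss_res = float(np.sum(err ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return RegressionMetrics(rmse, mae, r2)


def naive_zero_metrics(y: np.ndarray) -> RegressionMetrics:
    """Baseline that always predicts zero change."""
    return regression_metrics(np.asarray(y, float), np.zeros(len(y)))


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided t-distribution p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def format_pvalue(p: float, floor: float = 1e-16) -> str:
    """Report tiny p-values as '<1e-16' rather than a noise-level float."""
    return f"<{floor:g}" if p < floor else f"{p:.3g}"


def evaluate_ordering(labels: np.ndarray, logits: np.ndarray,
                      n_boot: int = 1000, seed: int = 0) -> EvalReport:
    point = auc(labels, logits)
    ci = bootstrap_auc_ci(labels, logits, n_boot=n_boot, seed=seed)
    return EvalReport(task="ordering", auc=point, auc_ci=ci, naive_auc=0.5,
                      n=len(labels))


def evaluate_regression(y: np.ndarray, y_hat: np.ndarray) -> EvalReport:
    m = regression_metrics(y, y_hat)
    nv = naive_zero_metrics(y)
    report = EvalReport(task="regression", rmse=m.rmse, mae=m.mae, r2=m.r2,
                        naive_rmse=nv.rmse, naive_mae=nv.mae, n=len(y))
    return report


@dataclass
class LMEResult:
    """No-intercept random-slope mixed-model fit."""

    fixed_slope: float
    fixed_slope_se: float
    group_effect: float | None
    group_effect_se: float | None
    random_slope_var: float
    resid_var: float
    lrt_random_stat: float
    lrt_random_p: float
    lrt_group_stat: float | None
    lrt_group_p: float | None
    converged: bool
    n_subjects: int
    n_obs: int

    def summary(self) -> str:
        lines = [
            "Mixed-effects slope analysis (no intercept, ML)",
            "-" * 47,
            f"subjects / observations: {self.n_subjects} / {self.n_obs}",
            f"fixed slope beta:        {self.fixed_slope:.4f} "
            f"(SE {self.fixed_slope_se:.4f})",
            f"random slope variance:   {self.random_slope_var:.4f}",
            f"LRT random slope:        stat={self.lrt_random_stat:.2f}, "
            f"p={format_pvalue(self.lrt_random_p)}",
        ]
        if self.group_effect is not None:
            lines += [
                f"group x time effect:     {self.group_effect:.4f} "
                f"(SE {self.group_effect_se:.4f})",
                f"LRT group effect:        stat={self.lrt_group_stat:.2f}, "
                f"p={format_pvalue(self.lrt_group_p)}",
            ]
        if not self.converged:
            lines.append("WARNING: optimizer did not fully converge")
        return "\n".join(lines)


def _mixedlm_fit(df: pd.DataFrame, exog_cols: list[str]):
    import statsmodels.api as sm

    endog = df["change"].to_numpy()
    exog = df[exog_cols].to_numpy()
    exog_re = df[["time"]].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=df["subject"], exog_re=exog_re)
        try:
            fit = model.fit(reml=False)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=False, method="powell")
    return fit


def lme_fit(df: pd.DataFrame, group: bool = False) -> LMEResult:
    """Fit the anchored-change mixed model by maximum likelihood.

    ``df`` needs columns ``subject``, ``time`` (time from the subject's
    first scan, > 0) and ``change`` (predicted change from the first scan);
    with ``group=True`` also a per-subject 0/1 ``group`` column.  The group
    term enters as group x time so every fitted line passes through the
    origin.
    """
    import statsmodels.api as sm

    required = {"subject", "time", "change"} | ({"group"} if group else set())
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"LME table is missing columns: {sorted(missing)}")
    if df["subject"].nunique() < 3:
        raise ValueError("mixed-model analysis needs at least 3 subjects")
    df = df.copy()
    if group:
        df["group_time"] = df["group"].astype(float) * df["time"]
        exog_cols = ["time", "group_time"]
    else:
        exog_cols = ["time"]

    full = _mixedlm_fit(df, exog_cols)
    ll_full = float(full.llf)

    # reduced model without the random slope: plain no-intercept OLS (ML)
    ols = sm.OLS(df["change"].to_numpy(), df[exog_cols].to_numpy()).fit()
    lrt_re = max(0.0, 2.0 * (ll_full - float(ols.llf)))
    # variance tested on its boundary: 0.5*chi2_0 + 0.5*chi2_1 mixture
    lrt_re_p = 0.5 * float(sps.chi2.sf(lrt_re, 1)) + (0.5 if lrt_re <= 0 else 0.0)

    lrt_g = lrt_g_p = None
    group_eff = group_se = None
    if group:
        reduced = _mixedlm_fit(df, ["time"])
        lrt_g = max(0.0, 2.0 * (ll_full - float(reduced.llf)))
        lrt_g_p = float(sps.chi2.sf(lrt_g, 1))
        group_eff = float(full.fe_params[1])
        group_se = float(full.bse_fe[1])

    return LMEResult(
        fixed_slope=float(full.fe_params[0]),
        fixed_slope_se=float(full.bse_fe[0]),
        group_effect=group_eff, group_effect_se=group_se,
        random_slope_var=float(np.asarray(full.cov_re)[0, 0]),
        resid_var=float(full.scale),
        lrt_random_stat=lrt_re, lrt_random_p=lrt_re_p,
        lrt_group_stat=lrt_g, lrt_group_p=lrt_g_p,
        converged=bool(full.converged),
        n_subjects=int(df["subject"].nunique()), n_obs=len(df))
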