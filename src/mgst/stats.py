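"""Statistical layer: correlations with neuropsychological scores and the
multiple regression of the late-error rate.

Spearman (default) or Pearson correlations are computed pairwise-complete
between subject oculomotor summaries and the covariate table, with raw
p-values at alpha = 0.05 (no multiplicity correction by default; a
Benjamini-Hochberg switch is available).  The regression models
%LateErrorRate on age, gender (0 = female, 1 = male), MoCA total, HADS-A,
HADS-D, and the two first Color-Trails outcomes by OLS with listwise
deletion, reporting coefficients, F on (k, n-k-1) df, R^2, per-predictor
VIF, and assumption diagnostics (Breusch-Pagan, Jarque-Bera,
Durbin-Watson, and a residual-vs-fitted linearity check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson, jarque_bera
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrelationResult", "RegressionResult", "correlate_all",
           "fit_late_error_regression", "vif", "DEFAULT_PREDICTORS"]

DEFAULT_PREDICTORS = ("age", "gender", "MOTS-1", "HDTSA-1", "HDTSD-1",
                      "CLRES01-1", "CLRES02-1")


@dataclass(frozen=True)
class CorrelationResult:
    covariate: str
    metric: str
    method: str
    coefficient: float
    p_value: float
    n: int
    significant: bool


def _encode_gender(series: pd.Series) -> pd.Series:
    """0 = female, 1 = male (a positive coefficient means a higher male rate)."""
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        mapped = series.astype(str).str.lower().map({"female": 0.0, "male": 1.0})
        if mapped.isna().any() and series.notna().any():
            bad = series[mapped.isna() & series.notna()].unique()
            raise ValueError(f"unrecognised gender labels: {bad}")
        return mapped
    return series.astype(float)


def correlate_all(summaries: pd.DataFrame, covariates: pd.DataFrame,
                  method: str = "spearman",
                  metrics: list[str] | None = None,
                  covariate_names: list[str] | None = None,
                  alpha: float = 0.05, fdr: bool = False) -> pd.DataFrame:
    """Correlate every (covariate, oculomotor metric) pair.

    Tables are joined on ``subject_id``; pairwise-complete observations are
    used per pair and pairs with fewer than 3 complete observations are
    omitted with a warning.  Returns a tidy frame (covariate, metric,
    method, coefficient, p_value, n, significant); with ``fdr=True``
    significance is assessed on Benjamini-Hochberg adjusted p-values,
    reported in ``p_adjusted``.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    df = covariates.merge(summaries, on="subject_id", how="inner")
    if covariate_names is None:
        covariate_names = [c for c in covariates.columns if c != "subject_id"]
    if metrics is None:
        metrics = [c for c in summaries.columns
                   if c != "subject_id" and pd.api.types.is_numeric_dtype(summaries[c])]
    rows = []
    for cov in covariate_names:
        x_all = _encode_gender(df[cov]) if cov == "gender" else df[cov].astype(float)
        for met in metrics:
            y_all = df[met].astype(float)
            mask = x_all.notna() & y_all.notna()
            n = int(mask.sum())
            if n < 3:
                warnings.warn(f"pair ({cov}, {met}): fewer than 3 complete observations; omitted")
                continue
            x, y = x_all[mask].to_numpy(), y_all[mask].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue  # degenerate: constant column
            if method == "spearman":
                r, p = _stats.spearmanr(x, y)
            else:
                r, p = _stats.pearsonr(x, y)
            rows.append({"covariate": cov, "metric": met, "method": method,
                         "coefficient": float(r), "p_value": float(p), "n": n})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if fdr:
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_j) per predictor.

    ``design`` holds predictor columns only (no constant).  Perfect
    collinearity yields inf for the involved predictors.
    """
    X = design.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


@dataclass
class RegressionResult:
    """OLS fit of an oculomotor rate on subject covariates."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    df1: int
    df2: int
    f_pvalue: float
    rsquared: float
    vif: pd.Series
    diagnostics: dict
    n: int
    dependent: str
    residuals: np.ndarray
    fitted: np.ndarray

    def to_table(self) -> pd.DataFrame:
        """Coefficient table: Predictor, B, SE, t, p."""
        return pd.DataFrame({
            "Predictor": self.params.index,
            "B": self.params.to_numpy(),
            "SE": self.bse.to_numpy(),
            "t": self.tvalues.to_numpy(),
            "p": self.pvalues.to_numpy(),
        })


def _name_rank_deficient(X: pd.DataFrame) -> str:
    full = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy(float)]))
    for col in X.columns:
        sub = X.drop(columns=[col])
        r = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), sub.to_numpy(float)]))
        if r == full:
            return col
    return X.columns[-1]


def fit_late_error_regression(data: pd.DataFrame,
                              dependent: str = "%LateErrorRate",
                              predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
                              alpha: float = 0.05) -> RegressionResult:
    """OLS of the dependent rate on the covariate predictors.

    ``data`` is the merged subject table (covariates + summary).  Listwise
    deletion is applied; gender strings are coded 0 = female, 1 = male.
    Requires n > k + 1 complete cases; a rank-deficient design is rejected
    with the offending predictor named.
    """
    cols = list(predictors) + [dependent]
    df = data[cols].copy()
    if "gender" in df.columns:
        df["gender"] = _encode_gender(df["gender"])
    df = df.dropna()
    n = len(df)
    k = len(predictors)
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} complete cases, got {n}")
    X = df[list(predictors)].astype(float)
    y = df[dependent].astype(float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()])) < k + 1:
        raise ValueError(f"design is rank deficient: predictor {_name_rank_deficient(X)!r} "
                         "is collinear with the others")

    model = sm.OLS(y, sm.add_constant(X)).fit()
    resid = np.asarray(model.resid)
    exog = np.asarray(sm.add_constant(X))

    bp_stat, bp_p, *_ = het_breuschpagan(resid, exog)
    jb_stat, jb_p, *_ = jarque_bera(resid)
    dw = float(durbin_watson(resid))
    # linearity heuristic: residuals should not track the square of the fit
    fitted = np.asarray(model.fittedvalues)
    if np.std(fitted) > 0:
        lin_r, lin_p = _stats.pearsonr(resid, (fitted - fitted.mean()) ** 2)
    else:
        lin_r, lin_p = 0.0, 1.0
    diagnostics = {
        "breusch_pagan_p": float(bp_p),
        "jarque_bera_p": float(jb_p),
        "durbin_watson": dw,
        "linearity_p": float(lin_p),
        "homoscedastic": bool(bp_p >= alpha),
        "residuals_normal": bool(jb_p >= alpha),
        "independent": bool(1.5 <= dw <= 2.5),
        "linear": bool(lin_p >= alpha),
    }
    return RegressionResult(
        params=model.params, bse=model.bse, tvalues=model.tvalues, pvalues=model.pvalues,
        fvalue=float(model.fvalue), df1=int(model.df_model), df2=int(model.df_resid),
        f_pvalue=float(model.f_pvalue), rsquared=float(model.rsquared),
        vif=vif(X), diagnostics=diagnostics, n=n, dependent=dependent,
        residuals=resid, fitted=fitted,
    )
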