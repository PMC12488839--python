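"""Inferential layer: outlier filtering, transformation, linear mixed
models with Satterthwaite effect sizes, Holm-corrected post-hocs, and
Pearson correlations.

The mixed model is ``response ~ condition * sex`` with a random intercept
per participant, fit by REML through statsmodels' ``MixedLM`` (an
established routine; re-implementing REML is a non-goal).  statsmodels does
not expose Satterthwaite denominator degrees of freedom, so they are
computed here from the fitted variance components: the REML profile
log-likelihood of the random-intercept model is written in closed form,
its numerical Hessian gives the covariance of the variance estimates, and
the delta method yields per-contrast dfs, combined across multi-df terms
as in lmerTest.  Effect sizes are partial eta squared
``η²p = F·df1 / (F·df1 + df2)`` and Cohen's ``f = sqrt(η²p / (1 - η²p))``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_filter",
    "prepare_mu_table",
    "holm_adjust",
    "cohens_f_from_eta_sq",
    "eta_sq_from_cohens_f",
    "LMMReport",
    "fit_lmm",
    "correlate",
    "corr_matrix",
]


def zscore_filter(values, z_max: float = 2.5) -> np.ndarray:
    """Boolean keep-mask: drop values with |z| > z_max (single pass).

    Zero-variance input keeps everything.  NaNs are kept (they carry their
    own missingness downstream).
    """
    x = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(x)) < 3:
        raise ValueError("need at least 3 finite values")
    m = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    if sd == 0:
        return np.ones_like(x, dtype=bool)
    keep = np.abs((x - m) / sd) <= z_max
    keep |= ~np.isfinite(x)
    return keep


def prepare_mu_table(df: pd.DataFrame, z_max: float = 2.5) -> pd.DataFrame:
    """Flag IDR outliers (|z| > z_max, computed over all MU observations)
    and add the natural-log transform of the kept IDR values.

    Returns a copy with ``idr_kept`` (bool) and ``log_idr`` (NaN where
    filtered or missing) columns; CV is left untouched.
    """
    out = df.copy()
    keep = zscore_filter(out["idr"].to_numpy(), z_max=z_max)
    out["idr_kept"] = keep
    with np.errstate(invalid="ignore", divide="ignore"):
        log_idr = np.log(out["idr"].to_numpy())
    log_idr[~keep] = np.nan
    out["log_idr"] = log_idr
    return out


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * p[idx]
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj


def cohens_f_from_eta_sq(eta_sq: float) -> float:
    """Cohen's f from partial eta squared: f = sqrt(η²p / (1 - η²p))."""
    if not (0 <= eta_sq < 1):
        raise ValueError("eta squared must be in [0, 1)")
    return float(np.sqrt(eta_sq / (1.0 - eta_sq)))


def eta_sq_from_cohens_f(f: float) -> float:
    """Inverse conversion: η²p = f² / (1 + f²)."""
    if f < 0:
        raise ValueError("f must be >= 0")
    return float(f**2 / (1.0 + f**2))


# ---------------------------------------------------------------------------
# Linear mixed model with Satterthwaite dfs
# ---------------------------------------------------------------------------


@dataclass
class LMMReport:
    """Summary of one REML mixed-model fit."""

    response: str
    terms: pd.DataFrame  # term, F, df1, df2, p, eta_sq_p, cohens_f
    contrasts: pd.DataFrame  # pairwise condition contrasts, Holm-adjusted
    sigma2_subject: float
    sigma2_resid: float
    random_effect_p: float
    r2_marginal: float
    r2_conditional: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    singular: bool = False
    extra: dict = field(default_factory=dict)


class _RandomInterceptREML:
    """Closed-form REML machinery for y = Xb + (subject intercept) + e."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X, self.y = X, y
        self.group_idx = [np.flatnonzero(groups == g) for g in pd.unique(groups)]

    def _per_group(self, theta):
        s2b, s2e = max(theta[0], 1e-12), max(theta[1], 1e-12)
        XtVX = np.zeros((self.X.shape[1], self.X.shape[1]))
        XtVy = np.zeros(self.X.shape[1])
        ytVy = 0.0
        logdet = 0.0
        for idx in self.group_idx:
            Xi, yi = self.X[idx], self.y[idx]
            ni = idx.size
            c = s2b / (s2e + ni * s2b)
            sx = Xi.sum(axis=0)
            sy = yi.sum()
            XtVX += (Xi.T @ Xi - c * np.outer(sx, sx)) / s2e
            XtVy += (Xi.T @ yi - c * sx * sy) / s2e
            ytVy += (yi @ yi - c * sy * sy) / s2e
            logdet += (ni - 1) * np.log(s2e) + np.log(s2e + ni * s2b)
        return XtVX, XtVy, ytVy, logdet

    def cov_beta(self, theta) -> np.ndarray:
        XtVX, _, _, _ = self._per_group(theta)
        return np.linalg.pinv(XtVX)

    def loglik(self, theta) -> float:
        """REML log-likelihood up to an additive constant."""
        XtVX, XtVy, ytVy, logdet = self._per_group(theta)
        beta = np.linalg.solve(XtVX, XtVy)
        ypy = ytVy - XtVy @ beta
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        return -0.5 * (logdet + logdet_xvx + ypy)

    def theta_cov(self, theta) -> np.ndarray:
        """Covariance of the variance-component estimates: inverse of the
        numerical Hessian of the negative REML log-likelihood."""
        theta = np.asarray(theta, dtype=float)
        h = 1e-4 * (theta + 1e-3 * theta[1])
        H = np.zeros((2, 2))
        f0 = self.loglik(theta)
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                if i == j:
                    H[i, i] = (
                        self.loglik(theta + ei) - 2 * f0 + self.loglik(theta - ei)
                    ) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        self.loglik(theta + ei + ej)
                        - self.loglik(theta + ei - ej)
                        - self.loglik(theta - ei + ej)
                        + self.loglik(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(-H)

    def satterthwaite_df(self, ell: np.ndarray, theta, theta_cov) -> float:
        """df = 2 v² / (∇v' A ∇v) with v = l' C(θ) l (delta method)."""
        theta = np.asarray(theta, dtype=float)

        def v(th):
            return float(ell @ self.cov_beta(th) @ ell)

        h = 1e-5 * (theta + 1e-3 * theta[1])
        grad = np.zeros(2)
        for i in range(2):
            ei = np.eye(2)[i] * h[i]
            grad[i] = (v(theta + ei) - v(np.maximum(theta - ei, 1e-14))) / (
                (theta[i] + ei[i]) - max(theta[i] - ei[i], 1e-14)
            )
        denom = float(grad @ theta_cov @ grad)
        v0 = v(theta)
        if denom <= 0 or not np.isfinite(denom):
            return np.inf
        return 2 * v0**2 / denom


def _term_f_test(reml, beta, cov_beta, L, theta, theta_cov, resid_df):
    """F statistic and Satterthwaite denominator df for contrast matrix L,
    combined over eigen-directions as in lmerTest."""
    q = L.shape[0]
    M = L @ cov_beta @ L.T
    vals, vecs = np.linalg.eigh(M)
    keep = vals > max(vals.max(), 0) * 1e-10
    vals, vecs = vals[keep], vecs[:, keep]
    q_eff = vals.size
    if q_eff == 0:
        return np.nan, q, np.nan, np.nan
    t2 = []
    dfs = []
    for i in range(q_eff):
        ell = L.T @ vecs[:, i]
        est = float(ell @ beta)
        t2.append(est**2 / vals[i])
        df_i = reml.satterthwaite_df(ell, theta, theta_cov)
        dfs.append(df_i if np.isfinite(df_i) else resid_df)
    F = float(np.sum(t2) / q)
    dfs = np.asarray(dfs, dtype=float)
    good = dfs > 2
    if good.any():
        E = float(np.sum(dfs[good] / (dfs[good] - 2)))
        df2 = 2 * E / (E - q_eff) if E > q_eff else resid_df
    else:
        df2 = resid_df
    p = float(spstats.f.sf(F, q, df2))
    return F, q, df2, p


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    condition_col: str = "condition",
    sex_col: str = "sex",
    group_col: str = "participant",
    include_interaction: bool = True,
    include_diagnostics: bool = True,
) -> LMMReport:
    """REML linear mixed model ``response ~ condition * sex`` with a random
    intercept per participant, with Satterthwaite F tests, effect sizes,
    Nakagawa R², the random-effect variance test, and Holm-corrected
    pairwise condition contrasts (averaged over sex).

    ``response`` is usually ``"log_idr"`` (after :func:`prepare_mu_table`)
    or ``"cv"``.  Rows with a missing response are dropped.  With
    ``include_diagnostics=False`` the pairwise contrasts, random-effect
    test and information criteria are skipped (useful in simulation loops).
    """
    import statsmodels.formula.api as smf
    from patsy import build_design_matrices

    d = table.dropna(subset=[response]).copy()
    for col, nmin in ((condition_col, 2), (sex_col, 2)):
        if d[col].nunique() < nmin:
            raise ValueError(f"need >= {nmin} levels of {col}")
    if (d.groupby(group_col).size() < 2).any():
        raise ValueError("need >= 2 observations per participant")
    inter = "*" if include_interaction else "+"
    # sum-to-zero coding so each term's F is the Type-III marginal test
    formula = f"{response} ~ C({condition_col}, Sum) {inter} C({sex_col}, Sum)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=d, groups=d[group_col])
        res = model.fit(reml=True)
    s2b = float(np.atleast_2d(res.cov_re)[0, 0])
    s2e = float(res.scale)
    singular = s2b < 1e-10 * s2e
    if singular:
        logger.warning("random-intercept variance is ~0 (singular fit)")
    X = np.asarray(model.exog)
    y = np.asarray(model.endog)
    groups = np.asarray(d[group_col])
    reml = _RandomInterceptREML(X, y, groups)
    theta = np.array([s2b, s2e])
    beta = np.asarray(res.fe_params)
    cov_beta = reml.cov_beta(theta)
    theta_cov = reml.theta_cov(theta)
    resid_df = X.shape[0] - X.shape[1]
    design_info = model.data.design_info
    p_fe = X.shape[1]

    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(p_fe)[sl]
        L = np.zeros((idx.size, p_fe))
        L[np.arange(idx.size), idx] = 1.0
        F, df1, df2, p = _term_f_test(
            reml, beta, cov_beta, L, theta, theta_cov, resid_df
        )
        eta = F * df1 / (F * df1 + df2) if np.isfinite(F) else np.nan
        friendly = (
            term.replace(f"C({condition_col}, Sum)", condition_col)
            .replace(f"C({sex_col}, Sum)", sex_col)
        )
        rows.append(
            {
                "term": friendly,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "eta_sq_p": eta,
                "cohens_f": cohens_f_from_eta_sq(eta) if np.isfinite(eta) else np.nan,
            }
        )
    terms = pd.DataFrame(rows)

    # pairwise condition contrasts averaged over sex (estimated marginal means)
    contrasts = pd.DataFrame()
    if include_diagnostics:
        conditions = sorted(d[condition_col].unique())
        sexes = sorted(d[sex_col].unique())
        cell_rows = {}
        for c in conditions:
            new = pd.DataFrame({condition_col: [c] * len(sexes), sex_col: sexes})
            (mat,) = build_design_matrices([design_info], new)
            cell_rows[c] = np.asarray(mat).mean(axis=0)
        crows = []
        for i in range(len(conditions)):
            for j in range(i + 1, len(conditions)):
                ell = cell_rows[conditions[j]] - cell_rows[conditions[i]]
                est = float(ell @ beta)
                se = float(np.sqrt(ell @ cov_beta @ ell))
                df = reml.satterthwaite_df(ell, theta, theta_cov)
                if not np.isfinite(df):
                    df = resid_df
                t = est / se if se > 0 else np.nan
                p = float(2 * spstats.t.sf(abs(t), df)) if np.isfinite(t) else np.nan
                crows.append(
                    {
                        "contrast": f"{conditions[j]} - {conditions[i]}",
                        "estimate": est,
                        "se": se,
                        "df": df,
                        "t": t,
                        "p_raw": p,
                    }
                )
        contrasts = pd.DataFrame(crows)
        if not contrasts.empty:
            contrasts["p_holm"] = holm_adjust(contrasts["p_raw"].to_numpy())

    # Nakagawa R²: fixed-effects variance over total
    var_f = float(np.var(X @ beta))
    total = var_f + s2b + s2e
    r2m = var_f / total
    r2c = (var_f + s2b) / total

    # random-effect test: boundary-corrected LR against the fixed-only model
    p_rand, aic, bic = np.nan, np.nan, np.nan
    if include_diagnostics:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ml = smf.mixedlm(formula, data=d, groups=d[group_col]).fit(reml=False)
            ols = smf.ols(formula, data=d).fit()
        lr = max(2 * (ml.llf - ols.llf), 0.0)
        p_rand = 0.5 * float(spstats.chi2.sf(lr, 1))
        aic, bic = float(ml.aic), float(ml.bic)

    return LMMReport(
        response=response,
        terms=terms,
        contrasts=contrasts,
        sigma2_subject=s2b,
        sigma2_resid=s2e,
        random_effect_p=p_rand,
        r2_marginal=r2m,
        r2_conditional=r2c,
        aic=aic,
        bic=bic,
        n_obs=int(X.shape[0]),
        n_groups=int(len(reml.group_idx)),
        singular=singular,
        extra={
            "formula": formula,
            "converged": bool(res.converged),
            "fe_params": dict(res.fe_params),
        },
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def correlate(
    df: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    shapiro_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations for the listed column pairs.

    Missing values are dropped pairwise; a Shapiro-Wilk normality screen is
    logged (never enforced as failure); constant input yields a missing
    coefficient with a flag.
    """
    rows = []
    for x_col, y_col in pairs:
        sub = df[[x_col, y_col]].dropna()
        x, y = sub[x_col].to_numpy(float), sub[y_col].to_numpy(float)
        n = x.size
        flag = ""
        if n < 3:
            rows.append(
                {"x": x_col, "y": y_col, "n": n, "r": np.nan, "p": np.nan, "flag": "n<3"}
            )
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append(
                {
                    "x": x_col,
                    "y": y_col,
                    "n": n,
                    "r": np.nan,
                    "p": np.nan,
                    "flag": "constant",
                }
            )
            continue
        for name, v in ((x_col, x), (y_col, y)):
            if n >= 4:
                w = spstats.shapiro(v)
                if w.pvalue < shapiro_alpha:
                    logger.info("Shapiro-Wilk: %s deviates from normality (p=%.3g)", name, w.pvalue)
                    flag = "non-normal"
        r, p = spstats.pearsonr(x, y)
        rows.append({"x": x_col, "y": y_col, "n": n, "r": float(r), "p": float(p), "flag": flag})
    return pd.DataFrame(rows)


def corr_matrix(df: pd.DataFrame, cols: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p matrices over ``cols`` (heatmap layout)."""
    cols = list(cols)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            sub = df[[cols[i], cols[j]]].dropna()
            if len(sub) < 3 or sub[cols[i]].std() == 0 or sub[cols[j]].std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = spstats.pearsonr(sub[cols[i]], sub[cols[j]])
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p
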