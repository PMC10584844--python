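"""Cohort-level inference for synchrony profiles.

Covers the study-level statistics: dependent-sample t-tests
(actual vs shuffled-pair surrogate, cleaned vs uncleaned, mirrored-lag
comparisons), linear mixed models with condition as fixed effect and a
per-dyad random intercept (REML, Satterthwaite denominator degrees of
freedom, Nakagawa-Schielzeth marginal R^2, pairwise condition
contrasts), Benjamini-Hochberg FDR correction organised in families
(across lags per condition and measure; across the six pairwise
contrasts per mixed model), and across-dyad Pearson correlation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------- paired t

@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float | None
    d: float | None
    n: int
    p_adj: float | None = None
    family_id: str = ""
    degenerate: bool = False
    label: str = ""


def paired_t(x, y, effect_size: str = "dz",
             family_id: str = "", label: str = "") -> PairedTestResult:
    """Classical dependent-samples t-test with listwise deletion.

    Effect size ``dz`` is mean(diff)/sd(diff); ``dav`` divides by the
    average of the two conditions' SDs instead. A zero-variance
    difference vector is degenerate: all-zero differences report
    t = 0, p = 1; constant nonzero differences report no p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, d=0.0, n=n,
                                    family_id=family_id, degenerate=True,
                                    label=label)
        return PairedTestResult(t=np.inf * np.sign(diff[0]), df=n - 1,
                                p=None, d=None, n=n, family_id=family_id,
                                degenerate=True, label=label)
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    if effect_size == "dav":
        denom = (x.std(ddof=1) + y.std(ddof=1)) / 2
        d = diff.mean() / denom if denom > 0 else None
    else:
        d = diff.mean() / sd
    return PairedTestResult(t=float(t), df=n - 1, p=float(p),
                            d=None if d is None else float(d), n=n,
                            family_id=family_id, label=label)


# ----------------------------------------------------------------- FDR

def fdr_adjust(pvals, family_id: str = "") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: list[PairedTestResult]) -> list[PairedTestResult]:
    """Adjust p-values within one correction family, in place."""
    idx = [i for i, r in enumerate(results) if r.p is not None]
    adj = fdr_adjust([results[i].p for i in idx])
    for j, i in enumerate(idx):
        results[i].p_adj = float(adj[j])
    return results


# ------------------------------------------------- mirrored-lag comparison

def compare_lag_signs(profiles, max_lag: int = 3,
                      effect_size: str = "dz",
                      family_id: str = "") -> list[PairedTestResult]:
    """Paired tests of r(-k) vs r(+k) for k = 1..max_lag.

    A cohort-level asymmetry toward negative lags means the child's
    signal systematically precedes the mother's. FDR is applied within
    the family of mirrored pairs.
    """
    results = []
    for k in range(1, max_lag + 1):
        neg = [p.r_at(-k) for p in profiles]
        pos = [p.r_at(+k) for p in profiles]
        results.append(paired_t(neg, pos, effect_size=effect_size,
                                family_id=family_id or "lag-signs",
                                label=f"lag -{k} vs +{k}"))
    return attach_fdr(results)


# ------------------------------------------------------------ mixed model

@dataclass
class LMMResult:
    F: float
    df_num: int
    df_den: float
    p: float
    R2: float
    var_fixed: float
    var_random: float
    var_resid: float
    contrasts: pd.DataFrame = field(default_factory=pd.DataFrame)
    singular: bool = False
    p_adj: float | None = None


def _reml_pieces(theta, y, X, group_idx, group_sizes):
    """Profile REML log-likelihood and fixed-effect covariance for a
    random-intercept model, by group-wise Woodbury identities."""
    # floors keep a degenerate (zero-variance) fit finite and invertible
    sb2, se2 = max(theta[0], 0.0), max(theta[1], 1e-30)
    XtViX = np.zeros((X.shape[1], X.shape[1]))
    XtViy = np.zeros(X.shape[1])
    logdet = 0.0
    yViy = 0.0
    for g, m in zip(group_idx, group_sizes):
        Xg, yg = X[g], y[g]
        c = sb2 / (se2 + m * sb2)
        sx, sy = Xg.sum(axis=0), yg.sum()
        XtViX += (Xg.T @ Xg - c * np.outer(sx, sx)) / se2
        XtViy += (Xg.T @ yg - c * sx * sy) / se2
        yViy += (yg @ yg - c * sy * sy) / se2
        logdet += (m - 1) * np.log(se2) + np.log(se2 + m * sb2)
    C = np.linalg.pinv(XtViX)      # pinv: boundary fits can be singular
    beta = C @ XtViy
    rss = yViy - XtViy @ beta
    eig = np.linalg.eigvalsh(XtViX)
    logdetX = float(np.log(np.clip(eig, 1e-300, None)).sum())
    ll = -0.5 * (logdet + logdetX + rss)
    return ll, beta, C


def _satterthwaite_df(l_vec, theta, A, y, X, group_idx, group_sizes,
                      rel_step: float = 1e-4):
    """Satterthwaite df for Var(l'beta) at the REML estimate.

    df = 2 g^2 / (grad' A grad) with g(theta) = l' C(theta) l and A the
    asymptotic covariance of the variance parameters.
    """
    def g(th):
        _, _, C = _reml_pieces(th, y, X, group_idx, group_sizes)
        return float(l_vec @ C @ l_vec)

    g0 = g(theta)
    grad = np.zeros(2)
    for j in range(2):
        h = max(theta[j], 1e-8) * rel_step + 1e-12
        up = theta.copy()
        up[j] += h
        if theta[j] > 2 * h:       # central difference away from boundary
            dn = theta.copy()
            dn[j] -= h
            grad[j] = (g(up) - g(dn)) / (2 * h)
        else:
            grad[j] = (g(up) - g0) / h
    denom = float(grad @ A @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return np.inf
    return 2.0 * g0 * g0 / denom


def _vcov_theta(theta, y, X, group_idx, group_sizes, rel_step: float = 1e-3):
    """Asymptotic covariance of (sigma_b^2, sigma_e^2): inverse observed
    information of the REML log-likelihood (central finite differences)."""
    def ll(th):
        return _reml_pieces(th, y, X, group_idx, group_sizes)[0]

    H = np.zeros((2, 2))
    h = np.array([max(t, 1e-6) * rel_step for t in theta])
    for i in range(2):
        for j in range(2):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            for t in (tpm, tmp, tmm):
                t[t < 1e-12] = 1e-12
            H[i, j] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * h[i] * h[j])
    try:
        return np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.full((2, 2), np.nan)


def condition_lmm(data: pd.DataFrame, value_col: str = "r",
                  condition_col: str = "condition",
                  subject_col: str = "dyad_id",
                  fdr_contrasts: bool = True) -> LMMResult:
    """Random-intercept mixed model of synchrony on condition.

    REML fit (via statsmodels MixedLM); omnibus F for the condition
    effect with Satterthwaite denominator df (per-eigencontrast df
    pooled as in lmerTest); marginal R^2 =
    var_fixed / (var_fixed + var_random + var_resid) following the
    Nakagawa-Schielzeth variance decomposition; pairwise condition
    contrasts with FDR across the comparisons. Unbalanced data are
    handled natively by REML; a singular random-effects fit is flagged
    and the fixed-effects F still returned.
    """
    import statsmodels.formula.api as smf

    df = data[[value_col, condition_col, subject_col]].dropna().copy()
    df.columns = ["y", "cond", "subj"]
    conds = sorted(df["cond"].unique())
    if len(conds) < 2:
        raise ValueError("need >= 2 conditions")
    counts = df.groupby("cond")["subj"].count()
    if (counts < 3).any():
        raise ValueError("need >= 3 observations per condition")

    model = smf.mixedlm("y ~ C(cond)", df, groups=df["subj"])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    sb2 = float(np.asarray(res.cov_re)[0, 0])
    se2 = float(res.scale)
    # floor keeps a zero-variance (degenerate) response well defined
    scale0 = max(float(np.var(df["y"])), 1.0)
    se2 = max(se2, 1e-12 * scale0)
    singular = sb2 < 1e-10 * (sb2 + se2)

    # design pieces for the Satterthwaite machinery
    X = pd.get_dummies(df["cond"], drop_first=True, dtype=float)
    X.insert(0, "Intercept", 1.0)
    Xm = X.to_numpy()
    y = df["y"].to_numpy()
    codes = pd.Categorical(df["subj"]).codes
    group_idx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    group_sizes = [len(g) for g in group_idx]
    theta = np.array([max(sb2, 1e-10), se2])
    _, beta, C = _reml_pieces(theta, y, Xm, group_idx, group_sizes)
    A = _vcov_theta(theta, y, Xm, group_idx, group_sizes)

    q = len(conds) - 1
    L = np.zeros((q, Xm.shape[1]))
    L[:, 1:1 + q] = np.eye(q)
    M = L @ C @ L.T
    F = float(beta[1:1 + q] @ np.linalg.solve(M, beta[1:1 + q]) / q)
    # pool per-eigencontrast Satterthwaite dfs (lmerTest-style)
    eigval, eigvec = np.linalg.eigh(M)
    nus = []
    for m_i in range(q):
        l_vec = eigvec[:, m_i] @ L
        nu = _satterthwaite_df(l_vec, theta, A, y, Xm, group_idx,
                               group_sizes)
        nus.append(nu)
    E = sum(nu / (nu - 2) for nu in nus if nu > 2)
    df_den = 2 * E / (E - q) if E > q else float(len(y) - Xm.shape[1])
    p = float(sps.f.sf(F, q, df_den)) if np.isfinite(df_den) else float(
        sps.chi2.sf(F * q, q))

    var_fixed = float(np.var(Xm @ beta))
    R2 = var_fixed / (var_fixed + sb2 + se2)

    rows = []
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            l_vec = np.zeros(Xm.shape[1])
            if i > 0:
                l_vec[i] = -1.0
            if j > 0:
                l_vec[j] = 1.0
            est = float(l_vec @ beta)
            se = float(np.sqrt(l_vec @ C @ l_vec))
            nu = _satterthwaite_df(l_vec, theta, A, y, Xm, group_idx,
                                   group_sizes)
            tval = est / se if se > 0 else np.nan
            pval = 2 * sps.t.sf(abs(tval), nu) if np.isfinite(nu) \
                else 2 * sps.norm.sf(abs(tval))
            rows.append({"contrast": f"{conds[j]} - {conds[i]}",
                         "estimate": est, "se": se, "t": tval,
                         "df": nu, "p": pval})
    contrasts = pd.DataFrame(rows)
    if fdr_contrasts and len(contrasts):
        contrasts["p_adj"] = fdr_adjust(contrasts["p"])
    return LMMResult(F=F, df_num=q, df_den=float(df_den), p=p, R2=float(R2),
                     var_fixed=var_fixed, var_random=sb2, var_resid=se2,
                     contrasts=contrasts, singular=singular)


# ----------------------------------------------------- correlation table

def across_dyad_correlations(table: pd.DataFrame
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between per-dyad variables.

    Pairwise-complete deletion per cell; returns ``(r, p)`` matrices.
    Cells with fewer than 4 complete pairs or zero variance are NaN.
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j < i:
                continue
            x = table[a].to_numpy(dtype=float)
            y = table[b].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4:
                continue
            if x[ok].std() == 0 or y[ok].std() == 0:
                continue
            rr, pp = sps.pearsonr(x[ok], y[ok])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p
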