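"""Lateralization indices and the repeated-measures statistical battery.

The hemispheric lateralization index of a metric X is

    X_lat = (right − left) / ((right + left)/2),

positive when right-dominant.  Recognition discriminability d' (3 retrievals
× 2 emotion categories, within subjects) is analyzed with a two-way
repeated-measures ANOVA; each oscillatory / lateralization variable is then
entered as a continuous covariate in a repeated-measures ANCOVA controlling
sex, measurement location and sleep duration (Model 1; Model 2 additionally
controls ln-transformed BDI and GAD-7).  Within-subject covariate effects
are computed by the univariate mixed-model approach: orthonormal
within-subject contrasts of the d' cells are regressed on the between-
subject design, and the covariate's extra sums of squares are pooled across
contrast columns.  Significant interactions are followed up with ordinary
least-squares regressions on difference scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectSummary",
    "EffectResult",
    "lateralization_index",
    "rm_anova_d",
    "rm_anova_posthoc",
    "rm_ancova_d",
    "followup_regression",
    "preliminary_screens",
    "MODEL1_CONTROLS",
    "MODEL2_CONTROLS",
]

MODEL1_CONTROLS = ("sex", "location", "sleep_duration")
MODEL2_CONTROLS = MODEL1_CONTROLS + ("bdi_ln", "gad7_ln")


@dataclass
class SubjectSummary:
    """Per-subject oscillatory metrics, lateralization indices and covariates."""

    subject: str
    spindle_density_frontal: float = math.nan
    spindle_density_central: float = math.nan
    coupling_distance_frontal: float = math.nan
    coupling_distance_central: float = math.nan
    rem_theta: float = math.nan
    spindle_lat: float = math.nan
    coupling_lat: float = math.nan
    theta_lat: float = math.nan
    sex: str = "F"
    location: str = "home"
    sleep_duration: float = math.nan   # hours
    bdi_ln: float = math.nan
    gad7_ln: float = math.nan
    handedness: str = "missing"


@dataclass
class EffectResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta2_p: float


def lateralization_index(right: float, left: float,
                         guard_eps: float = 1e-6) -> float:
    """(right − left) / mean(right, left); NaN when |mean| < guard_eps."""
    mean = (right + left) / 2.0
    if not np.isfinite(mean) or abs(mean) < guard_eps:
        logger.warning("lateralization denominator |%.3g| below guard %.1g; "
                       "flagged missing", mean, guard_eps)
        return math.nan
    return (right - left) / mean


# ---------------------------------------------------------------------------
# Two-way repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_d(scores: np.ndarray,
               factor_names: tuple[str, str] = ("time", "emotion"),
               sphericity: str = "none") -> list[EffectResult]:
    """Two-way fully-within repeated-measures ANOVA by sums-of-squares
    decomposition.

    ``scores`` is (n_subjects, a, b) — here (n, 3 retrievals, 2 emotions).
    By default no sphericity correction is applied (plain dfs are reported);
    ``sphericity="gg"`` applies the Greenhouse–Geisser epsilon to the
    p-value of each multi-df effect.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 3:
        raise ValueError("scores must be (n_subjects, levels_A, levels_B)")
    n, a, b = Y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(Y).any():
        raise ValueError("complete cases required")

    m = Y.mean()
    S = Y.mean(axis=(1, 2))          # subject means
    A = Y.mean(axis=(0, 2))          # factor-A (time) means
    B = Y.mean(axis=(0, 1))          # factor-B (emotion) means
    AB = Y.mean(axis=0)              # (a, b)
    AS = Y.mean(axis=2)              # (n, a)
    BS = Y.mean(axis=1)              # (n, b)

    ss_a = n * b * ((A - m) ** 2).sum()
    ss_b = n * a * ((B - m) ** 2).sum()
    ss_ab = n * ((AB - A[:, None] - B[None, :] + m) ** 2).sum()
    ss_s = a * b * ((S - m) ** 2).sum()
    ss_as = b * ((AS - A[None, :] - S[:, None] + m) ** 2).sum()
    ss_bs = a * ((BS - B[None, :] - S[:, None] + m) ** 2).sum()
    ss_tot = ((Y - m) ** 2).sum()
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    def gg_epsilon(Yc: np.ndarray) -> float:
        """Greenhouse–Geisser epsilon from contrast-projected scores (n, q)."""
        q = Yc.shape[1]
        if q < 2:
            return 1.0
        S = np.cov(Yc, rowvar=False)
        eps = np.trace(S) ** 2 / (q * np.trace(S @ S))
        return float(min(max(eps, 1.0 / q), 1.0))

    def effect(name, ss_e, df1, ss_err, df2, Yc=None):
        if ss_err <= 0:
            f = 0.0 if ss_e <= 0 else math.inf
        else:
            f = (ss_e / df1) / (ss_err / df2)
        eps = gg_epsilon(Yc) if (sphericity == "gg" and Yc is not None) else 1.0
        p = (float(sp_stats.f.sf(f, df1 * eps, df2 * eps))
             if np.isfinite(f) else 0.0)
        eta = ss_e / (ss_e + ss_err) if (ss_e + ss_err) > 0 else 0.0
        return EffectResult(effect=name, F=float(f), df1=df1, df2=df2,
                            p=p, eta2_p=float(eta))

    Ma = _orthonormal_contrasts(a)
    Mb = _orthonormal_contrasts(b)
    na, nb = factor_names
    return [
        effect(na, ss_a, a - 1, ss_as, (a - 1) * (n - 1), AS @ Ma),
        effect(nb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1), BS @ Mb),
        effect(f"{na} x {nb}", ss_ab, (a - 1) * (b - 1),
               ss_abs, (a - 1) * (b - 1) * (n - 1),
               Y.reshape(n, a * b) @ np.kron(Ma, Mb)),
    ]


def rm_anova_posthoc(scores: np.ndarray,
                     level_names: tuple = ("immediate", "12h", "24h")) -> pd.DataFrame:
    """Bonferroni-corrected paired follow-ups.

    Pairwise retrieval comparisons of d' (pooled over emotion) and
    neutral-vs-emotional comparisons within each retrieval.
    """
    Y = np.asarray(scores, dtype=float)
    n, a, b = Y.shape
    pooled = Y.mean(axis=2)
    rows = []
    pairs = [(i, j) for i in range(a) for j in range(i + 1, a)]
    m_tests = len(pairs) + a
    for i, j in pairs:
        t, p = sp_stats.ttest_rel(pooled[:, i], pooled[:, j])
        rows.append({"comparison": f"{level_names[i]} vs {level_names[j]}",
                     "t": float(t), "p_uncorrected": float(p),
                     "p_bonferroni": min(1.0, float(p) * m_tests)})
    for i in range(a):
        t, p = sp_stats.ttest_rel(Y[:, i, 0], Y[:, i, 1])
        rows.append({"comparison": f"neutral vs emotional at {level_names[i]}",
                     "t": float(t), "p_uncorrected": float(p),
                     "p_bonferroni": min(1.0, float(p) * m_tests)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated-measures ANCOVA with a continuous covariate
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k−1) orthonormal within-subject contrast matrix (Helmert-based)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0 / j
        h[j, j - 1] = -1.0
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def _design_matrix(covariate: np.ndarray, controls: pd.DataFrame | None,
                   center: bool = True) -> tuple[np.ndarray, int]:
    """[1, covariate, dummy-coded controls]; returns (X, covariate column)."""
    cov = np.asarray(covariate, dtype=float)
    if center:
        cov = cov - cov.mean()
    cols = [np.ones_like(cov), cov]
    if controls is not None:
        enc = pd.get_dummies(controls, drop_first=True, dtype=float)
        for c in enc.columns:
            v = enc[c].to_numpy(dtype=float)
            cols.append(v - v.mean())
    X = np.column_stack(cols)
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise ValueError(f"collinear design (condition number {cond:.2g}); "
                         "inspect the control variables")
    return X, 1


def _extra_ss(X: np.ndarray, y: np.ndarray, col: int) -> tuple[float, float]:
    """(extra SS of column ``col`` given all others, residual SS of full model)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(((y - X @ beta) ** 2).sum())
    Xr = np.delete(X, col, axis=1)
    beta_r, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    rss_red = float(((y - Xr @ beta_r) ** 2).sum())
    return rss_red - rss_full, rss_full


def rm_ancova_d(scores: np.ndarray, covariate: np.ndarray,
                controls: pd.DataFrame | None = None,
                factor_names: tuple[str, str] = ("time", "emotion")) -> list[EffectResult]:
    """Repeated-measures ANCOVA of d' with a continuous subject-level covariate.

    Tests the covariate's main effect (association with overall d') and its
    interactions with time, emotion and time×emotion, controlling for the
    supplied between-subject terms.  Missing control values are mean-imputed
    (numeric) before fitting.  Implemented by regressing orthonormal
    within-subject contrast scores on the between-subject design and pooling
    the covariate's extra sums of squares across contrast columns.
    """
    Y = np.asarray(scores, dtype=float)
    n, a, b = Y.shape
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != n:
        raise ValueError("covariate length must match subjects")
    keep = np.isfinite(cov) & np.isfinite(Y.reshape(n, -1)).all(axis=1)
    if controls is not None:
        controls = controls.reset_index(drop=True)
        num = controls.select_dtypes(include=[np.number]).columns
        controls[num] = controls[num].fillna(controls[num].mean())
        keep &= controls.notna().all(axis=1).to_numpy()
    if keep.sum() < n:
        logger.info("rm_ancova_d: dropping %d incomplete cases", n - keep.sum())
    Y = Y[keep]
    cov = cov[keep]
    controls = controls.loc[keep].reset_index(drop=True) if controls is not None else None
    n = len(cov)

    X, cov_col = _design_matrix(cov, controls)
    p = X.shape[1]
    if n <= p:
        raise ValueError("too few subjects for the design")

    Ma = _orthonormal_contrasts(a)                  # (a, a-1)
    Mb = _orthonormal_contrasts(b)                  # (b, b-1)
    ones_a = np.full((a, 1), 1.0 / np.sqrt(a))
    ones_b = np.full((b, 1), 1.0 / np.sqrt(b))

    Y2 = Y.reshape(n, a * b)                        # cells ordered (a, b)

    def kron_cols(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
        return np.kron(ca, cb)                      # (a*b, qa*qb)

    na, nb = factor_names
    effect_contrasts = {
        "main": kron_cols(ones_a, ones_b),
        f"x {na}": kron_cols(Ma, ones_b),
        f"x {nb}": kron_cols(ones_a, Mb),
        f"x {na} x {nb}": kron_cols(Ma, Mb),
    }
    results = []
    for name, C in effect_contrasts.items():
        Yc = Y2 @ C                                 # (n, q)
        q = C.shape[1]
        ss_hyp = 0.0
        ss_err = 0.0
        for col in range(q):
            dh, de = _extra_ss(X, Yc[:, col], cov_col)
            ss_hyp += dh
            ss_err += de
        df1, df2 = q, q * (n - p)
        F = (ss_hyp / df1) / (ss_err / df2)
        pval = float(sp_stats.f.sf(F, df1, df2))
        eta = ss_hyp / (ss_hyp + ss_err) if (ss_hyp + ss_err) > 0 else 0.0
        results.append(EffectResult(effect=name, F=float(F), df1=df1, df2=df2,
                                    p=pval, eta2_p=float(eta)))
    return results


# ---------------------------------------------------------------------------
# Follow-up regressions and preliminary screens
# ---------------------------------------------------------------------------

def followup_regression(delta: np.ndarray, predictor: np.ndarray,
                        controls: pd.DataFrame | None = None,
                        prior_delta: np.ndarray | None = None) -> tuple[float, float, float]:
    """OLS of a difference score on a predictor (+ controls, + the matching
    difference score from the previous retrieval when given).

    Returns (t, two-sided p, coefficient) for the predictor.
    """
    import statsmodels.api as sm

    y = np.asarray(delta, dtype=float)
    x = np.asarray(predictor, dtype=float)
    parts = {"predictor": x}
    if controls is not None:
        enc = pd.get_dummies(controls.reset_index(drop=True), drop_first=True,
                             dtype=float)
        for c in enc.columns:
            parts[str(c)] = enc[c].to_numpy(dtype=float)
    if prior_delta is not None:
        parts["prior_delta"] = np.asarray(prior_delta, dtype=float)
    Xdf = pd.DataFrame(parts)
    keep = np.isfinite(y) & np.isfinite(Xdf.to_numpy()).all(axis=1)
    Xc = sm.add_constant(Xdf.loc[keep])
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("rank-deficient follow-up design")
    fit = sm.OLS(y[keep], Xc).fit()
    return (float(fit.tvalues["predictor"]), float(fit.pvalues["predictor"]),
            float(fit.params["predictor"]))


def preliminary_screens(variables: pd.DataFrame, group: str,
                        correlate_pairs: list[tuple[str, str]] | None = None,
                        crosstab: tuple[str, str] | None = None,
                        outlier_z: float = 3.0) -> dict:
    """Confounder screens: one-way ANOVA per variable by group, Pearson
    correlations for requested pairs, an optional chi-squared cross-tab,
    and |z| > 3 outlier flags.
    """
    report: dict = {"anova": {}, "pearson": {}, "chi2": None, "outliers": {}}
    numeric = variables.select_dtypes(include=[np.number]).columns
    for var in numeric:
        groups = [g[var].dropna().to_numpy()
                  for _, g in variables.groupby(group)]
        groups = [g for g in groups if len(g) >= 3]
        if len(groups) >= 2:
            f, p = sp_stats.f_oneway(*groups)
            report["anova"][var] = {"F": float(f), "p": float(p)}
    for x, y in correlate_pairs or []:
        sub = variables[[x, y]].dropna()
        if sub[x].nunique() < 2 or sub[y].nunique() < 2:
            report["pearson"][(x, y)] = {"r": math.nan, "p": math.nan}
            continue
        r, p = sp_stats.pearsonr(sub[x], sub[y])
        report["pearson"][(x, y)] = {"r": float(r), "p": float(p)}
    if crosstab is not None:
        tab = pd.crosstab(variables[crosstab[0]], variables[crosstab[1]])
        chi2, p, dof, _ = sp_stats.chi2_contingency(tab)
        report["chi2"] = {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
    for var in numeric:
        v = variables[var].to_numpy(dtype=float)
        mu, sd = np.nanmean(v), np.nanstd(v, ddof=1)
        if sd > 0:
            z = (v - mu) / sd
            flagged = variables.index[np.abs(z) > outlier_z].tolist()
            if flagged:
                report["outliers"][var] = flagged
    return report
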