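"""Network-level mixed-effects inference on percent-signal-change tables.

The response of a functional network is modelled as

    psc ~ condition_code + (condition_code | subject) + (condition_code | roi)

with the two-level condition deviation-coded (-0.5 / +0.5), so the fixed
slope is the condition difference and the intercept the grand mean.  Random
intercepts and slopes are crossed over subjects and ROIs.

Estimation
----------
For complete balanced tables (every subject x ROI x condition cell exactly
once) the model with uncorrelated random effects factorises exactly: the
per-cell condition *sums* carry the intercepts and the per-cell *differences*
carry the slopes, and each part is a balanced two-way crossed layout whose
REML likelihood depends on the data only through its ANOVA mean squares.
The five variance components (subject/ROI intercept and slope variances and
the residual) are then estimated by direct REML on those sufficient
statistics, and degrees of freedom come from the classical Satterthwaite
combination of mean squares — the same approximation lmerTest reports.
This path is exact, deterministic and fast enough for simulation studies.

Unbalanced tables fall back to ``statsmodels`` ``MixedLM`` with variance
components (slower; residual-style degrees of freedom).

Intercept-slope correlations are not estimated on either path: the fitter
starts from the *uncorrelated* maximal structure, which is also the first
step of the standard keep-it-maximal simplification ladder; components that
collapse to zero are recorded in the simplification trace, exactly like
dropping the corresponding random term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = ["MixedModelFit", "deviation_code", "NetworkLMM", "fit_network_lmm",
           "fit_interaction_lmm", "fit_roi_models", "network_overlap",
           "localizer_scope_effect", "DEFAULT_CONDITION_CODES"]

#: deviation coding of the critical naming conditions
DEFAULT_CONDITION_CODES = {"L1_after_L1": -0.5, "L1_after_L2": 0.5}

_EPS = 1e-10


@dataclass(frozen=True)
class MixedModelFit:
    """Fixed-effect inference plus variance components and provenance."""

    term: str
    beta: float
    se: float
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    intercept: float
    intercept_se: float
    effect_size: float
    effect_size_method: str
    vc: dict[str, float]
    converged: bool
    method: str  # "balanced_reml" | "mixedlm_vc"
    trace: tuple[str, ...]
    n_subjects: int
    n_rois: int
    n_obs: int
    fixed_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"mixed model ({self.method}); random-effects trace: "
                 + " -> ".join(self.trace)]
        for name, fe in self.fixed_effects.items():
            lines.append(f"  {name}: beta={fe['beta']:+.4f} SE={fe['se']:.4f} "
                         f"t({fe['df']:.1f})={fe['t']:.3f} p={fe['p']:.4g}")
        lines.append(f"  effect size ({self.effect_size_method}) = {self.effect_size:.3f}")
        lines.append("  variance components: "
                     + ", ".join(f"{k}={v:.5g}" for k, v in self.vc.items()))
        return "\n".join(lines)


def deviation_code(table: pd.DataFrame, condition_col: str = "condition",
                   codes: dict[str, float] | None = None) -> pd.DataFrame:
    """Attach a -0.5/+0.5 ``condition_code`` column for a two-level factor.

    With ``codes=None`` the two labels are coded in sorted order
    (first -> -0.5, second -> +0.5).  More than two levels is an error.
    """
    levels = sorted(table[condition_col].unique())
    if codes is None:
        if len(levels) != 2:
            raise ValueError(f"deviation coding needs exactly 2 levels, got {levels}")
        codes = {levels[0]: -0.5, levels[1]: 0.5}
    else:
        unknown = set(levels) - set(codes)
        if unknown:
            raise ValueError(f"conditions without a code: {sorted(unknown)}")
        if sorted(set(codes.values())) != [-0.5, 0.5]:
            raise ValueError("codes must take the values -0.5 and +0.5")
    out = table.copy()
    out["condition_code"] = out[condition_col].map(codes).astype(float)
    return out


# ----------------------------------------------------- balanced REML engine

def _two_way_stats(X: np.ndarray, groups: np.ndarray):
    """Sufficient statistics of a balanced two-way crossed layout.

    ``X`` is subjects x ROIs; ``groups`` assigns each ROI column to a fixed
    group (all-same for the single-network model, two groups when a network
    fixed effect is present).  Returns group means and the three strata
    (SS, df) with ROI effects centred within group.
    """
    S, R = X.shape
    gm = X.mean()
    rs = X.mean(axis=1)
    cs = X.mean(axis=0)
    uniq = np.unique(groups)
    group_means = {g: X[:, groups == g].mean() for g in uniq}
    cs_centered = cs - np.array([group_means[g] for g in groups])
    ss_s = R * ((rs - gm) ** 2).sum()
    ss_r = S * (cs_centered ** 2).sum()
    ss_e = ((X - rs[:, None] - cs[None, :] + gm) ** 2).sum()
    return group_means, (ss_s, S - 1), (ss_r, R - len(uniq)), (ss_e, (S - 1) * (R - 1))


def _reml_crossed(D: np.ndarray, M: np.ndarray, roi_groups: np.ndarray):
    """Joint REML of (subj_int, subj_slope, roi_int, roi_slope, residual).

    ``D`` holds per-cell condition differences, ``M`` per-cell condition
    means.  Returns (theta, strata-description, converged).
    """
    S, R = D.shape
    _, (ssd_s, dfd_s), (ssd_r, dfd_r), (ssd_e, dfd_e) = _two_way_stats(D, roi_groups)
    _, (ssm_s, dfm_s), (ssm_r, dfm_r), (ssm_e, dfm_e) = _two_way_stats(M, roi_groups)

    # theta = (va subj_int, vb subj_slope, vg roi_int, vh roi_slope, s2 resid)
    # strata eigenvalues: lam = A @ theta  (all linear)
    A = np.array([
        [0, R, 0, 0, 2.0],    # D subject stratum
        [0, 0, 0, S, 2.0],    # D roi stratum
        [0, 0, 0, 0, 2.0],    # D residual stratum
        [R, 0, 0, 0, 0.5],    # M subject stratum
        [0, 0, S, 0, 0.5],    # M roi stratum
        [0, 0, 0, 0, 0.5],    # M residual stratum
    ])
    ss = np.array([ssd_s, ssd_r, ssd_e, ssm_s, ssm_r, ssm_e])
    dfs = np.array([dfd_s, dfd_r, dfd_e, dfm_s, dfm_r, dfm_e], dtype=float)
    use = dfs > 0
    if R == 1:
        # residual and ROI effects unidentifiable: fold into subject terms
        A = A.copy()
        A[0, 1], A[0, 4] = 1.0, 0.0  # D subject stratum ~ vb alone
        A[3, 0], A[3, 4] = 1.0, 0.0
    # a component is estimable only if it enters a stratum with positive df
    free = A[use].astype(bool).any(axis=0)

    # moment-based start
    with np.errstate(divide="ignore", invalid="ignore"):
        ms = np.where(dfs > 0, ss / np.maximum(dfs, 1), 0.0)
    start = np.array([
        max((ms[3] - ms[5]) / R, ms[3] / R if R == 1 else 0.0, _EPS),
        max((ms[0] - ms[2]) / R, ms[0] / R if R == 1 else 0.0, _EPS),
        max((ms[4] - ms[5]) / S, _EPS),
        max((ms[1] - ms[2]) / S, _EPS),
        max(ms[2] / 2.0, ms[5] * 2.0, _EPS),
    ])

    idx = np.where(free)[0]

    def negll(log_th_free: np.ndarray) -> float:
        th = np.zeros(5)
        th[idx] = np.exp(np.clip(log_th_free, -46, 46))
        lam = A @ th
        val = 0.0
        for i in np.where(use)[0]:
            if lam[i] <= 0:
                return np.inf
            val += dfs[i] * np.log(lam[i]) + ss[i] / lam[i]
        return 0.5 * val

    res = optimize.minimize(negll, np.log(start[idx]), method="Nelder-Mead",
                            options=dict(xatol=1e-12, fatol=1e-12,
                                         maxiter=40000, maxfev=40000))
    theta = np.zeros(5)
    theta[idx] = np.exp(res.x)
    theta[theta < 1e-9 * max(theta.max(), 1.0)] = 0.0
    return theta, (A, ss, dfs, use, free), bool(np.isfinite(res.fun))


def _satterthwaite(var_grad: np.ndarray, var_beta: float, theta: np.ndarray,
                   strata) -> float:
    """Satterthwaite df: 2 Var(beta)^2 / Var_hat(Var(beta))."""
    A, ss, dfs, use, free = strata
    lam = A @ theta
    est_free = free & (theta > 0)
    if not est_free.any() or var_beta <= 0:
        return np.inf
    rows = np.where(use & (lam > 0))[0]
    if rows.size == 0:
        return np.inf
    Asub = A[np.ix_(rows, np.where(est_free)[0])]
    info = 0.5 * np.einsum("s,sj,sk->jk", dfs[rows] / lam[rows] ** 2, Asub, Asub)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.inf
    g = var_grad[est_free]
    denom = float(g @ cov @ g)
    if denom <= 0:
        return np.inf
    return 2.0 * var_beta ** 2 / denom


def _is_balanced(table: pd.DataFrame) -> bool:
    counts = table.groupby(["subject", "roi", "condition_code"], sort=False).size()
    if (counts != 1).any():
        return False
    n_s = table["subject"].nunique()
    n_r = table["roi"].nunique()
    return len(counts) == n_s * n_r * 2


def _cube(table: pd.DataFrame):
    """Pivot a balanced table to difference/mean matrices (subjects x ROIs)."""
    wide = table.pivot_table(index=["subject", "roi"], columns="condition_code",
                             values="psc")
    D = (wide[0.5] - wide[-0.5]).unstack()
    M = ((wide[0.5] + wide[-0.5]) / 2.0).unstack()
    return D.values, M.values, list(D.index), list(D.columns)


def _effect_size(table: pd.DataFrame, t: float, df: float, method: str) -> float:
    if method == "d_from_t":
        return 2.0 * t / np.sqrt(df) if df > 0 and np.isfinite(df) else np.nan
    if method == "d_z":
        per_subj = table.groupby(["subject", "condition_code"])["psc"].mean().unstack()
        diff = per_subj[0.5] - per_subj[-0.5]
        sd = diff.std(ddof=1)
        return float(diff.mean() / sd) if sd > 0 else np.nan
    raise ValueError(f"unknown effect size method {method!r}")


_VC_NAMES = ("subject_intercept", "subject_slope", "roi_intercept",
             "roi_slope", "residual")


def _trace_from_theta(theta: np.ndarray, free: np.ndarray) -> tuple[str, ...]:
    trace = ["maximal_uncorrelated"]
    order = [("roi_slope", 3), ("subject_slope", 1), ("roi_intercept", 2),
             ("subject_intercept", 0)]
    for name, j in order:
        if (not free[j]) or theta[j] == 0.0:
            trace.append(f"dropped_{name}" if free[j] else f"unidentifiable_{name}")
    return tuple(trace)


def _fit_balanced(table: pd.DataFrame, effect_size: str,
                  alpha: float = 0.05) -> MixedModelFit:
    D, M, subjects, rois = _cube(table)
    S, R = D.shape
    roi_groups = np.zeros(R, dtype=int)
    theta, strata, ok = _reml_crossed(D, M, roi_groups)
    va, vb, vg, vh, s2 = theta
    beta = float(D.mean())
    mu = float(M.mean())
    var_beta = (R * vb + S * vh + 2 * s2) / (S * R)
    var_mu = (R * va + S * vg + 0.5 * s2) / (S * R)
    g_beta = np.array([0, R, 0, S, 2.0]) / (S * R)
    g_mu = np.array([R, 0, S, 0, 0.5]) / (S * R)
    if R == 1:  # folded parametrisation
        g_beta = np.array([0, 1.0, 0, 0, 0]) / S
        g_mu = np.array([1.0, 0, 0, 0, 0]) / S
        var_beta = vb / S
        var_mu = va / S
    df = _satterthwaite(g_beta, var_beta, theta, strata)
    df_mu = _satterthwaite(g_mu, var_mu, theta, strata)
    se = float(np.sqrt(var_beta))
    se_mu = float(np.sqrt(var_mu))
    t, p, lo, hi = _t_inference(beta, se, df, alpha)
    t_mu, p_mu, *_ = _t_inference(mu, se_mu, df_mu, alpha)
    es = _effect_size(table, t, df, effect_size)
    fixed = {
        "condition_code": dict(beta=beta, se=se, t=t, df=df, p=p),
        "intercept": dict(beta=mu, se=se_mu, t=t_mu, df=df_mu, p=p_mu),
    }
    return MixedModelFit(
        term="condition_code", beta=beta, se=se, t=t, df=df, p=p,
        ci_low=lo, ci_high=hi, intercept=mu, intercept_se=se_mu,
        effect_size=es, effect_size_method=effect_size,
        vc=dict(zip(_VC_NAMES, (float(x) for x in theta))),
        converged=ok, method="balanced_reml",
        trace=_trace_from_theta(theta, strata[4]),
        n_subjects=S, n_rois=R, n_obs=len(table), fixed_effects=fixed)


def _t_inference(est: float, se: float, df: float, alpha: float):
    if se == 0:
        if est == 0:
            return 0.0, 1.0, 0.0, 0.0
        return float(np.inf) * np.sign(est), 0.0, est, est
    t = est / se
    if np.isfinite(df):
        p = float(2 * stats.t.sf(abs(t), df))
        q = stats.t.ppf(1 - alpha / 2, df)
    else:
        p = float(2 * stats.norm.sf(abs(t)))
        q = stats.norm.ppf(1 - alpha / 2)
    return float(t), p, float(est - q * se), float(est + q * se)


def _fit_mixedlm(table: pd.DataFrame, effect_size: str, fixed_formula: str,
                 term: str, alpha: float = 0.05) -> MixedModelFit:
    """Unbalanced-data fallback: statsmodels MixedLM with variance components
    and the fixed simplification ladder (drop ROI slope, then subject slope)."""
    import statsmodels.formula.api as smf

    data = table.copy()
    data["_group"] = 1
    ladders = [
        ("maximal_uncorrelated",
         {"subject_intercept": "0 + C(subject)",
          "subject_slope": "0 + C(subject):condition_code",
          "roi_intercept": "0 + C(roi)",
          "roi_slope": "0 + C(roi):condition_code"}),
        ("dropped_roi_slope",
         {"subject_intercept": "0 + C(subject)",
          "subject_slope": "0 + C(subject):condition_code",
          "roi_intercept": "0 + C(roi)"}),
        ("dropped_subject_slope",
         {"subject_intercept": "0 + C(subject)",
          "roi_intercept": "0 + C(roi)"}),
    ]
    trace = ["maximal_uncorrelated"]
    result = None
    vc_used = None
    for step, vcf in ladders:
        if step != "maximal_uncorrelated":
            trace.append(step)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = smf.mixedlm(fixed_formula, data, groups="_group",
                                    re_formula="0", vc_formula=vcf)
                result = model.fit(reml=True, method="lbfgs", maxiter=500)
            except Exception:
                result = None
                continue
        if result is not None and np.isfinite(result.params[term]) and \
                np.isfinite(result.bse[term]) and result.bse[term] > 0:
            vc_used = vcf
            break
    if result is None or vc_used is None:
        raise RuntimeError("mixed model failed to converge on every ladder step")
    beta = float(result.params[term])
    se = float(result.bse[term])
    df = float(len(data) - len(result.fe_params))  # residual-style df
    t, p, lo, hi = _t_inference(beta, se, df, alpha)
    mu = float(result.params.get("Intercept", np.nan))
    mu_se = float(result.bse.get("Intercept", np.nan))
    vc = {name: 0.0 for name in _VC_NAMES[:-1]}
    for name, val in zip(vc_used, result.vcomp):
        vc[name] = float(val)
    vc["residual"] = float(result.scale)
    fixed = {}
    for name in result.fe_params.index:
        b, s_ = float(result.params[name]), float(result.bse[name])
        tt, pp, *_ = _t_inference(b, s_, df, alpha)
        fixed[name] = dict(beta=b, se=s_, t=tt, df=df, p=pp)
    es = _effect_size(table, t, df, effect_size) if term == "condition_code" else np.nan
    return MixedModelFit(
        term=term, beta=beta, se=se, t=t, df=df, p=p, ci_low=lo, ci_high=hi,
        intercept=mu, intercept_se=mu_se, effect_size=es,
        effect_size_method=effect_size, vc=vc,
        converged=bool(getattr(result, "converged", True)),
        method="mixedlm_vc", trace=tuple(trace),
        n_subjects=table["subject"].nunique(), n_rois=table["roi"].nunique(),
        n_obs=len(table), fixed_effects=fixed)


class NetworkLMM(BaseEstimator):
    """Crossed mixed-effects model of one network's PSC table.

    ``fit`` expects a long-format table with columns ``subject``, ``roi``,
    ``condition_code`` (+-0.5) and ``psc``; the fitted summary is exposed as
    ``fit_`` (a :class:`MixedModelFit`) plus flat attributes ``beta_``,
    ``se_``, ``t_``, ``df_``, ``p_``.
    """

    def __init__(self, effect_size: str = "d_from_t", alpha: float = 0.05,
                 allow_single_roi: bool = False):
        self.effect_size = effect_size
        self.alpha = alpha
        self.allow_single_roi = allow_single_roi

    def fit(self, table: pd.DataFrame) -> "NetworkLMM":
        t = table
        if "condition_code" not in t.columns:
            t = deviation_code(t)
        codes = set(np.round(t["condition_code"].unique(), 6))
        if codes != {-0.5, 0.5}:
            raise ValueError(f"condition_code must be deviation-coded ±0.5, got {sorted(codes)}")
        if t["subject"].nunique() < 2:
            raise ValueError("need at least 2 subjects")
        if t["roi"].nunique() < 2 and not self.allow_single_roi:
            raise ValueError("need at least 2 ROIs (or allow_single_roi=True)")
        if _is_balanced(t):
            self.fit_ = _fit_balanced(t, self.effect_size, self.alpha)
        else:
            self.fit_ = _fit_mixedlm(t, self.effect_size,
                                     "psc ~ condition_code", "condition_code",
                                     self.alpha)
        f = self.fit_
        self.beta_, self.se_, self.t_, self.df_, self.p_ = f.beta, f.se, f.t, f.df, f.p
        return self


def fit_network_lmm(table: pd.DataFrame, effect_size: str = "d_from_t",
                    alpha: float = 0.05, allow_single_roi: bool = False) -> MixedModelFit:
    return NetworkLMM(effect_size, alpha, allow_single_roi).fit(table).fit_


def fit_interaction_lmm(table: pd.DataFrame, alpha: float = 0.05) -> MixedModelFit:
    """Condition x network interaction across two networks' PSC tables.

    The network factor is deviation-coded over its two (sorted) labels.  For
    complete balanced tables the closed-form REML path is used with the
    network fixed effect absorbed into per-network ROI means; otherwise the
    statsmodels fallback fits ``psc ~ condition_code * network_code``.
    """
    nets = sorted(table["network"].unique())
    if len(nets) != 2:
        raise ValueError(f"need exactly two networks, got {nets}")
    t = table.copy()
    if "condition_code" not in t.columns:
        t = deviation_code(t)
    t["network_code"] = t["network"].map({nets[0]: -0.5, nets[1]: 0.5})
    # ROIs must be unique across networks for the crossed structure
    per_roi_nets = t.groupby("roi")["network"].nunique()
    if (per_roi_nets > 1).any():
        raise ValueError("a roi id appears in both networks; make ids unique")
    if _is_balanced(t):
        return _fit_interaction_balanced(t, nets, alpha)
    return _fit_mixedlm(t, "d_from_t", "psc ~ condition_code * network_code",
                        "condition_code:network_code", alpha)


def _fit_interaction_balanced(t: pd.DataFrame, nets: list[str],
                              alpha: float) -> MixedModelFit:
    D, M, subjects, rois = _cube(t)
    S, R = D.shape
    net_of_roi = t.drop_duplicates("roi").set_index("roi")["network"]
    groups = np.array([0 if net_of_roi[r] == nets[0] else 1 for r in rois])
    n_a, n_b = int((groups == 1).sum()), int((groups == 0).sum())  # +0.5 / -0.5
    if min(n_a, n_b) < 1:
        raise ValueError("each network needs at least one ROI")
    theta, strata, ok = _reml_crossed(D, M, groups)
    va, vb, vg, vh, s2 = theta
    d_pos = D[:, groups == 1].mean()
    d_neg = D[:, groups == 0].mean()
    beta_int = float(d_pos - d_neg)
    inv = 1.0 / n_a + 1.0 / n_b
    var_int = vh * inv + 2 * s2 * inv / S
    g_int = np.array([0, 0, 0, inv, 2 * inv / S])
    df = _satterthwaite(g_int, var_int, theta, strata)
    se = float(np.sqrt(var_int))
    tval, p, lo, hi = _t_inference(beta_int, se, df, alpha)
    beta_cond = float((d_pos + d_neg) / 2.0)
    var_cond = vb / S + var_int / 4.0
    g_cond = np.array([0, 1.0 / S, 0, 0, 0]) + g_int / 4.0
    df_cond = _satterthwaite(g_cond, var_cond, theta, strata)
    t_c, p_c, *_ = _t_inference(beta_cond, np.sqrt(var_cond), df_cond, alpha)
    fixed = {
        "condition_code:network_code": dict(beta=beta_int, se=se, t=tval, df=df, p=p),
        "condition_code": dict(beta=beta_cond, se=float(np.sqrt(var_cond)),
                               t=t_c, df=df_cond, p=p_c),
    }
    return MixedModelFit(
        term="condition_code:network_code", beta=beta_int, se=se, t=tval,
        df=df, p=p, ci_low=lo, ci_high=hi, intercept=float(M.mean()),
        intercept_se=np.nan, effect_size=np.nan, effect_size_method="none",
        vc=dict(zip(_VC_NAMES, (float(x) for x in theta))), converged=ok,
        method="balanced_reml", trace=_trace_from_theta(theta, strata[4]),
        n_subjects=S, n_rois=R, n_obs=len(t), fixed_effects=fixed)


def fit_roi_models(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-ROI paired comparison with Benjamini-Hochberg correction.

    Each ROI is tested by a paired t on the per-subject condition difference
    (the within-ROI mixed model collapses to exactly this when every subject
    contributes one value per condition); FDR is controlled across the ROIs
    of each network.
    """
    from statsmodels.stats.multitest import multipletests

    t = table if "condition_code" in table.columns else deviation_code(table)
    rows = []
    for (net, roi), sub in t.groupby(["network", "roi"], sort=True):
        per = sub.groupby(["subject", "condition_code"])["psc"].mean().unstack()
        if per.shape[1] != 2 or len(per) < 2:
            continue
        diff = (per[0.5] - per[-0.5]).dropna()
        n = len(diff)
        sd = diff.std(ddof=1)
        se = sd / np.sqrt(n) if sd > 0 else 0.0
        tval, p, *_ = _t_inference(float(diff.mean()), float(se), n - 1, alpha)
        rows.append({"network": net, "roi": roi, "n_subjects": n,
                     "beta": float(diff.mean()), "se": float(se), "t": tval,
                     "df": n - 1, "p": p,
                     "d_z": float(diff.mean() / sd) if sd > 0 else np.nan})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_fdr"] = np.nan
    for net, idx in out.groupby("network").groups.items():
        out.loc[idx, "p_fdr"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_fdr"] < alpha
    return out


def network_overlap(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Set-overlap statistics between two parcel atlases on the same grid."""
    if labels_a.shape != labels_b.shape:
        raise ValueError("atlases are not on the same grid")
    a = np.asarray(labels_a) > 0
    b = np.asarray(labels_b) > 0
    inter = int((a & b).sum())
    na, nb = int(a.sum()), int(b.sum())
    dice = 2.0 * inter / (na + nb) if (na + nb) else np.nan
    union = int((a | b).sum())
    jacc = inter / union if union else np.nan
    per_parcel = []
    for pid in range(1, int(np.asarray(labels_a).max()) + 1):
        pm = labels_a == pid
        n = int(pm.sum())
        per_parcel.append({"parcel_id": pid, "n_vox": n,
                           "overlap_fraction": float((pm & b).sum() / n) if n else np.nan})
    return {"dice": dice, "jaccard": jacc, "shared_voxels": inter,
            "n_vox_a": na, "n_vox_b": nb,
            "per_parcel": pd.DataFrame(per_parcel)}


def localizer_scope_effect(cv_table: pd.DataFrame,
                           codes: dict[str, float] | None = None,
                           effect_size: str = "d_from_t") -> MixedModelFit:
    """Task > control contrast of a localizer from its cross-validated PSC
    table, fitted with the same network-level machinery (single-ROI tables
    collapse exactly to the paired mean difference)."""
    t = deviation_code(cv_table, codes=codes)
    return fit_network_lmm(t, effect_size=effect_size, allow_single_roi=True)
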