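"""Group-level inference on aggregated reaching metrics.

Three analyses mirror the study design:

* a fully within-subject three-way repeated-measures ANOVA (direction x
  side x time) per quality metric, with Mauchly's sphericity test per
  multi-level effect and Greenhouse-Geisser-corrected degrees of freedom
  applied when sphericity is rejected;
* a linear mixed-effects model for the participant-pooled mediolateral
  displacement proportion, with side, time, and their interaction as fixed
  effects and a participant random intercept (REML fit, Satterthwaite
  denominator degrees of freedom);
* a paired t test on the clinical scores at admission vs discharge.

The ANOVA is computed from first principles as a balanced within-subject
sum-of-squares decomposition (inclusion-exclusion over marginal means);
each within effect is tested against its interaction with subjects.  The
decomposition conserves the total sum of squares exactly, which is asserted
on every run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

__all__ = [
    "SphericityResult",
    "AnovaResult",
    "LmmResult",
    "PairedTResult",
    "aggregate",
    "rm_anova_3way",
    "fit_lmm_proportion",
    "paired_t",
]

QUALITY_METRICS = ("movement_time_ms", "path_length_cm", "n_velocity_peaks")


# ---------------------------------------------------------------------------
# Aggregation


def aggregate(metrics: pd.DataFrame, analysis_arm: str) -> pd.DataFrame:
    """Collapse per-trial metrics to the design cells.

    ``analysis_arm="quality"``: per (participant, side, timepoint,
    direction) means of movement time, path length, and velocity-peak count
    over quality-qualified trials.

    ``analysis_arm="quantity"``: one pooled mediolateral-proportion value
    per (participant, side, timepoint); participants with no qualified
    trial or zero pooled displacement yield a missing (NaN) row rather than
    being dropped silently.
    """
    if analysis_arm == "quality":
        rows = metrics[metrics["quality_included"]]
        cells = (
            rows.groupby(
                ["participant", "side", "timepoint", "direction"], observed=True
            )[list(QUALITY_METRICS)]
            .mean()
            .reset_index()
        )
        return cells
    if analysis_arm == "quantity":
        rows = metrics[metrics["quantity_included"]]
        sums = (
            rows.groupby(["participant", "side", "timepoint"], observed=True)[
                ["ap_total_cm", "ml_total_cm"]
            ]
            .sum(min_count=1)
            .reset_index()
        )
        total = sums["ap_total_cm"] + sums["ml_total_cm"]
        with np.errstate(invalid="ignore", divide="ignore"):
            sums["ml_pct"] = np.where(
                total > 0, 100.0 * sums["ml_total_cm"] / total, np.nan
            )
        # Re-attach design cells that produced no qualified trial at all.
        full = (
            metrics[["participant", "side", "timepoint"]]
            .drop_duplicates()
            .merge(sums, how="left", on=["participant", "side", "timepoint"])
        )
        return full
    raise ValueError("analysis_arm must be 'quality' or 'quantity'")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


@dataclass(frozen=True)
class SphericityResult:
    mauchly_w: float
    p_value: float
    gg_epsilon: float


@dataclass
class AnovaResult:
    """Effect table of the within-subject ANOVA plus diagnostics."""

    metric: str
    table: pd.DataFrame
    n_subjects: int
    ss_total: float
    ss_accounted: float
    alpha: float = 0.05

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _ss_decomposition(y: np.ndarray) -> Dict[Tuple[int, ...], float]:
    """Balanced ANOVA sums of squares for every factor subset.

    ``y`` has one observation per cell; axis 0 is the subject factor.  For
    a subset T of axes, the marginal-mean sum of squares f(T) is reduced by
    every proper subset's SS (inclusion-exclusion), yielding effect SS that
    sum exactly to the total SS.
    """
    axes = tuple(range(y.ndim))
    grand = y.mean()
    n_total = y.size
    ss: Dict[Tuple[int, ...], float] = {(): 0.0}
    for r in range(1, len(axes) + 1):
        for t in itertools.combinations(axes, r):
            other = tuple(a for a in axes if a not in t)
            m = y.mean(axis=other) if other else y
            reps = n_total // m.size
            f_t = reps * float(((m - grand) ** 2).sum())
            ss[t] = f_t - sum(
                ss[u] for rr in range(r) for u in itertools.combinations(t, rr)
            )
    return ss


def _effect_df(shape: Sequence[int], t: Tuple[int, ...]) -> int:
    df = 1
    for a in t:
        df *= shape[a] - 1
    return df


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1) x levels orthonormal contrast matrix (rows sum to zero)."""
    return sla.helmert(levels, full=False)


def _effect_scores(y: np.ndarray, effect_axes: Tuple[int, ...]) -> np.ndarray:
    """Per-subject contrast scores for a within effect.

    Within axes in the effect are contrasted (orthonormal Helmert rows),
    the remaining within axes are averaged; the Kronecker product of those
    row blocks maps each subject's flattened cell vector to the effect's
    score vector.
    """
    n = y.shape[0]
    k = np.ones((1, 1))
    for axis in range(1, y.ndim):
        levels = y.shape[axis]
        block = (
            _orthonormal_contrasts(levels)
            if axis in effect_axes
            else np.full((1, levels), 1.0 / levels)
        )
        k = np.kron(k, block)
    flat = y.reshape(n, -1)
    return flat @ k.T


def _sphericity(scores: np.ndarray) -> SphericityResult:
    """Mauchly's W and the Greenhouse-Geisser epsilon from effect scores."""
    n, q = scores.shape
    if q < 2:
        return SphericityResult(mauchly_w=np.nan, p_value=np.nan, gg_epsilon=1.0)
    s = np.cov(scores, rowvar=False, ddof=1)
    tr = float(np.trace(s))
    tr2 = float(np.trace(s @ s))
    eps = tr**2 / (q * tr2) if tr2 > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / q, 1.0))
    f = n - 1
    if f <= q or tr <= 0:
        # Covariance singular by construction; the test is undefined.
        return SphericityResult(mauchly_w=np.nan, p_value=np.nan, gg_epsilon=eps)
    sign, logdet = np.linalg.slogdet(s)
    if sign <= 0:
        return SphericityResult(mauchly_w=np.nan, p_value=np.nan, gg_epsilon=eps)
    log_w = logdet - q * np.log(tr / q)
    w = float(np.exp(log_w))
    d = 1.0 - (2.0 * q * q + q + 2.0) / (6.0 * q * f)
    chi2 = -f * d * log_w
    df = q * (q + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return SphericityResult(mauchly_w=w, p_value=p, gg_epsilon=eps)


def _pivot_complete(
    table: pd.DataFrame,
    metric: str,
    subject: str,
    within: Sequence[str],
    level_orders: Optional[Dict[str, Sequence]] = None,
) -> Tuple[np.ndarray, List[str], Dict[str, List]]:
    level_orders = level_orders or {}
    levels = {
        f: list(level_orders.get(f, sorted(table[f].unique(), key=str)))
        for f in within
    }
    subjects = sorted(table[subject].unique(), key=str)
    piv = table.set_index([subject, *within])[metric]
    if piv.index.has_duplicates:
        raise ValueError("more than one row per design cell")
    shape = (len(subjects), *(len(levels[f]) for f in within))
    y = np.full(shape, np.nan)
    idx = {
        f: {lv: i for i, lv in enumerate(levels[f])} for f in within
    }
    sub_idx = {s: i for i, s in enumerate(subjects)}
    for key, value in piv.items():
        s, *ws = key
        y[(sub_idx[s], *(idx[f][w] for f, w in zip(within, ws)))] = value
    if np.isnan(y).any():
        missing = []
        it = np.argwhere(np.isnan(y))
        for row in it[:10]:
            s = subjects[row[0]]
            cell = {f: levels[f][row[j + 1]] for j, f in enumerate(within)}
            missing.append(f"{subject}={s}, {cell}")
        raise ValueError(
            "incomplete within-subject design; missing cells: "
            + "; ".join(missing)
        )
    return y, subjects, levels


def rm_anova_3way(
    table: pd.DataFrame,
    metric: str,
    subject: str = "participant",
    within: Sequence[str] = ("direction", "side", "timepoint"),
    alpha: float = 0.05,
    level_orders: Optional[Dict[str, Sequence]] = None,
) -> AnovaResult:
    """Fully within-subject repeated-measures ANOVA.

    Requires a complete subject x within-cells design (one cell mean per
    combination); incomplete designs are rejected listing the missing
    cells.  Each within effect is tested against its interaction with
    subjects; Mauchly's sphericity test runs per multi-level effect and the
    Greenhouse-Geisser correction is applied to the degrees of freedom when
    Mauchly's P falls below ``alpha``.
    """
    y, subjects, levels = _pivot_complete(
        table, metric, subject, within, level_orders
    )
    n = y.shape[0]
    if n < 2:
        raise ValueError("at least two subjects are required")
    ss = _ss_decomposition(y)
    shape = y.shape
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_accounted = float(sum(v for k, v in ss.items() if k))

    rows = []
    within_axes = tuple(range(1, y.ndim))
    for r in range(1, len(within_axes) + 1):
        for t in itertools.combinations(within_axes, r):
            name = " x ".join(within[a - 1] for a in t)
            err = (0, *t)
            df1 = _effect_df(shape, t)
            df2 = _effect_df(shape, err)
            ms1 = ss[t] / df1
            ms2 = ss[err] / df2
            f_stat = ms1 / ms2 if ms2 > 0 else np.inf
            p_unc = float(stats.f.sf(f_stat, df1, df2))
            sph = _sphericity(_effect_scores(y, t))
            corrected = (
                df1 > 1
                and np.isfinite(sph.p_value)
                and sph.p_value < alpha
            )
            if corrected:
                df1_r = df1 * sph.gg_epsilon
                df2_r = df2 * sph.gg_epsilon
                p = float(stats.f.sf(f_stat, df1_r, df2_r))
            else:
                df1_r, df2_r, p = float(df1), float(df2), p_unc
            rows.append(
                {
                    "effect": name,
                    "ss_effect": ss[t],
                    "ss_error": ss[err],
                    "df1": df1_r,
                    "df2": df2_r,
                    "F": f_stat,
                    "p": p,
                    "p_uncorrected": p_unc,
                    "df1_uncorrected": df1,
                    "df2_uncorrected": df2,
                    "mauchly_w": sph.mauchly_w,
                    "mauchly_p": sph.p_value,
                    "gg_epsilon": sph.gg_epsilon,
                    "correction_applied": corrected,
                    "significant": p < alpha,
                }
            )
    result = AnovaResult(
        metric=metric,
        table=pd.DataFrame(rows),
        n_subjects=n,
        ss_total=ss_total,
        ss_accounted=ss_accounted,
        alpha=alpha,
    )
    if not np.isclose(ss_total, ss_accounted, rtol=1e-8, atol=1e-8):
        raise AssertionError(
            f"sum-of-squares decomposition does not conserve the total "
            f"({ss_accounted} vs {ss_total})"
        )
    return result


# ---------------------------------------------------------------------------
# Linear mixed-effects model (random intercept, REML, Satterthwaite df)


@dataclass
class LmmResult:
    """Fixed-effect tests and variance components of the proportion model."""

    table: pd.DataFrame
    var_participant: float
    var_residual: float
    loglik: float
    n_obs: int
    n_groups: int
    singular: bool
    method: str = "REML + Satterthwaite"

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _design_sum_coded(df: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    """Sum-to-zero (effects-coded) design for side * time: intercept, side,
    time, side x time.  Single-df effects, so each F test is t squared."""
    side = np.where(df["side"] == "more_affected", 1.0, -1.0)
    time = np.where(df["timepoint"] == "discharge", 1.0, -1.0)
    x = np.column_stack([np.ones(len(df)), side, time, side * time])
    return x, ["intercept", "side", "timepoint", "side x timepoint"]


def _reml_quantities(
    theta: np.ndarray, x: np.ndarray, z: np.ndarray, y: np.ndarray
):
    sb, se = theta
    n = len(y)
    v = se * np.eye(n) + sb * (z @ z.T)
    vi = np.linalg.inv(v)
    xtvx = x.T @ vi @ x
    c = np.linalg.inv(xtvx)
    beta = c @ x.T @ vi @ y
    r = y - x @ beta
    _, logdet_v = np.linalg.slogdet(v)
    _, logdet_x = np.linalg.slogdet(xtvx)
    ll = -0.5 * (logdet_v + logdet_x + float(r @ vi @ r))
    return ll, beta, c, vi

def _satterthwaite(
    x: np.ndarray, z: np.ndarray, theta: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Coefficient variances and Satterthwaite dfs for each fixed effect.

    Uses the expected information of the variance components,
    I_jk = tr(P dV_j P dV_k) / 2 with P the REML projection, and the delta
    method on g_j = d Var(beta_i)/d theta_j.
    """
    n = x.shape[0]
    sb, se = theta
    zzt = z @ z.T
    v = se * np.eye(n) + sb * zzt
    vi = np.linalg.inv(v)
    c = np.linalg.inv(x.T @ vi @ x)
    p = vi - vi @ x @ c @ x.T @ vi
    dv = [zzt, np.eye(n)]
    info = np.empty((2, 2))
    for j in range(2):
        for k in range(2):
            info[j, k] = 0.5 * float(np.trace(p @ dv[j] @ p @ dv[k]))
    try:
        cov_theta = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(info)
    var_beta = np.diag(c)
    dfs = np.empty(x.shape[1])
    for i in range(x.shape[1]):
        cl = c[:, i]  # C @ unit vector for coefficient i
        b = vi @ (x @ cl)
        g = np.array([float(b @ (dv[j] @ b)) for j in range(2)])
        denom = float(g @ cov_theta @ g)
        dfs[i] = 2.0 * var_beta[i] ** 2 / denom if denom > 0 else np.inf
    return var_beta, dfs


def fit_lmm_proportion(table: pd.DataFrame, alpha: float = 0.05) -> LmmResult:
    """Random-intercept model for the mediolateral proportion.

    ``table`` needs columns participant, side, timepoint, ml_pct; rows with
    missing ml_pct are dropped (the model tolerates unbalanced data without
    discarding whole participants).  Fixed effects side, time, and side x
    time are effects-coded; the fit is REML via statsmodels MixedLM and
    each fixed effect gets an F test (= squared t) with a Satterthwaite
    denominator df.  An all-but-zero random-intercept variance is flagged
    as a singular fit.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = table.dropna(subset=["ml_pct"]).reset_index(drop=True)
    groups = df["participant"].astype(str)
    counts = groups.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError(
            "need at least two participants with two or more observations"
        )
    y = df["ml_pct"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("all responses are identical; the model is degenerate")
    x, names = _design_sum_coded(df)
    model = MixedLM(y, x, groups=groups.to_numpy())
    fit = None
    # Gradient-based optimizers can fail when the random-intercept variance
    # collapses toward the boundary; fall back to derivative-free searches.
    for method in ("lbfgs", "powell", "nm"):
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True, method=method, maxiter=500)
            break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if fit is None:
        raise ValueError("mixed-model fit failed with every optimizer")
    var_b = float(np.asarray(fit.cov_re)[0, 0])
    var_e = float(fit.scale)
    singular = var_b < 1e-8 * max(var_e, 1e-12)

    z = pd.get_dummies(groups).to_numpy(dtype=float)
    theta = np.array([max(var_b, 1e-10), var_e])
    ll, beta, c, _ = _reml_quantities(theta, x, z, y)
    var_beta, dfs = _satterthwaite(x, z, theta)

    rows = []
    for i, name in enumerate(names):
        if name == "intercept":
            continue
        se_i = float(np.sqrt(var_beta[i]))
        f_stat = float(beta[i] ** 2 / var_beta[i])
        p = float(stats.f.sf(f_stat, 1, dfs[i]))
        rows.append(
            {
                "effect": name,
                "estimate": float(beta[i]),
                "se": se_i,
                "F": f_stat,
                "df1": 1.0,
                "df2": float(dfs[i]),
                "p": p,
                "significant": p < alpha,
            }
        )
    return LmmResult(
        table=pd.DataFrame(rows),
        var_participant=var_b,
        var_residual=var_e,
        loglik=float(ll),
        n_obs=len(df),
        n_groups=int(groups.nunique()),
        singular=singular,
    )


# ---------------------------------------------------------------------------
# Paired t test


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_difference: float


def paired_t(
    scores_admission: Sequence[float], scores_discharge: Sequence[float]
) -> PairedTResult:
    """Classical paired t test on discharge - admission differences."""
    adm = np.asarray(scores_admission, dtype=float)
    dis = np.asarray(scores_discharge, dtype=float)
    if adm.shape != dis.shape or adm.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = adm.size
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = dis - adm
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero variance of the paired differences; t is undefined")
    res = stats.ttest_rel(dis, adm)
    return PairedTResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        mean_difference=float(diff.mean()),
    )
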