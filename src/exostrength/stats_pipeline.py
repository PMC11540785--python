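"""Inferential chain: screening, selection, OLS, effect size, power,
and bootstrap-with-noise robustness.

The modelling target is the composite strength index
(``total_performance``); candidate predictors are the 27 exercise
performance metrics. The chain is:

1. Shapiro–Wilk normality screen on every candidate metric;
2. single-predictor residual diagnostics (residual normality via
   Shapiro–Wilk, homoscedasticity via Breusch–Pagan);
3. redundancy pruning: hierarchical clustering of the survivors on the
   distance 1 − |r| and one representative per cluster (the metric most
   correlated with the target);
4. multivariable OLS reported as unstandardized coefficients B with SE,
   standardized coefficients beta, multiple R, adjusted R², Cohen's
   f² = R²/(1−R²), and post-hoc power of the overall F test
   (noncentral F with noncentrality λ = f²·n);
5. bootstrap validation: resample rows with replacement to a target
   size, perturb variables with SD-proportional Gaussian noise,
   recompute the dependent variable with the *frozen* original z-score
   moments, refit, and summarize R and adjusted R² across repeats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from .muscle_parameters import COMPOSITE_VARS, CohortStandardizer

log = logging.getLogger(__name__)


@dataclass
class SelectionCriteria:
    """Thresholds of the variable-screening pipeline."""

    normality_alpha: float = 0.05
    residual_alpha: float = 0.05
    linearity_threshold: float = 0.7  # |r| bound between predictors
    cluster_linkage: str = "average"
    representative_rule: str = "max_target_corr"

    def __post_init__(self) -> None:
        for a in (self.normality_alpha, self.residual_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError("alphas must be in (0, 1)")
        if not (0.0 < self.linearity_threshold <= 1.0):
            raise ValueError("linearity_threshold must be in (0, 1]")
        if self.cluster_linkage not in ("average", "complete", "single"):
            raise ValueError(f"unsupported linkage {self.cluster_linkage!r}")


@dataclass
class RegressionModel:
    """Fitted multivariable OLS, Table-style report fields."""

    target_name: str
    predictor_names: list[str]
    B: np.ndarray  # intercept first, then per-predictor coefficients
    SE: np.ndarray  # same layout
    beta: np.ndarray  # standardized, per predictor (no intercept)
    R: float
    r2: float
    adj_r2: float
    f2: float
    power: float
    p_overall: float
    p_per_term: np.ndarray  # intercept first
    n: int

    def summary_frame(self) -> pd.DataFrame:
        terms = ["(Constant)"] + list(self.predictor_names)
        betas = [math.nan] + list(self.beta)
        return pd.DataFrame(
            {"term": terms, "B": self.B, "SE": self.SE, "beta": betas,
             "p": self.p_per_term}
        )


@dataclass
class BootstrapSpec:
    """One cell of the bootstrap-robustness grid."""

    n_resamples: int = 100
    noise_fraction: float = 0.10
    n_repeats: int = 200
    include_demographics: bool = False  # add sex (male=1/female=0) and age
    resample: bool = True
    noise_order: str = "after"  # noise added before/after resampling
    noise_scope: str = "all"  # "all" or "predictors_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_fraction < 1.0):
            raise ValueError("noise_fraction must be in [0, 1)")
        if self.n_resamples < 2 or self.n_repeats < 1:
            raise ValueError("n_resamples >= 2 and n_repeats >= 1 required")
        if self.noise_order not in ("before", "after"):
            raise ValueError("noise_order must be 'before' or 'after'")
        if self.noise_scope not in ("all", "predictors_only"):
            raise ValueError("noise_scope must be 'all' or 'predictors_only'")


@dataclass
class BootstrapResult:
    mean_R: float
    sd_R: float
    mean_adj_r2: float
    sd_adj_r2: float
    R_values: np.ndarray
    adj_r2_values: np.ndarray
    spec: BootstrapSpec


@dataclass
class ClusteringResult:
    columns: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    labels: dict[str, int]  # column -> flat cluster id


def normality_test(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p for one sample (3 <= n <= 5000)."""
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro–Wilk needs 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = st.shapiro(x)
    return float(w), float(p)


def correlation_matrix(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix.

    Cells with fewer than ``min_pairs`` complete pairs are left missing
    with a warning.
    """
    num = table.select_dtypes(include=[np.number])
    corr = num.corr(method="pearson", min_periods=min_pairs)
    missing = corr.isna().sum().sum() - np.isnan(np.diag(corr.to_numpy())).sum()
    if missing:
        log.warning("correlation matrix has %d cells with < %d complete pairs",
                    int(missing), min_pairs)
    return corr


def cluster_metrics(corr: pd.DataFrame, criteria: SelectionCriteria) -> ClusteringResult:
    """Agglomerative clustering on distance 1 − |r|.

    Flat clusters are cut at distance 1 − ``linearity_threshold``, so two
    metrics sharing |r| above the threshold always co-cluster.
    """
    cols = list(corr.columns)
    if len(cols) == 1:
        return ClusteringResult(cols, np.empty((0, 4)), cols, {cols[0]: 1})
    dist = 1.0 - np.abs(corr.to_numpy())
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce symmetry
    condensed = squareform(dist, checks=False)
    Z = sch.linkage(condensed, method=criteria.cluster_linkage)
    cut = 1.0 - criteria.linearity_threshold
    flat = sch.fcluster(Z, t=cut, criterion="distance")
    order = [cols[i] for i in sch.leaves_list(Z)]
    return ClusteringResult(cols, Z, order, dict(zip(cols, (int(c) for c in flat))))


def residual_diagnostics(residuals, exog) -> tuple[float, float]:
    """Residual normality (Shapiro–Wilk p) and homoscedasticity
    (Breusch–Pagan p) for a fitted model.

    ``exog`` is the design matrix including the constant. Raises on
    numerically degenerate residuals (e.g. an exact linear fit).
    """
    resid = np.asarray(residuals, dtype=float)
    exog = np.asarray(exog, dtype=float)
    scale = float(np.abs(resid).max(initial=0.0))
    if scale < 1e-10 or np.ptp(resid) < 1e-12:
        raise ValueError("degenerate residuals: no stochastic error to test")
    _, shapiro_p = st.shapiro(resid)
    _, bp_p, _, _ = het_breuschpagan(resid, exog)
    return float(shapiro_p), float(bp_p)


def posthoc_power(f2: float, n: int, n_predictors: int, alpha: float = 0.05) -> float:
    """Power of the overall F test at effect size f².

    Noncentral F with u = n_predictors numerator df,
    v = n − u − 1 denominator df, noncentrality λ = f²·n.
    """
    if f2 < 0:
        raise ValueError("f2 must be >= 0")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    u = int(n_predictors)
    v = int(n) - u - 1
    if u < 1 or v < 1:
        raise ValueError(f"invalid degrees of freedom u={u}, v={v}")
    crit = st.f.isf(alpha, u, v)
    if f2 == 0.0:
        return alpha
    return float(st.ncf.sf(crit, u, v, f2 * n))


def fit_ols(table: pd.DataFrame, target_name: str, predictors: list[str]) -> RegressionModel:
    """Multivariable OLS with the full Table-style report.

    Rows with any missing value among the used columns are dropped
    (listwise). Raises on rank-deficient designs or n <= p + 1.
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    cols = [target_name] + list(predictors)
    data = table[cols].dropna()
    n, p = len(data), len(predictors)
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors")
    y = data[target_name].to_numpy(dtype=float)
    X = data[list(predictors)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        bad = [
            f"{predictors[i]}~{predictors[j]}"
            for i in range(p) for j in range(i + 1, p)
            if p > 1 and abs(corr[i, j]) > 0.9999
        ]
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear: {bad or predictors}"
        )
    fit = sm.OLS(y, design).fit()
    sd_y = float(np.std(y, ddof=1))
    sd_x = np.std(X, axis=0, ddof=1)
    beta = fit.params[1:] * sd_x / sd_y
    r2 = float(max(fit.rsquared, 0.0))
    R = math.sqrt(r2)
    f2 = r2 / (1.0 - r2) if r2 < 1.0 else math.inf
    power = posthoc_power(f2, n, p) if math.isfinite(f2) else 1.0
    return RegressionModel(
        target_name=target_name,
        predictor_names=list(predictors),
        B=np.asarray(fit.params),
        SE=np.asarray(fit.bse),
        beta=np.asarray(beta),
        R=R,
        r2=r2,
        adj_r2=float(fit.rsquared_adj),
        f2=float(f2),
        power=power,
        p_overall=float(fit.f_pvalue) if p >= 1 else math.nan,
        p_per_term=np.asarray(fit.pvalues),
        n=n,
    )


@dataclass
class SelectionAudit:
    column: str
    stage: str  # "normality" | "residuals" | "cluster" | "kept"
    detail: str


def select_variables(
    table: pd.DataFrame,
    target_name: str,
    criteria: SelectionCriteria | None = None,
    candidates: list[str] | None = None,
) -> tuple[list[str], list[SelectionAudit]]:
    """Screen candidate metrics down to an admissible predictor set.

    Stage 1 drops non-normal metrics; stage 2 drops metrics whose
    single-predictor regression on the target fails residual normality
    or homoscedasticity; stage 3 clusters the survivors at the
    |r| threshold and keeps one representative per cluster (highest
    |corr| with the target, ties alphabetical). Every decision is
    recorded in the audit trail. An empty survivor set is a valid
    result, not an error.
    """
    criteria = criteria or SelectionCriteria()
    if target_name not in table.columns:
        raise KeyError(f"target {target_name!r} not in table")
    if candidates is None:
        candidates = [
            c for c in table.select_dtypes(include=[np.number]).columns
            if c != target_name
        ]
    audit: list[SelectionAudit] = []
    survivors: list[str] = []

    for col in candidates:
        vals = table[col].dropna()
        try:
            _, p = normality_test(vals)
        except ValueError as exc:
            audit.append(SelectionAudit(col, "normality", f"untestable: {exc}"))
            continue
        if p <= criteria.normality_alpha:
            audit.append(SelectionAudit(col, "normality", f"p={p:.4g} <= alpha"))
        else:
            survivors.append(col)

    stage2: list[str] = []
    for col in survivors:
        pair = table[[target_name, col]].dropna()
        if len(pair) < 4:
            audit.append(SelectionAudit(col, "residuals", "too few complete rows"))
            continue
        X = sm.add_constant(pair[col].to_numpy(dtype=float))
        fit = sm.OLS(pair[target_name].to_numpy(dtype=float), X).fit()
        try:
            sh_p, bp_p = residual_diagnostics(fit.resid, X)
        except ValueError as exc:
            audit.append(SelectionAudit(col, "residuals", str(exc)))
            continue
        if sh_p <= criteria.residual_alpha or bp_p <= criteria.residual_alpha:
            audit.append(
                SelectionAudit(col, "residuals",
                               f"shapiro_p={sh_p:.4g}, bp_p={bp_p:.4g}")
            )
        else:
            stage2.append(col)

    if not stage2:
        return [], audit

    if len(stage2) == 1:
        audit.append(SelectionAudit(stage2[0], "kept", "sole survivor"))
        return stage2, audit

    corr = correlation_matrix(table[stage2])
    clusters = cluster_metrics(corr, criteria)
    target_corr = {
        col: abs(float(table[[target_name, col]].dropna().corr().iloc[0, 1]))
        for col in stage2
    }
    kept: list[str] = []
    by_cluster: dict[int, list[str]] = {}
    for col in stage2:
        by_cluster.setdefault(clusters.labels[col], []).append(col)
    for cid in sorted(by_cluster):
        members = sorted(by_cluster[cid])
        # members sorted alphabetically and max() keeps the first maximum,
        # so exact ties break to the alphabetically first name
        rep = max(members, key=lambda c: target_corr[c])
        kept.append(rep)
        audit.append(SelectionAudit(rep, "kept", f"cluster {cid} representative"))
        for m in members:
            if m != rep:
                audit.append(
                    SelectionAudit(m, "cluster",
                                   f"redundant with {rep} (cluster {cid})")
                )
    return kept, audit


def bootstrap_validate(
    table: pd.DataFrame,
    target_name: str,
    predictors: list[str],
    spec: BootstrapSpec,
    std: CohortStandardizer,
) -> BootstrapResult:
    """Bootstrap-with-noise robustness of one regression model.

    Per repeat: resample rows with replacement to ``n_resamples``,
    add independent Gaussian noise with SD = noise_fraction × the
    *original* per-column SD to every predictor and every raw dependent
    component, recompute the dependent variable with the frozen z-score
    moments, and refit. ``table`` must carry the raw composite columns
    (vj, rm_le_lc_weight, iso_le_lc_weight) alongside the predictors,
    plus ``sex_male``/``age`` when demographics are requested.
    """
    needed = list(predictors) + list(COMPOSITE_VARS)
    use_predictors = list(predictors)
    if spec.include_demographics:
        needed += ["sex_male", "age"]
        use_predictors += ["sex_male", "age"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks required columns: {missing}")
    base = table[list(dict.fromkeys(needed))].dropna().reset_index(drop=True)

    noisy_cols = list(predictors) + list(COMPOSITE_VARS)
    if spec.noise_scope == "predictors_only":
        noisy_cols = list(predictors)
    col_sd = {}
    for c in noisy_cols:
        sd = float(base[c].std(ddof=1))
        if sd == 0:
            raise ValueError(f"column {c!r} has zero SD; cannot scale noise")
        col_sd[c] = sd

    rng = np.random.default_rng(spec.seed)
    Rs, adjs = [], []
    for _ in range(spec.n_repeats):
        frame = base.copy()
        if spec.noise_order == "before" and spec.noise_fraction > 0:
            for c in noisy_cols:
                frame[c] = frame[c] + rng.normal(
                    0.0, spec.noise_fraction * col_sd[c], size=len(frame)
                )
        if spec.resample:
            idx = rng.integers(0, len(frame), size=spec.n_resamples)
            frame = frame.iloc[idx].reset_index(drop=True)
        if spec.noise_order == "after" and spec.noise_fraction > 0:
            for c in noisy_cols:
                frame[c] = frame[c] + rng.normal(
                    0.0, spec.noise_fraction * col_sd[c], size=len(frame)
                )
        z = sum(
            (frame[v] - std.means[v]) / std.sds[v] for v in COMPOSITE_VARS
        )
        frame[target_name] = z
        model = fit_ols(frame, target_name, use_predictors)
        Rs.append(model.R)
        adjs.append(model.adj_r2)
    Rs_arr, adjs_arr = np.asarray(Rs), np.asarray(adjs)
    return BootstrapResult(
        mean_R=float(Rs_arr.mean()),
        sd_R=float(Rs_arr.std(ddof=1)) if len(Rs_arr) > 1 else 0.0,
        mean_adj_r2=float(adjs_arr.mean()),
        sd_adj_r2=float(adjs_arr.std(ddof=1)) if len(adjs_arr) > 1 else 0.0,
        R_values=Rs_arr,
        adj_r2_values=adjs_arr,
        spec=spec,
    )
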