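"""Longitudinal trajectory modelling of HRV metrics over the mouse life course.

The central object is a tidy "longitudinal table": a DataFrame with columns
``mouse_id, age_months, state, metric, value`` holding one number per
(mouse, age, state, metric).  Murine HRV trajectories bend sharply around
21 months of age, so they are modelled in two parts (early 6-21 months,
late 21-30 months, the boundary visit belonging to both) with a quadratic
linear mixed-effects model per part:

    y_ij = (b0 + u0_i) + (b1 + u1_i) * Age + (b2 + u2_i) * Age^2 + e_ij

fitted by REML (statsmodels MixedLM).  When the data cannot support the
random quadratic term it is dropped (fixed quadratic retained); with fewer
than three distinct ages the model degrades to a random-intercept/slope
line.  The mouse-specific rate of change of a metric is the derivative of
the mouse's fitted trajectory,

    Rate_i = (b1 + u1_i) + 2 * (b2 + u2_i) * Age,

conventionally evaluated at 6 months (early period) and 24 months (late).

The module also provides the intrinsic-minus-basal "autonomic signature",
6-month baseline normalisation, loess trajectory smoothing with a 95%
band, repeated-measures (mixed) ANOVA on age, variable clustering of rates
with the 1 - |r| correlation distance, the early/late correlation-triangle
table, and the Pitman-Morgan test for equality of paired variances.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import statsmodels.api as sm
from statsmodels.stats.anova import AnovaRM

logger = logging.getLogger(__name__)

__all__ = [
    "FitFailureError",
    "LMEFit",
    "RateEstimate",
    "autonomic_signature",
    "baseline_normalize",
    "cluster_rates",
    "correlation_triangle_table",
    "fit_lme",
    "loess_trajectory",
    "mixed_anova",
    "mouse_rates",
    "pitman_morgan",
    "rate_correlations",
    "split_periods",
    "validate_longitudinal_table",
]

TABLE_COLUMNS = ("mouse_id", "age_months", "state", "metric", "value")

PERIOD_EARLY = (6.0, 21.0)
PERIOD_LATE = (21.0, 30.0)
#: conventional rate-evaluation ages (months) per period
RATE_EVAL_AGE = {"early": 6.0, "late": 24.0}

ModelForm = Literal["quadratic_full", "quadratic_fixed_only_quad", "linear"]


class FitFailureError(RuntimeError):
    """Mixed-model estimation failed at every fallback level."""


def validate_longitudinal_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy-table schema and the one-value-per-cell invariant."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"longitudinal table missing columns: {missing}")
    key = table[["mouse_id", "age_months", "state", "metric"]]
    if key.duplicated().any():
        raise ValueError("longitudinal table has duplicate (mouse, age, state, metric) cells")
    return table


def split_periods(
    table: pd.DataFrame,
    early: tuple[float, float] = PERIOD_EARLY,
    late: tuple[float, float] = PERIOD_LATE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into early (6-21 months) and late (21-30) tables; the boundary age is in both."""
    a = table["age_months"]
    return (
        table[(a >= early[0]) & (a <= early[1])].copy(),
        table[(a >= late[0]) & (a <= late[1])].copy(),
    )


# ---------------------------------------------------------------------------
# mixed-effects trajectory model


@dataclass
class LMEFit:
    """Two-part quadratic mixed-model fit for one metric/state/period."""

    metric: str
    state: str
    period: str                       # "early" | "late"
    model_form: ModelForm
    beta0: float
    beta1: float
    beta2: float                      # 0.0 for the linear form
    se_beta: np.ndarray               # SEs of (beta0, beta1, beta2) on the original age scale
    random_effects: pd.DataFrame      # columns mouse_id, b0, b1, b2 (absent terms are 0)
    cov_re: np.ndarray                # random-effect covariance (centred-age scale)
    resid_var: float
    converged: bool
    age_center: float
    n_mice: int
    n_obs: int

    def predict(self, mouse_id: str, age: float | np.ndarray) -> np.ndarray:
        """Mouse-specific fitted trajectory at the given age(s)."""
        row = self.random_effects.set_index("mouse_id").loc[mouse_id]
        b0, b1, b2 = (self.beta0 + row["b0"], self.beta1 + row["b1"], self.beta2 + row["b2"])
        a = np.asarray(age, dtype=float)
        return b0 + b1 * a + b2 * a**2


@dataclass
class RateEstimate:
    """Mouse-specific rate of change of one metric at one evaluation age."""

    mouse_id: str
    metric: str
    state: str
    period: str
    age_at_eval: float
    rate: float


def _transform_to_original_scale(g: np.ndarray, a0: float) -> np.ndarray:
    """Map quadratic coefficients in (age - a0) to coefficients in age."""
    g0, g1, g2 = g
    return np.array([g0 - g1 * a0 + g2 * a0**2, g1 - 2.0 * g2 * a0, g2])


def _fit_mixedlm(y, exog, exog_re, groups):
    """Fit by REML, trying several optimisers and keeping the best likelihood.

    Gradient optimisers sometimes stop short of their tolerance on nearly
    singular problems while Powell happily reports a boundary (zero
    variance) solution; comparing restricted log-likelihoods picks the
    better optimum rather than the first one that sets a convergence flag.
    """
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups, exog_re=exog_re)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                result = model.fit(reml=True, method=[method], maxiter=300)
            except Exception:
                continue
            if not np.all(np.isfinite(np.asarray(result.fe_params))):
                continue
            if best is None or result.llf > best.llf + 1e-8:
                best = result
            if best is not None and best.converged and method == "lbfgs":
                break
    if best is None:
        raise FitFailureError("all optimisers failed")
    return best


def _is_singular(result, tol: float = 1e-8) -> bool:
    diag = np.diag(np.atleast_2d(np.asarray(result.cov_re)))
    return bool(np.min(diag) < tol * max(result.scale, 1e-12))


def fit_lme(
    table: pd.DataFrame,
    metric: str,
    state: str,
    period: str = "early",
    allow_random_quad: bool = True,
    early: tuple[float, float] = PERIOD_EARLY,
    late: tuple[float, float] = PERIOD_LATE,
) -> LMEFit:
    """Fit the quadratic random-intercept/slope(/quadratic) model by REML.

    Fallback chain: full random quadratic -> random quadratic removed
    (fixed Age^2 retained) -> linear (with fewer than three distinct ages,
    or if the quadratic fits fail).  Age is centred at the period midpoint
    internally; reported coefficients are on the original months scale.
    """
    lo, hi = early if period == "early" else late
    sub = table[
        (table["metric"] == metric)
        & (table["state"] == state)
        & (table["age_months"] >= lo)
        & (table["age_months"] <= hi)
    ].dropna(subset=["value"])
    if sub["mouse_id"].nunique() < 5 or sub["age_months"].nunique() < 2:
        raise FitFailureError(
            f"{metric}/{state}/{period}: need >= 5 mice and >= 2 ages, have "
            f"{sub['mouse_id'].nunique()} mice / {sub['age_months'].nunique()} ages"
        )
    a0 = (lo + hi) / 2.0
    age = sub["age_months"].to_numpy(dtype=float)
    c = age - a0
    y = sub["value"].to_numpy(dtype=float)
    groups = sub["mouse_id"].to_numpy()
    mice = pd.unique(groups)

    n_ages = sub["age_months"].nunique()
    quad_ok = n_ages >= 3

    attempts: list[tuple[ModelForm, np.ndarray, np.ndarray]] = []
    x_quad = np.column_stack([np.ones_like(c), c, c**2])
    x_lin = x_quad[:, :2]
    if quad_ok and allow_random_quad:
        attempts.append(("quadratic_full", x_quad, x_quad))
    if quad_ok:
        attempts.append(("quadratic_fixed_only_quad", x_quad, x_lin))
    attempts.append(("linear", x_lin, x_lin))

    last_error: Exception | None = None
    for form, exog, exog_re in attempts:
        try:
            result = _fit_mixedlm(y, exog, exog_re, groups)
        except Exception as exc:  # singular matrices etc.
            last_error = exc
            continue
        if form == "quadratic_full" and (not result.converged or _is_singular(result)):
            continue  # random quadratic not supported by the data
        return _package_fit(result, form, metric, state, period, a0, mice, len(sub))
    raise FitFailureError(f"{metric}/{state}/{period}: no model form converged ({last_error})")


def _package_fit(result, form: ModelForm, metric, state, period, a0, mice, n_obs) -> LMEFit:
    k_fix = result.k_fe
    g = np.zeros(3)
    g[:k_fix] = np.asarray(result.fe_params)
    beta = _transform_to_original_scale(g, a0)

    # delta-method SEs on the original scale: beta = T g
    t_mat = np.array([[1.0, -a0, a0**2], [0.0, 1.0, -2.0 * a0], [0.0, 0.0, 1.0]])
    cov_g = np.zeros((3, 3))
    cov_g[:k_fix, :k_fix] = np.asarray(result.cov_params())[:k_fix, :k_fix]
    se = np.sqrt(np.maximum(np.diag(t_mat @ cov_g @ t_mat.T), 0.0))

    k_re = np.atleast_2d(np.asarray(result.cov_re)).shape[0]
    try:
        blups = result.random_effects
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effect covariance: no mouse-level variation is
        # identifiable, so the BLUPs are zero
        blups = {}
    re_rows = []
    for mouse in mice:
        u = np.zeros(3)
        if mouse in blups:
            vals = np.asarray(blups[mouse], dtype=float)
            u[: vals.size] = vals
        b = _transform_to_original_scale(u, a0)
        re_rows.append({"mouse_id": mouse, "b0": b[0], "b1": b[1], "b2": b[2]})
    re_df = pd.DataFrame(re_rows, columns=["mouse_id", "b0", "b1", "b2"])

    return LMEFit(
        metric=metric,
        state=state,
        period=period,
        model_form=form,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        se_beta=se,
        random_effects=re_df,
        cov_re=np.atleast_2d(np.asarray(result.cov_re))[:k_re, :k_re].copy(),
        resid_var=float(result.scale),
        converged=bool(result.converged),
        age_center=a0,
        n_mice=len(mice),
        n_obs=n_obs,
    )


def mouse_rates(fit: LMEFit, age_at_eval: float | None = None) -> list[RateEstimate]:
    """Per-mouse trajectory derivative Rate_i = (b1+u1_i) + 2 (b2+u2_i) Age.

    ``age_at_eval`` defaults to 6 months for the early period and 24 for
    the late.  For the linear form the rate is age-independent.
    """
    if age_at_eval is None:
        age_at_eval = RATE_EVAL_AGE[fit.period]
    out = []
    for _, row in fit.random_effects.iterrows():
        rate = (fit.beta1 + row["b1"]) + 2.0 * (fit.beta2 + row["b2"]) * age_at_eval
        out.append(
            RateEstimate(
                mouse_id=row["mouse_id"],
                metric=fit.metric,
                state=fit.state,
                period=fit.period,
                age_at_eval=float(age_at_eval),
                rate=float(rate),
            )
        )
    return out


def rates_matrix(rates: Sequence[RateEstimate]) -> pd.DataFrame:
    """Pivot RateEstimates into a mice x metrics matrix."""
    df = pd.DataFrame([r.__dict__ for r in rates])
    return df.pivot_table(index="mouse_id", columns="metric", values="rate")


# ---------------------------------------------------------------------------
# signatures and normalisation


def autonomic_signature(
    table: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    sign: Literal["intrinsic_minus_basal", "basal_minus_intrinsic"] = "intrinsic_minus_basal",
) -> pd.DataFrame:
    """Per-(mouse, age, metric) difference between intrinsic (abk) and basal values.

    Pairs whose (mouse, age) failed blockade QC — or that lack one state —
    are omitted.  ``qc`` is a decisions table with mouse_id, age_months,
    passed; ``None`` keeps all complete pairs.
    """
    wide = table.pivot_table(
        index=["mouse_id", "age_months", "metric"], columns="state", values="value"
    )
    if "basal" not in wide.columns or "abk" not in wide.columns:
        return pd.DataFrame(columns=["mouse_id", "age_months", "metric", "value"])
    wide = wide.dropna(subset=["basal", "abk"]).reset_index()
    if qc is not None:
        passed = qc[qc["passed"]][["mouse_id", "age_months"]]
        wide = wide.merge(passed, on=["mouse_id", "age_months"], how="inner")
    diff = wide["abk"] - wide["basal"]
    if sign == "basal_minus_intrinsic":
        diff = -diff
    out = wide[["mouse_id", "age_months", "metric"]].copy()
    out["value"] = diff
    return out


def baseline_normalize(table: pd.DataFrame, baseline_age: float = 6.0) -> pd.DataFrame:
    """Divide each (mouse, metric, state) trajectory by its value at ``baseline_age``.

    Trajectories with a missing or zero baseline are skipped (logged).
    """
    out_parts = []
    for (mouse, metric, state), grp in table.groupby(["mouse_id", "metric", "state"]):
        base = grp.loc[grp["age_months"] == baseline_age, "value"]
        if base.empty or base.isna().any() or float(base.iloc[0]) == 0.0:
            logger.info("baseline_normalize: skipping %s/%s/%s (no usable %s-month value)",
                        mouse, metric, state, baseline_age)
            continue
        g = grp.copy()
        g["value"] = g["value"] / float(base.iloc[0])
        out_parts.append(g)
    if not out_parts:
        return table.iloc[0:0].copy()
    return pd.concat(out_parts, ignore_index=True)


# ---------------------------------------------------------------------------
# smoothing and ANOVA


def loess_trajectory(
    table: pd.DataFrame,
    metric: str,
    state: str,
    span: float = 0.75,
    eval_ages: np.ndarray | None = None,
) -> pd.DataFrame:
    """Loess (local quadratic, tricube-weighted) age trajectory with a 95% band.

    Pools all mice.  With fewer than 10 points, falls back to raw per-age
    means (flagged in the ``fallback`` column).  Returns a DataFrame with
    age, fit, se, lo95, hi95.
    """
    sub = table[(table["metric"] == metric) & (table["state"] == state)].dropna(subset=["value"])
    x = sub["age_months"].to_numpy(dtype=float)
    y = sub["value"].to_numpy(dtype=float)
    if eval_ages is None:
        eval_ages = np.unique(x)
    if x.size < 10:
        means = sub.groupby("age_months")["value"].mean()
        return pd.DataFrame({
            "age": means.index.to_numpy(), "fit": means.to_numpy(),
            "se": np.nan, "lo95": np.nan, "hi95": np.nan, "fallback": True,
        })
    n = x.size
    q = max(int(math.ceil(span * n)), 4)

    def smoother_row(x0: float) -> np.ndarray:
        """l(x0) such that the local-quadratic fit at x0 is l(x0) @ y."""
        d = np.abs(x - x0)
        h = np.sort(d)[min(q, n) - 1]
        if h == 0:
            h = max(float(np.max(d)), 1.0)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        w = np.maximum(w, np.where(d <= h, 1e-12, 0.0))  # keep the neighbourhood invertible
        basis = np.column_stack([np.ones_like(x), x - x0, (x - x0) ** 2])
        wb = basis * w[:, None]
        gram = basis.T @ wb
        try:
            coef_map = np.linalg.solve(gram, wb.T)
        except np.linalg.LinAlgError:
            coef_map = np.linalg.pinv(gram) @ wb.T
        return coef_map[0]

    fits = np.empty(eval_ages.size)
    l2 = np.empty(eval_ages.size)     # ||l(x0)||^2 for pointwise variance
    for j, x0 in enumerate(eval_ages):
        lvec = smoother_row(float(x0))
        fits[j] = lvec @ y
        l2[j] = float(lvec @ lvec)
    obs_fit = np.empty(n)
    trace_l = 0.0                     # effective model dof
    for j, x0 in enumerate(x):
        lvec = smoother_row(float(x0))
        obs_fit[j] = lvec @ y
        trace_l += float(lvec[j])
    resid = y - obs_fit
    dof = max(n - trace_l, 1.0)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * l2)
    z = stats.t.ppf(0.975, dof)
    return pd.DataFrame({
        "age": eval_ages, "fit": fits, "se": se,
        "lo95": fits - z * se, "hi95": fits + z * se, "fallback": False,
    })


def mixed_anova(table: pd.DataFrame, metric: str, state: str) -> tuple[float, float]:
    """Repeated-measures test of an age effect: F statistic and p-value.

    Age enters as a categorical factor with mouse as the repeated unit.
    Balanced complete designs use the exact repeated-measures ANOVA
    (AnovaRM); incomplete designs fall back to a random-intercept mixed
    model with a Wald F test on the age terms.
    """
    sub = table[(table["metric"] == metric) & (table["state"] == state)].dropna(subset=["value"])
    if sub["age_months"].nunique() < 2:
        return math.nan, math.nan
    counts = sub.groupby("mouse_id")["age_months"].nunique()
    n_ages = sub["age_months"].nunique()
    balanced = bool((counts == n_ages).all()) and not sub.duplicated(
        ["mouse_id", "age_months"]
    ).any()
    if balanced:
        res = AnovaRM(sub, depvar="value", subject="mouse_id", within=["age_months"]).fit()
        row = res.anova_table.iloc[0]
        return float(row["F Value"]), float(row["Pr > F"])
    # unbalanced: random-intercept LMM, Wald test on the age-factor contrasts
    sub = sub.copy()
    sub["age_f"] = sub["age_months"].astype("category")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("value ~ C(age_f)", groups="mouse_id", data=sub)
        result = model.fit(reml=True)
        names = [n for n in result.model.exog_names if n.startswith("C(age_f)")]
        contrast = np.zeros((len(names), len(result.fe_params)))
        for i, name in enumerate(names):
            contrast[i, result.model.exog_names.index(name)] = 1.0
        wald = result.wald_test(contrast, scalar=False)
    return float(np.squeeze(wald.statistic)), float(wald.pvalue)


# ---------------------------------------------------------------------------
# rate structure across metrics


@dataclass
class ClusterResult:
    """Variable clustering of rate columns."""

    metrics: list[str]
    linkage: np.ndarray
    assignments: dict[str, int]
    newick: str
    dropped: list[str] = field(default_factory=list)

    def cluster_of(self, metric: str) -> int:
        return self.assignments[metric]


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cluster_rates(
    rates: pd.DataFrame,
    height_cut: float = 0.5,
) -> ClusterResult:
    """Hierarchically cluster metric columns with distance 1 - |Pearson r|.

    ``rates`` is a mice x metrics matrix.  Average linkage; the |r| makes
    sign-flipped (mirror-image) metrics cluster together.  Zero-variance
    columns are dropped with a warning.  Flat clusters come from cutting
    the dendrogram at ``height_cut``.
    """
    if rates.shape[1] < 2 or rates.shape[0] < 4:
        raise ValueError("cluster_rates needs >= 2 metrics and >= 4 mice")
    variances = rates.var(ddof=1)
    dropped = [str(c) for c in rates.columns[~(variances > 0)]]
    if dropped:
        logger.warning("cluster_rates: dropping zero-variance metrics %s", dropped)
    use = rates.loc[:, variances > 0]
    corr = use.corr(method="pearson")
    dist = 1.0 - corr.abs()
    # undefined correlations (e.g. a constant pairwise-complete subset)
    # carry no similarity information: treat as maximally distant
    dist = dist.fillna(1.0)
    np.fill_diagonal(dist.values, 0.0)
    condensed = squareform(dist.to_numpy(), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(link, t=height_cut, criterion="distance")
    labels = [str(c) for c in use.columns]
    return ClusterResult(
        metrics=labels,
        linkage=link,
        assignments=dict(zip(labels, (int(v) for v in flat))),
        newick=_linkage_to_newick(link, labels),
        dropped=dropped,
    )


def rate_correlations(rates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations among rate columns.

    Uses pairwise-complete observations.  Returns (r, p, n) square
    DataFrames; the diagonal of r is 1 with p = 0.
    """
    cols = list(rates.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(rates))
    for i in range(k):
        for j in range(i + 1, k):
            pair = rates[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 4:
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = math.nan
                continue
            rr, pp = stats.pearsonr(pair[cols[i]], pair[cols[j]])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    idx = pd.Index(cols)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )


def correlation_triangle_table(
    early_rates: pd.DataFrame, late_rates: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One square table: early-period correlations above the diagonal, late below.

    Returns (r, p) DataFrames over the metrics common to both periods.
    """
    common = [c for c in early_rates.columns if c in late_rates.columns]
    r_e, p_e, _ = rate_correlations(early_rates[common])
    r_l, p_l, _ = rate_correlations(late_rates[common])
    k = len(common)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    iu = np.triu_indices(k, 1)
    il = np.tril_indices(k, -1)
    r[iu] = r_e.to_numpy()[iu]
    p[iu] = p_e.to_numpy()[iu]
    r[il] = r_l.to_numpy()[il]
    p[il] = p_l.to_numpy()[il]
    np.fill_diagonal(r, 1.0)
    idx = pd.Index(common)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def pitman_morgan(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pitman-Morgan test of equal variances for paired samples.

    t = (s_x^2 - s_y^2) * sqrt(n-2) / (2 s_x s_y sqrt(1 - r^2)), df = n-2,
    two-sided p.  Algebraically identical to testing cor(x+y, x-y) = 0.
    Returns (t, df, p); NaNs when both variances are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pitman_morgan requires equal-length 1-D paired samples")
    n = x.size
    if n < 4:
        raise ValueError("pitman_morgan requires n >= 4")
    sx2 = float(np.var(x, ddof=1))
    sy2 = float(np.var(y, ddof=1))
    df = float(n - 2)
    if sx2 == 0 and sy2 == 0:
        return math.nan, df, math.nan
    if sx2 == sy2:
        return 0.0, df, 1.0
    r = float(np.corrcoef(x, y)[0, 1]) if sx2 > 0 and sy2 > 0 else 0.0
    denom = 2.0 * math.sqrt(sx2 * sy2) * math.sqrt(max(1.0 - r**2, 0.0))
    if denom == 0:
        t = math.inf if sx2 > sy2 else -math.inf
        return t, df, 0.0
    t = (sx2 - sy2) * math.sqrt(df) / denom
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p
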