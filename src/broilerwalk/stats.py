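"""Statistical analysis of walking features against gait and leg-health classes.

Covers the full analysis stage of a walkway study:

* Pearson correlations among features with Fisher-z confidence intervals,
* exact r x c Fisher tests of association between class variables,
* per-feature linear models (class factor + body-weight covariate, with
  the interaction retained only if a partial F-test keeps it at alpha),
  least-squares means at the mean body weight and Tukey-adjusted pairwise
  contrasts,
* Welch's t-test and one-way ANOVA for body-weight comparisons,
* K-means clustering (K = 3) of z-standardized features with a confusion
  matrix against gait-score classes.

Significance is reported at P <= 0.05 with a tendency band 0.05 < P <= 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

ALPHA = 0.05
TENDENCY = 0.10


def significance_label(p: float) -> str:
    if p <= ALPHA:
        return "significant"
    if p <= TENDENCY:
        return "tendency"
    return "ns"


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def pearson_cor_ci(x, y, level: float = 0.95) -> tuple[float, float, float, float]:
    """Pearson correlation with Fisher-z confidence interval.

    Returns ``(r, ci_low, ci_high, p)``; p is two-sided from the t
    distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    n = len(x)
    r, p = sps.pearsonr(x, y)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = sps.norm.ppf(0.5 + level / 2)
    return float(r), float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)), float(p)


def correlation_matrix(features: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations (with CI and p) among feature columns."""
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r, lo, hi, p = pearson_cor_ci(features[a], features[b])
            rows.append({"feature_a": a, "feature_b": b, "r": r,
                         "ci_low": lo, "ci_high": hi, "p": p,
                         "label": significance_label(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher's exact test (r x c)
# ---------------------------------------------------------------------------

#: Relative tolerance when comparing table probabilities to the observed
#: one; absorbs floating-point ties, matching mainstream exact tests.
_FISHER_REL_TOL = 1e-7


def _table_logprob(table: np.ndarray, row_margins, col_margins, n) -> float:
    """Log multivariate hypergeometric probability with fixed margins."""
    return (
        gammaln(np.asarray(row_margins) + 1).sum()
        + gammaln(np.asarray(col_margins) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_logprobs(row_margins, col_margins):
    """Log-probabilities of every table consistent with the margins."""
    r, c = len(row_margins), len(col_margins)
    n = int(sum(row_margins))
    const = (
        gammaln(np.asarray(row_margins, float) + 1).sum()
        + gammaln(np.asarray(col_margins, float) + 1).sum()
        - gammaln(n + 1)
    )
    out: list[float] = []
    cells = np.zeros((r, c), dtype=int)
    col_left = np.asarray(col_margins, dtype=int).copy()

    def rec(i: int, j: int, row_left: int, lg: float):
        if i == r - 1:
            # last row fully determined by the column remainders
            last = col_left.copy()
            if (last < 0).any():
                return
            out.append(const + lg - gammaln(last + 1).sum())
            return
        if j == c - 1:
            v = row_left
            if v < 0 or v > col_left[j]:
                return
            col_left[j] -= v
            rec(i + 1, 0, int(row_margins[i + 1]), lg - gammaln(v + 1))
            col_left[j] += v
            return
        hi = min(row_left, col_left[j])
        for v in range(hi + 1):
            col_left[j] -= v
            rec(i, j + 1, row_left - v, lg - gammaln(v + 1))
            col_left[j] += v

    rec(0, 0, int(row_margins[0]), 0.0)
    return np.array(out)


def fisher_exact(
    table,
    budget: int = 500,
    monte_carlo: bool = False,
    n_samples: int = 100_000,
    seed: int | None = None,
) -> float:
    """Two-sided Fisher exact test for an r x c contingency table.

    The p-value sums the null (multivariate hypergeometric with both
    margins fixed) probabilities of every margin-consistent table whose
    probability does not exceed the observed table's (up to a relative
    tie tolerance). Exact enumeration is used up to ``budget`` total
    counts; beyond that, request ``monte_carlo`` (seeded) sampling of
    margin-fixed tables.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if (t < 0).any():
        raise ValueError("negative counts")
    row_m, col_m = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty table")
    lp_obs = _table_logprob(t, row_m, col_m, n)
    cutoff = lp_obs + np.log1p(_FISHER_REL_TOL)
    if monte_carlo:
        rng = np.random.default_rng(seed)
        sampler = sps.random_table(row_m, col_m)
        samples = sampler.rvs(n_samples, method="patefield", random_state=rng)
        lps = np.array([_table_logprob(s, row_m, col_m, n) for s in samples])
        return float((1 + np.sum(lps <= cutoff)) / (n_samples + 1))
    if n > budget:
        raise ValueError(
            f"table total {n} exceeds enumeration budget {budget}; "
            "use monte_carlo=True with a seed"
        )
    lps = _enumerate_logprobs(row_m, col_m)
    total = np.exp(lps).sum()
    if abs(total - 1.0) > 1e-10:
        raise AssertionError(f"enumeration probabilities sum to {total}, not 1")
    p = float(np.exp(lps[lps <= cutoff]).sum())
    return min(p, 1.0)


def contingency(classified: pd.DataFrame, row_var: str, col_var: str,
                row_levels, col_levels) -> pd.DataFrame:
    """Cross-tabulation of two class columns with fixed level order."""
    tab = pd.crosstab(classified[row_var], classified[col_var])
    tab = tab.reindex(index=row_levels, columns=col_levels, fill_value=0)
    return tab


# ---------------------------------------------------------------------------
# Welch's t and one-way ANOVA
# ---------------------------------------------------------------------------

def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test: ``(t, Satterthwaite df, two-sided p)``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both groups")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def one_way_anova(values, labels) -> tuple[float, float, float, float]:
    """One-way ANOVA: ``(F, df_between, df_within, p)``."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(values) - len(groups)
    if ss_within == 0:
        raise ValueError("zero within-group variance: F undefined")
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), float(df1), float(df2), float(sps.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# Linear models with LS means and Tukey contrasts
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted feature ~ class + body-weight model.

    LS means are the model predictions per class level evaluated at the
    sample-mean body weight; pairwise p-values are adjusted through the
    studentized-range (Tukey) distribution.
    """

    response: str
    factor_levels: list[str]
    covariate: str
    interaction_included: bool
    interaction_p: float
    params: pd.Series
    bse: pd.Series
    df_resid: float
    covariate_p: float
    ls_means: pd.Series
    ls_se: pd.Series
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    model_p: float = float("nan")


def fit_feature_model(
    feature,
    classes,
    weights,
    response_name: str = "feature",
    alpha: float = ALPHA,
) -> ModelFit:
    """OLS of a walking feature on a class factor with body weight as
    covariate; the factor x weight interaction is dropped when a partial
    F-test finds it non-significant (P > alpha) and the model refitted.
    """
    import statsmodels.formula.api as smf
    from patsy import build_design_matrices
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({
        "y": np.asarray(feature, float),
        "cls": pd.Categorical(classes),
        "w": np.asarray(weights, float),
    })
    levels = list(df["cls"].cat.categories)
    if len(levels) < 2:
        raise ValueError("need at least 2 class levels")
    if len(df) <= 2 * len(levels) + 1:
        raise ValueError("too few observations for the model")

    reduced = smf.ols("y ~ cls + w", data=df).fit()
    interaction_included = False
    interaction_p = float("nan")
    fit = reduced
    full = smf.ols("y ~ cls + w + cls:w", data=df).fit()
    if full.model.rank < full.model.exog.shape[1]:
        warnings.warn("singular design for the interaction model; "
                      "falling back to the additive fit")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_tab = anova_lm(reduced, full)
        interaction_p = float(cmp_tab["Pr(>F)"].iloc[1])
        if interaction_p <= alpha:
            interaction_included = True
            fit = full

    new = pd.DataFrame({"cls": pd.Categorical(levels, categories=levels),
                        "w": df["w"].mean()})
    (design,) = build_design_matrices([fit.model.data.design_info], new)
    X = np.asarray(design)
    beta = fit.params.to_numpy()
    cov = fit.cov_params().to_numpy()
    ls = X @ beta
    ls_cov = X @ cov @ X.T
    ls_se = np.sqrt(np.diag(ls_cov))

    k = len(levels)
    dfres = float(fit.df_resid)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = ls[i] - ls[j]
            se = np.sqrt(ls_cov[i, i] + ls_cov[j, j] - 2 * ls_cov[i, j])
            tval = d / se
            p_adj = float(sps.studentized_range.sf(abs(tval) * np.sqrt(2), k, dfres))
            rows.append({
                "level_a": levels[i], "level_b": levels[j],
                "estimate": float(d), "se": float(se), "t": float(tval),
                "p_adj": p_adj, "label": significance_label(p_adj),
            })
    return ModelFit(
        response=response_name,
        factor_levels=levels,
        covariate="weight_g",
        interaction_included=interaction_included,
        interaction_p=interaction_p,
        params=fit.params,
        bse=fit.bse,
        df_resid=dfres,
        covariate_p=float(fit.pvalues.get("w", np.nan)),
        ls_means=pd.Series(ls, index=levels),
        ls_se=pd.Series(ls_se, index=levels),
        pairwise=pd.DataFrame(rows),
        model_p=float(fit.f_pvalue),
    )


# ---------------------------------------------------------------------------
# K-means clustering of walking features
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series          # cluster label per bird_id
    centroids: np.ndarray           # in standardized feature space
    inertia: float                  # within-cluster sum of squares
    confusion: pd.DataFrame         # clusters x GS classes, counts
    confusion_pct: pd.DataFrame     # % within each GS class
    cluster_summary: pd.DataFrame   # per-cluster feature mean +/- SD


def kmeans_gait_clusters(
    features: pd.DataFrame,
    classified: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    feature_columns: Sequence[str] = ("osc_px", "step_count", "completion_s"),
) -> ClusterResult:
    """K-means on z-standardized walking features, scored against GS classes.

    Clusters are relabelled deterministically by mean completion time:
    'A' = fastest, 'B' = slowest, 'C' = intermediate (for K = 3; otherwise
    alphabetical in ascending completion-time order), so labels carry the
    same meaning across seeds. The confusion matrix rows are clusters,
    columns GS classes, with within-GS-class percentages alongside.
    """
    from sklearn.cluster import KMeans

    merged = features.merge(classified[["bird_id", "gs_class"]], on="bird_id")
    if merged["bird_id"].duplicated().any():
        raise ValueError("duplicate bird_id")
    if len(merged) < k:
        raise ValueError(f"need at least {k} birds for K={k}")
    X = merged[list(feature_columns)].to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw_labels = km.fit_predict(Z)

    ct_col = list(feature_columns).index("completion_s") if "completion_s" in feature_columns else 0
    order = np.argsort([Z[raw_labels == c, ct_col].mean() if (raw_labels == c).any() else np.inf
                        for c in range(k)])
    if k == 3:
        names = ["A", "C", "B"]  # fastest, intermediate, slowest
        label_map = {int(order[0]): "A", int(order[1]): "C", int(order[2]): "B"}
    else:
        label_map = {int(c): chr(ord("A") + i) for i, c in enumerate(order)}
        names = sorted(label_map.values())
    labels = pd.Series([label_map[int(c)] for c in raw_labels],
                       index=merged["bird_id"], name="cluster")

    gs_levels = [g for g in ("GS1", "GS2", "GS3+") if g in set(merged["gs_class"])] or \
        sorted(set(merged["gs_class"]))
    conf = pd.crosstab(labels.to_numpy(), merged["gs_class"].to_numpy())
    conf = conf.reindex(index=sorted(set(labels)), columns=gs_levels, fill_value=0)
    conf.index.name = "cluster"
    conf.columns.name = "gs_class"
    pct = 100 * conf / conf.sum(axis=0)

    summ_rows = []
    for name in conf.index:
        sub = merged.loc[labels.to_numpy() == name, list(feature_columns)]
        row = {"cluster": name, "n": len(sub)}
        for c in feature_columns:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sd"] = sub[c].std(ddof=1)
        summ_rows.append(row)

    centroids = km.cluster_centers_[[int(np.flatnonzero(
        [label_map[c] == nm for c in range(k)])[0]) for nm in conf.index]]
    return ClusterResult(
        k=k, assignments=labels, centroids=centroids,
        inertia=float(km.inertia_),
        confusion=conf, confusion_pct=pct,
        cluster_summary=pd.DataFrame(summ_rows),
    )


# ---------------------------------------------------------------------------
# Full analysis stage
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = {"osc_px": "Lateral body oscillation (px)",
                   "step_count": "Step count (n)",
                   "completion_s": "Completion time (s)"}


def analyze(features: pd.DataFrame, classified: pd.DataFrame,
            seed: int = 0, k: int = 3) -> dict:
    """Run the complete statistical stage on feature + phenotype tables.

    Returns a dict with the correlation matrix, Fisher-test p-values,
    body-weight tests, per-feature ModelFits by GS/HB/FPD class, and the
    K-means ClusterResult. Birds flagged as excluded are dropped first.
    """
    feats = features.loc[~features["excluded_flag"].astype(bool)].copy()
    data = feats.merge(classified, on="bird_id")
    if data.empty:
        raise ValueError("no birds left after exclusion / merge")

    out: dict = {"n_birds": len(data)}
    out["correlations"] = correlation_matrix(data, list(FEATURE_COLUMNS))

    from .phenotypes import FPD_CLASSES, GS_CLASSES, HB_CLASSES
    tabs = {
        "gs_hb": contingency(data, "hb_class", "gs_class", HB_CLASSES, GS_CLASSES),
        "gs_fpd": contingency(data, "fpd_class", "gs_class", FPD_CLASSES, GS_CLASSES),
        "hb_fpd": contingency(data, "hb_class", "fpd_class", HB_CLASSES, FPD_CLASSES),
    }
    out["fisher"] = {name: {"table": tab, "p": fisher_exact(tab.to_numpy())}
                     for name, tab in tabs.items()}

    def _anova_or_none(cls_var):
        sizes = data[cls_var].value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            return None  # a singleton class cannot support the F-test
        f, df1, df2, p = one_way_anova(data["weight_g"], data[cls_var])
        return {"F": f, "df1": df1, "df2": df2, "p": p}

    out["weight_by_gs_anova"] = _anova_or_none("gs_class")
    out["weight_by_fpd_anova"] = _anova_or_none("fpd_class")
    hb0 = data.loc[data["hb_class"] == "HB0", "weight_g"]
    hb1 = data.loc[data["hb_class"] == "HB1", "weight_g"]
    if len(hb0) >= 2 and len(hb1) >= 2:
        t, df, p = welch_t(hb0, hb1)
        out["weight_by_hb_welch"] = {"t": t, "df": df, "p": p}
    else:
        out["weight_by_hb_welch"] = None

    models: dict[str, dict[str, ModelFit]] = {}
    for col in FEATURE_COLUMNS:
        models[col] = {}
        for cls_var in ("gs_class", "hb_class", "fpd_class"):
            sizes = data[cls_var].value_counts()
            if len(sizes) < 2 or (sizes < 2).any():
                continue
            models[col][cls_var] = fit_feature_model(
                data[col], data[cls_var], data["weight_g"], response_name=col)
    out["models"] = models

    out["clusters"] = kmeans_gait_clusters(feats, classified, k=k, seed=seed)
    return out


def format_model_table(models: dict) -> str:
    """Render per-feature LS means (SE) by class, Table-2 style."""
    lines = []
    for col, per_cls in models.items():
        lines.append(FEATURE_COLUMNS.get(col, col))
        for cls_var, fit in per_cls.items():
            cells = "  ".join(
                f"{lev}: {fit.ls_means[lev]:.1f} ({fit.ls_se[lev]:.1f})"
                for lev in fit.factor_levels
            )
            worst = fit.pairwise["p_adj"].min() if len(fit.pairwise) else float("nan")
            lines.append(f"  {cls_var:10} {cells}  min adj-P={worst:.3g}")
    return "\n".join(lines)
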