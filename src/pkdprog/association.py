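"""Per-protein association analyses with the annual eGFR slope.

Implements empirical-Bayes moderated t-testing (per-protein linear fits
with variance shrinkage toward a scaled-F-matched prior), Benjamini-
Hochberg FDR adjustment, Pearson eGFR-dependency correlations with
cross-cohort sign concordance, detection-indicator association for
high-missingness proteins, correlation-distance hierarchical clustering
and cluster-characteristic tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModeratedResult",
    "CorrelationResult",
    "ClusterResult",
    "moderated_association",
    "estimate_variance_prior",
    "bh_adjust",
    "pearson_with_pvalue",
    "egfr_dependency",
    "sign_concordance",
    "detection_association",
    "hclust_corr",
    "compare_clusters",
]


@dataclass
class ModeratedResult:
    """Moderated association table plus the fitted variance prior."""

    table: pd.DataFrame  # gene, coef, s2, df, s2_post, t_mod, p, fdr
    d0: float  # prior degrees of freedom (inf = full shrinkage)
    s0_sq: float  # prior variance


@dataclass
class CorrelationResult:
    table: pd.DataFrame  # gene, r, n, p, sign


@dataclass
class ClusterResult:
    axis: str  # "proteins" or "samples"
    linkage: np.ndarray  # scipy linkage matrix (merge order + heights)
    labels: list[str]
    assignment: pd.Series  # item -> cluster id (1..k)


def _trigamma_inverse(x: float, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (Smyth's method)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled F distribution.

    Returns (d0, s0_sq): prior degrees of freedom and prior variance.  When
    the observed spread of log-variances is no larger than expected from
    pure chi-square sampling noise the moment system has no finite solution
    and d0 = inf (full shrinkage to s0_sq).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df[ok] / 2) + np.log(df[ok] / 2)
    e_mean = float(np.mean(e))
    n = e.size
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    excess = e_var - float(np.mean(polygamma(1, df[ok] / 2)))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def moderated_association(
    matrix: pd.DataFrame,
    slopes: pd.Series,
    alpha: float = 0.05,
) -> ModeratedResult:
    """Empirical-Bayes moderated test of each protein against eGFR slope.

    Each protein's abundance is regressed on the slope (single covariate
    plus intercept); residual variances are shrunk toward the prior
    s0_sq with weight d0 — ``s2_post = (d0*s0_sq + df*s2)/(d0 + df)`` — and
    the moderated t-statistic is referred to a t distribution with
    ``d0 + df`` degrees of freedom.  P-values are BH-adjusted.
    """
    common = matrix.index.intersection(slopes.index)
    if len(common) != len(matrix.index) or len(common) != len(slopes.index):
        raise ValueError(
            f"samples misaligned: matrix has {len(matrix.index)}, slopes "
            f"{len(slopes.index)}, overlap {len(common)}"
        )
    X = matrix.loc[common].to_numpy(dtype=float)
    y = slopes.loc[common].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples")
    zero_var = X.std(axis=0) == 0
    if zero_var.any():
        bad = matrix.columns[zero_var].tolist()
        raise ValueError(f"zero-variance protein(s): {bad[:10]}")

    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0:
        raise ValueError("slope vector is constant")
    Xc = X - X.mean(axis=0)
    # abundance ~ slope: coef_g = <x_g, y> / <y, y>
    coef = (Xc.T @ yc) / syy
    fitted = np.outer(yc, coef)
    resid = Xc - fitted
    df_resid = n - 2
    s2 = (resid**2).sum(axis=0) / df_resid
    se_unit = np.sqrt(1.0 / syy)  # per-unit-variance factor of SE(coef)

    d0, s0_sq = estimate_variance_prior(s2, np.full_like(s2, df_resid))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    t_mod = coef / (np.sqrt(s2_post) * se_unit)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": matrix.columns,
            "coef": coef,
            "s2": s2,
            "df": df_resid,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "p": p,
            "fdr": fdr,
            "significant": fdr < alpha,
        }
    ).set_index("gene")
    return ModeratedResult(table=table, d0=d0, s0_sq=s0_sq)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_with_pvalue(x, y) -> tuple[float, float, int]:
    """Pairwise-complete Pearson correlation with t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("constant vector")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


def egfr_dependency(
    matrix: pd.DataFrame,
    egfr_at_sampling: pd.Series,
    protein_panel: list[str],
) -> CorrelationResult:
    """Correlate each panel protein's abundance with eGFR at biosampling."""
    if not protein_panel:
        raise ValueError("empty protein panel")
    missing = [g for g in protein_panel if g not in matrix.columns]
    if missing:
        raise ValueError(f"panel protein(s) not in matrix: {missing}")
    egfr = egfr_at_sampling.reindex(matrix.index)
    rows = []
    for g in protein_panel:
        r, p, n = pearson_with_pvalue(matrix[g].to_numpy(), egfr.to_numpy())
        rows.append({"gene": g, "r": r, "n": n, "p": p,
                     "sign": int(np.sign(r))})
    return CorrelationResult(pd.DataFrame(rows).set_index("gene"))


def sign_concordance(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Proteins significant in both cohorts, with sign-agreement flags.

    Input tables are indexed by gene with columns r and p (as produced by
    :func:`egfr_dependency`).
    """
    shared = table_a.index.intersection(table_b.index)
    if shared.empty:
        raise ValueError("no overlapping proteins")
    a = table_a.loc[shared]
    b = table_b.loc[shared]
    both = (a["p"] < alpha) & (b["p"] < alpha)
    out = pd.DataFrame(
        {
            "r_a": a["r"],
            "r_b": b["r"],
            "significant_both": both,
            "concordant": np.sign(a["r"]) == np.sign(b["r"]),
        }
    )
    return out[out["significant_both"]].drop(columns="significant_both")


def detection_association(
    observed_mask: pd.DataFrame, slopes: pd.Series, protein: str
) -> tuple[float, float]:
    """Point-biserial correlation of a protein's detection with slope.

    Asks whether merely detecting the protein (vs missing) tracks the
    patient's eGFR slope — informative for strongly left-censored markers.
    """
    if protein not in observed_mask.columns:
        raise ValueError(f"protein {protein!r} not in mask")
    detected = observed_mask[protein].reindex(slopes.index).to_numpy(dtype=float)
    if np.all(detected == 1) or np.all(detected == 0):
        raise ValueError(f"protein {protein!r} has no detection contrast")
    r, p = stats.pointbiserialr(detected, slopes.to_numpy(dtype=float))
    return float(r), float(p)


def _corr_distance(data: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows."""
    sd = data.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant rows have undefined correlation")
    corr = np.corrcoef(data)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    return squareform(dist, checks=False)


def hclust_corr(
    matrix: pd.DataFrame,
    axis: str = "proteins",
    k: int = 3,
    sort_samples_by: pd.Series | None = None,
) -> ClusterResult:
    """Average-linkage hierarchical clustering on 1 - Pearson distances.

    ``axis`` selects whether proteins (columns) or samples (rows) are
    clustered; the dendrogram is cut into ``k`` clusters.  For sample
    clustering an optional covariate (e.g. eGFR) orders items within each
    cluster.
    """
    if axis == "proteins":
        data = matrix.to_numpy(dtype=float).T
        labels = list(matrix.columns)
    elif axis == "samples":
        data = matrix.to_numpy(dtype=float)
        labels = list(matrix.index)
    else:
        raise ValueError("axis must be 'proteins' or 'samples'")
    if len(labels) < k:
        raise ValueError(f"cannot cut {len(labels)} items into {k} clusters")
    Z = hierarchy.linkage(_corr_distance(data), method="average")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    assignment = pd.Series(flat, index=labels, name="cluster")
    if sort_samples_by is not None and axis == "samples":
        order = (
            pd.DataFrame({"cluster": assignment, "key": sort_samples_by})
            .sort_values(["cluster", "key"])
            .index
        )
        assignment = assignment.loc[order]
    return ClusterResult(axis=axis, linkage=Z, labels=labels, assignment=assignment)


def compare_clusters(
    assignment: pd.Series,
    covariates: pd.DataFrame,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Cluster-characteristic tests.

    Continuous covariates: all pairwise two-sided Welch t-tests between
    clusters, Bonferroni-adjusted within covariate.  Categorical covariates
    (binary-codeable): each cluster's proportion against the whole-cohort
    proportion by a one-sample chi-square proportion test (no continuity
    correction).
    """
    categorical = categorical or []
    cov = covariates.reindex(assignment.index)
    clusters = sorted(assignment.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    rows = []
    for col in cov.columns:
        if col in categorical:
            series = cov[col]
            overall = series.value_counts(normalize=True)
            level = overall.index[0]
            p0 = float(overall.iloc[0])
            for c in clusters:
                vals = series[assignment == c]
                x = int((vals == level).sum())
                n = int(vals.notna().sum())
                expected = np.array([n * p0, n * (1 - p0)])
                observed = np.array([x, n - x])
                if np.any(expected == 0):
                    stat, p = np.nan, 1.0
                else:
                    stat = float((((observed - expected) ** 2) / expected).sum())
                    p = float(stats.chi2.sf(stat, df=1))
                rows.append(
                    {"covariate": col, "comparison": f"cluster{c}_vs_cohort",
                     "statistic": stat, "p": p, "p_adj": p}
                )
        else:
            pair_rows = []
            pairs = [
                (a, b) for i, a in enumerate(clusters) for b in clusters[i + 1:]
            ]
            for a, b in pairs:
                va = cov.loc[assignment == a, col].dropna()
                vb = cov.loc[assignment == b, col].dropna()
                if len(va) < 2 or len(vb) < 2:
                    raise ValueError(
                        f"cluster with < 2 observations for t-test on {col!r}"
                    )
                t, p = stats.ttest_ind(va, vb, equal_var=False)
                pair_rows.append(
                    {"covariate": col, "comparison": f"cluster{a}_vs_cluster{b}",
                     "statistic": float(t), "p": float(p)}
                )
            m = len(pair_rows)
            for r in pair_rows:
                r["p_adj"] = min(1.0, r["p"] * m)
            rows.extend(pair_rows)
    return pd.DataFrame(rows)
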