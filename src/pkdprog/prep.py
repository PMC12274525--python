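"""DIA proteome preprocessing: from a long-format protein-group report to a
filtered, normalized, imputed, outlier-flagged, batch-corrected matrix.

The processing order mirrors standard serum DIA practice: identification
q-value filtering (entries, not rows), removal of protein groups with more
than 80% missing values, variance-stabilizing normalization (per-sample
affine arsinh calibration, a generalized-log transform), imputation of
left-censored missing values by sampling from the low tail, PCA-based
outlier flagging, and empirical-Bayes location/scale batch correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "RawProteomeTable",
    "ProteomeMatrix",
    "NormalizationFit",
    "BatchFit",
    "read_report",
    "build_matrix",
    "filter_missing",
    "vsn_normalize",
    "impute_low",
    "detect_outliers",
    "combat_correct",
    "preprocess_pipeline",
]

REPORT_COLUMNS = ["Run", "Protein.Group", "Genes", "Q.Value", "Intensity"]


@dataclass
class RawProteomeTable:
    """Typed long-format protein-group report."""

    table: pd.DataFrame  # columns: Run, Protein.Group, Genes, Q.Value, Intensity

    def __post_init__(self) -> None:
        missing = [c for c in REPORT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"report is missing required column(s): {missing}")
        dup = self.table.duplicated(subset=["Run", "Protein.Group"], keep=False)
        if dup.any():
            pairs = (
                self.table.loc[dup, ["Run", "Protein.Group"]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise ValueError(f"duplicate (run, protein group) rows: {list(pairs)[:10]}")
        q = self.table["Q.Value"].to_numpy(dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("Q.Value outside [0, 1]")


@dataclass
class ProteomeMatrix:
    """Samples x proteins abundance matrix with mask, batches and provenance.

    ``data`` holds transformed (or raw) abundances with NaN for missing;
    ``observed`` marks entries that were measured (False = missing before any
    imputation — imputation fills ``data`` but leaves the mask untouched so
    downstream detection analyses can recover the original pattern).
    """

    data: pd.DataFrame  # index: sample/run ids; columns: gene names
    observed: pd.DataFrame
    batch: pd.Series | None = None
    provenance: list = field(default_factory=list)

    def copy_with(self, data=None, observed=None, step=None) -> "ProteomeMatrix":
        out = ProteomeMatrix(
            data=self.data.copy() if data is None else data,
            observed=self.observed.copy() if observed is None else observed,
            batch=None if self.batch is None else self.batch.copy(),
            provenance=list(self.provenance),
        )
        if step is not None:
            out.provenance.append(step)
        return out

    @property
    def na_fraction(self) -> pd.Series:
        return 1.0 - self.observed.mean(axis=0)


@dataclass
class NormalizationFit:
    """Per-sample affine calibration of the arsinh transform.

    The applied transform is ``h(x) = arsinh(a_s + b_s * x)`` with
    ``b_s > 0`` (strictly monotone per sample).
    """

    offsets: pd.Series  # a_s per sample
    factors: pd.Series  # b_s per sample
    converged: bool
    n_calibration_proteins: int
    message: str = ""


@dataclass
class BatchFit:
    """Empirical-Bayes location/scale batch parameters.

    ``gamma_star``/``delta2_star`` are the shrunken per-batch, per-protein
    additive and multiplicative effects; priors are normal for gamma
    (mean/variance) and inverse-gamma for delta2 (shape/scale), estimated by
    method of moments across proteins.
    """

    gamma_star: pd.DataFrame  # batches x proteins
    delta2_star: pd.DataFrame
    gamma_prior: dict
    delta2_prior: dict


def read_report(path) -> RawProteomeTable:
    """Read a tab-separated DIA protein-group report.

    Requires columns Run, Protein.Group, Genes, Q.Value, Intensity; rejects
    duplicated (run, protein group) pairs and unparseable numerics.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REPORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"report at {path} is missing column(s): {missing}")
    for col in ("Q.Value", "Intensity"):
        table[col] = pd.to_numeric(table[col], errors="raise")
    return RawProteomeTable(table)


def build_matrix(raw: RawProteomeTable, q_max: float = 0.01) -> ProteomeMatrix:
    """Pivot the report to runs x genes; q-value failures become missing.

    Entries with identification q-value strictly above ``q_max`` are set
    missing rather than dropped as rows, so they contribute to downstream
    missing-value accounting exactly like undetected entries.
    """
    table = raw.table
    if table.empty:
        raise ValueError("empty report")
    t = table.copy()
    t.loc[t["Q.Value"] > q_max, "Intensity"] = np.nan
    data = t.pivot(index="Run", columns="Genes", values="Intensity").sort_index()
    data.columns.name = None
    data.index.name = "sample"
    observed = data.notna()
    return ProteomeMatrix(
        data=data,
        observed=observed,
        provenance=[{"step": "build_matrix", "q_max": q_max}],
    )


def filter_missing(matrix: ProteomeMatrix, max_na: float = 0.80) -> ProteomeMatrix:
    """Drop proteins whose missing fraction strictly exceeds ``max_na``."""
    keep = matrix.na_fraction <= max_na
    cols = matrix.data.columns[keep]
    return matrix.copy_with(
        data=matrix.data[cols],
        observed=matrix.observed[cols],
        step={"step": "filter_missing", "max_na": max_na,
              "dropped": int((~keep).sum())},
    )


def _vsn_objective(theta, x, obs, row_counts):
    """Profile negative log-likelihood of the calibrated arsinh model.

    ``x`` is proteins x samples raw intensities (NaN where unobserved),
    theta = [a_1..a_S, log b_1..log b_S].  The likelihood is the normal
    within-protein model on h = arsinh(a + b x) with sigma profiled out,
    including the log-Jacobian of the transform (which is what prevents the
    degenerate b -> 0 collapse).
    """
    n_p, n_s = x.shape
    a = theta[:n_s]
    b = np.exp(theta[n_s:])
    y = a[None, :] + b[None, :] * x
    h = np.arcsinh(y)
    hm = np.where(obs, h, 0.0)
    row_mean = hm.sum(axis=1) / row_counts
    r = np.where(obs, h - row_mean[:, None], 0.0)
    n_tot = float(row_counts.sum())
    # floor guards the degenerate perfect-fit case (e.g. identical samples)
    rss = max(float((r * r).sum()), 1e-12 * n_tot)
    sq = 1.0 + y * y
    jac = np.where(obs, np.log(b[None, :]) - 0.5 * np.log(sq), 0.0).sum()
    nll = 0.5 * n_tot * np.log(rss) - jac
    # gradients
    dh_da = np.where(obs, 1.0 / np.sqrt(sq), 0.0)
    dh_dc = np.where(obs, (b[None, :] * x) / np.sqrt(sq), 0.0)
    pref = n_tot / rss
    g_a = pref * (r * dh_da).sum(axis=0) + np.where(obs, y / sq, 0.0).sum(axis=0)
    g_c = (
        pref * (r * dh_dc).sum(axis=0)
        - obs.sum(axis=0)
        + np.where(obs, y * b[None, :] * x / sq, 0.0).sum(axis=0)
    )
    return nll, np.concatenate([g_a, g_c])


def vsn_normalize(
    matrix: ProteomeMatrix,
    trim: float = 0.90,
    max_iter: int = 5000,
) -> tuple[ProteomeMatrix, NormalizationFit]:
    """Variance-stabilizing normalization via per-sample arsinh calibration.

    Estimates per-sample affine parameters (a_s, b_s) by maximum profile
    likelihood of the model ``arsinh(a_s + b_s x) = mu_protein + noise``
    over a calibration subset (the ``trim`` fraction of least-variable
    proteins), then applies the fitted transform to all entries.  The
    transform is strictly increasing per sample, so within-sample ranks are
    preserved; a pure multiplicative shift between samples becomes an
    approximately additive offset on the transformed scale.
    """
    X = matrix.data.to_numpy(dtype=float).T  # proteins x samples
    obs = matrix.observed.to_numpy().T
    n_p, n_s = X.shape
    if n_s < 2:
        raise ValueError("vsn_normalize needs at least 2 samples")
    if np.nanmin(matrix.data.to_numpy()) <= 0:
        raise ValueError("intensities must be positive")

    # init: b_s = 1 / (robust per-sample scale of raw intensities)
    med = np.array([np.nanmedian(X[obs[:, s], s]) for s in range(n_s)])
    b0 = 1.0 / np.maximum(med, 1e-12)
    a0 = np.zeros(n_s)

    # calibration subset: least-variable proteins on the init transform
    h0 = np.arcsinh(a0[None, :] + b0[None, :] * X)
    with np.errstate(invalid="ignore"):
        hv = np.where(obs, h0, np.nan)
        row_var = np.nanvar(hv, axis=1)
        row_n = obs.sum(axis=1)
    eligible = row_n >= 2
    order = np.argsort(np.where(eligible, row_var, np.inf))
    n_keep = max(2, int(np.floor(trim * eligible.sum())))
    subset = np.zeros(n_p, dtype=bool)
    subset[order[:n_keep]] = True

    xs, os_ = X[subset], obs[subset]
    row_counts = os_.sum(axis=1).astype(float)
    good = row_counts >= 2
    xs, os_, row_counts = xs[good], os_[good], row_counts[good]
    xs = np.where(os_, xs, 0.0)

    theta0 = np.concatenate([a0, np.log(b0)])
    res = optimize.minimize(
        _vsn_objective,
        theta0,
        args=(xs, os_, row_counts),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    a = res.x[:n_s]
    b = np.exp(res.x[n_s:])
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm <= 1e-6 * max(1.0, abs(res.fun))
    if not converged:
        raise RuntimeError(
            f"vsn calibration did not converge: {res.message} "
            f"(iterations={res.nit}, max|grad|={grad_norm:.3g})"
        )
    h_all = np.arcsinh(a[None, :] + b[None, :] * X).T
    data = pd.DataFrame(h_all, index=matrix.data.index, columns=matrix.data.columns)
    data[~matrix.observed] = np.nan
    fit = NormalizationFit(
        offsets=pd.Series(a, index=matrix.data.index),
        factors=pd.Series(b, index=matrix.data.index),
        converged=converged,
        n_calibration_proteins=int(good.sum()),
        message=str(res.message),
    )
    out = matrix.copy_with(data=data, step={"step": "vsn_normalize", "trim": trim})
    return out, fit


def impute_low(
    matrix: ProteomeMatrix, percentile: float = 5.0, seed: int = 0
) -> ProteomeMatrix:
    """Replace missing values by draws from the low-abundance pool.

    The pool is all observed values at or below the dataset-wide
    ``percentile``-th percentile (left-censored missingness model: an
    undetected protein is assumed low-abundant).  Draws are with
    replacement and deterministic under ``seed``.  The observation mask is
    left unchanged.
    """
    vals = matrix.data.to_numpy(dtype=float)
    obs = matrix.observed.to_numpy()
    observed_vals = vals[obs & np.isfinite(vals)]
    if observed_vals.size == 0:
        raise ValueError("no observed values to impute from")
    cutoff = np.percentile(observed_vals, percentile)
    pool = observed_vals[observed_vals <= cutoff]
    if pool.size < 10:
        raise ValueError(
            f"low-abundance pool has only {pool.size} values; "
            "increase the imputation percentile"
        )
    n_missing = int((~obs).sum())
    out_vals = vals.copy()
    if n_missing:
        rng = np.random.default_rng(seed)
        out_vals[~obs] = rng.choice(pool, size=n_missing, replace=True)
    data = pd.DataFrame(out_vals, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.copy_with(
        data=data,
        step={"step": "impute_low", "percentile": percentile, "seed": seed,
              "n_imputed": n_missing},
    )


def detect_outliers(matrix: ProteomeMatrix, k_mad: float = 5.0) -> list[str]:
    """Flag samples far from the main cluster in PCA space.

    The centered, unit-variance matrix (complete data required) is projected
    onto its first two principal components; each component is robustly
    standardized by median/MAD, and samples whose Euclidean robust distance
    exceeds ``k_mad`` are flagged.  Flagging is a report — removal is a user
    decision.
    """
    X = matrix.data.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    if np.isnan(X).any():
        raise ValueError("outlier detection requires a complete (imputed) matrix")
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("constant matrix")
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # PCA via SVD of the centered/scaled matrix
    u, s, _ = np.linalg.svd(Z, full_matrices=False)
    pcs = u[:, :2] * s[:2]
    med = np.median(pcs, axis=0)
    mad = np.median(np.abs(pcs - med), axis=0) * 1.4826
    mad = np.where(mad > 0, mad, np.finfo(float).eps)
    dist = np.sqrt((((pcs - med) / mad) ** 2).sum(axis=1))
    flagged = matrix.data.index[dist > k_mad]
    return list(flagged)


def _moment_priors(gamma_hat: np.ndarray, delta2_hat: np.ndarray):
    """Method-of-moments priors per batch: normal for gamma, inv-gamma for delta2."""
    gbar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 0.0
    m = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1) if delta2_hat.size > 1 else 0.0
    if s2 > 0:
        lam = (2 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2
    else:  # flat scale prior when proteins agree exactly
        lam, theta = 2.0 + 1e-8, m
    return gbar, t2, lam, theta


def combat_correct(
    matrix: ProteomeMatrix,
    batch_labels: pd.Series | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[ProteomeMatrix, BatchFit]:
    """Parametric empirical-Bayes location/scale batch correction.

    Per protein, data are standardized against the (batch-size weighted)
    grand mean and pooled variance; per-batch additive effects gamma and
    multiplicative effects delta2 are estimated and shrunk toward
    method-of-moments priors (normal for gamma, inverse-gamma for delta2)
    by the standard iterative conditional solution, then removed and the
    data back-transformed.  A single batch is a no-op.
    """
    labels = batch_labels if batch_labels is not None else matrix.batch
    if labels is None:
        raise ValueError("batch labels required")
    labels = pd.Series(labels).reindex(matrix.data.index)
    if labels.isna().any():
        raise ValueError("batch label missing for some samples")
    batches = sorted(labels.unique())
    X = matrix.data.to_numpy(dtype=float).T  # proteins x samples
    if np.isnan(X).any():
        raise ValueError("batch correction requires a complete (imputed) matrix")
    n_p, n_s = X.shape
    counts = labels.value_counts()
    if len(batches) == 1:
        fit = BatchFit(
            gamma_star=pd.DataFrame(0.0, index=batches, columns=matrix.data.columns),
            delta2_star=pd.DataFrame(1.0, index=batches, columns=matrix.data.columns),
            gamma_prior={}, delta2_prior={},
        )
        return matrix.copy_with(step={"step": "combat_correct", "batches": 1}), fit
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"singleton batch(es): {small}")

    idx = {b: np.where(labels.to_numpy() == b)[0] for b in batches}
    props = np.array([len(idx[b]) / n_s for b in batches])
    batch_means = np.stack([X[:, idx[b]].mean(axis=1) for b in batches])  # B x P
    grand = (props[:, None] * batch_means).sum(axis=0)
    bm_full = np.zeros_like(X)
    for i, b in enumerate(batches):
        bm_full[:, idx[b]] = batch_means[i][:, None]
    resid = X - bm_full
    pooled_var = (resid**2).mean(axis=1)
    pooled_var = np.where(pooled_var > 0, pooled_var, np.finfo(float).eps)
    sd = np.sqrt(pooled_var)
    Z = (X - grand[:, None]) / sd[:, None]

    gamma_star = np.zeros((len(batches), n_p))
    delta2_star = np.ones((len(batches), n_p))
    gprior, dprior = {}, {}
    Z_adj = Z.copy()
    for bi, b in enumerate(batches):
        Zb = Z[:, idx[b]]
        nb = Zb.shape[1]
        g_hat = Zb.mean(axis=1)
        d2_hat = Zb.var(axis=1, ddof=1)
        gbar, t2, lam, theta = _moment_priors(g_hat, d2_hat)
        gprior[b] = {"mean": float(gbar), "var": float(t2)}
        dprior[b] = {"shape": float(lam), "scale": float(theta)}
        g = g_hat.copy()
        d2 = d2_hat.copy()
        for _ in range(max_iter):
            if t2 > 0:
                g_new = (nb * t2 * g_hat + d2 * gbar) / (nb * t2 + d2)
            else:
                g_new = np.full_like(g_hat, gbar)
            sse = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d2_new = (theta + 0.5 * sse) / (nb / 2 + lam - 1)
            change = max(
                np.max(np.abs(g_new - g)), np.max(np.abs(d2_new - d2))
            )
            g, d2 = g_new, d2_new
            if change < tol:
                break
        gamma_star[bi], delta2_star[bi] = g, np.maximum(d2, np.finfo(float).eps)
        Z_adj[:, idx[b]] = (Zb - g[:, None]) / np.sqrt(delta2_star[bi])[:, None]

    X_adj = Z_adj * sd[:, None] + grand[:, None]
    data = pd.DataFrame(
        X_adj.T, index=matrix.data.index, columns=matrix.data.columns
    )
    fit = BatchFit(
        gamma_star=pd.DataFrame(gamma_star, index=batches,
                                columns=matrix.data.columns),
        delta2_star=pd.DataFrame(delta2_star, index=batches,
                                 columns=matrix.data.columns),
        gamma_prior=gprior,
        delta2_prior=dprior,
    )
    out = matrix.copy_with(
        data=data, step={"step": "combat_correct", "batches": len(batches)}
    )
    out.batch = labels
    return out, fit


def preprocess_pipeline(
    raw: RawProteomeTable,
    batch_labels: pd.Series | None = None,
    q_max: float = 0.01,
    max_na: float = 0.80,
    impute_percentile: float = 5.0,
    k_mad: float = 5.0,
    seed: int = 0,
    remove_outliers: bool = True,
) -> tuple[ProteomeMatrix, dict]:
    """Standard preprocessing chain in the documented order.

    build_matrix -> filter_missing -> vsn_normalize -> impute_low ->
    detect_outliers (optional removal) -> combat_correct (if batches given).
    Returns the final matrix and a dict of intermediate fits/flags.
    """
    matrix = build_matrix(raw, q_max=q_max)
    matrix = filter_missing(matrix, max_na=max_na)
    matrix, norm_fit = vsn_normalize(matrix)
    matrix = impute_low(matrix, percentile=impute_percentile, seed=seed)
    flagged = detect_outliers(matrix, k_mad=k_mad)
    if remove_outliers and flagged:
        keep = ~matrix.data.index.isin(flagged)
        matrix = matrix.copy_with(
            data=matrix.data[keep],
            observed=matrix.observed[keep],
            step={"step": "remove_outliers", "removed": list(flagged)},
        )
    batch_fit = None
    if batch_labels is not None:
        labels = pd.Series(batch_labels).reindex(matrix.data.index)
        matrix, batch_fit = combat_correct(matrix, labels)
    return matrix, {
        "normalization": norm_fit,
        "outliers": flagged,
        "batch": batch_fit,
    }
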