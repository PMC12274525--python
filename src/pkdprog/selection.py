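"""Weighted-LASSO stability selection of proteins predicting eGFR slope.

Extreme eGFR slopes (strong gainers or very fast progressors) are often
measurement artifacts or intercurrent illness; the selection procedure
down-weights them with Huber-style observation weights, then repeatedly
resamples 2:1 train/test splits, tunes the L1 penalty by 10-fold
cross-validation within each training part, and keeps proteins whose
coefficient is nonzero in at least 75% of the resampled fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from sklearn.linear_model import lasso_path

__all__ = [
    "StabilityConfig",
    "SelectionResult",
    "slope_weights",
    "weighted_lasso_cv",
    "stability_select",
]


@dataclass(frozen=True)
class StabilityConfig:
    n_reps: int = 100
    train_fraction: float = 2.0 / 3.0  # 2:1 train:test split
    cv_folds: int = 10
    frequency_threshold: float = 0.75
    weight_scheme: str = "huber"  # "huber" | "uniform" | "custom"
    huber_k: float = 1.345
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if not 0 < self.frequency_threshold <= 1:
            errors.append("frequency_threshold must be in (0, 1]")
        if self.cv_folds < 2:
            errors.append("cv_folds must be >= 2")
        if self.n_reps < 1:
            errors.append("n_reps must be >= 1")
        if not 0 < self.train_fraction < 1:
            errors.append("train_fraction must be in (0, 1)")
        if self.weight_scheme not in {"huber", "uniform", "custom"}:
            errors.append(f"unknown weight scheme {self.weight_scheme!r}")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class SelectionResult:
    frequency: pd.Series  # per protein, in [0, 1]
    selected: list[str]
    lambda_opt: list[float]  # per replicate
    nonzero_sets: list[list[str]] = field(default_factory=list)


def slope_weights(slopes, scheme: str = "huber", k: float = 1.345) -> np.ndarray:
    """Observation weights for the outcome vector.

    Huber scheme: standardized residual ``u = (y - median) / MAD_sigma``
    (MAD scaled by 1.4826 for consistency at the normal), weight 1 inside
    |u| <= k and k/|u| outside, so extreme slopes lose influence smoothly.
    """
    y = np.asarray(slopes, dtype=float)
    if y.size < 1:
        raise ValueError("need at least one slope")
    if scheme == "uniform":
        return np.ones_like(y)
    if scheme != "huber":
        raise ValueError(f"unknown scheme {scheme!r}")
    mad = median_abs_deviation(y, scale="normal")
    if mad == 0:
        raise ValueError("MAD of slopes is zero; huber weights undefined")
    u = np.abs(y - np.median(y)) / mad
    with np.errstate(divide="ignore"):
        w = np.where(u <= k, 1.0, k / u)
    return w


def _lambda_grid(Xw: np.ndarray, yw: np.ndarray, n_lambdas: int,
                 min_ratio: float) -> np.ndarray:
    # smallest penalty with an all-zero solution under the stated objective
    lam_max = 2.0 * np.max(np.abs(Xw.T @ yw)) / len(yw)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def weighted_lasso_cv(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    folds: int = 10,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Cross-validated weighted LASSO on a pathwise penalty grid.

    The objective is ``sum w_i (y_i - b0 - X beta)^2 / sum(w) +
    lambda * ||beta||_1``; observations enter through the square-root-weight
    transform, the grid runs from the smallest all-zero penalty down by
    ``lambda_min_ratio``, and the penalty minimizing the mean weighted CV
    error is chosen (ties broken toward the larger, sparser lambda).
    Returns (lambda_opt, coefficients-on-input-scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(y)
    if X.shape[0] != n or len(w) != n:
        raise ValueError("X, y and w must agree in length")
    if folds > n:
        raise ValueError(f"{folds} folds but only {n} observations")
    wn = w * n / w.sum()  # normalize mean weight to 1

    def _prepare(Xs, ys, ws):
        """Weighted centering + sqrt-weight transform (intercept absorbed)."""
        mw = ws / ws.sum()
        xm = mw @ Xs
        ym = float(mw @ ys)
        sw = np.sqrt(ws)
        return sw[:, None] * (Xs - xm), sw * (ys - ym), xm, ym

    Xw, yw, _, _ = _prepare(X, y, wn)
    lambdas = _lambda_grid(Xw, yw, n_lambdas, lambda_min_ratio)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)
    cv_err = np.zeros((folds, len(lambdas)))
    cv_wsum = np.zeros(folds)
    for f, test_idx in enumerate(fold_ids):
        if test_idx.size == 0:
            raise ValueError("degenerate (empty) CV fold")
        train = np.setdiff1d(perm, test_idx)
        Xt, yt, xm, ym = _prepare(X[train], y[train], wn[train])
        # alphas for sklearn's (1/2n)||.||^2 + alpha||.||_1 convention
        _, coefs, _ = lasso_path(Xt, yt, alphas=lambdas / 2.0, max_iter=5000,
                                 tol=1e-3)
        pred = (X[test_idx] - xm) @ coefs + ym  # n_test x n_lambdas
        err = (y[test_idx][:, None] - pred) ** 2
        cv_err[f] = wn[test_idx] @ err
        cv_wsum[f] = wn[test_idx].sum()
    mean_err = cv_err.sum(axis=0) / cv_wsum.sum()
    best = int(np.flatnonzero(mean_err <= mean_err.min() + 1e-12)[0])
    lam_opt = float(lambdas[best])

    _, coefs_full, _ = lasso_path(Xw, yw, alphas=lambdas / 2.0, max_iter=5000)
    return lam_opt, coefs_full[:, best]


def stability_select(
    X: pd.DataFrame,
    y: pd.Series,
    config: StabilityConfig = StabilityConfig(),
    custom_weights: np.ndarray | None = None,
) -> SelectionResult:
    """Resampled weighted-LASSO selection frequencies.

    For each of ``n_reps`` seeded 2:1 train/test splits the weighted LASSO
    is tuned by ``cv_folds``-fold CV on the training part (predictors
    z-scored within the split); a protein's frequency is the fraction of
    replicates in which its coefficient is nonzero, and the selected set is
    every protein at or above the frequency threshold.
    """
    config.validate()
    common = X.index.intersection(y.index)
    if len(common) != len(X.index):
        raise ValueError("X and y sample sets differ")
    n = len(common)
    n_train = int(round(n * config.train_fraction))
    if n < 15 or n_train <= config.cv_folds:
        raise ValueError(
            f"{n} samples cannot support a 2:1 split with {config.cv_folds}-fold CV"
        )
    Xv = X.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    genes = list(X.columns)

    if config.weight_scheme == "custom":
        if custom_weights is None or len(custom_weights) != n:
            raise ValueError("custom scheme requires per-sample weights")

    root = np.random.default_rng(config.seed)
    counts = np.zeros(len(genes))
    lam_opts: list[float] = []
    nonzero_sets: list[list[str]] = []
    for rep in range(config.n_reps):
        rep_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        order = rng.permutation(n)
        train = order[:n_train]
        Xt = Xv[train]
        yt = yv[train]
        mu, sd = Xt.mean(axis=0), Xt.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xt = (Xt - mu) / sd
        if config.weight_scheme == "custom":
            w = np.asarray(custom_weights, dtype=float)[train]
        else:
            w = slope_weights(yt, scheme=config.weight_scheme, k=config.huber_k)
        lam, coef = weighted_lasso_cv(
            Xt, yt, w,
            folds=config.cv_folds,
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
            seed=rep_seed,
        )
        nz = np.abs(coef) > 1e-12
        counts += nz
        lam_opts.append(lam)
        nonzero_sets.append([g for g, flag in zip(genes, nz) if flag])

    freq = pd.Series(counts / config.n_reps, index=genes, name="frequency")
    selected = [g for g in genes if freq[g] >= config.frequency_threshold]
    return SelectionResult(
        frequency=freq,
        selected=selected,
        lambda_opt=lam_opts,
        nonzero_sets=nonzero_sets,
    )
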