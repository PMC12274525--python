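"""Linear eGFR-slope progression models and the imaging-based comparator.

Provides design-matrix construction for the standard model families
(proteome / clinical / combined, with optional genotype terms and a
four-protein variant), ordinary-least-squares fitting with per-term Wald
inference, evaluation of the published screening-cohort coefficient sets
shipped as packaged data, the Mayo Imaging Classification (class from the
htTKV-derived theoretical kidney growth rate, with a refit class-mean slope
model), and seeded 2:1 train/test cross-validation.

Protein predictors are standardized (z-scored); clinical terms enter in
natural units.  The published coefficient sets assume the same scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PROTEOME_PANEL",
    "PROTEOME4_PANEL",
    "ModelSpec",
    "FittedModel",
    "MICClassification",
    "load_published_models",
    "build_design",
    "fit_linear_model",
    "adjusted_r2",
    "evaluate_published",
    "mic_classify",
    "fit_mic_model",
    "cross_validate",
]

PROTEOME_PANEL = ["SERPINF1", "GPX3", "AFM", "FERMT3", "CFHR1", "RARRES2"]
PROTEOME4_PANEL = ["SERPINF1", "GPX3", "AFM", "CFHR1"]

MIC_REFERENCE_HTTKV = 150.0  # mL/m; htTKV of a notional cyst-free kidney
MIC_BOUNDS = [0.015, 0.03, 0.045, 0.06]  # yearly growth-rate class bounds
MIC_CLASSES = ["1A", "1B", "1C", "1D", "1E"]


@dataclass(frozen=True)
class ModelSpec:
    """Term set of one model family."""

    name: str
    proteins: tuple = ()
    clinical: bool = False  # age, sex, eGFR, Mayo dummies
    genotype: bool = False  # PKD1-truncating / PKD1-non-truncating vs PKD2

    @classmethod
    def named(cls, name: str) -> "ModelSpec":
        registry = {
            "proteome": cls("proteome", tuple(PROTEOME_PANEL)),
            "proteome4": cls("proteome4", tuple(PROTEOME4_PANEL)),
            "clinical": cls("clinical", (), clinical=True),
            "combined": cls("combined", tuple(PROTEOME_PANEL), clinical=True),
            "clinical_genotype": cls(
                "clinical_genotype", (), clinical=True, genotype=True
            ),
            "combined_genotype": cls(
                "combined_genotype", tuple(PROTEOME_PANEL), clinical=True,
                genotype=True,
            ),
        }
        if name not in registry:
            raise ValueError(f"unknown model spec {name!r}; "
                             f"choose from {sorted(registry)}")
        return registry[name]


@dataclass
class FittedModel:
    """OLS fit with per-term Wald inference and stored predictor scaling."""

    name: str
    terms: list[str]  # includes "(Intercept)"
    beta: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    n: int
    r2: float
    r2_adjusted: float
    resid_se: float
    scaling: dict = field(default_factory=dict)  # protein -> (mean, sd)

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(design))]
            + [design[t].to_numpy(dtype=float) for t in self.terms[1:]]
        )
        return X @ self.beta

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
            },
            index=self.terms,
        )

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "terms": self.terms,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "ci_lower": self.ci_lower.tolist(),
            "ci_upper": self.ci_upper.tolist(),
            "p": self.p.tolist(),
            "n": self.n,
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "resid_se": self.resid_se,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            name=d["name"],
            terms=d["terms"],
            beta=np.asarray(d["beta"]),
            se=np.asarray(d["se"]),
            ci_lower=np.asarray(d["ci_lower"]),
            ci_upper=np.asarray(d["ci_upper"]),
            p=np.asarray(d["p"]),
            n=d["n"],
            r2=d["r2"],
            r2_adjusted=d["r2_adjusted"],
            resid_se=d["resid_se"],
            scaling={k: tuple(v) for k, v in d["scaling"].items()},
        )


def load_published_models() -> dict:
    """The published screening-cohort coefficient sets (packaged data).

    Keys: ``proteome``, ``clinical``, ``combined``.  Protein coefficients
    are per standardized abundance unit; clinical coefficients per natural
    unit; Mayo and sex enter as indicator terms.
    """
    text = (
        resources.files("pkdprog").joinpath("data/published_models.json").read_text()
    )
    models = json.loads(text)
    models.pop("_comment", None)
    return models


def _mayo_dummies(mayo: pd.Series) -> pd.DataFrame:
    valid = set(MIC_CLASSES)
    bad = set(mayo.dropna().astype(str)) - valid
    if bad:
        raise ValueError(f"unknown Mayo class(es): {sorted(bad)}")
    m = mayo.astype(str)
    return pd.DataFrame(
        {
            "MAYO[1C]": (m == "1C").astype(float),
            "MAYO[1D-1E]": m.isin(["1D", "1E"]).astype(float),
        },
        index=mayo.index,
    )


def build_design(
    clinical: pd.DataFrame,
    matrix: pd.DataFrame | None,
    spec: ModelSpec,
    response: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series | None, dict]:
    """Assemble the design matrix for one model family.

    ``clinical`` is indexed by sample/patient id with columns as needed
    (age, sex, egfr, mayo_class, genotype); ``matrix`` holds protein
    abundances.  Protein columns are z-scored (scaling returned for later
    evaluation on the training scale); Mayo is coded as 1C and pooled 1D-1E
    dummies against the pooled 1A-1B reference; sex is male=1.  Rows with
    any missing required term are dropped (complete cases).
    """
    parts = []
    if spec.proteins:
        if matrix is None:
            raise ValueError("model spec requires a protein matrix")
        missing = [g for g in spec.proteins if g not in matrix.columns]
        if missing:
            raise ValueError(f"protein(s) absent from matrix: {missing}")
        parts.append(matrix[list(spec.proteins)].astype(float))
    if spec.clinical:
        for col in ("age", "sex", "egfr", "mayo_class"):
            if col not in clinical.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        male = (
            clinical["sex"].astype(str).str.lower().isin(["m", "male"])
        ).astype(float)
        clin = pd.DataFrame(
            {"Age": clinical["age"].astype(float), "Sex[Male]": male,
             "eGFR": clinical["egfr"].astype(float)},
            index=clinical.index,
        )
        clin = pd.concat([clin, _mayo_dummies(clinical["mayo_class"])], axis=1)
        parts.append(clin)
    if spec.genotype:
        if "genotype" not in clinical.columns:
            raise ValueError("clinical table lacks required column 'genotype'")
        g = clinical["genotype"].astype(str)
        parts.append(
            pd.DataFrame(
                {
                    "PKD1[truncating]": (g == "PKD1_truncating").astype(float),
                    "PKD1[non-truncating]": (
                        g == "PKD1_non_truncating"
                    ).astype(float),
                },
                index=clinical.index,
            )
        )
    if not parts:
        raise ValueError("model spec has no terms")
    design = pd.concat(parts, axis=1, join="inner")
    if response is not None:
        design = design.join(response.rename("__y__"), how="inner")
    design = design.dropna()
    y = None
    if response is not None:
        y = design.pop("__y__")
    scaling: dict = {}
    for g in spec.proteins:
        mu = float(design[g].mean())
        sd = float(design[g].std(ddof=0))
        if sd == 0:
            raise ValueError(f"protein {g} is constant in the design")
        design[g] = (design[g] - mu) / sd
        scaling[g] = (mu, sd)
    return design, y, scaling


def fit_linear_model(
    design: pd.DataFrame,
    y: pd.Series | np.ndarray,
    name: str = "model",
    scaling: dict | None = None,
) -> FittedModel:
    """Ordinary least squares with t-based CIs and two-sided p-values."""
    yv = np.asarray(y, dtype=float)
    n, k = design.shape
    if n <= k + 1:
        raise ValueError(f"n={n} observations cannot fit {k} terms + intercept")
    X = np.column_stack([np.ones(n), design.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by QR pivoting on the R diagonal
        _, R = np.linalg.qr(X)
        small = np.abs(np.diag(R)) < 1e-8 * np.abs(np.diag(R)).max()
        names = ["(Intercept)"] + list(design.columns)
        bad = [names[i] for i in np.flatnonzero(small)]
        raise ValueError(f"rank-deficient design; collinear term(s): {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    df = n - X.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tval = beta / se
    p = 2 * stats.t.sf(np.abs(tval), df)
    tcrit = stats.t.ppf(0.975, df)
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    return FittedModel(
        name=name,
        terms=["(Intercept)"] + list(design.columns),
        beta=beta,
        se=se,
        ci_lower=beta - tcrit * se,
        ci_upper=beta + tcrit * se,
        p=p,
        n=n,
        r2=r2,
        r2_adjusted=adjusted_r2(r2, n, k),
        resid_se=float(np.sqrt(s2)),
        scaling=scaling or {},
    )


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError(f"n={n} must exceed k+1={k + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def evaluate_published(
    model: dict | str, inputs: dict | pd.DataFrame
) -> float | np.ndarray:
    """Evaluate a published coefficient set at given inputs.

    ``model`` is a name (``proteome``/``clinical``/``combined``) or a dict
    with a ``terms`` mapping.  ``inputs`` supplies each non-intercept term
    on the training scale: protein terms as z-scores, Age in years, eGFR in
    mL/min/1.73m2, Sex[Male] and Mayo dummies as 0/1.  Protein inputs with
    |z| > 10 are rejected as presumably unscaled.
    """
    if isinstance(model, str):
        model = load_published_models()[model]
    terms = model["terms"]
    frame = isinstance(inputs, pd.DataFrame)
    needed = [t for t in terms if t != "(Intercept)"]
    for t in needed:
        if (t not in inputs) if not frame else (t not in inputs.columns):
            raise ValueError(f"missing model term {t!r}")
        val = np.asarray(inputs[t], dtype=float)
        if t in PROTEOME_PANEL and np.any(np.abs(val) > 10):
            raise ValueError(
                f"{t} input magnitude {np.max(np.abs(val)):.3g} implausible "
                "for a z-scored abundance; standardize proteins first"
            )
    out = np.full(len(inputs) if frame else 1, terms["(Intercept)"]["beta"],
                  dtype=float)
    for t in needed:
        out = out + terms[t]["beta"] * np.asarray(inputs[t], dtype=float)
    return out if frame else float(out[0])


@dataclass
class MICClassification:
    patient_id: str
    httkv: float  # mL/m
    age: float  # years
    growth_rate: float  # estimated yearly fractional kidney growth
    mic_class: str  # 1A..1E


def mic_classify(httkv, age, patient_id: str = "") -> MICClassification:
    """Mayo Imaging Classification from height-adjusted TKV and age.

    The theoretical yearly kidney growth rate ``r = ln(htTKV/150)/age``
    maps to classes 1A < 1.5%, 1B [1.5, 3)%, 1C [3, 4.5)%, 1D [4.5, 6)%,
    1E >= 6% per year (half-open intervals).
    """
    if httkv <= 0:
        raise ValueError("htTKV must be positive")
    if age <= 0:
        raise ValueError("age must be positive")
    r = float(np.log(httkv / MIC_REFERENCE_HTTKV) / age)
    idx = int(np.searchsorted(MIC_BOUNDS, r, side="right"))
    return MICClassification(patient_id, float(httkv), float(age), r,
                             MIC_CLASSES[idx])


def fit_mic_model(classes: pd.Series, slopes: pd.Series) -> FittedModel:
    """Class-mean slope model on Mayo class indicators (refit comparator).

    The prediction for a patient is the mean observed slope of their Mayo
    class in the fitting cohort; implemented as OLS on class dummies so the
    output carries the same inference fields as the other models.
    """
    common = classes.index.intersection(slopes.index)
    cls = classes.loc[common].astype(str)
    present = sorted(cls.unique())
    if len(present) < 2:
        raise ValueError("need >= 2 Mayo classes to fit the comparator")
    small = [c for c in present if (cls == c).sum() < 2]
    if small:
        raise ValueError(f"Mayo class(es) with < 2 patients: {small}")
    dummies = pd.get_dummies(cls, prefix="MIC", prefix_sep="[").astype(float)
    dummies.columns = [c + "]" for c in dummies.columns]
    design = dummies.iloc[:, 1:]  # first class is the reference
    return fit_linear_model(design, slopes.loc[common], name="mic")


def cross_validate(
    design: pd.DataFrame,
    y: pd.Series,
    reps: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Repeated 2:1 train/test validation of an OLS model.

    Returns (median test R^2, mean test RMSE, per-rep table).  Test R^2 is
    1 - SSE/SST with SST around the test-set mean.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(design)
    n_train = int(round(n * train_fraction))
    if n_train <= design.shape[1] + 1 or n_train >= n:
        raise ValueError(f"n={n} cannot support the requested split")
    rng = np.random.default_rng(seed)
    yv = np.asarray(y, dtype=float)
    Xv = design.to_numpy(dtype=float)
    rows = []
    for rep in range(reps):
        order = rng.permutation(n)
        tr, te = order[:n_train], order[n_train:]
        Xtr = np.column_stack([np.ones(len(tr)), Xv[tr]])
        beta, _, _, _ = np.linalg.lstsq(Xtr, yv[tr], rcond=None)
        pred = np.column_stack([np.ones(len(te)), Xv[te]]) @ beta
        err = yv[te] - pred
        sst = float(((yv[te] - yv[te].mean()) ** 2).sum())
        r2 = 1.0 - float(err @ err) / sst if sst > 0 else np.nan
        rows.append({"rep": rep, "r2_test": r2,
                     "rmse_test": float(np.sqrt(np.mean(err**2)))})
    table = pd.DataFrame(rows)
    return (
        float(table["r2_test"].median()),
        float(table["rmse_test"].mean()),
        table,
    )
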