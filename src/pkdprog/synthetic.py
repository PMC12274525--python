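"""Synthetic ADPKD cohort and DIA serum-proteome generator.

The registry data the analysis pipeline was designed for are not public, so
this module generates inputs with the same statistical structure: a clinical
table with demographics matching a typical ADPKD screening cohort (median
age ~46 y, ~57% female, median eGFR ~66 mL/min/1.73m2, median follow-up
~6.8 y), per-patient linear eGFR trajectories observed through noisy serum
creatinine at jittered annual visits, intervention events that censor
subsequent measurements, and a long-format DIA protein-group report whose
log-intensities carry slope-linked effects for six designated marker
proteins, eGFR-linked effects, batch location/scale structure, left-censored
(missing-not-at-random) low-abundance values and injected outlier samples.

Ground truth (true slopes, effect coefficients, batch parameters, outlier
ids) is exported alongside so recovery tests are self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .renal import creatinine_from_egfr, DAYS_PER_YEAR

__all__ = [
    "CohortConfig",
    "ProteomeSimConfig",
    "GroundTruth",
    "MARKER_EFFECT_SIGNS",
    "default_marker_effects",
    "generate_cohort",
    "generate_proteome",
    "apply_cohort_shift",
    "write_cohort",
]

# The six serum markers of the progression panel and the direction of their
# association with annual eGFR slope (negative: lower abundance in faster
# progressors ... i.e. abundance falls as the slope becomes more negative).
MARKER_EFFECT_SIGNS = {
    "SERPINF1": -1.0,
    "GPX3": +1.0,
    "AFM": +1.0,
    "FERMT3": -1.0,
    "CFHR1": -1.0,
    "RARRES2": -1.0,
}


def default_marker_effects(
    effect_size_sd: float = 1.0,
    slope_sd: float = 2.5,
    noise_sd: float = 0.5,
) -> dict[str, float]:
    """Slope coefficients on log-intensity for the six marker proteins.

    ``effect_size_sd`` is the per-slope-SD shift of log-intensity expressed
    in residual-noise SDs; the returned coefficient is per unit of slope
    (mL/min/1.73m2/year).  The default of one noise-SD per slope-SD is set
    so that after batch scale jitter, variance-stabilizing compression and
    low-tail imputation the realized standardized effect in the processed
    matrix still reaches the half-SD design point of a clearly detectable
    serum marker.
    """
    coef = effect_size_sd * noise_sd / slope_sd
    return {g: s * coef for g, s in MARKER_EFFECT_SIGNS.items()}


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of the clinical cohort."""

    n_patients: int = 214
    female_fraction: float = 0.565
    age_mean: float = 46.0  # years at baseline
    age_sd: float = 12.0
    baseline_egfr_range: tuple[float, float] = (30.0, 110.0)  # mL/min/1.73m2
    true_slope_mean: float = -2.7  # mL/min/1.73m2/year
    true_slope_sd: float = 2.5
    creatinine_noise_cv: float = 0.05  # multiplicative log-normal CV
    visits_per_year: float = 4.0  # routine-care creatinine draws, ~quarterly
    followup_years_median: float = 6.8
    tolvaptan_prob: float = 0.15
    dialysis_prob: float = 0.01
    nephrectomy_prob: float = 0.02
    transplant_prob: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_patients < 1:
            errors.append("n_patients must be >= 1")
        for name in (
            "female_fraction",
            "tolvaptan_prob",
            "dialysis_prob",
            "nephrectomy_prob",
            "transplant_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must be in [0, 1], got {v}")
        if self.creatinine_noise_cv < 0:
            errors.append("creatinine_noise_cv must be >= 0")
        lo, hi = self.baseline_egfr_range
        if not 0 < lo < hi:
            errors.append("baseline_egfr_range must satisfy 0 < lo < hi")
        # need at least 3 scheduled visits within the median follow-up
        if self.followup_years_median * self.visits_per_year < 2:
            errors.append(
                "followup_years_median * visits_per_year must be >= 2 "
                "(supports >= 3 visits)"
            )
        if errors:
            raise ValueError("; ".join(errors))


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Generative parameters of the DIA protein-group report."""

    n_proteins: int = 200
    marker_effects: dict = field(default_factory=default_marker_effects)
    egfr_effects: dict = field(default_factory=lambda: {"CST3": -0.015})
    n_batches: int = 2
    batch_shift_sd: float = 0.3  # log-intensity units
    batch_scale_sd: float = 0.2  # log of per-batch scale factor
    noise_sd: float = 0.5
    baseline_mean: float = 14.0  # natural-log intensity level
    baseline_sd: float = 2.0
    missing_censor_quantile: float = 0.02
    censor_mode: str = "global"  # "global" detection limit | "per_protein"
    rarres2_like_missing_rate: float = 0.222
    rarres2_like_protein: str = "RARRES2"
    rarres2_like_baseline_shift: float = -1.0  # baseline SDs; near detection limit
    outlier_samples: int = 0
    outlier_shift: float = 5.0  # log-intensity offset added to outliers
    q_value_fail_rate: float = 0.02  # fraction of rows with q > 0.01
    plasma_shift_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_proteins < len(MARKER_EFFECT_SIGNS):
            errors.append("n_proteins must cover the marker panel")
        for name in ("missing_censor_quantile", "rarres2_like_missing_rate",
                     "q_value_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must be in [0, 1], got {v}")
        if self.n_batches < 1:
            errors.append("n_batches must be >= 1")
        if self.censor_mode not in {"global", "per_protein"}:
            errors.append(f"unknown censor_mode {self.censor_mode!r}")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class GroundTruth:
    """Frozen generative state used by recovery tests."""

    true_slope: dict[str, float]
    true_baseline_egfr: dict[str, float]
    age_at_baseline: dict[str, float]
    sex: dict[str, str]
    baseline_date: dict[str, str]
    intervention_dates: dict[str, list]
    protein_slope_effects: dict[str, float] = field(default_factory=dict)
    protein_egfr_effects: dict[str, float] = field(default_factory=dict)
    batch_of_sample: dict[str, str] = field(default_factory=dict)
    batch_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    outlier_sample_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _patient_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate clinical, creatinine and intervention tables plus truth.

    Each patient follows a linear true eGFR trajectory
    ``egfr(t) = baseline + slope * t`` (floored at 5 to stay in the
    physiologic domain); serum creatinine at each visit is the exact CKD-EPI
    inverse of the true eGFR at the visit's age, multiplied by log-normal
    noise with the configured CV.  Visits follow a regular schedule of
    ``visits_per_year`` jittered uniformly by +/-30 days (baseline fixed).
    Interventions are placed uniformly in the middle of follow-up and do not
    alter the generated creatinine; they matter through censoring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = _patient_ids(n)

    female = rng.random(n) < config.female_fraction
    age0 = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 80.0)
    lo, hi = config.baseline_egfr_range
    egfr0 = rng.uniform(lo, hi, n)
    slope = rng.normal(config.true_slope_mean, config.true_slope_sd, n)
    # htTKV on a log scale centred near Mayo class 1C for a mid-aged cohort
    httkv = np.exp(rng.normal(np.log(700.0), 0.45, n)) + 150.0
    genotype = rng.choice(
        ["PKD1_truncating", "PKD1_non_truncating", "PKD2"], size=n,
        p=[0.55, 0.17, 0.28],
    )
    base_dates = np.datetime64("2015-01-01") + rng.integers(0, 731, n).astype(
        "timedelta64[D]"
    )
    followup = config.followup_years_median * np.exp(rng.normal(0.0, 0.25, n))
    min_follow = 2.0 / config.visits_per_year + 90.0 / DAYS_PER_YEAR
    followup = np.maximum(followup, min_follow)

    sigma = np.sqrt(np.log1p(config.creatinine_noise_cv**2))

    clin_rows, scr_rows, int_rows = [], [], []
    truth = GroundTruth(
        true_slope={}, true_baseline_egfr={}, age_at_baseline={}, sex={},
        baseline_date={}, intervention_dates={},
    )
    interval_days = DAYS_PER_YEAR / config.visits_per_year
    for i, pid in enumerate(pids):
        sex = "female" if female[i] else "male"
        birth = base_dates[i] - np.timedelta64(
            int(round(age0[i] * DAYS_PER_YEAR)), "D"
        )
        clin_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "birth_date": str(birth),
                "htTKV_ml_per_m": round(float(httkv[i]), 1),
                "genotype": genotype[i],
            }
        )
        n_visits = int(np.floor(followup[i] * config.visits_per_year)) + 1
        sched = np.arange(n_visits) * interval_days
        jitter = rng.uniform(-30, 30, n_visits)
        jitter[0] = 0.0
        days = np.unique(np.round(sched + jitter).astype(int))
        days = days[days >= 0]
        for d in days:
            t_years = d / DAYS_PER_YEAR
            egfr_t = max(egfr0[i] + slope[i] * t_years, 5.0)
            # exact age from birth date keeps the generator/estimator maps inverse
            age_exact = ((base_dates[i] + np.timedelta64(int(d), "D")) - birth
                         ).astype(float) / DAYS_PER_YEAR
            scr = creatinine_from_egfr(egfr_t, age_exact, sex)
            scr *= np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            scr_rows.append(
                {
                    "patient_id": pid,
                    "date": str(base_dates[i] + np.timedelta64(int(d), "D")),
                    "scr_mg_dl": float(scr),
                }
            )
        events = []
        for ev, prob in (
            ("tolvaptan", config.tolvaptan_prob),
            ("dialysis", config.dialysis_prob),
            ("nephrectomy", config.nephrectomy_prob),
            ("transplant", config.transplant_prob),
        ):
            if rng.random() < prob:
                at = rng.uniform(0.3, 0.9) * followup[i] * DAYS_PER_YEAR
                date = base_dates[i] + np.timedelta64(int(round(at)), "D")
                int_rows.append({"patient_id": pid, "type": ev, "date": str(date)})
                events.append([ev, str(date)])
        truth.true_slope[pid] = float(slope[i])
        truth.true_baseline_egfr[pid] = float(egfr0[i])
        truth.age_at_baseline[pid] = float(age0[i])
        truth.sex[pid] = sex
        truth.baseline_date[pid] = str(base_dates[i])
        truth.intervention_dates[pid] = events

    clinical = pd.DataFrame(clin_rows)
    creatinine = pd.DataFrame(scr_rows)
    interventions = pd.DataFrame(int_rows, columns=["patient_id", "type", "date"])
    return clinical, creatinine, interventions, truth


def _gene_names(n: int, named: list[str]) -> list[str]:
    genes = list(named)
    i = 1
    while len(genes) < n:
        g = f"PROT{i:04d}"
        if g not in genes:
            genes.append(g)
        i += 1
    return genes[:n]


def generate_proteome(
    truth: GroundTruth,
    config: ProteomeSimConfig,
    patients: list[str] | None = None,
    run_prefix: str = "S",
) -> pd.DataFrame:
    """Long-format DIA protein-group report for one sample per patient.

    Log-intensity model per sample i, protein g::

        log I_ig = b_g + beta_g * slope_i + gamma_g * eGFR_i
                   + shift[batch(i), g] + scale[batch(i), g] * eps_ig

    Intensities are reported on the raw (exponentiated) scale with
    simulated q-values; a configurable fraction of rows receives q > 0.01
    to exercise the identification-confidence filter.  Values below each
    protein's censor quantile are dropped from the report (left-censored
    MNAR), with a designated high-missingness protein censored at
    ``rarres2_like_missing_rate``.  Outlier samples receive a global
    log-intensity offset.  Mutates ``truth`` with proteome ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if patients is None:
        patients = sorted(truth.true_slope)
    unknown = [p for p in patients if p not in truth.true_slope]
    if unknown:
        raise ValueError(f"patients not in ground truth: {unknown[:5]}")
    named = list(dict.fromkeys(
        list(config.marker_effects) + list(config.egfr_effects)
        + [config.rarres2_like_protein]
    ))
    genes = _gene_names(config.n_proteins, named)
    missing_effects = (
        set(config.marker_effects) | set(config.egfr_effects)
    ) - set(genes)
    if missing_effects:
        raise ValueError(
            f"effect map references absent proteins: {sorted(missing_effects)}"
        )
    n_s, n_p = len(patients), len(genes)

    slope = np.array([truth.true_slope[p] for p in patients])
    egfr = np.array([truth.true_baseline_egfr[p] for p in patients])
    beta = np.array([config.marker_effects.get(g, 0.0) for g in genes])
    gamma = np.array([config.egfr_effects.get(g, 0.0) for g in genes])
    b_g = rng.normal(config.baseline_mean, config.baseline_sd, n_p)
    for g in config.marker_effects:
        # panel markers other than the designated left-censored one are
        # abundant serum proteins, comfortably above the detection limit
        if g != config.rarres2_like_protein and g in genes:
            j = genes.index(g)
            b_g[j] = max(b_g[j], config.baseline_mean)
    if config.rarres2_like_protein in genes:
        # the designated high-missingness protein sits near the detection
        # limit, as real strongly left-censored serum proteins do
        b_g[genes.index(config.rarres2_like_protein)] = (
            config.baseline_mean
            + config.rarres2_like_baseline_shift * config.baseline_sd
        )

    batches = np.array([f"B{(i % config.n_batches) + 1}" for i in range(n_s)])
    shift = rng.normal(0.0, config.batch_shift_sd, (config.n_batches, n_p))
    scale = np.exp(rng.normal(0.0, config.batch_scale_sd, (config.n_batches, n_p)))
    batch_idx = np.array([int(b[1:]) - 1 for b in batches])

    eps = rng.normal(0.0, config.noise_sd, (n_s, n_p))
    logint = (
        b_g[None, :]
        + beta[None, :] * slope[:, None]
        + gamma[None, :] * egfr[:, None]
        + shift[batch_idx, :]
        + scale[batch_idx, :] * eps
    )
    outlier_ids: list[str] = []
    if config.outlier_samples > 0:
        pick = rng.choice(n_s, size=min(config.outlier_samples, n_s), replace=False)
        # sign-alternating per-protein displacement: a shared aberrant
        # direction that no per-sample affine recalibration can absorb
        pattern = rng.choice([-1.0, 1.0], size=n_p)
        logint[pick, :] += config.outlier_shift * pattern[None, :]
        outlier_ids = [f"{run_prefix}{patients[i]}" for i in pick]

    # left-censoring below the detection limit.  Default: one global
    # intensity threshold (the dataset-wide censor quantile), so missingness
    # concentrates in genuinely low-abundance proteins; "per_protein" mode
    # instead censors each protein at its own low quantile.
    if config.censor_mode == "global" and config.missing_censor_quantile > 0:
        thresh_global = np.quantile(logint, config.missing_censor_quantile)
        observed = logint > thresh_global
    elif config.censor_mode == "per_protein" and config.missing_censor_quantile > 0:
        thresh = np.quantile(logint, config.missing_censor_quantile, axis=0)
        observed = logint > thresh[None, :]
    else:
        observed = np.ones_like(logint, dtype=bool)
    if (
        config.rarres2_like_protein in genes
        and config.rarres2_like_missing_rate > 0
    ):
        j = genes.index(config.rarres2_like_protein)
        thresh_j = np.quantile(logint[:, j], config.rarres2_like_missing_rate)
        observed[:, j] = logint[:, j] > thresh_j

    runs = [f"{run_prefix}{p}" for p in patients]
    qvals = 10.0 ** rng.uniform(-4, -2.5, (n_s, n_p))
    if config.q_value_fail_rate > 0:
        # identification confidence degrades toward low intensity: failure
        # probability decays linearly in the global intensity rank, with the
        # configured overall rate
        ranks = np.argsort(np.argsort(logint.ravel())).reshape(
            logint.shape
        ) / logint.size
        p_fail = np.clip(2.0 * config.q_value_fail_rate * (1.0 - ranks), 0, 1)
        fail = rng.random((n_s, n_p)) < p_fail
        qvals[fail] = rng.uniform(0.011, 0.5, int(fail.sum()))

    rows = {
        "Run": np.repeat(runs, n_p),
        "Protein.Group": np.tile([f"PG_{g}" for g in genes], n_s),
        "Genes": np.tile(genes, n_s),
        "Q.Value": qvals.ravel(),
        "Intensity": np.exp(logint).ravel(),
    }
    report = pd.DataFrame(rows)[observed.ravel()]

    truth.protein_slope_effects = dict(zip(genes, beta.tolist()))
    truth.protein_egfr_effects = dict(zip(genes, gamma.tolist()))
    truth.batch_of_sample = dict(zip(runs, batches.tolist()))
    truth.batch_shift = {
        f"B{b + 1}": dict(zip(genes, shift[b].tolist()))
        for b in range(config.n_batches)
    }
    truth.outlier_sample_ids = outlier_ids
    return report.reset_index(drop=True)


def apply_cohort_shift(
    report: pd.DataFrame, plasma_shift_sd: float, seed: int
) -> pd.DataFrame:
    """Add a per-protein global log-intensity offset (cross-cohort shift).

    Emulates a systematic matrix difference (e.g. EDTA plasma vs serum):
    one offset per protein drawn N(0, plasma_shift_sd) and applied to all
    its intensities, leaving within-cohort correlation structure intact.
    """
    if plasma_shift_sd == 0:
        return report.copy()
    rng = np.random.default_rng(seed)
    genes = report["Genes"].unique()
    offset = dict(zip(genes, rng.normal(0.0, plasma_shift_sd, len(genes))))
    out = report.copy()
    out["Intensity"] = out["Intensity"] * np.exp(out["Genes"].map(offset))
    return out


def write_cohort(
    outdir: str | Path,
    clinical: pd.DataFrame,
    creatinine: pd.DataFrame,
    interventions: pd.DataFrame,
    truth: GroundTruth,
    report: pd.DataFrame | None = None,
) -> None:
    """Serialize generated tables to ``outdir`` in the documented formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(outdir / "clinical.csv", index=False)
    creatinine.to_csv(outdir / "creatinine.csv", index=False)
    interventions.to_csv(outdir / "interventions.csv", index=False)
    truth.to_json(outdir / "ground_truth.json")
    if report is not None:
        report.to_csv(outdir / "dia_report.tsv", sep="\t", index=False)
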