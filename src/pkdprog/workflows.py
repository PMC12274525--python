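"""End-to-end convenience workflows tying the pipeline stages together."""

from __future__ import annotations

import pandas as pd

from . import prep, renal, synthetic

__all__ = ["simulate_processed_cohort"]


def simulate_processed_cohort(
    cohort_cfg: synthetic.CohortConfig,
    prot_cfg: synthetic.ProteomeSimConfig,
    q_max: float = 0.01,
    max_na: float = 0.80,
    impute_percentile: float = 5.0,
    k_mad: float = 5.0,
    correct_batches: bool = True,
    remove_outliers: bool = True,
):
    """Simulate a cohort and run it through slopes + proteome preprocessing.

    Returns ``(matrix, slopes, truth, extras)`` where ``matrix`` is the
    processed abundance matrix indexed by patient id, ``slopes`` the
    included patients' annual eGFR slopes aligned to the matrix, ``truth``
    the generator's ground truth, and ``extras`` the slope table plus
    preprocessing fits.
    """
    clinical, creatinine, interventions, truth = synthetic.generate_cohort(cohort_cfg)
    slope_table = renal.slopes_pipeline(creatinine, clinical, interventions)
    report = synthetic.generate_proteome(truth, prot_cfg)
    batch = pd.Series(truth.batch_of_sample)
    matrix, fits = prep.preprocess_pipeline(
        prep.RawProteomeTable(report),
        batch_labels=batch if correct_batches else None,
        q_max=q_max,
        max_na=max_na,
        impute_percentile=impute_percentile,
        k_mad=k_mad,
        seed=prot_cfg.seed,
        remove_outliers=remove_outliers,
    )
    # matrix rows are run ids (one sample per patient): strip the run prefix
    matrix.data.index = [r[1:] for r in matrix.data.index]
    matrix.observed.index = matrix.data.index
    included = slope_table[slope_table["included"]].set_index("patient_id")
    common = matrix.data.index.intersection(included.index)
    matrix.data = matrix.data.loc[common]
    matrix.observed = matrix.observed.loc[common]
    slopes = included.loc[common, "slope_annual"]
    return matrix, slopes, truth, {"slope_table": slope_table, **fits}
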