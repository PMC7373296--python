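"""Preprocessing of the protein quantity matrix.

Pipeline order mirrors standard label-free proteomics practice: an optional
local-regression (LOESS) normalization of intensity-dependent per-sample
bias, missingness bookkeeping on the *unimputed* matrix, detection-limit
imputation at half the per-protein minimum, then log10 transform with
control-SD rescaling.  The association scan downstream uses all imputable
proteins; the classifier stage restricts to proteins passing the
missingness filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import CohortTable

__all__ = [
    "TransformedMatrix",
    "impute_nondetects",
    "log10_and_scale",
    "local_regression_normalize",
    "filter_by_missingness",
    "summarize_by_group",
    "preprocess_cohort",
]


@dataclass
class TransformedMatrix:
    """Analysis-ready matrix: log10-transformed, control-SD-rescaled.

    ``values[s, p] = log10(quantity) / scale_factors[p]`` where the scale
    factor is the control-group SD of the log10 levels of protein ``p``
    (no centering; the logistic intercept absorbs location).
    ``retained_proteins`` lists proteins passing the pre-imputation
    missingness filter (used by the classifier stage).
    """

    values: pd.DataFrame
    scale_factors: pd.Series
    imputation_log: pd.DataFrame
    retained_proteins: list[str] = field(default_factory=list)

    def inverse_transform(self, protein: str, t: float | np.ndarray) -> float | np.ndarray:
        """Map a transformed level back to the raw intensity scale."""
        return 10.0 ** (np.asarray(t, dtype=float) * self.scale_factors[protein])

    def transform_raw(self, protein: str, raw: float | np.ndarray) -> float | np.ndarray:
        return np.log10(np.asarray(raw, dtype=float)) / self.scale_factors[protein]


def impute_nondetects(table: CohortTable) -> tuple[CohortTable, pd.DataFrame]:
    """Replace each missing cell with 50% of that protein's smallest observed value.

    Proteins with no observed value at all are dropped with a warning (no
    imputation value can be defined).  Returns the imputed table together
    with a per-protein log of imputed-cell counts and imputation values.
    Idempotent: a second application changes nothing.
    """
    q = table.quantities
    n_missing = q.isna().sum(axis=0)
    all_missing = q.columns[q.notna().sum(axis=0) == 0]
    if len(all_missing):
        warnings.warn(
            f"dropping {len(all_missing)} protein(s) with no observed values: "
            f"{list(all_missing)[:5]}",
            stacklevel=2,
        )
        q = q.drop(columns=all_missing)
        n_missing = n_missing.drop(all_missing)
    impute_value = 0.5 * q.min(axis=0, skipna=True)
    filled = q.fillna(impute_value)
    log = pd.DataFrame(
        {"n_imputed": n_missing.astype(int), "impute_value": impute_value}
    ).rename_axis(index="protein")
    out = CohortTable(filled, table.subjects.copy(), table.truth)
    return out, log


def filter_by_missingness(table: CohortTable, threshold: float = 0.5) -> list[str]:
    """Proteins whose missing fraction is <= threshold (strict > excludes).

    Assessed on the pre-imputation table: a protein missing in exactly
    half the subjects is retained, one missing in more than half is not.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    frac = table.quantities.isna().mean(axis=0)
    return list(frac.index[frac <= threshold])


def log10_and_scale(table: CohortTable, retained: list[str] | None = None) -> TransformedMatrix:
    """log10-transform and rescale every protein by its control-group SD.

    Expects a fully observed (imputed) table.  A protein whose control
    log10 levels have (near-)zero variance has no defined scale and raises
    an error naming it.
    """
    q = table.quantities
    if q.isna().any().any():
        raise ValueError("log10_and_scale expects an imputed (fully observed) matrix")
    controls = ~table.case_mask
    if controls.sum() < 2:
        raise ValueError("need at least two controls to define the control SD")
    log10_vals = np.log10(q)
    sd = log10_vals.loc[controls].std(axis=0, ddof=1)
    degenerate = sd.index[sd < 1e-12]
    if len(degenerate):
        raise ValueError(
            f"zero control variance for protein(s) {list(degenerate)[:5]}; "
            "scale undefined"
        )
    values = log10_vals / sd
    return TransformedMatrix(
        values=values,
        scale_factors=sd,
        imputation_log=pd.DataFrame(index=q.columns),
        retained_proteins=retained if retained is not None else list(q.columns),
    )


def local_regression_normalize(table: CohortTable, span: float = 0.75) -> CohortTable:
    """Remove per-sample intensity-dependent bias by LOESS on log ratios.

    The reference profile is the per-protein median log10 intensity across
    subjects.  For each subject, a LOESS curve of (log ratio to reference)
    versus (reference log intensity) is fitted and subtracted on the log
    scale; the output is re-exponentiated.  Subjects sharing fewer than 10
    observed proteins with the reference are left unnormalized with a
    warning.  Off by default in the pipeline.
    """
    q = table.quantities
    log_q = np.log10(q)
    ref = log_q.median(axis=0, skipna=True)
    out = log_q.to_numpy(copy=True)
    ref_ok = ref.notna().to_numpy()
    ref_vals = ref.to_numpy()
    for i, sid in enumerate(q.index):
        row = out[i]
        shared = ref_ok & ~np.isnan(row)
        if shared.sum() < 10:
            warnings.warn(
                f"subject {sid!r} shares <10 proteins with the reference; "
                "left unnormalized",
                stacklevel=2,
            )
            continue
        x = ref_vals[shared]
        y = row[shared] - x
        fitted = lowess(y, x, frac=span, return_sorted=False)
        row[shared] = row[shared] - fitted
    quantities = pd.DataFrame(10.0 ** out, index=q.index, columns=q.columns)
    quantities[q.isna()] = np.nan
    return CohortTable(quantities, table.subjects.copy(), table.truth)


def summarize_by_group(table: CohortTable, grouping: pd.Series) -> pd.DataFrame:
    """Per protein x group: n observed, mean and SEM of the raw levels.

    Missing cells are excluded from the moments; a single-observation
    group yields an undefined (NaN) SEM.
    """
    grouping = grouping.reindex(table.quantities.index)
    if grouping.isna().any():
        raise ValueError("grouping labels must cover all subjects")
    rows = []
    for label, idx in table.quantities.groupby(grouping).groups.items():
        sub = table.quantities.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"empty group {label!r}")
        n = sub.notna().sum(axis=0)
        mean = sub.mean(axis=0, skipna=True)
        sd = sub.std(axis=0, ddof=1, skipna=True)
        sem = sd / np.sqrt(n.where(n > 0))
        rows.append(pd.DataFrame({
            "group": label, "protein": sub.columns,
            "n": n.to_numpy(), "mean": mean.to_numpy(), "sem": sem.to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def preprocess_cohort(
    table: CohortTable,
    missingness_threshold: float = 0.5,
    lrn: bool = False,
    span: float = 0.75,
) -> TransformedMatrix:
    """Full preprocessing: (LOESS) -> filter bookkeeping -> impute -> transform.

    The missingness filter is evaluated on the pre-imputation matrix by
    construction; its verdict is recorded in ``retained_proteins`` and
    consumed only by the classifier stage.
    """
    if lrn:
        table = local_regression_normalize(table, span=span)
    retained = filter_by_missingness(table, missingness_threshold)
    imputed, log = impute_nondetects(table)
    retained = [p for p in retained if p in imputed.quantities.columns]
    tm = log10_and_scale(imputed, retained=retained)
    tm.imputation_log = log
    return tm
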