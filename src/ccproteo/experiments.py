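"""Simulation experiments calibrating the scan and the evaluation metrics.

These are the study-scale Monte-Carlo checks the pipeline's guarantees
rest on: family-wise error of the gate-keeping quadratic scan under a
global null, parameter recovery / CI coverage for an injected U-shaped
effect, its selection power, and AUROC calibration of the rank-statistic
estimator.  Both the test suite and the acceptance script drive these
functions, so the quantities are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .association import run_scan
from .cohort import CohortConfig, EffectSpec, generate_cohort
from .logistic import fit_logistic
from .panel import auroc
from .preprocess import preprocess_cohort

__all__ = [
    "NULL_SCAN_CONFIG",
    "FwerResult",
    "null_scan_fwer",
    "RecoveryResult",
    "quadratic_recovery",
    "ushape_selection_power",
    "null_auroc",
    "perfect_auroc",
]

#: null calibration cohort: 80 subjects x 100 proteins, no protein effects,
#: full covariate structure
NULL_SCAN_CONFIG = CohortConfig(
    n_cases=39, n_controls=41, n_proteins=100, effect_specs=(),
)


@dataclass
class FwerResult:
    n_cohorts: int
    n_any_quadratic: int
    n_any_linear: int

    @property
    def fwer_quadratic(self) -> float:
        return self.n_any_quadratic / self.n_cohorts

    @property
    def fwer_linear(self) -> float:
        return self.n_any_linear / self.n_cohorts

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(0.05 * 0.95 / self.n_cohorts))


def null_scan_fwer(
    n_cohorts: int = 300,
    seed: int = 0,
    alpha: float = 0.05,
    config: CohortConfig = NULL_SCAN_CONFIG,
) -> FwerResult:
    """Empirical FWER of the full scan over null-simulated cohorts.

    Each cohort is generated with all protein effects zero, preprocessed,
    and scanned with full covariate adjustment; a family-wise error is a
    cohort in which at least one protein is declared significant.
    """
    ss = np.random.SeedSequence(seed)
    n_any_q = n_any_l = 0
    for child in ss.spawn(n_cohorts):
        cohort_seed = int(child.generate_state(1)[0] % 2**31)
        table = generate_cohort(replace(config, seed=cohort_seed))
        tm = preprocess_cohort(table)
        results = run_scan(tm, table.subjects, alpha=alpha)
        n_any_q += any(r.quadratic_selected for r in results)
        n_any_l += any(r.linear_selected for r in results)
    return FwerResult(n_cohorts, n_any_q, n_any_l)


@dataclass
class RecoveryResult:
    n_replicates: int
    coverage_beta2: float
    mean_beta2_hat: float


def quadratic_recovery(
    n_replicates: int = 200,
    beta2: float = 1.5,
    beta1: float = 0.0,
    seed: int = 0,
) -> RecoveryResult:
    """Refit the generating quadratic model; 95% Wald CI coverage for beta2.

    The refit uses the generating parameterization (standardized log10
    level from the recorded truth) with the full covariate adjustment, so
    the Wald CI should cover the injected coefficient ~95% of the time
    (Prentice-Pyke retrospective-sampling property).  Cohorts are
    generated without censoring: the oracle checks the sampling design,
    not the detection-limit imputation.
    """
    from .association import build_design

    config = replace(NULL_SCAN_CONFIG, n_proteins=20,
                     detection_quantile=0.0, mcar_rate=0.0,
                     effect_specs=(EffectSpec(0, beta1=beta1, beta2=beta2),))
    ss = np.random.SeedSequence(seed)
    covered = 0
    estimates = []
    for child in ss.spawn(n_replicates):
        cohort_seed = int(child.generate_state(1)[0] % 2**31)
        table = generate_cohort(replace(config, seed=cohort_seed))
        mu = table.truth["protein_log10_mean"][0]
        sd = table.truth["protein_log10_sd"]
        z = (np.log10(table.quantities["P0001"].to_numpy()) - mu) / sd
        X0, _ = build_design(table.subjects)
        X = np.column_stack([X0.to_numpy(), z, z * z])
        y = table.case_mask.to_numpy(dtype=float)
        fit = fit_logistic(X, y)
        b2 = fit.coefficients[-1]
        se = np.sqrt(max(fit.covariance[-1, -1], 0.0))
        if abs(b2 - beta2) <= 1.959963984540054 * se:
            covered += 1
        estimates.append(b2)
    return RecoveryResult(n_replicates, covered / n_replicates,
                          float(np.mean(estimates)))


def ushape_selection_power(
    n_replicates: int = 30,
    beta2: float = 1.5,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """(true-selection rate, per-cohort false-selection count) of the scan
    on cohorts carrying one injected U-shaped protein."""
    config = replace(NULL_SCAN_CONFIG,
                     effect_specs=(EffectSpec(0, beta1=0.0, beta2=beta2),))
    ss = np.random.SeedSequence(seed)
    hits = 0
    false = 0
    for child in ss.spawn(n_replicates):
        cohort_seed = int(child.generate_state(1)[0] % 2**31)
        table = generate_cohort(replace(config, seed=cohort_seed))
        tm = preprocess_cohort(table)
        results = run_scan(tm, table.subjects, alpha=alpha)
        selected = {r.protein for r in results if r.quadratic_selected}
        hits += "P0001" in selected
        false += len(selected - {"P0001"})
    return hits / n_replicates, false / n_replicates


def null_auroc(n: int = 1000, seed: int = 0) -> float:
    """AUROC of scores independent of balanced random labels."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    rng.shuffle(labels)
    scores = rng.standard_normal(labels.size)
    return auroc(scores, labels)


def perfect_auroc(n_per_class: int = 100) -> float:
    """AUROC when every case score strictly exceeds every control score."""
    labels = np.r_[np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)]
    scores = np.r_[np.linspace(0, 1, n_per_class), np.linspace(2, 3, n_per_class)]
    return auroc(scores, labels)
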