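"""Synthetic case-control proteome cohorts with known ground truth.

Emulates a small plasma DIA-MS case-control study: ~80 subjects, a few
hundred proteins with relative intensities spanning orders of magnitude,
censoring of values below a per-protein detection limit, frequency-matched
demographic covariates, a clinically enriched binary comorbidity (sr-IBS),
and a handful of proteins whose transformed levels carry linear or U-shaped
log-odds effects on case status.

Outcome generation follows the retrospective-sampling design: a
superpopulation is drawn, case status is assigned prospectively by a
logistic model over standardized log10 protein levels and covariates, and
exactly ``n_cases`` cases and ``n_controls`` controls are then sampled.  By
the Prentice-Pyke result, logistic regression fitted to the sampled cohort
recovers the generating odds ratios (all coefficients except the
intercept), which is what makes the generator usable as a test oracle for
the downstream association scan.

Protein effects are parameterized on the centered, standardized log10
scale ``z = (log10(x) - mu_p) / sigma_p`` using the generating (true) mean
and SD of each protein, so that ``beta2 > 0`` produces a genuine U-shaped
risk profile with the minimum-risk level inside the observed range.  The
downstream scan fits the uncentered log10/control-SD scale; the two are
affinely related, so the quadratic model family and its likelihood-ratio
test are identical under either coding.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EffectSpec",
    "BinaryCovariate",
    "CategoricalCovariate",
    "CovariateModel",
    "CohortConfig",
    "CohortTable",
    "generate_cohort",
    "apply_missingness",
    "write_cohort",
    "read_cohort",
]

SUBJECT_COLUMNS = [
    "outcome",
    "age",
    "sex",
    "race",
    "site",
    "season",
    "bmi_class",
    "sr_ibs",
    "antidepressant",
    "batch",
]


@dataclass(frozen=True)
class EffectSpec:
    """Log-odds effect of one protein on case status.

    ``beta1``/``beta2`` are the linear/quadratic coefficients on the
    standardized log10 level; ``beta2 = 0`` is a purely linear effect,
    ``beta2 > 0`` a U-shaped risk profile.
    """

    protein_index: int
    beta1: float
    beta2: float = 0.0


@dataclass(frozen=True)
class BinaryCovariate:
    """Binary covariate with outcome-conditional prevalences.

    The generator draws the covariate conditionally on the sampled
    outcome.  Because the covariate is independent of the protein levels
    given the outcome, the implied joint model P(case | proteins, x) is
    exactly logistic with the protein coefficients unchanged and a
    covariate log-odds equal to the 2x2 log odds ratio of the two
    prevalences — so outcome-conditional sampling is consistent with the
    covariate-adjusted logistic scan.  Equal prevalences encode a
    frequency-matched covariate (zero effect).
    """

    name: str
    prevalence_cases: float
    prevalence_controls: float

    @property
    def log_odds(self) -> float:
        pc, p0 = self.prevalence_cases, self.prevalence_controls
        if pc == p0:
            return 0.0
        return math.log(pc / (1 - pc)) - math.log(p0 / (1 - p0))

    @property
    def marginal(self) -> float:
        return 0.5 * (self.prevalence_cases + self.prevalence_controls)


@dataclass(frozen=True)
class CategoricalCovariate:
    """Frequency-matched categorical covariate (no outcome effect)."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]


@dataclass(frozen=True)
class CovariateModel:
    """Generative settings for the subject covariates.

    Defaults emulate an ME/CFS case-control cohort of ~80 subjects:
    matched age/sex/race-ethnicity/site/season, overweight somewhat
    enriched in cases, sr-IBS strongly enriched in cases (48% vs 2%), and
    moderately enriched antidepressant use.
    """

    age_mean: float = 51.7
    age_sd: float = 11.0
    sex: BinaryCovariate = BinaryCovariate("sex", 0.775, 0.775)  # P(female)
    season: BinaryCovariate = BinaryCovariate("season", 0.55, 0.55)  # P(summer)
    bmi_class: BinaryCovariate = BinaryCovariate("bmi_class", 0.615, 0.44)  # P(overweight)
    sr_ibs: BinaryCovariate = BinaryCovariate("sr_ibs", 0.48, 0.02)
    antidepressant: BinaryCovariate = BinaryCovariate("antidepressant", 0.30, 0.10)
    race: CategoricalCovariate = CategoricalCovariate(
        "race", ("white", "hispanic", "asian", "other"), (0.87, 0.075, 0.03, 0.025)
    )
    site: CategoricalCovariate = CategoricalCovariate(
        "site",
        ("miami", "new_york", "salt_lake_city", "sierra"),
        (0.16, 0.30, 0.28, 0.26),
    )

    def validate(self) -> None:
        for cov in (self.sex, self.season, self.bmi_class, self.sr_ibs, self.antidepressant):
            for p in (cov.prevalence_cases, cov.prevalence_controls):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence of {cov.name!r} outside [0, 1]: {p}")
        for cov in (self.race, self.site):
            if len(cov.levels) != len(cov.probs):
                raise ValueError(f"levels/probs length mismatch for {cov.name!r}")
            if not math.isclose(sum(cov.probs), 1.0, abs_tol=1e-9):
                raise ValueError(f"probabilities of {cov.name!r} do not sum to 1")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of one synthetic cohort.

    Defaults are the study-scale conditions: 39 cases / 41 controls, 250
    proteins log-normal over roughly three orders of magnitude, a
    per-protein detection limit censoring the lowest 10% of values plus 2%
    missing completely at random, a single batch, and a signal consisting
    of eight moderate linear-effect proteins (a biomarker-panel-like
    signature) plus one strong U-shaped protein.
    """

    n_cases: int = 39
    n_controls: int = 41
    n_proteins: int = 250
    base_log10_mean_range: tuple[float, float] = (3.0, 6.0)
    base_log10_sd: float = 0.3
    effect_specs: tuple[EffectSpec, ...] = ()
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    detection_quantile: float = 0.10
    mcar_rate: float = 0.02
    n_batches: int = 1
    batch_shift_sd: float = 0.0
    seed: int = 0
    superpopulation_factor: int = 25

    def validate(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_proteins) < 1:
            raise ValueError("n_cases, n_controls and n_proteins must all be >= 1")
        if not 0.0 <= self.detection_quantile < 1.0:
            raise ValueError("detection_quantile must be in [0, 1)")
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValueError("mcar_rate must be in [0, 1)")
        if self.detection_quantile + self.mcar_rate >= 1.0:
            raise ValueError("detection_quantile + mcar_rate must be < 1")
        if self.base_log10_sd <= 0:
            raise ValueError("base_log10_sd must be positive")
        lo, hi = self.base_log10_mean_range
        if not lo <= hi:
            raise ValueError("base_log10_mean_range must be (low, high) with low <= high")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        seen: set[int] = set()
        for eff in self.effect_specs:
            if not 0 <= eff.protein_index < self.n_proteins:
                raise ValueError(f"effect references protein index {eff.protein_index} "
                                 f"outside [0, {self.n_proteins})")
            if eff.protein_index in seen:
                raise ValueError(f"duplicate effect for protein index {eff.protein_index}")
            seen.add(eff.protein_index)
        self.covariate_model.validate()


def default_effects() -> tuple[EffectSpec, ...]:
    """Study-condition signal: an 8-protein linear signature plus one U-shape."""
    linear = tuple(
        EffectSpec(i, beta1=0.5 if i % 2 == 0 else -0.5) for i in range(8)
    )
    return linear + (EffectSpec(8, beta1=0.0, beta2=1.5),)


@dataclass
class CohortTable:
    """Subjects x proteins quantity matrix plus subject metadata.

    ``quantities`` is indexed by subject id with protein-id columns;
    missing cells are NaN, observed cells strictly positive relative
    intensities (arbitrary units).  ``subjects`` carries outcome and
    covariates; ``truth`` optionally records the generating parameters for
    use as a test oracle.
    """

    quantities: pd.DataFrame
    subjects: pd.DataFrame
    truth: dict | None = None

    @property
    def proteins(self) -> list[str]:
        return list(self.quantities.columns)

    @property
    def case_mask(self) -> pd.Series:
        return self.subjects["outcome"] == "case"

    def validate(self) -> None:
        if not self.quantities.index.equals(self.subjects.index):
            raise ValueError("quantity matrix and subject table index mismatch")
        vals = self.quantities.to_numpy()
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("non-missing quantities must be strictly positive")
        bad = ~self.subjects["outcome"].isin(["case", "control"])
        if bad.any():
            sid = self.subjects.index[bad][0]
            raise ValueError(f"subject {sid!r} has invalid outcome label")


def _binary_columns(model: CovariateModel) -> list[BinaryCovariate]:
    return [model.sex, model.season, model.bmi_class, model.sr_ibs, model.antidepressant]


# display encodings for binary covariates in subjects.tsv
_BINARY_LEVELS = {
    "sex": ("female", "male"),
    "season": ("summer", "fall"),
    "bmi_class": ("overweight", "normal"),
    "sr_ibs": ("yes", "no"),
    "antidepressant": ("yes", "no"),
}


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Generate one cohort with exactly the configured group sizes.

    Raises ``ValueError`` naming the deficit if the superpopulation yields
    fewer cases or controls than requested (a sign of misconfigured
    effects or prevalences).  Deterministic for a fixed config/seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cm = config.covariate_model
    n_req = config.n_cases + config.n_controls
    m = max(400, config.superpopulation_factor * n_req)

    # matched covariates (no outcome effect), drawn marginally
    age = rng.normal(cm.age_mean, cm.age_sd, size=m)
    race = rng.choice(cm.race.levels, size=m, p=cm.race.probs)
    site = rng.choice(cm.site.levels, size=m, p=cm.site.probs)

    # protein intensities: per-protein log-normal
    lo, hi = config.base_log10_mean_range
    mu = rng.uniform(lo, hi, size=config.n_proteins)
    z = rng.standard_normal((m, config.n_proteins))
    log10_vals = mu[None, :] + config.base_log10_sd * z

    # prospective outcome model on the superpopulation: proteins only; the
    # binary covariates enter via their outcome-conditional prevalences below,
    # which is equivalent to logistic terms with gamma = log OR (see
    # BinaryCovariate)
    binaries = _binary_columns(cm)
    gamma = {c.name: c.log_odds for c in binaries}
    # center so the marginal case fraction sits near 45% for sampling efficiency
    alpha0 = math.log(0.45 / 0.55) - sum(e.beta2 for e in config.effect_specs)
    eta = np.full(m, alpha0)
    for e in config.effect_specs:
        zi = z[:, e.protein_index]
        eta += e.beta1 * zi + e.beta2 * zi * zi
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    y = rng.random(m) < prob

    case_idx = np.flatnonzero(y)
    ctrl_idx = np.flatnonzero(~y)
    if len(case_idx) < config.n_cases:
        raise ValueError(
            f"superpopulation of {m} yielded only {len(case_idx)} cases, "
            f"{config.n_cases} requested (deficit {config.n_cases - len(case_idx)})"
        )
    if len(ctrl_idx) < config.n_controls:
        raise ValueError(
            f"superpopulation of {m} yielded only {len(ctrl_idx)} controls, "
            f"{config.n_controls} requested (deficit {config.n_controls - len(ctrl_idx)})"
        )
    sel = np.concatenate([case_idx[: config.n_cases], ctrl_idx[: config.n_controls]])
    outcome = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)

    # batch assignment and additive log10 batch shifts
    batch = rng.integers(config.n_batches, size=len(sel))
    shifts = (
        rng.normal(0.0, config.batch_shift_sd, size=config.n_batches)
        if config.batch_shift_sd > 0
        else np.zeros(config.n_batches)
    )
    log10_sel = log10_vals[sel] + shifts[batch][:, None]

    ids = [f"S{i + 1:03d}" for i in range(len(sel))]
    prot_ids = [f"P{j + 1:04d}" for j in range(config.n_proteins)]
    quantities = pd.DataFrame(10.0 ** log10_sel, index=ids, columns=prot_ids)
    quantities.index.name = "subject_id"

    subjects = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    subjects["outcome"] = outcome
    subjects["age"] = np.round(age[sel], 1)
    is_case = outcome == "case"
    for c in binaries:
        yes, no = _BINARY_LEVELS[c.name]
        prev = np.where(is_case, c.prevalence_cases, c.prevalence_controls)
        subjects[c.name] = np.where(rng.random(len(sel)) < prev, yes, no)
    subjects["race"] = race[sel]
    subjects["site"] = site[sel]
    subjects["batch"] = batch + 1
    subjects = subjects[SUBJECT_COLUMNS]

    truth = {
        "config": _config_to_dict(config),
        "alpha0": alpha0,
        "covariate_log_odds": gamma,
        "protein_log10_mean": mu.tolist(),
        "protein_log10_sd": config.base_log10_sd,
        "batch_log10_shifts": shifts.tolist(),
        "effects": [dataclasses.asdict(e) for e in config.effect_specs],
    }
    table = CohortTable(quantities, subjects, truth)
    if config.detection_quantile > 0 or config.mcar_rate > 0:
        table = apply_missingness(
            table,
            config.detection_quantile,
            config.mcar_rate,
            seed=int(rng.integers(2**31)),
        )
    table.validate()
    return table


def apply_missingness(
    table: CohortTable,
    detection_quantile: float,
    mcar_rate: float,
    seed: int,
) -> CohortTable:
    """Censor below the per-protein detection quantile, plus MCAR dropout.

    Per protein, the lowest ``ceil(detection_quantile * n)`` values are set
    missing (missing-not-at-random detection-limit censoring); an
    independent ``mcar_rate`` fraction of cells is additionally hidden.
    The MCAR draw does not depend on ``detection_quantile``, so raising the
    quantile under the same seed only grows the missing set.
    """
    if detection_quantile + mcar_rate >= 1.0:
        raise ValueError("detection_quantile + mcar_rate must be < 1 "
                         "(would blank entire proteins)")
    if not 0.0 <= detection_quantile < 1.0 or not 0.0 <= mcar_rate < 1.0:
        raise ValueError("detection_quantile and mcar_rate must be in [0, 1)")
    vals = table.quantities.to_numpy(copy=True)
    if np.isnan(vals).any():
        raise ValueError("apply_missingness expects a fully observed table")
    n = vals.shape[0]
    mask = np.zeros_like(vals, dtype=bool)
    k = int(math.ceil(detection_quantile * n))
    if k > 0:
        order = np.argsort(vals, axis=0, kind="stable")
        rows = order[:k, :]
        cols = np.broadcast_to(np.arange(vals.shape[1]), rows.shape)
        mask[rows, cols] = True
    rng = np.random.default_rng(seed)
    u = rng.random(vals.shape)
    if mcar_rate > 0:
        mask |= u < mcar_rate
    vals[mask] = np.nan
    quantities = pd.DataFrame(vals, index=table.quantities.index,
                              columns=table.quantities.columns)
    truth = dict(table.truth) if table.truth is not None else None
    if truth is not None:
        truth["missingness"] = {
            "detection_quantile": detection_quantile,
            "mcar_rate": mcar_rate,
            "seed": seed,
        }
    return CohortTable(quantities, table.subjects.copy(), truth)


def _config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    # JSON-normalize (tuples -> lists) so the truth block survives a
    # write/read round trip unchanged
    return json.loads(json.dumps(d, default=list))


def write_cohort(table: CohortTable, path: str | Path, strip_truth: bool = False) -> None:
    """Write ``quantities.tsv`` / ``subjects.tsv`` (+ ``truth.json``) to a directory.

    Missing cells are written as empty fields; floats use Python's
    shortest-repr formatting, so the round trip is lossless.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    table.validate()
    table.quantities.to_csv(path / "quantities.tsv", sep="\t", na_rep="")
    table.subjects.to_csv(path / "subjects.tsv", sep="\t")
    if table.truth is not None and not strip_truth:
        (path / "truth.json").write_text(json.dumps(table.truth, indent=1))


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort directory written by :func:`write_cohort`.

    Raises a parse error naming the offending subject/cell on invalid
    quantities, missing outcome labels, or matrix/metadata mismatch.
    """
    path = Path(path)
    quantities = pd.read_csv(path / "quantities.tsv", sep="\t", index_col="subject_id")
    quantities = quantities.astype(float)
    subjects = pd.read_csv(
        path / "subjects.tsv", sep="\t", index_col="subject_id",
        keep_default_na=False, na_values=[""],
    )
    if not quantities.index.equals(subjects.index):
        only_q = set(quantities.index) - set(subjects.index)
        only_s = set(subjects.index) - set(quantities.index)
        raise ValueError(
            "quantities.tsv and subjects.tsv disagree on subjects: "
            f"only in quantities {sorted(only_q)[:5]}, only in subjects {sorted(only_s)[:5]}"
        )
    vals = quantities.to_numpy()
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive quantity at subject {quantities.index[i]!r}, "
            f"protein {quantities.columns[j]!r}"
        )
    if "outcome" not in subjects.columns:
        raise ValueError("subjects.tsv lacks an 'outcome' column")
    bad_outcome = ~subjects["outcome"].isin(["case", "control"])
    if bad_outcome.any():
        sid = subjects.index[bad_outcome][0]
        raise ValueError(f"subject {sid!r} lacks a valid outcome label")
    truth = None
    truth_path = path / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    table = CohortTable(quantities, subjects, truth)
    table.validate()
    return table
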