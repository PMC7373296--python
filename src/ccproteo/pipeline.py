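"""End-to-end pipeline: simulate -> preprocess -> scan -> panel -> report.

Driven by a single YAML config with one section per stage; unknown keys
are rejected before any computation.  Each stochastic stage draws its
seed from the master seed by a counter-based rule (SeedSequence over
(master, stage index)), so stages re-run in isolation reproduce the full
run bit for bit.  All artifacts are plain text (TSV/JSON); the report
stage renders plots and tables from artifacts only, never recomputing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import STRATA, aor_curve, run_scan, scan_to_frame
from .cohort import (
    BinaryCovariate,
    CohortConfig,
    CohortTable,
    CovariateModel,
    EffectSpec,
    default_effects,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .panel import compute_importances, consensus_panel, evaluate_panel
from .preprocess import preprocess_cohort

__all__ = ["load_config", "stage_seed", "run_pipeline", "report"]

_STAGES = ("simulate", "preprocess", "scan", "panel")

_SCHEMA = {
    "seed": int,
    "output": str,
    "cohort": {
        "simulate", "quantities", "subjects", "n_cases", "n_controls",
        "n_proteins", "base_log10_mean_range", "base_log10_sd", "effects",
        "default_effects", "detection_quantile", "mcar_rate", "n_batches",
        "batch_shift_sd", "covariates", "strip_truth",
    },
    "preprocess": {"missingness_threshold", "local_regression_normalize", "span"},
    "scan": {"alpha", "strata", "adjust_batch", "curve_points"},
    "panel": {
        "top_k", "iterations", "split", "contrasts", "n_trees", "boost_rounds",
        "classifiers",
    },
}


def load_config(path: str | Path) -> dict:
    """Load and schema-check a pipeline config; unknown keys are rejected."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("config must set a seed")
    for section, allowed in _SCHEMA.items():
        if isinstance(allowed, set) and section in cfg:
            bad = set(cfg[section] or {}) - allowed
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
    return cfg


def stage_seed(master: int, stage: str) -> int:
    """Counter-based per-stage seed derivation (stage index into SeedSequence)."""
    idx = _STAGES.index(stage) if stage in _STAGES else len(_STAGES) + hash(stage) % 100
    ss = np.random.SeedSequence([int(master), idx])
    return int(ss.generate_state(1)[0] % 2**31)


def _cohort_config(cfg: dict, seed: int) -> CohortConfig:
    c = dict(cfg.get("cohort") or {})
    c.pop("simulate", None)
    c.pop("quantities", None)
    c.pop("subjects", None)
    strip = c.pop("strip_truth", False)
    effects = c.pop("effects", None)
    if c.pop("default_effects", effects is None):
        spec = default_effects()
    else:
        spec = tuple(EffectSpec(**e) for e in (effects or []))
    cov = c.pop("covariates", None)
    model = CovariateModel()
    if cov:
        overrides = {}
        for name, prev in cov.items():
            overrides[name] = BinaryCovariate(name, float(prev["cases"]),
                                              float(prev["controls"]))
        model = dataclasses.replace(model, **overrides)
    if "base_log10_mean_range" in c:
        c["base_log10_mean_range"] = tuple(c["base_log10_mean_range"])
    config = CohortConfig(effect_specs=spec, covariate_model=model, seed=seed, **c)
    config.validate()
    config = dataclasses.replace(config)  # frozen copy
    object.__setattr__(config, "_strip_truth", strip)  # carried to the writer
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _contrast_mask(subjects: pd.DataFrame, contrast: str) -> pd.Series:
    is_case = subjects["outcome"] == "case"
    if contrast == "all":
        return pd.Series(True, index=subjects.index)
    if contrast == "sr_ibs_cases":
        return ~is_case | (subjects["sr_ibs"] == "yes")
    if contrast == "non_sr_ibs_cases":
        return ~is_case | (subjects["sr_ibs"] == "no")
    raise ValueError(f"unknown panel contrast {contrast!r}")


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None,
                 stages: tuple[str, ...] | None = None) -> Path:
    """Run the configured stages, writing artifacts and a run manifest.

    Stage failures leave earlier artifacts in place; the manifest records
    the failure point.  Returns the artifact directory.
    """
    cfg = load_config(config) if not isinstance(config, dict) else _check(config)
    master = int(cfg["seed"])
    out = Path(out_dir or cfg.get("output", "artifacts"))
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or _STAGES
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "seeds": {s: stage_seed(master, s) for s in _STAGES},
        "stages": {},
        "inputs": {},
    }

    def _finish(stage, status, t0):
        manifest["stages"][stage] = {
            "status": status, "seconds": round(time.time() - t0, 3),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    try:
        # --- simulate (or ingest user tables) -------------------------------
        t0 = time.time()
        cohort_cfg = dict(cfg.get("cohort") or {})
        cohort_dir = out / "cohort"
        if "simulate" in stages:
            if cohort_cfg.get("simulate", True):
                config_obj = _cohort_config(cfg, stage_seed(master, "simulate"))
                table = generate_cohort(config_obj)
                write_cohort(table, cohort_dir,
                             strip_truth=getattr(config_obj, "_strip_truth", False))
            else:
                src_q = Path(cohort_cfg["quantities"])
                src_s = Path(cohort_cfg["subjects"])
                cohort_dir.mkdir(parents=True, exist_ok=True)
                (cohort_dir / "quantities.tsv").write_bytes(src_q.read_bytes())
                (cohort_dir / "subjects.tsv").write_bytes(src_s.read_bytes())
                table = read_cohort(cohort_dir)
            for f in ("quantities.tsv", "subjects.tsv"):
                manifest["inputs"][f] = _sha256(cohort_dir / f)
            _finish("simulate", "ok", t0)
        else:
            table = read_cohort(cohort_dir)

        # --- preprocess -----------------------------------------------------
        t0 = time.time()
        pp = cfg.get("preprocess") or {}
        tm = preprocess_cohort(
            table,
            missingness_threshold=pp.get("missingness_threshold", 0.5),
            lrn=pp.get("local_regression_normalize", False),
            span=pp.get("span", 0.75),
        )
        if "preprocess" in stages:
            tm.values.to_csv(out / "transformed.tsv", sep="\t")
            prov = {
                "scale_factors": tm.scale_factors.to_dict(),
                "retained_proteins": tm.retained_proteins,
                "imputation": {
                    p: {"n_imputed": int(r["n_imputed"]),
                        "impute_value": float(r["impute_value"])}
                    for p, r in tm.imputation_log.iterrows()
                },
            }
            (out / "preprocess_provenance.json").write_text(
                json.dumps(prov, indent=1))
            _finish("preprocess", "ok", t0)

        # --- association scan ----------------------------------------------
        if "scan" in stages:
            t0 = time.time()
            sc = cfg.get("scan") or {}
            alpha = sc.get("alpha", 0.05)
            covariates = None
            if sc.get("adjust_batch", False):
                from .association import DEFAULT_COVARIATES
                covariates = DEFAULT_COVARIATES + ("batch",)
            for name in sc.get("strata", ["all"]):
                stratum = STRATA[name]
                kwargs = {"covariates": covariates} if covariates else {}
                results = run_scan(tm, table.subjects, stratum=stratum,
                                   alpha=alpha, **kwargs)
                scan_to_frame(results).to_csv(
                    out / f"scan_{name}.tsv", sep="\t", index=False)
                for r in results:
                    if not r.quadratic_selected:
                        continue
                    sd = tm.scale_factors[r.protein]
                    raw_lo = 10.0 ** (r.t_min * sd)
                    raw_hi = 10.0 ** (r.t_max * sd)
                    grid = np.geomspace(raw_lo, raw_hi,
                                        sc.get("curve_points", 50))
                    curve = aor_curve(
                        np.array([r.beta1, r.beta2]), r.beta_cov,
                        r.reference_level_raw, grid,
                        transform=lambda x, s=sd: np.log10(x) / s,
                        protein=r.protein, stratum=name,
                    )
                    curve.grid.to_csv(
                        out / f"aor_curve_{name}_{r.protein}.tsv",
                        sep="\t", index=False)
            _finish("scan", "ok", t0)

        # --- biomarker panel -------------------------------------------------
        if "panel" in stages:
            t0 = time.time()
            pn = cfg.get("panel") or {}
            seed = stage_seed(master, "panel")
            retained = tm.retained_proteins
            for contrast in pn.get("contrasts", ["all"]):
                mask = _contrast_mask(table.subjects, contrast)
                X = tm.values.loc[mask, retained]
                y = (table.subjects.loc[mask, "outcome"] == "case").to_numpy(int)
                scores = compute_importances(
                    X, y,
                    iterations=pn.get("iterations", 1000), seed=seed,
                    n_trees=pn.get("n_trees", 500),
                    boost_rounds=pn.get("boost_rounds", 200),
                )
                scores.table.to_csv(out / f"importance_{contrast}.tsv", sep="\t")
                panel = consensus_panel(scores, k=pn.get("top_k", 20),
                                        outcome_contrast=contrast)
                (out / f"panel_{contrast}.json").write_text(json.dumps(
                    {"proteins": panel.proteins, "k": panel.k,
                     "contrast": contrast}, indent=1))
                if not panel.proteins:
                    continue
                cv = evaluate_panel(
                    X[panel.proteins], y,
                    iterations=pn.get("iterations", 1000),
                    split=pn.get("split", 0.8), seed=seed,
                    classifiers=tuple(pn.get(
                        "classifiers",
                        ["logistic", "random_forest", "boosted_trees"])),
                    n_trees=pn.get("n_trees", 500),
                    boost_rounds=pn.get("boost_rounds", 200),
                )
                summary = []
                for name, res in cv.items():
                    pd.DataFrame({"auroc": res.aurocs}).to_csv(
                        out / f"cv_{contrast}_{name}.tsv", sep="\t", index=False)
                    res.roc.to_csv(out / f"roc_{contrast}_{name}.tsv",
                                   sep="\t", index=False)
                    summary.append({
                        "classifier": name, "mean_auroc": res.mean_auroc,
                        "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                        "iterations": len(res.aurocs),
                    })
                (out / f"cv_summary_{contrast}.json").write_text(
                    json.dumps(summary, indent=1))
            _finish("panel", "ok", t0)
    except Exception:
        _finish("failed", "error", time.time())
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def _check(cfg: dict) -> dict:
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("config must set a seed")
    for section, allowed in _SCHEMA.items():
        if isinstance(allowed, set) and section in cfg:
            bad = set(cfg[section] or {}) - allowed
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
    return cfg


def report(artifact_dir: str | Path) -> Path:
    """Render plots and a markdown summary from pipeline artifacts.

    Purely presentational: reads the TSV/JSON artifacts, computes nothing
    new, and is idempotent.  Raises naming the missing stage when
    artifacts are absent.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(artifact_dir)
    if not (out / "manifest.json").exists():
        raise FileNotFoundError("manifest.json missing: run the pipeline first")
    lines = ["# Pipeline report", ""]
    scan_files = sorted(out.glob("scan_*.tsv"))
    if not scan_files:
        raise FileNotFoundError("no scan artifacts: re-run the 'scan' stage")
    for f in scan_files:
        stratum = f.stem.removeprefix("scan_")
        df = pd.read_csv(f, sep="\t")
        sel = df[df["quadratic_selected"] == True]  # noqa: E712
        lines.append(f"## Stratum `{stratum}`")
        lines.append(f"- proteins scanned: {len(df)}")
        lines.append(f"- quadratic (U-shape) selections: {len(sel)}"
                     + (f" ({', '.join(sel['protein'])})" if len(sel) else ""))
        lines.append("")
        for _, row in sel.iterrows():
            cf = out / f"aor_curve_{stratum}_{row['protein']}.tsv"
            if not cf.exists():
                continue
            curve = pd.read_csv(cf, sep="\t")
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.plot(curve["level_raw"], curve["aor"], color="C0")
            ax.fill_between(curve["level_raw"], curve["ci_low"],
                            curve["ci_high"], alpha=0.2, color="C0")
            ax.axhline(1.0, color="grey", lw=0.8)
            ax.set_xscale("log")
            ax.set_yscale("log")
            ax.set_xlabel("protein level (a.u.)")
            ax.set_ylabel("aOR vs reference")
            ax.set_title(f"{row['protein']} ({stratum})")
            fig.tight_layout()
            fig.savefig(out / f"aor_curve_{stratum}_{row['protein']}.png", dpi=110)
            plt.close(fig)
    for f in sorted(out.glob("cv_summary_*.json")):
        contrast = f.stem.removeprefix("cv_summary_")
        summary = json.loads(f.read_text())
        lines.append(f"## Panel evaluation ({contrast})")
        panel_file = out / f"panel_{contrast}.json"
        if panel_file.exists():
            panel = json.loads(panel_file.read_text())
            if panel["proteins"]:
                lines.append(f"- panel: {', '.join(panel['proteins'])}")
            else:
                lines.append("- panel: EMPTY (three top-k sets do not intersect); "
                             "no evaluation performed")
        fig, ax = plt.subplots(figsize=(4.2, 4))
        for row in summary:
            roc = pd.read_csv(out / f"roc_{contrast}_{row['classifier']}.tsv",
                              sep="\t")
            ax.plot(roc["fpr"], roc["tpr"],
                    label=f"{row['classifier']} (AUROC {row['mean_auroc']:.3f})")
            lines.append(
                f"- {row['classifier']}: mean AUROC {row['mean_auroc']:.3f} "
                f"(95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}, "
                f"{row['iterations']} iterations)")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"roc_{contrast}.png", dpi=110)
        plt.close(fig)
        lines.append("")
    for f in sorted(out.glob("panel_*.json")):
        contrast = f.stem.removeprefix("panel_")
        if not (out / f"cv_summary_{contrast}.json").exists():
            panel = json.loads(f.read_text())
            if not panel["proteins"]:
                lines.append(f"## Panel evaluation ({contrast})")
                lines.append("- panel: EMPTY; evaluation skipped")
                lines.append("")
    report_path = out / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
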