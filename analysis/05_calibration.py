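"""Monte-Carlo calibration checks of the scan and the AUROC estimator.

A reduced version of the package's calibration experiments: family-wise
error of the gate-keeping scan over 100 null cohorts (the full
300-cohort run lives in the test suite and acceptance script), Wald CI
coverage for an injected U-shaped effect, and AUROC sanity values.
Writes results/calibration.json.
"""

import json
from pathlib import Path

from ccproteo.experiments import (
    null_auroc,
    null_scan_fwer,
    perfect_auroc,
    quadratic_recovery,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "calibration.json"


def main() -> None:
    fwer = null_scan_fwer(n_cohorts=100, seed=2)
    rec = quadratic_recovery(n_replicates=100, beta2=1.5, seed=2)
    results = {
        "fwer_quadratic_family": fwer.fwer_quadratic,
        "fwer_linear_family": fwer.fwer_linear,
        "n_null_cohorts": fwer.n_cohorts,
        "beta2_ci95_coverage": rec.coverage_beta2,
        "n_recovery_replicates": rec.n_replicates,
        "auroc_null_scores": null_auroc(1000, seed=2),
        "auroc_complete_separation": perfect_auroc(100),
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(results, indent=1))
    print(f"written to {OUT}")
    print(f"FWER over {fwer.n_cohorts} null cohorts: quadratic family "
          f"{fwer.fwer_quadratic:.3f}, linear family {fwer.fwer_linear:.3f} "
          f"(alpha = 0.05)")
    print(f"95% Wald CI coverage of injected beta2=1.5: "
          f"{rec.coverage_beta2:.2f} over {rec.n_replicates} cohorts")
    print(f"AUROC: null scores {results['auroc_null_scores']:.3f}, "
          f"complete separation {results['auroc_complete_separation']:.1f}")


if __name__ == "__main__":
    main()
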