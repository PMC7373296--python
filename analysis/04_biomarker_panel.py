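"""Consensus biomarker panels and repeated-holdout evaluation.

For each contrast (all cases / sr-IBS cases / non-sr-IBS cases, each vs
controls): Lasso selection frequency, random-forest out-of-bag
permutation importance, and boosting gain on the filtered matrix; the
top-20 consensus panel; and stratified 80/20 holdout AUROC for logistic
regression, random forest, and boosted trees.  Writes importance tables,
panels, per-iteration AUROCs and pooled ROC points under
results/pipeline/.
"""

import json
from pathlib import Path

from ccproteo.pipeline import run_pipeline

HERE = Path(__file__).resolve().parent
CONFIG = HERE / "config_demo.yaml"


def main() -> None:
    out = run_pipeline(CONFIG, stages=("panel",))
    for f in sorted(out.glob("panel_*.json")):
        contrast = f.stem.removeprefix("panel_")
        panel = json.loads(f.read_text())
        print(f"contrast {contrast}: consensus panel "
              f"({len(panel['proteins'])} proteins): "
              f"{', '.join(panel['proteins']) or 'EMPTY'}")
        summary_file = out / f"cv_summary_{contrast}.json"
        if summary_file.exists():
            for row in json.loads(summary_file.read_text()):
                print(f"  {row['classifier']:14s} mean AUROC "
                      f"{row['mean_auroc']:.3f} "
                      f"(95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}, "
                      f"{row['iterations']} iterations)")


if __name__ == "__main__":
    main()
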