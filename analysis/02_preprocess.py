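"""Preprocess the simulated cohort: impute, transform, filter.

Half-minimum imputation of non-detects, log10 transform with control-SD
rescaling, and the 50% missingness filter for the classifier stage.
Writes transformed.tsv + provenance under results/pipeline/.
"""

import json
from pathlib import Path

from ccproteo.pipeline import load_config, run_pipeline

HERE = Path(__file__).resolve().parent
CONFIG = HERE / "config_demo.yaml"


def main() -> None:
    out = run_pipeline(CONFIG, stages=("preprocess",))
    prov = json.loads((out / "preprocess_provenance.json").read_text())
    n_prot = len(prov["scale_factors"])
    n_imputed = sum(v["n_imputed"] for v in prov["imputation"].values())
    n_retained = len(prov["retained_proteins"])
    cfg = load_config(CONFIG)
    thresh = cfg["preprocess"]["missingness_threshold"]
    print(f"transformed matrix written to {out / 'transformed.tsv'}")
    print(f"proteins transformed: {n_prot}")
    print(f"cells imputed at half the per-protein minimum: {n_imputed}")
    print(f"proteins passing the {thresh:.0%} missingness filter "
          f"(classifier stage): {n_retained}; excluded: {n_prot - n_retained}")


if __name__ == "__main__":
    main()
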