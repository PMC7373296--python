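"""Render the pipeline report: aOR-curve plots, ROC curves, summary tables.

Purely presentational over the artifacts written by scripts 01-04.
"""

from pathlib import Path

from ccproteo.pipeline import report

ARTIFACTS = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main() -> None:
    path = report(ARTIFACTS)
    print(f"report written to {path}")
    print(path.read_text())


if __name__ == "__main__":
    main()
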