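#!/usr/bin/env python
"""Generate the synthetic multi-disease cohort used by the downstream analyses.

Writes the raw inputs (KGML pathways, expression matrix, sample sheet,
ground truth) under scratch/synthetic_cohort/ and a small cohort summary
under results/.
"""

from pathlib import Path

import pandas as pd

from psfsom.synth import SyntheticDesign, generate_dataset

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "synthetic_cohort"
RESULTS = ROOT / "results"


def main() -> None:
    design = SyntheticDesign(seed=SEED)
    graphs, kgml, expression, sheet, truth = generate_dataset(design)

    (OUT / "pathways").mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    for pid, text in kgml.items():
        (OUT / "pathways" / f"{pid}.xml").write_text(text)
    expression.to_csv(OUT / "expression.tsv", sep="\t")
    sheet.to_csv(OUT / "samples.tsv", sep="\t", index=False)
    (OUT / "truth.json").write_text(truth.to_json())

    summary = (
        sheet.groupby("class_label")
        .size()
        .rename("n_samples")
        .to_frame()
        .assign(
            n_truth_sinks=lambda df: [
                len(truth.class_sinks.get(label, {})) for label in df.index
            ],
            block=lambda df: [truth.blocks.get(label, -1) for label in df.index],
            supergroup=lambda df: [
                truth.supergroups.get(label, -1) for label in df.index
            ],
        )
    )
    summary.to_csv(RESULTS / "cohort_summary.tsv", sep="\t")

    n_sinks = sum(len(g.sinks) for g in graphs)
    print(f"cohort: {expression.shape[0]} genes x {expression.shape[1]} samples, "
          f"{len(graphs)} pathways with {n_sinks} sinks "
          f"({n_sinks / len(graphs):.1f} per pathway)")
    print(summary.to_string())
    print(f"raw inputs -> {OUT}")


if __name__ == "__main__":
    main()
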