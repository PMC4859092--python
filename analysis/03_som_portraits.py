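#!/usr/bin/env python
"""Train the sink-profile SOM and detect deregulation spots per class.

Uses a 10x10 map (desk-scale stand-in for the published 50x50 grid; the
other learning parameters keep their published values). Writes the spot
catalogue to results/spots.json and portrait heatmaps to scratch/portraits/.
"""

import json
from pathlib import Path

from psfsom import expression, psf, som
from psfsom.synth import SyntheticDesign, generate_dataset

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    graphs, _, expr, sheet, truth = generate_dataset(SyntheticDesign(seed=SEED))
    linear, _ = expression.detect_and_linearize(expr)
    fc = expression.compute_fold_change(linear, sheet)
    centralized = psf.centralize(psf.compute_psf_matrix(graphs, fc))

    config = som.SOMConfig(grid_rows=10, grid_cols=10, seed=SEED)
    model = som.train_som(centralized, config)
    print(f"SOM: {centralized.shape[0]} sinks on {config.grid_rows}x"
          f"{config.grid_cols} grid, quantization error "
          f"{model.quantization_error:.3f}")

    portraits = som.all_portraits(model, sheet)
    spotsets = [som.detect_spots(p, model) for p in portraits.values()]
    summary = som.summary_spot_map(spotsets, model, polarity="over")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "spots.json").write_text(som.spots_to_json(spotsets, summary))
    portrait_dir = ROOT / "scratch" / "portraits"
    portrait_dir.mkdir(parents=True, exist_ok=True)
    for label, p in portraits.items():
        som.portrait_png(p, portrait_dir / f"{label}.png")

    print(f"summary over-spots: {len(summary)}")
    for spot in summary:
        print(f"  spot {spot.label}: {len(spot.units)} units, "
              f"{len(spot.sink_ids)} sinks, peak {spot.peak_value:+.2f}, "
              f"classes {', '.join(spot.classes)}")
    planted_up = {s for sinks in truth.class_sinks.values()
                  for s, sign in sinks.items() if sign > 0}
    covered = {s for spot in summary for s in spot.sink_ids}
    print(f"planted up-regulated sinks covered by over-spots: "
          f"{len(planted_up & covered)}/{len(planted_up)}")


if __name__ == "__main__":
    main()
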