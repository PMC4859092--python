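"""End-to-end pipeline: preprocess -> PSF -> SOM -> differential -> communities.

`run_pipeline` chains every stage on files referenced by a `RunConfig`,
writes all intermediate artifacts under one run directory, and records a
manifest (parameters, seed, file checksums) so that a rerun with the same
config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, expression, pathway, psf, similarity, som, stats

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    # paths
    pathway_dir: str = ""
    expression_files: list[str] = field(default_factory=list)
    sample_sheet: str = ""
    probe_map: str | None = None
    exclusion_file: str | None = None
    out_dir: str = "psfsom_run"
    # class handling
    control_label: str = "HC"
    # preprocessing
    transform: str = "auto"          # auto | linear | log2 | log10
    # PSF
    input_signal: float = 1.0
    missing_fc: float = 1.0
    # SOM (published defaults)
    grid_rows: int = 50
    grid_cols: int = 50
    learning_rate: float = 0.02
    lr_constant: float = 0.01
    radius: float = 3.0
    epochs: int = 12
    spot_method: str = "threshold"
    spot_threshold: float = 0.90
    # differential testing
    alpha_p: float = 0.05
    alpha_q: float = 0.2
    # disease graph
    coregulation_level: str = "pathway"   # pathway | sink
    walktrap_steps: int = 4
    # global
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.pathway_dir or not Path(self.pathway_dir).is_dir():
            raise ConfigError(f"pathway_dir not found: {self.pathway_dir!r}")
        for f in self.expression_files:
            if not Path(f).is_file():
                raise ConfigError(f"expression file not found: {f!r}")
        if not self.expression_files:
            raise ConfigError("no expression files configured")
        if not Path(self.sample_sheet).is_file():
            raise ConfigError(f"sample sheet not found: {self.sample_sheet!r}")
        sheet = expression.read_sample_sheet(self.sample_sheet)
        if self.control_label not in set(sheet["class_label"]):
            raise ConfigError(
                f"control class {self.control_label!r} absent from sample sheet"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context manager logging stage timing and attributing failures."""

    def __init__(self, name: str, timings: dict):
        self.name, self.timings = name, timings

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        self.t0 = time.monotonic()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.monotonic() - self.t0
        self.timings[self.name] = round(dt, 3)
        if exc is not None:
            logger.error("stage %s failed after %.1fs: %s", self.name, dt, exc)
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", self.name, dt)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis chain; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    with _Stage("preprocess", timings):
        sheet = expression.read_sample_sheet(config.sample_sheet)
        fc_blocks = []
        for path in config.expression_files:
            if Path(path).name.endswith((".txt", ".gz")) and _looks_series_matrix(path):
                mat, _meta = expression.read_series_matrix(path)
            else:
                mat = expression.read_matrix_tsv(path)
            if config.probe_map:
                mat = expression.collapse_probes(
                    mat, expression.read_probe_map(config.probe_map)
                )
            mat, decision = expression.detect_and_linearize(mat, config.transform)
            logger.info("%s: scale %s", path, decision)
            fc_blocks.append(expression.compute_fold_change(mat, sheet))
        fc = pd.concat(fc_blocks, axis=1, join="inner") if len(fc_blocks) > 1 \
            else fc_blocks[0]
        expression.write_matrix_tsv(fc, out / "fold_change.tsv")

    with _Stage("pathways", timings):
        graphs = [
            pathway.parse_kgml(str(p))
            for p in sorted(Path(config.pathway_dir).glob("*.xml"))
        ]
        exclusion = (
            pathway.read_exclusion_file(config.exclusion_file)
            if config.exclusion_file else []
        )
        graphs = pathway.filter_pathway_collection(graphs, exclusion)
        graphs = [pathway.break_cycles(g) for g in graphs]
        with open(out / "pathways.json", "w") as fh:
            json.dump([json.loads(g.to_json()) for g in graphs], fh, indent=1)

    with _Stage("psf", timings):
        psf_matrix = psf.compute_psf_matrix(
            graphs, fc, input_signal=config.input_signal,
            missing_fc=config.missing_fc,
        )
        expression.write_matrix_tsv(psf_matrix, out / "psf.tsv")
        centralized = psf.centralize(psf_matrix)
        expression.write_matrix_tsv(centralized, out / "psf_centralized.tsv")

    with _Stage("som", timings):
        cfg = som.SOMConfig(
            config.grid_rows, config.grid_cols, config.learning_rate,
            config.lr_constant, config.radius, config.epochs, config.seed,
        )
        model = som.train_som(centralized, cfg)
        model.save(out / "som_model.json", out / "som_weights.tsv")

    with _Stage("portraits_spots", timings):
        portraits = som.all_portraits(model, sheet)
        spotsets = [
            som.detect_spots(p, model, config.spot_threshold, config.spot_method)
            for p in portraits.values()
        ]
        summary = som.summary_spot_map(spotsets, model, polarity="over")
        (out / "spots.json").write_text(som.spots_to_json(spotsets, summary))
        portrait_dir = out / "portraits"
        portrait_dir.mkdir(exist_ok=True)
        for label, p in portraits.items():
            som.portrait_png(p, portrait_dir / f"{label}.png")

    with _Stage("differential", timings):
        differential = stats.differential_all_classes(
            psf_matrix, sheet, config.control_label,
            alpha_p=config.alpha_p, alpha_q=config.alpha_q,
        )
        for label, table in differential.items():
            table.to_csv(out / f"differential_{label}.tsv", sep="\t", index=False)

    with _Stage("disease_graph", timings):
        profiles = similarity.class_profile_matrix(model, sheet)
        for metric in ("pearson", "euclidean"):
            linkage, labels = similarity.hierarchical_cluster(profiles, metric)
            (out / f"dendrogram_{metric}.nwk").write_text(
                similarity.dendrogram_newick(linkage, labels)
            )
        graph = similarity.build_disease_graph(
            differential, level=config.coregulation_level
        )
        similarity.graph_to_edge_list(graph).to_csv(
            out / "disease_graph.tsv", sep="\t", index=False
        )
        graph.write_graphml(str(out / "disease_graph.graphml"))
        if graph.ecount() > 0:
            communities = similarity.walktrap_communities(
                graph, steps=config.walktrap_steps
            )
            (out / "communities.json").write_text(
                json.dumps(communities.to_dict(), indent=1)
            )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "timings_s": timings,
        "checksums": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.suffix != ".png" and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _looks_series_matrix(path) -> bool:
    try:
        with open(path) as fh:
            head = fh.read(4096)
        return "!series_matrix_table_begin" in head or head.startswith("!")
    except UnicodeDecodeError:
        return False
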