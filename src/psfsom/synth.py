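"""Synthetic pathway collections and expression cohorts with known truth.

The generator emulates the study setting at desk scale: a collection of
layered, branched pathway DAGs with activation/inhibition edges and
multi-gene nodes (serialized as valid KGML so the real parser is
exercised), plus a group-structured expression cohort — one control class
whose fold changes scatter around 1, and disease classes in which the genes
of selected pathway branches are multiplied by a planted effect size under
multiplicative log-normal noise.

Deregulation is planted in two ways.  A class may deregulate whole target
pathways (every gene of the pathway multiplied by the effect size — a
lesion that shifts the entire map), or the *private branch* of individual
target sinks — the nodes from which no other sink is reachable — leaving
all other sinks of that pathway exactly unaffected.  The resulting ground
truth is always derived by noise-free signal propagation, because
inhibitory edges can attenuate or invert a planted up-regulation at a
sink: sinks whose noise-free |log2 PSF shift| reaches half the per-gene
log2 effect are *truth* sinks; weaker but nonzero shifts are recorded as
*background* (real yet faint, excluded from recovery bookkeeping).

The default design is a desk-scale analogue of a multi-disease cohort:
10 pathways; 4 disease blocks of 3 classes, each block fully deregulating
its 2 own branched pathways; and 2 super-groups (blocks 1-2
up-regulating, "cancer-like"; blocks 3-4 down-regulating,
"inflammation-like") that deregulate the same 2 unbranched *mirror
chain* pathways in opposite directions — the mirrored family signature.
A fully deregulated chain compounds the per-gene effect along its length,
so the mirror dominates profile similarity between classes (driving the
family split in hierarchical clustering) while adding only its single
sink per chain to the co-regulation graph, leaving the block structure
dominant there.  Effect size 2, log2 noise SD 0.3, 20 samples per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from xml.sax.saxutils import quoteattr

import numpy as np
import pandas as pd

from .pathway import PathwayEdge, PathwayGraph, PathwayNode
from .psf import compute_psf_matrix

LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class ClassSpec:
    """One sample class: a control (effect 1) or a planted disease class."""

    label: str
    n_samples: int = 20
    effect_size: float = 1.0
    direction: str = "up"            # "up" | "down"
    target_pathways: tuple[str, ...] = ()  # fully deregulated pathway ids
    #: per-pathway direction overrides ("up"/"down"); None = class direction
    target_pathway_directions: tuple[str, ...] | None = None
    target_sinks: tuple[str, ...] = ()     # "pathway:node", private branch only
    block: int | None = None
    supergroup: int | None = None

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if self.n_samples < 2:
            raise ValueError("every class needs at least 2 samples")

    @property
    def is_control(self) -> bool:
        return self.effect_size == 1.0 and not (
            self.target_sinks or self.target_pathways
        )


@dataclass(frozen=True)
class SyntheticDesign:
    n_pathways: int = 10
    n_layers: int = 4
    layer_widths: tuple[int, ...] | None = None  # explicit widths override
    sinks_per_pathway: int = 7
    inhibition_probability: float = 0.2
    genes_per_node: int = 2
    effect_size: float = 2.0
    noise_sd: float = 0.3            # SD of log2-scale multiplicative noise
    n_samples_per_class: int = 20
    n_blocks: int = 4
    classes_per_block: int = 3
    pathways_per_block: int = 2
    n_mirror_chains: int = 2         # unbranched pathways mirrored between groups
    seed: int = 0
    classes: tuple[ClassSpec, ...] | None = None

    def resolved_classes(self) -> tuple[ClassSpec, ...]:
        """Explicit classes, or the default block-structured cohort."""
        if self.classes is not None:
            return self.classes
        specs = [ClassSpec("HC", self.n_samples_per_class)]
        for b in range(self.n_blocks):
            group = b // max(1, self.n_blocks // 2)
            direction = "up" if group == 0 else "down"
            for c in range(self.classes_per_block):
                specs.append(
                    ClassSpec(
                        f"B{b + 1}C{c + 1}",
                        self.n_samples_per_class,
                        self.effect_size,
                        direction,
                        block=b,
                        supergroup=group,
                    )
                )
        return tuple(specs)


@dataclass
class GroundTruth:
    """Planted deregulation: per class the affected sinks, genes, and blocks.

    ``class_sinks`` holds the strong truth (noise-free |log2 shift| at least
    half the per-gene log2 effect) with its sign; ``background_sinks`` holds
    sinks with weaker but nonzero noise-free shifts — genuinely affected yet
    too faint to count for or against a detection method.
    """

    class_sinks: dict[str, dict[str, int]]      # label -> sink_id -> +-1
    background_sinks: dict[str, list[str]]      # label -> faintly shifted sinks
    class_factors: dict[str, dict[str, float]]  # label -> gene -> multiplier
    blocks: dict[str, int]                      # disease label -> block id
    supergroups: dict[str, int]
    control_label: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_sinks": self.class_sinks,
                "background_sinks": self.background_sinks,
                "class_factors": self.class_factors,
                "blocks": self.blocks,
                "supergroups": self.supergroups,
                "control_label": self.control_label,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            {k: {s: int(v) for s, v in m.items()}
             for k, m in d["class_sinks"].items()},
            d["background_sinks"],
            {k: {g: float(v) for g, v in m.items()}
             for k, m in d["class_factors"].items()},
            {k: int(v) for k, v in d["blocks"].items()},
            {k: int(v) for k, v in d["supergroups"].items()},
            d["control_label"],
        )

    @property
    def all_true_sinks(self) -> set[str]:
        return {s for m in self.class_sinks.values() for s in m}

    def null_sinks(self, label: str, all_sinks) -> set[str]:
        """Sinks that are exactly unaffected in class ``label``."""
        return (
            set(all_sinks)
            - set(self.class_sinks.get(label, ()))
            - set(self.background_sinks.get(label, ()))
        )


# ---------------------------------------------------------------------------
# pathway generation
# ---------------------------------------------------------------------------

def _layer_widths(design: SyntheticDesign, rng: np.random.Generator) -> list[int]:
    if design.layer_widths is not None:
        if len(design.layer_widths) < 2:
            raise ValueError("a pathway needs at least 2 layers")
        return list(design.layer_widths)
    if design.n_layers < 2:
        raise ValueError("a pathway needs at least 2 layers")
    widths = [int(rng.integers(1, 3))]
    widths += [int(rng.integers(3, 7)) for _ in range(design.n_layers - 2)]
    widths.append(max(1, design.sinks_per_pathway + int(rng.integers(-2, 3))))
    return widths


def _generate_graph(
    pathway_id: str,
    design: SyntheticDesign,
    rng: np.random.Generator,
    chain: bool = False,
) -> PathwayGraph:
    widths = [1] * design.n_layers if chain else _layer_widths(design, rng)
    layers: list[list[str]] = []
    counter = 1
    nodes: dict[str, PathwayNode] = {}
    for width in widths:
        layer = []
        for _ in range(width):
            nid = f"{counter:02d}"
            genes = frozenset(
                f"{pathway_id}_{nid}_g{j}" for j in range(design.genes_per_node)
            )
            nodes[nid] = PathwayNode(nid, genes, "gene", f"{pathway_id}.{nid}")
            layer.append(nid)
            counter += 1
        layers.append(layer)

    def sign() -> int:
        # mirror chains are pure activation cascades: the family signature
        # compounds deterministically along the chain instead of being
        # attenuated by inhibition parity
        if chain:
            return +1
        return -1 if rng.random() < design.inhibition_probability else +1

    edges: list[PathwayEdge] = []
    for upper, lower in zip(layers, layers[1:]):
        childless = set(upper)
        for child in lower:
            n_par = int(rng.integers(1, min(2, len(upper)) + 1))
            for parent in rng.choice(upper, size=n_par, replace=False):
                s = sign()
                edges.append(PathwayEdge(
                    str(parent), child, s,
                    "activation" if s > 0 else "inhibition"))
                childless.discard(str(parent))
        for parent in sorted(childless):  # keep sinks confined to the last layer
            child = str(rng.choice(lower))
            s = sign()
            edges.append(PathwayEdge(
                parent, child, s, "activation" if s > 0 else "inhibition"))

    dedup = {(e.from_id, e.to_id): e for e in edges}
    ordered = tuple(dedup[k] for k in sorted(dedup))
    return PathwayGraph(pathway_id, f"Synthetic pathway {pathway_id}",
                        nodes, ordered)


def pathway_to_kgml(graph: PathwayGraph) -> str:
    """Serialize a pathway as a KGML document that round-trips the parser."""
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name={quoteattr("path:" + graph.pathway_id)} org="syn" '
        f'number="0" title={quoteattr(graph.name)}>',
    ]
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        names = " ".join(f"syn:{g}" for g in sorted(node.gene_ids)) or "undefined"
        lines.append(
            f'  <entry id={quoteattr(nid)} name={quoteattr(names)} '
            f'type={quoteattr(node.node_kind)}>'
        )
        lines.append(f'    <graphics name={quoteattr(node.label)} type="rectangle"/>')
        lines.append("  </entry>")
    for e in graph.edges:
        arrow = "--&gt;" if e.sign > 0 else "--|"
        lines.append(
            f'  <relation entry1={quoteattr(e.from_id)} '
            f'entry2={quoteattr(e.to_id)} type="PPrel">'
        )
        lines.append(f'    <subtype name={quoteattr(e.subtype_label)} value="{arrow}"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


def private_branch(graph: PathwayGraph, sink: str) -> set[str]:
    """Nodes from which ``sink`` is the only reachable sink (incl. the sink)."""
    children: dict[str, set[str]] = {nid: set() for nid in graph.nodes}
    for e in graph.edges:
        children[e.from_id].add(e.to_id)
    sinks = graph.sinks
    reach: dict[str, frozenset[str]] = {}
    for nid in reversed(graph.topological_order()):
        acc = set()
        if nid in sinks:
            acc.add(nid)
        for c in children[nid]:
            acc |= reach[c]
        reach[nid] = frozenset(acc)
    return {nid for nid, r in reach.items() if r == frozenset({sink})}


def _allocate_targets(
    design: SyntheticDesign,
    classes: tuple[ClassSpec, ...],
    graphs: list[PathwayGraph],
    rng: np.random.Generator,
) -> tuple[ClassSpec, ...]:
    """Fill in targets for block-structured classes.

    Each block owns ``pathways_per_block`` whole pathways (all classes of
    the block deregulate them fully, so blocks share nothing with each
    other); the last ``n_mirror_chains`` pathways of the collection — the
    unbranched chains — are deregulated by *every* disease class in its own
    direction, i.e. oppositely between the two super-groups.
    """
    blocks = sorted({c.block for c in classes if c.block is not None})
    if not blocks:
        return classes
    needed = len(blocks) * design.pathways_per_block + design.n_mirror_chains
    if needed > len(graphs):
        raise ValueError(
            f"block design needs {needed} pathways, only {len(graphs)} generated"
        )
    ordered = sorted(graphs, key=lambda g: g.pathway_id)
    cursor = 0
    block_pathways: dict[int, tuple[str, ...]] = {}
    for b in blocks:
        block_pathways[b] = tuple(
            g.pathway_id for g in ordered[cursor:cursor + design.pathways_per_block]
        )
        cursor += design.pathways_per_block
    mirror = tuple(
        g.pathway_id for g in ordered[len(ordered) - design.n_mirror_chains:]
    )

    out = []
    for spec in classes:
        if spec.is_control or spec.target_sinks or spec.target_pathways:
            out.append(spec)
            continue
        own = block_pathways.get(spec.block, ())
        flip = {"up": "down", "down": "up"}
        # alternate directions over the block's own pathways so class profiles
        # stay balanced; the mirror chains carry the super-group direction
        own_dirs = tuple(
            spec.direction if i % 2 == 0 else flip[spec.direction]
            for i in range(len(own))
        )
        out.append(replace(
            spec,
            target_pathways=own + mirror,
            target_pathway_directions=own_dirs + (spec.direction,) * len(mirror),
        ))
    return tuple(out)


def plant_truth(
    classes: tuple[ClassSpec, ...], graphs: list[PathwayGraph]
) -> GroundTruth:
    """Derive gene factors and exact sink-level truth by noise-free propagation.

    Strong truth requires a noise-free |log2 PSF shift| of at least half the
    per-gene log2 effect; nonzero weaker shifts (possible when inhibitory
    edges partly cancel a planted effect along parallel paths) are recorded
    as background.
    """
    by_id = {g.pathway_id: g for g in graphs}
    all_genes = sorted({g for gr in graphs for n in gr.nodes.values()
                        for g in n.gene_ids})
    control = [c.label for c in classes if c.is_control]
    if len(control) != 1:
        raise ValueError(f"exactly one control class required, found {control}")

    class_sinks: dict[str, dict[str, int]] = {}
    background: dict[str, list[str]] = {}
    class_factors: dict[str, dict[str, float]] = {}
    blocks: dict[str, int] = {}
    supergroups: dict[str, int] = {}
    for spec in classes:
        if spec.is_control:
            continue
        factor = (spec.effect_size if spec.direction == "up"
                  else 1.0 / spec.effect_size)
        directions = spec.target_pathway_directions or (
            (spec.direction,) * len(spec.target_pathways)
        )
        if len(directions) != len(spec.target_pathways):
            raise ValueError("one direction per target pathway required")
        factors: dict[str, float] = {}
        for pid, pdir in zip(spec.target_pathways, directions):
            f = spec.effect_size if pdir == "up" else 1.0 / spec.effect_size
            for node in by_id[pid].nodes.values():
                for g in node.gene_ids:
                    factors[g] = f
        for sink_id in spec.target_sinks:
            pid, node_id = sink_id.split(":", 1)
            graph = by_id[pid]
            if node_id not in graph.sinks:
                raise ValueError(f"{sink_id} is not a sink of pathway {pid}")
            for nid in private_branch(graph, node_id):
                for g in graph.nodes[nid].gene_ids:
                    factors[g] = factor

        fc = pd.DataFrame(
            {"c": [factors.get(g, 1.0) for g in all_genes]}, index=all_genes
        )
        logp = np.log2(compute_psf_matrix(graphs, fc)["c"])
        strong_cut = 0.5 * abs(np.log2(spec.effect_size))
        class_sinks[spec.label] = {
            sink: int(np.sign(v))
            for sink, v in logp.items()
            if abs(v) > 1e-9 and abs(v) >= strong_cut
        }
        background[spec.label] = sorted(
            sink for sink, v in logp.items() if 1e-9 < abs(v) < strong_cut
        )
        class_factors[spec.label] = factors
        if spec.block is not None:
            blocks[spec.label] = spec.block
        if spec.supergroup is not None:
            supergroups[spec.label] = spec.supergroup
    return GroundTruth(class_sinks, background, class_factors,
                       blocks, supergroups, control[0])


def generate_pathways(
    design: SyntheticDesign,
) -> tuple[list[PathwayGraph], dict[str, str], GroundTruth]:
    """Generate the pathway collection, its KGML documents, and the truth.

    Fully deterministic for a fixed ``design.seed`` (identical KGML bytes on
    repeats).  Classes without explicit target sinks receive them via the
    block allocation scheme.
    """
    rng = np.random.default_rng(design.seed)
    has_blocks = any(
        c.block is not None for c in design.resolved_classes()
    )
    n_chains = design.n_mirror_chains if has_blocks else 0
    graphs = [
        _generate_graph(
            f"syn{i:03d}", design, rng,
            chain=i >= design.n_pathways - n_chains,
        )
        for i in range(design.n_pathways)
    ]
    classes = _allocate_targets(design, design.resolved_classes(), graphs, rng)
    truth = plant_truth(classes, graphs)
    kgml = {g.pathway_id: pathway_to_kgml(g) for g in graphs}
    return graphs, kgml, truth


def simulate_expression(
    design: SyntheticDesign,
    graphs: list[PathwayGraph],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a linear-scale expression cohort with planted deregulation.

    Every gene draws a log-normal baseline (meanlog 7, sdlog 1 on the
    natural-log scale) shared across samples; each sample multiplies it by
    ``2**N(0, noise_sd)`` gene-wise noise, and disease samples additionally
    multiply their class's branch genes by the effect size (its reciprocal
    for down-regulation).  Returns ``(expression, sample_sheet)``.
    """
    classes = design.resolved_classes()
    genes = sorted({g for gr in graphs for n in gr.nodes.values()
                    for g in n.gene_ids})
    rng = np.random.default_rng((design.seed + 1) % 2**31)
    baseline = rng.lognormal(mean=7.0, sigma=1.0, size=len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}

    columns: dict[str, np.ndarray] = {}
    rows = []
    for spec in classes:
        factor = np.ones(len(genes))
        if not spec.is_control:
            if spec.label not in truth.class_factors:
                raise ValueError(f"class {spec.label!r} missing from truth")
            for g, f in truth.class_factors[spec.label].items():
                factor[gene_pos[g]] = f
        noise = np.power(
            2.0, rng.normal(0.0, design.noise_sd, size=(len(genes), spec.n_samples))
        )
        values = baseline[:, None] * noise * factor[:, None]
        for k in range(spec.n_samples):
            sid = f"{spec.label}_{k:03d}"
            columns[sid] = values[:, k]
            rows.append((sid, spec.label, "synth1", spec.is_control))

    expression = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    sheet = pd.DataFrame(
        rows, columns=["sample_id", "class_label", "dataset_id", "is_control"]
    )
    return expression, sheet


def generate_dataset(design: SyntheticDesign):
    """Convenience wrapper: pathways + expression + sheet + truth."""
    graphs, kgml, truth = generate_pathways(design)
    expression, sheet = simulate_expression(design, graphs, truth)
    return graphs, kgml, expression, sheet, truth
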