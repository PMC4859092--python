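"""Pathway signal flow (PSF): topology-aware pathway activity at sink nodes.

A unit input signal is injected at every source node of an acyclic pathway
graph and propagated towards the sinks.  Each node multiplies the incoming
signal by its own fold change (the mean FC of its genes; 1 if unmeasured);
an activating edge transmits the parent signal as is, an inhibitory edge
transmits its reciprocal, and a node with several parents averages their
contributions.  The scheme is calibrated so that fold change 1 everywhere
(no deregulation) yields PSF = 1 at every sink; PSF > 1 signals pathway
activation and PSF < 1 de-activation.

All propagation here is vectorized over samples: node weights are
(node x sample) arrays, so a whole fold-change matrix is scored in one pass
per pathway.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .pathway import PathwayGraph

logger = logging.getLogger(__name__)

DEFAULT_INPUT_SIGNAL = 1.0
DEFAULT_MISSING_FC = 1.0


def map_fc_to_nodes(
    graph: PathwayGraph,
    fc: pd.Series | pd.DataFrame,
    missing_fc: float = DEFAULT_MISSING_FC,
) -> tuple[pd.DataFrame, float]:
    """Map gene fold changes onto pathway nodes.

    ``fc`` is a Series (one sample) or DataFrame (genes x samples) of
    positive linear fold changes.  A multi-gene node receives the arithmetic
    mean FC of its measured genes; nodes with no measured gene (and compound
    nodes, which carry no genes) receive the neutral value ``missing_fc``.

    Returns ``(weights, coverage)`` where ``weights`` is node x sample and
    ``coverage`` is the fraction of gene nodes with at least one measured
    gene.
    """
    if isinstance(fc, pd.Series):
        fc = fc.to_frame("sample")
    values = fc.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or (values <= 0).any():
        raise ValueError("fold changes must be finite and strictly positive")
    gene_index = {g: i for i, g in enumerate(fc.index)}

    node_ids = sorted(graph.nodes)
    weights = np.full((len(node_ids), fc.shape[1]), float(missing_fc))
    n_gene_nodes = 0
    n_covered = 0
    for row, nid in enumerate(node_ids):
        node = graph.nodes[nid]
        if not node.gene_ids:
            continue
        n_gene_nodes += 1
        rows = [gene_index[g] for g in node.gene_ids if g in gene_index]
        if rows:
            n_covered += 1
            weights[row] = values[rows].mean(axis=0)
    coverage = n_covered / n_gene_nodes if n_gene_nodes else 0.0
    return pd.DataFrame(weights, index=node_ids, columns=fc.columns), coverage


def compute_psf(
    graph: PathwayGraph,
    weights: pd.DataFrame | pd.Series | dict,
    input_signal: float = DEFAULT_INPUT_SIGNAL,
) -> pd.DataFrame:
    """Propagate the input signal and return sink PSF values.

    ``weights`` holds per-node fold changes (node x sample DataFrame, or a
    Series/dict for a single sample).  Returns a sink x sample DataFrame.

    Propagation in topological order: a source starts from
    ``input_signal * FC(source)``; any other node multiplies its FC by the
    arithmetic mean of parent contributions, where an activating parent
    contributes its signal and an inhibiting parent the reciprocal of its
    signal.
    """
    if isinstance(weights, dict):
        weights = pd.Series(weights)
    if isinstance(weights, pd.Series):
        weights = weights.to_frame("sample")
    if not graph.is_acyclic():
        raise ValueError(
            f"pathway {graph.pathway_id} contains cycles; run break_cycles first"
        )
    missing = set(graph.nodes) - set(weights.index)
    if missing:
        raise ValueError(f"node weights missing for: {sorted(missing)[:5]}")
    w = weights.to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("node weights must be strictly positive")

    order = graph.topological_order()
    idx = {nid: weights.index.get_loc(nid) for nid in graph.nodes}
    parents: dict[str, list] = {nid: [] for nid in graph.nodes}
    for e in graph.edges:
        parents[e.to_id].append(e)

    signal = np.empty_like(w)
    for nid in order:
        i = idx[nid]
        inc = parents[nid]
        if not inc:
            signal[i] = input_signal * w[i]
        else:
            contrib = np.empty((len(inc), w.shape[1]))
            for k, e in enumerate(inc):
                s = signal[idx[e.from_id]]
                contrib[k] = s if e.sign > 0 else 1.0 / s
            signal[i] = w[i] * contrib.mean(axis=0)

    sinks = sorted(graph.sinks)
    out = pd.DataFrame(
        np.stack([signal[idx[s]] for s in sinks]) if sinks else
        np.empty((0, w.shape[1])),
        index=sinks,
        columns=weights.columns,
    )
    return out


def compute_psf_matrix(
    graphs: list[PathwayGraph],
    fc: pd.DataFrame,
    input_signal: float = DEFAULT_INPUT_SIGNAL,
    missing_fc: float = DEFAULT_MISSING_FC,
) -> pd.DataFrame:
    """PSF for every (pathway, sink) pair over every sample.

    Rows are labelled ``pathway_id:sink_node_id`` and ordered by pathway id
    then node id; columns follow the fold-change matrix.  A pathway whose
    propagation fails is skipped with a logged error.
    """
    blocks = []
    for graph in sorted(graphs, key=lambda g: g.pathway_id):
        try:
            weights, coverage = map_fc_to_nodes(graph, fc, missing_fc=missing_fc)
            psf = compute_psf(graph, weights, input_signal=input_signal)
        except ValueError as exc:
            logger.error("pathway %s skipped: %s", graph.pathway_id, exc)
            continue
        psf.index = [f"{graph.pathway_id}:{sink}" for sink in psf.index]
        blocks.append(psf)
        logger.debug("pathway %s: coverage %.2f", graph.pathway_id, coverage)
    if not blocks:
        raise ValueError("no pathway produced PSF values")
    return pd.concat(blocks, axis=0)


def centralize(psf: pd.DataFrame) -> pd.DataFrame:
    """Sink-wise centered log2 PSF.

    Each row of ``log2(PSF)`` is shifted to zero mean over all samples, so
    the values express per-sample deviation from the cohort-average activity
    of that sink rather than absolute signal levels.
    """
    if (psf.to_numpy() <= 0).any():
        raise ValueError("PSF values must be strictly positive")
    logp = np.log2(psf)
    return logp.sub(logp.mean(axis=1), axis=0)


def pathway_report(graph: PathwayGraph, psf: pd.DataFrame, coverage: float) -> str:
    """Per-pathway JSON report of sink values and node coverage."""
    return json.dumps(
        {
            "pathway_id": graph.pathway_id,
            "name": graph.name,
            "coverage": coverage,
            "sinks": {
                sink: dict(zip(psf.columns.astype(str), map(float, row)))
                for sink, row in psf.iterrows()
            },
        },
        indent=1,
    )
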