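import numpy as np
import pandas as pd
import pytest

from psfsom import expression, psf, synth

TOY_KGML = """<?xml version="1.0"?>
<pathway name="path:toy01" org="hsa" title="Toy cascade">
  <entry id="A" name="hsa:10" type="gene"><graphics name="GA"/></entry>
  <entry id="B" name="hsa:20" type="gene"><graphics name="GB"/></entry>
  <entry id="C" name="hsa:30" type="gene"><graphics name="GC"/></entry>
  <relation entry1="A" entry2="B" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="B" entry2="C" type="PPrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
</pathway>
"""

GROUP_KGML = """<?xml version="1.0"?>
<pathway name="path:toy02" org="hsa" title="Grouped">
  <entry id="1" name="hsa:g1" type="gene"><graphics name="G1"/></entry>
  <entry id="2" name="hsa:g2" type="gene"><graphics name="G2"/></entry>
  <entry id="3" name="undefined" type="group">
    <graphics name="complex"/>
    <component id="1"/>
    <component id="2"/>
  </entry>
  <entry id="4" name="hsa:g4" type="gene"><graphics name="G4"/></entry>
  <entry id="5" name="path:hsa00010" type="map"><graphics name="Glycolysis"/></entry>
  <relation entry1="3" entry2="4" type="PPrel">
    <subtype name="expression" value="--&gt;"/>
  </relation>
  <relation entry1="4" entry2="5" type="maplink">
    <subtype name="compound" value="..&gt;"/>
  </relation>
</pathway>
"""


@pytest.fixture
def toy_kgml():
    return TOY_KGML


@pytest.fixture
def group_kgml():
    return GROUP_KGML


@pytest.fixture(scope="session")
def block_dataset():
    """One full synthetic cohort with the default block design (seed 7)."""
    design = synth.SyntheticDesign(seed=7)
    graphs, kgml, expr, sheet, truth = synth.generate_dataset(design)
    return {
        "design": design, "graphs": graphs, "kgml": kgml,
        "expression": expr, "sheet": sheet, "truth": truth,
    }


@pytest.fixture(scope="session")
def block_psf(block_dataset):
    """Fold changes and PSF matrix for the session-wide synthetic cohort."""
    linear, _ = expression.detect_and_linearize(block_dataset["expression"])
    fc = expression.compute_fold_change(linear, block_dataset["sheet"])
    psf_matrix = psf.compute_psf_matrix(block_dataset["graphs"], fc)
    return {"fc": fc, "psf": psf_matrix, "centralized": psf.centralize(psf_matrix)}


def chain_graph(fcs, signs=None, pathway_id="chain"):
    """Build an unbranched path pathway plus its node-weight Series.

    ``fcs`` are the node fold changes from source to sink; ``signs`` the edge
    signs (defaults to all activation).
    """
    from psfsom.pathway import PathwayEdge, PathwayGraph, PathwayNode

    n = len(fcs)
    signs = list(signs or [1] * (n - 1))
    nodes = {
        f"n{i:02d}": PathwayNode(f"n{i:02d}", frozenset({f"g{i}"}), "gene")
        for i in range(n)
    }
    edges = tuple(
        PathwayEdge(f"n{i:02d}", f"n{i + 1:02d}", s,
                    "activation" if s > 0 else "inhibition")
        for i, s in enumerate(signs)
    )
    graph = PathwayGraph(pathway_id, pathway_id, nodes, edges)
    weights = pd.Series({f"n{i:02d}": float(f) for i, f in enumerate(fcs)})
    return graph, weights
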