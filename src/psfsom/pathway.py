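"""Signed directed pathway graphs parsed from KEGG KGML files.

A pathway is modelled as a directed graph whose nodes are gene sets (a KGML
``gene`` entry may carry several gene identifiers, and ``group`` entries are
flattened into one multi-gene node) or compounds, and whose edges carry a
sign: +1 for activating interactions, -1 for inhibitory ones.  Signal
propagation (:mod:`psfsom.psf`) requires an acyclic graph with at least one
source (in-degree 0) and one sink (out-degree 0), so feedback loops present
in curated maps are broken deterministically before scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
from lxml import etree

logger = logging.getLogger(__name__)

#: KGML relation subtype names that flip the edge sign to inhibition.
_INHIBITORY_MARKERS = ("inhibition", "repression")

#: KGML entry types kept as pathway nodes.
_NODE_TYPES = frozenset({"gene", "compound", "group"})


class KGMLParseError(ValueError):
    """Malformed KGML XML; carries the reported byte offset when available."""


class PathwayStructureError(ValueError):
    """Structurally invalid pathway (dangling relation, unresolvable cycles...)."""


@dataclass(frozen=True)
class PathwayNode:
    node_id: str
    gene_ids: frozenset[str]
    node_kind: str  # "gene" | "compound" | "group"
    label: str = ""

    def __post_init__(self) -> None:
        if self.node_kind == "gene" and not self.gene_ids:
            raise PathwayStructureError(
                f"gene node {self.node_id!r} has an empty gene set"
            )


@dataclass(frozen=True)
class PathwayEdge:
    from_id: str
    to_id: str
    sign: int  # +1 activation, -1 inhibition
    subtype_label: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise PathwayStructureError(f"edge sign must be +-1, got {self.sign}")


@dataclass(frozen=True)
class PathwayGraph:
    """A signed pathway topology with designated sources and sinks.

    ``sources``/``sinks`` are recomputed from the edge set, never stored
    independently, so they stay consistent under cycle breaking.
    """

    pathway_id: str
    name: str
    nodes: dict[str, PathwayNode]
    edges: tuple[PathwayEdge, ...]
    removed_edges: tuple[PathwayEdge, ...] = field(default=())

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.from_id not in self.nodes or e.to_id not in self.nodes:
                raise PathwayStructureError(
                    f"pathway {self.pathway_id}: edge {e.from_id}->{e.to_id} "
                    "references a missing node"
                )

    # -- degree-derived views -------------------------------------------------
    @property
    def sources(self) -> frozenset[str]:
        has_in = {e.to_id for e in self.edges}
        return frozenset(n for n in self.nodes if n not in has_in)

    @property
    def sinks(self) -> frozenset[str]:
        has_out = {e.from_id for e in self.edges}
        return frozenset(n for n in self.nodes if n not in has_out)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(pathway_id=self.pathway_id, name=self.name)
        for nid, node in self.nodes.items():
            g.add_node(nid, node=node)
        for e in self.edges:
            g.add_edge(e.from_id, e.to_id, sign=e.sign, subtype=e.subtype_label)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def topological_order(self) -> list[str]:
        """Node ids in a deterministic topological order (ties by node_id)."""
        return list(
            nx.lexicographical_topological_sort(nx.DiGraph(self.to_networkx()))
        )

    # -- (de)serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "pathway_id": self.pathway_id,
            "name": self.name,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "gene_ids": sorted(n.gene_ids),
                    "node_kind": n.node_kind,
                    "label": n.label,
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.node_id)
            ],
            "edges": [
                {
                    "from": e.from_id,
                    "to": e.to_id,
                    "sign": e.sign,
                    "subtype": e.subtype_label,
                }
                for e in self.edges
            ],
            "sources": sorted(self.sources),
            "sinks": sorted(self.sinks),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PathwayGraph":
        d = json.loads(text)
        nodes = {
            n["node_id"]: PathwayNode(
                n["node_id"], frozenset(n["gene_ids"]), n["node_kind"], n["label"]
            )
            for n in d["nodes"]
        }
        edges = tuple(
            PathwayEdge(e["from"], e["to"], e["sign"], e["subtype"])
            for e in d["edges"]
        )
        return cls(d["pathway_id"], d["name"], nodes, edges)


def _entry_gene_ids(name_attr: str) -> frozenset[str]:
    """Split a KGML ``name`` attribute and strip database prefixes (``hsa:``)."""
    ids = set()
    for token in name_attr.split():
        if token in ("undefined", ""):
            continue
        ids.add(token.rsplit(":", 1)[-1])
    return frozenset(ids)


def parse_kgml(source) -> PathwayGraph:
    """Parse one KGML document into a :class:`PathwayGraph`.

    ``source`` may be a path, a file object, or a bytes/str XML document.
    Entries of type ``map`` (links to other pathways) are dropped together
    with relations touching them; a relation naming an id absent from the
    document raises :class:`PathwayStructureError`.
    """
    try:
        if isinstance(source, (str, bytes)) and (
            (isinstance(source, str) and source.lstrip().startswith("<"))
            or (isinstance(source, bytes) and source.lstrip().startswith(b"<"))
        ):
            root = etree.fromstring(
                source.encode() if isinstance(source, str) else source
            )
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(f"malformed KGML: {exc}") from exc

    pathway_id = root.get("name", root.get("title", "pathway")).rsplit(":", 1)[-1]
    name = root.get("title", pathway_id)

    entries: dict[str, etree._Element] = {}
    dropped: set[str] = set()
    for entry in root.findall("entry"):
        eid = entry.get("id")
        entries[eid] = entry
        if entry.get("type") not in _NODE_TYPES:
            dropped.add(eid)

    nodes: dict[str, PathwayNode] = {}
    for eid, entry in entries.items():
        etype = entry.get("type")
        if eid in dropped:
            continue
        gene_ids = _entry_gene_ids(entry.get("name", ""))
        if etype == "group":
            # flatten component entries into one multi-gene node
            for comp in entry.findall("component"):
                member = entries.get(comp.get("id"))
                if member is not None:
                    gene_ids |= _entry_gene_ids(member.get("name", ""))
        graphics = entry.find("graphics")
        label = graphics.get("name", "") if graphics is not None else ""
        if etype == "gene" and not gene_ids:
            # rare malformed entries: keep topology, treat as compound-like
            etype = "compound"
        nodes[eid] = PathwayNode(eid, gene_ids if etype != "compound" else frozenset(),
                                 etype, label.split(",")[0] if label else "")

    edges: list[PathwayEdge] = []
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in entries or e2 not in entries:
            raise PathwayStructureError(
                f"pathway {pathway_id}: relation references unknown entry "
                f"({e1!r} -> {e2!r})"
            )
        if e1 in dropped or e2 in dropped:
            continue  # maplink / pathway-map endpoints are not scored
        subtypes = [s.get("name", "") for s in rel.findall("subtype")]
        label = ", ".join(subtypes)
        sign = -1 if any(
            marker in s for s in subtypes for marker in _INHIBITORY_MARKERS
        ) else +1
        edges.append(PathwayEdge(e1, e2, sign, label))

    return PathwayGraph(pathway_id, name, nodes, tuple(edges))


def break_cycles(graph: PathwayGraph) -> PathwayGraph:
    """Return an acyclic copy of ``graph`` with DFS back edges removed.

    Depth-first search is rooted at the source nodes (then at any remaining
    unvisited nodes), visiting ids in lexicographic order, and every edge
    closing a cycle back onto the active DFS stack is discarded.  The rule is
    deterministic, so repeated runs remove the same feedback edges.
    """
    if graph.is_acyclic():
        return graph

    succ: dict[str, list[PathwayEdge]] = {nid: [] for nid in graph.nodes}
    for e in graph.edges:
        succ[e.from_id].append(e)
    for lst in succ.values():
        lst.sort(key=lambda e: (e.to_id, e.sign, e.subtype_label))

    roots = sorted(graph.sources)
    if not roots:
        raise PathwayStructureError(
            f"pathway {graph.pathway_id}: no sources after cycle analysis"
        )

    removed: list[PathwayEdge] = []
    color: dict[str, int] = {}  # 1 = on stack, 2 = done

    def dfs(root: str) -> None:
        stack: list[tuple[str, int]] = [(root, 0)]
        color[root] = 1
        while stack:
            node, idx = stack[-1]
            if idx < len(succ[node]):
                stack[-1] = (node, idx + 1)
                edge = succ[node][idx]
                state = color.get(edge.to_id)
                if state == 1:
                    removed.append(edge)  # back edge: closes a cycle
                elif state is None:
                    color[edge.to_id] = 1
                    stack.append((edge.to_id, 0))
            else:
                color[node] = 2
                stack.pop()

    for root in roots:
        if root not in color:
            dfs(root)
    for nid in sorted(graph.nodes):
        if nid not in color:
            dfs(nid)

    removed_set = set(removed)
    kept = tuple(e for e in graph.edges if e not in removed_set)
    logger.info(
        "pathway %s: removed %d feedback edge(s): %s",
        graph.pathway_id,
        len(removed),
        ", ".join(f"{e.from_id}->{e.to_id}" for e in removed),
    )
    out = replace(graph, edges=kept,
                  removed_edges=graph.removed_edges + tuple(removed))
    assert out.is_acyclic()
    return out


def filter_pathway_collection(
    graphs: list[PathwayGraph], exclusion_ids: list[str] | None = None
) -> list[PathwayGraph]:
    """Drop excluded pathways and pathways without annotated interactions."""
    excluded = set(exclusion_ids or ())
    kept = [g for g in graphs if g.pathway_id not in excluded and g.edges]
    if not kept:
        logger.warning("pathway filter removed every pathway")
    return kept


def read_exclusion_file(path) -> list[str]:
    """One pathway id per line; blank lines and ``#`` comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
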