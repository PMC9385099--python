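"""Signed pathway graphs and their group-node augmentation.

A pathway is represented as a directed graph whose nodes are gene
identifiers and whose edges carry a discrete ``weight`` in {-1, 0, +1}
encoding repression, neutral interaction, and activation, respectively
(the convention used by curated signalling databases such as KEGG).
The module provides readers/writers for GraphML, GML and signed edge
lists, the augmentation that attaches an exogenous binary group node to
every gene, component filtering, and the pathway-level up/down
regulation call derived from the edge-weight bookkeeping.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

VALID_WEIGHTS = (-1, 0, 1)

#: default identifier for the exogenous group node added by augmentation
DEFAULT_GROUP_NODE = "GROUP"


class PathwayGraphError(ValueError):
    """Raised for malformed pathway graphs or unreadable graph files."""


@dataclass
class PathwayGraph:
    """A signed, directed gene-gene interaction graph for one pathway.

    Parameters
    ----------
    name
        Pathway identifier (e.g. a KEGG id or a free-form label).
    graph
        Directed graph whose edges carry an integer ``weight`` attribute
        in {-1, 0, +1}.  Self-loops and parallel edges are rejected: the
        structural equations regress each gene on its *other* parents,
        so a ``j -> j`` term has no meaning in the model.
    bidirected
        Optional unordered gene pairs ``k <-> j`` representing latent
        confounding (correlated errors).  Accepted in the data model;
        see :mod:`semgsa.fitting` for how they are treated during
        estimation.
    """

    name: str
    graph: nx.DiGraph
    bidirected: tuple[frozenset, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        g = self.graph
        if not isinstance(g, nx.DiGraph) or g.is_multigraph():
            raise PathwayGraphError(
                f"pathway {self.name!r}: expected a simple nx.DiGraph"
            )
        for u, v, data in g.edges(data=True):
            if u == v:
                raise PathwayGraphError(
                    f"pathway {self.name!r}: self-loop on node {u!r} rejected"
                )
            w = data.get("weight")
            if w is None:
                warnings.warn(
                    f"pathway {self.name!r}: edge {u!r}->{v!r} has no weight; "
                    "treating as 0 (neutral)",
                    stacklevel=2,
                )
                data["weight"] = 0
            elif w not in VALID_WEIGHTS:
                raise PathwayGraphError(
                    f"pathway {self.name!r}: edge {u!r}->{v!r} has weight {w!r}; "
                    "only -1, 0, +1 are allowed"
                )
        self.bidirected = tuple(frozenset(p) for p in self.bidirected)
        for pair in self.bidirected:
            if len(pair) != 2:
                raise PathwayGraphError(
                    f"pathway {self.name!r}: bidirected pair {set(pair)!r} "
                    "must join two distinct genes"
                )
            if not pair <= set(g.nodes):
                raise PathwayGraphError(
                    f"pathway {self.name!r}: bidirected pair {set(pair)!r} "
                    "references unknown genes"
                )

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def directed_edges(self) -> list[tuple]:
        """Edges as ``(source, target, weight)`` triples, sorted."""
        return sorted(
            (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        )

    def subgraph(self, nodes: Iterable, name: str | None = None) -> "PathwayGraph":
        """Induced subgraph on ``nodes`` (bidirected pairs restricted too)."""
        keep = set(nodes)
        sub = self.graph.subgraph(keep).copy()
        bid = tuple(p for p in self.bidirected if p <= keep)
        return PathwayGraph(name or self.name, sub, bid)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PathwayGraph({self.name!r}, nodes={self.n_nodes}, "
            f"edges={self.n_edges})"
        )


@dataclass(frozen=True)
class AugmentedGraph:
    """A pathway graph plus an exogenous binary group node.

    The group node ``X`` receives an edge ``X -> j`` for every gene, so
    the undirected skeleton of the augmented graph is connected even
    when the pathway consists of several components and singletons.
    Genes split into the exogenous set ``v_x`` (sources and singletons,
    i.e. genes with no gene parents) and the endogenous set ``v_y``
    (connectors and sinks).
    """

    base: PathwayGraph
    group_node: str
    graph: nx.DiGraph
    v_x: frozenset
    v_y: frozenset

    @property
    def genes(self) -> frozenset:
        return self.base.nodes


@dataclass(frozen=True)
class RegulationCall:
    """Pathway-level up/down regulation derived from edge weights.

    ``weight_sum`` is the grand total of directed-edge weights (equal to
    summing the per-source column sums of the weighted adjacency
    matrix).  The pathway is called ``down`` when the total is below 1
    and ``up`` otherwise; when the graph contains no +1 or -1 edge the
    call is ``not_available`` and downstream perturbation labels become
    ``NA``.
    """

    status: Literal["up", "down", "not_available"]
    weight_sum: int


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_EXTENSIONS = {
    ".graphml": "graphml",
    ".gml": "gml",
    ".tsv": "signed_edge_list",
    ".txt": "signed_edge_list",
    ".sif": "signed_edge_list",
    ".edges": "signed_edge_list",
}


def _coerce_weight(raw, where: str) -> int:
    try:
        w = int(float(raw))
    except (TypeError, ValueError):
        raise PathwayGraphError(f"{where}: unparseable edge weight {raw!r}")
    if w not in VALID_WEIGHTS or float(raw) != w:
        raise PathwayGraphError(
            f"{where}: edge weight {raw!r} outside {{-1, 0, +1}}"
        )
    return w


def _read_edge_list(path: str, name: str) -> PathwayGraph:
    g = nx.DiGraph()
    seen: set[tuple] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                warnings.warn(
                    f"{path}:{ln}: missing weight column; treating as 0",
                    stacklevel=2,
                )
                parts.append("0")
            if len(parts) != 3:
                raise PathwayGraphError(
                    f"{path}:{ln}: expected 'source target weight', got {line!r}"
                )
            u, v, raw = parts
            if (u, v) in seen:
                raise PathwayGraphError(
                    f"{path}:{ln}: duplicate directed edge {u!r}->{v!r}"
                )
            seen.add((u, v))
            g.add_edge(u, v, weight=_coerce_weight(raw, f"{path}:{ln}"))
    return PathwayGraph(name, g)


def _read_nx(path: str, fmt: str, name: str) -> PathwayGraph:
    try:
        if fmt == "graphml":
            raw = nx.read_graphml(path, force_multigraph=True)
        else:
            raw = nx.read_gml(path)
    except Exception as exc:  # pragma: no cover - networkx error text varies
        raise PathwayGraphError(f"{path}: unparseable {fmt} file ({exc})") from exc
    if raw.is_multigraph():
        pairs = [(u, v) for u, v in raw.edges()]
        if len(pairs) != len(set(pairs)):
            raise PathwayGraphError(
                f"{path}: parallel edges between the same gene pair rejected"
            )
    if not raw.is_directed():
        raise PathwayGraphError(f"{path}: expected a directed graph")
    g = nx.DiGraph()
    g.add_nodes_from(str(n) for n in raw.nodes)
    for u, v, data in raw.edges(data=True):
        if "weight" not in data:
            warnings.warn(
                f"{path}: edge {u!r}->{v!r} has no weight attribute; "
                "treating as 0",
                stacklevel=2,
            )
            w = 0
        else:
            w = _coerce_weight(data["weight"], path)
        g.add_edge(str(u), str(v), weight=w)
    return PathwayGraph(name, g)


def read_pathways(
    path: str,
    format: str | None = None,
) -> list[PathwayGraph]:
    """Read one or more pathway graphs from ``path``.

    ``path`` may be a single file or a directory, in which case every
    file with a recognised extension (.graphml, .gml, .tsv/.txt/.sif
    signed edge list) is read in sorted order.  The pathway name is the
    file name without extension; node identifiers are preserved
    verbatim.  Edges with a missing weight get weight 0 with a warning;
    weights outside {-1, 0, +1}, self-loops and parallel edges are
    fatal.
    """
    if os.path.isdir(path):
        out = []
        for fname in sorted(os.listdir(path)):
            ext = os.path.splitext(fname)[1].lower()
            if ext in _EXTENSIONS:
                out.extend(read_pathways(os.path.join(path, fname), format))
        if not out:
            raise PathwayGraphError(f"{path}: no pathway files found")
        return out

    if not os.path.exists(path):
        raise PathwayGraphError(f"{path}: no such file")
    name = os.path.splitext(os.path.basename(path))[0]
    fmt = format or _EXTENSIONS.get(os.path.splitext(path)[1].lower())
    if fmt is None:
        raise PathwayGraphError(
            f"{path}: cannot infer format; pass format= one of "
            "graphml, gml, signed_edge_list"
        )
    if fmt == "signed_edge_list":
        return [_read_edge_list(path, name)]
    if fmt in ("graphml", "gml"):
        return [_read_nx(path, fmt, name)]
    raise PathwayGraphError(f"unknown graph format {fmt!r}")


def write_pathway(g: PathwayGraph, path: str) -> None:
    """Serialize ``g`` as a signed edge list (TSV: source, target, weight).

    Singleton nodes are written as comment lines ``#node <id>`` so that
    a read/write round trip is an identity on the graph.
    """
    with open(path, "w") as fh:
        covered = set()
        for u, v, w in g.directed_edges():
            fh.write(f"{u}\t{v}\t{w}\n")
            covered.update((u, v))
        for n in sorted(set(g.graph.nodes) - covered):
            fh.write(f"#node {n}\n")


def _read_edge_list_with_singletons(path: str, name: str) -> PathwayGraph:
    pg = _read_edge_list(path, name)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#node "):
                pg.graph.add_node(line.split(maxsplit=1)[1].strip())
    return pg


def read_pathway_edge_list(path: str) -> PathwayGraph:
    """Read a single signed edge list, honouring ``#node`` singleton lines."""
    name = os.path.splitext(os.path.basename(path))[0]
    return _read_edge_list_with_singletons(path, name)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def augment_with_group(
    g: PathwayGraph, group_node: str = DEFAULT_GROUP_NODE
) -> AugmentedGraph:
    """Attach the exogenous group node ``X`` with an edge to every gene.

    Genes with no gene parents in the base graph form ``v_x`` (their
    group effect is a marginal two-group comparison); the rest form
    ``v_y`` (group effect adjusted for gene parents).  The resulting
    undirected skeleton is connected regardless of the input topology.
    """
    if g.n_nodes == 0:
        raise PathwayGraphError(f"pathway {g.name!r}: empty graph")
    if group_node in g.nodes:
        raise PathwayGraphError(
            f"pathway {g.name!r}: gene named like the reserved group node "
            f"{group_node!r}; rename the gene or pass a different group_node"
        )
    aug = g.graph.copy()
    for j in g.graph.nodes:
        aug.add_edge(group_node, j, weight=0)
    v_x = frozenset(j for j in g.graph.nodes if g.graph.in_degree(j) == 0)
    v_y = g.nodes - v_x
    return AugmentedGraph(base=g, group_node=group_node, graph=aug, v_x=v_x, v_y=v_y)


def pathway_regulation(g: PathwayGraph) -> RegulationCall:
    """Up/down regulation call from the total of directed-edge weights."""
    weights = [d["weight"] for _, _, d in g.graph.edges(data=True)]
    if not any(w != 0 for w in weights):
        return RegulationCall("not_available", int(sum(weights)))
    total = int(sum(weights))
    return RegulationCall("down" if total < 1 else "up", total)


def max_component(g: PathwayGraph) -> PathwayGraph:
    """Induced subgraph on the largest weakly connected component.

    Ties on size are broken deterministically in favour of the
    component containing the lexicographically smallest node label.
    """
    if g.n_nodes == 0:
        raise PathwayGraphError(f"pathway {g.name!r}: empty graph")
    comps = list(nx.weakly_connected_components(g.graph))
    best = min(comps, key=lambda c: (-len(c), min(str(n) for n in c)))
    return g.subgraph(best)


def filter_pathways(
    gs: Sequence[PathwayGraph],
    min_nodes: int = 30,
    max_nodes: int = 300,
    min_component_frac: float = 0.6,
) -> list[PathwayGraph]:
    """Size/connectivity filter used before enrichment or simulation.

    Keeps pathways with ``min_nodes <= |V| <= max_nodes`` whose largest
    weakly connected component covers at least ``min_component_frac``
    of the nodes, and returns the largest components of the survivors.
    """
    out = []
    for g in gs:
        if not (min_nodes <= g.n_nodes <= max_nodes):
            continue
        comp = max_component(g)
        if comp.n_nodes / g.n_nodes < min_component_frac:
            continue
        out.append(comp)
    return out
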