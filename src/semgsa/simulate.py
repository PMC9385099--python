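"""Dysregulation simulator and type-I-error / power harness.

The harness emulates the benchmark evaluation protocol: a collection
of pathways, a designated subset of ``q1`` dysregulated pathways in
which ``s`` genes are selected by a topological rule (betweenness,
community, or order-2 neighbourhood), a signed mean signal injected
into the selected genes for case subjects, and the remaining pathways
with at most one affected gene serving as true negatives (``q0``).
Base expression data are synthetic: multivariate-normal draws
standardised to zero mean and unit variance per gene within each
group, optionally with a block correlation structure.  Each replicate
regenerates the data, reruns the enrichment test, and records which
pathways are rejected; type I error and power are the rejection
fractions on ``q0`` and ``q1`` averaged over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .graphs import PathwayGraph
from .model import semgsa

Topology = Literal["betweenness", "community", "neighbourhood"]

TOPOLOGIES: tuple[Topology, ...] = ("betweenness", "community", "neighbourhood")

#: mean-shift magnitudes (per-gene standard deviations) of the study design
SIGNAL_LEVELS = (0.5, 0.6, 0.7)


# ---------------------------------------------------------------------------
# synthetic pathway generation
# ---------------------------------------------------------------------------


def generate_pathways(
    n_pathways: int = 20,
    size_range: tuple[int, int] = (30, 60),
    gene_pool_size: int | None = None,
    edge_factor: float = 1.5,
    weight_probs: tuple[float, float, float] = (0.70, 0.25, 0.05),
    seed=None,
) -> list[PathwayGraph]:
    """Random connected signed DAGs standing in for curated pathways.

    Each pathway draws its node set from a shared gene pool (so
    pathways can overlap, as real pathway collections do), builds a
    random spanning tree oriented by a random topological order
    (guaranteeing a weakly connected DAG), and adds forward edges up to
    roughly ``edge_factor`` edges per node -- the sparsity of typical
    curated signalling pathways.  The default pool holds eight times
    the total node slots, mirroring the sparse pathway coverage of a
    genome-wide expression matrix (a pathway of ~50 genes drawn from
    ~10000 measured genes), so that genes dysregulated in one pathway
    leak into others only occasionally.  Edge weights are drawn as
    +1 / -1 / 0 with probabilities ``weight_probs``; the default is
    activation-heavy, matching the predominance of activating
    interactions in curated signalling maps.
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if lo < 2:
        raise ValueError("pathways need at least 2 nodes")
    sizes = rng.integers(lo, hi + 1, size=n_pathways)
    if gene_pool_size is None:
        gene_pool_size = max(8 * int(sizes.sum()), hi)
    width = len(str(gene_pool_size))
    pool = np.array([f"g{i:0{width}d}" for i in range(1, gene_pool_size + 1)])
    out = []
    for i, size in enumerate(sizes):
        size = int(min(size, gene_pool_size))
        nodes = rng.choice(pool, size=size, replace=False)
        order = rng.permutation(size)
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        edges: set[tuple[int, int]] = set()
        for k in range(1, size):
            j = int(rng.integers(0, k))
            edges.add((j, k))
        target = min(int(round(edge_factor * size)), size * (size - 1) // 2)
        while len(edges) < target:
            a, b = rng.integers(0, size, size=2)
            if a == b:
                continue
            a, b = (int(min(a, b)), int(max(a, b)))
            edges.add((a, b))
        weights = rng.choice([1, -1, 0], size=len(edges), p=weight_probs)
        for (a, b), w in zip(sorted(edges), weights):
            g.add_edge(nodes[order[a]], nodes[order[b]], weight=int(w))
        out.append(PathwayGraph(f"pathway{i + 1:02d}", g))
    return out


# ---------------------------------------------------------------------------
# topology-driven selection of affected genes
# ---------------------------------------------------------------------------


def _check_size(g: PathwayGraph, s: int) -> bool:
    if g.n_nodes < s:
        warnings.warn(
            f"pathway {g.name!r} has {g.n_nodes} < s={s} nodes; "
            "taking all of them",
            stacklevel=3,
        )
        return False
    return True


def select_affected_betweenness(g: PathwayGraph, s: int) -> list[str]:
    """Top-``s`` nodes by directed shortest-path betweenness.

    Ties are broken by node label order for determinism.
    """
    if not _check_size(g, s):
        return sorted(g.graph.nodes)
    bc = nx.betweenness_centrality(g.graph, normalized=False)
    ranked = sorted(bc, key=lambda n: (-bc[n], str(n)))
    return ranked[:s]


def _largest_community(g: PathwayGraph) -> list[str]:
    skeleton = g.graph.to_undirected()
    communities = nx.community.greedy_modularity_communities(skeleton)
    best = min(communities, key=lambda c: (-len(c), min(str(n) for n in c)))
    return sorted(best)


def select_affected_community(g: PathwayGraph, s: int, seed=None) -> list[str]:
    """``s`` genes sampled uniformly from the largest community.

    Community detection is greedy modularity maximisation on the
    undirected skeleton; if the largest community holds fewer than
    ``s`` genes the whole community is taken with a warning.
    """
    members = _largest_community(g)
    rng = np.random.default_rng(seed)
    if len(members) < s:
        warnings.warn(
            f"pathway {g.name!r}: largest community has {len(members)} < s={s} "
            "members; taking the whole community",
            stacklevel=2,
        )
        return members
    return sorted(rng.choice(members, size=s, replace=False))


def select_affected_neighbourhood(
    g: PathwayGraph, s: int, order: int = 2, seed=None
) -> list[str]:
    """``s`` genes sampled from the largest order-``order`` neighbourhood.

    For every vertex the set of vertices within distance ``order`` on
    the undirected skeleton (centre included) is computed; the largest
    one is kept (ties broken by centre label order) and ``s`` vertices
    are sampled from it.
    """
    skeleton = g.graph.to_undirected()
    best: set | None = None
    for center in sorted(skeleton.nodes, key=str):
        hood = set(
            nx.single_source_shortest_path_length(skeleton, center, cutoff=order)
        )
        if best is None or len(hood) > len(best):
            best = hood
    members = sorted(best)
    rng = np.random.default_rng(seed)
    if len(members) < s:
        warnings.warn(
            f"pathway {g.name!r}: largest order-{order} neighbourhood has "
            f"{len(members)} < s={s} vertices; taking all of them",
            stacklevel=2,
        )
        return members
    return sorted(rng.choice(members, size=s, replace=False))


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffectedSet:
    """Affected genes per dysregulated pathway, with their signs.

    ``signs`` maps each unique affected gene to +1 (shifted up in
    cases) or -1 (shifted down); ``unique_genes`` is the deduplicated
    union across pathways, bounded by ``s * len(per_pathway)``.
    """

    per_pathway: dict[str, tuple[str, ...]]
    signs: dict[str, int]

    @property
    def unique_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.signs))


def _gene_sign(g: PathwayGraph, gene: str) -> int:
    """Up/down weight of a gene: sign of its summed outgoing edge weights.

    Sinks and zero-sum genes default to +1 (up-regulated).
    """
    total = sum(d["weight"] for _, _, d in g.graph.out_edges(gene, data=True))
    return -1 if total < 0 else 1


def build_design(
    pathways: Sequence[PathwayGraph],
    q1_names: Sequence[str],
    topology: Topology,
    s: int = 10,
    seed=None,
) -> tuple[AffectedSet, list[str]]:
    """Select affected genes in the ``q1`` pathways and derive ``q0``.

    Returns the affected set and the names of the true-negative
    pathways: those outside ``q1`` containing at most one affected
    gene.  When a gene is selected in several pathways its sign is
    taken from the first pathway (in ``q1_names`` order) that selected
    it.
    """
    by_name = {g.name: g for g in pathways}
    unknown = [n for n in q1_names if n not in by_name]
    if unknown:
        raise ValueError(f"q1 pathways not in the collection: {unknown}")
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; one of {TOPOLOGIES}")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(len(q1_names))
    per_pathway: dict[str, tuple[str, ...]] = {}
    signs: dict[str, int] = {}
    for name, child in zip(q1_names, children):
        g = by_name[name]
        if topology == "betweenness":
            genes = select_affected_betweenness(g, s)
        elif topology == "community":
            genes = select_affected_community(g, s, seed=child)
        else:
            genes = select_affected_neighbourhood(g, s, seed=child)
        per_pathway[name] = tuple(genes)
        for gene in genes:
            signs.setdefault(gene, _gene_sign(g, gene))
    affected = AffectedSet(per_pathway=per_pathway, signs=signs)
    unique = set(affected.unique_genes)
    q0 = [
        g.name
        for g in pathways
        if g.name not in set(q1_names) and len(g.nodes & unique) <= 1
    ]
    return affected, q0


# ---------------------------------------------------------------------------
# data generation and signal injection
# ---------------------------------------------------------------------------


def generate_base_data(
    genes: Sequence[str],
    n_cases: int = 46,
    n_controls: int = 23,
    block_corr: float = 0.0,
    blocks: Sequence[Sequence[str]] | None = None,
    standardize: bool = True,
    seed=None,
) -> ExpressionDataset:
    """Null expression data, standardised per gene within each group.

    Draws are multivariate normal with unit variances; when
    ``block_corr > 0`` genes belonging to the same block (e.g. the same
    pathway) share an equicorrelation ``rho`` induced by a common
    factor.  With ``standardize=True`` (the study protocol) every gene
    is then centred and scaled to unit sample variance within cases and
    within controls separately, so the null of no group difference
    holds exactly; pass ``standardize=False`` for plain noise whose
    group contrasts fluctuate as in unnormalised data.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("gene identifiers must be unique")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    Y = rng.standard_normal((n, len(genes)))
    if block_corr and blocks:
        if not (0.0 <= block_corr < 1.0):
            raise ValueError("block correlation must be in [0, 1)")
        col = {g: i for i, g in enumerate(genes)}
        assigned: set[int] = set()
        for block in blocks:
            idx = [col[g] for g in block if g in col and col[g] not in assigned]
            if len(idx) < 2:
                continue
            assigned.update(idx)
            f = rng.standard_normal(n)
            Y[:, idx] = np.sqrt(block_corr) * f[:, None] + np.sqrt(
                1.0 - block_corr
            ) * Y[:, idx]
    group = np.array([1] * n_cases + [0] * n_controls)
    if standardize:
        for grp in (0, 1):
            rows = group == grp
            block_data = Y[rows]
            Y[rows] = (block_data - block_data.mean(axis=0)) / block_data.std(
                axis=0, ddof=1
            )
    values = pd.DataFrame(
        Y, index=[f"s{i + 1:03d}" for i in range(n)], columns=genes
    )
    return ExpressionDataset(values, group)


def inject_signal(
    data: ExpressionDataset, affected: AffectedSet, signal: float
) -> ExpressionDataset:
    """Shift case subjects of each affected gene by ``sign * signal``.

    Controls and unaffected genes are untouched; the magnitude is in
    units of the per-gene (within-group) standard deviation because the
    base data are standardised.
    """
    missing = [g for g in affected.unique_genes if g not in data.genes]
    if missing:
        raise ValueError(f"affected genes absent from the data: {missing[:10]}")
    out = data.copy()
    case_rows = out.group == 1
    for gene in affected.unique_genes:
        out.values.loc[case_rows, gene] += affected.signs[gene] * signal
    return out


# ---------------------------------------------------------------------------
# simulation harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the dysregulation study.

    ``signal`` is the injected mean shift in per-gene standard
    deviations (study levels 0.5, 0.6, 0.7); ``s`` the number of
    affected genes per dysregulated pathway; ``q1_pathways`` the names
    of the dysregulated pathways.  ``n_permutations`` is the label
    permutation count handed to the enrichment test.

    Group-wise normalisation applies to the population scale of the
    generator (every gene has mean 0 and variance 1 within each group
    in expectation); replicates are fresh draws from that model, so
    in-sample group contrasts fluctuate as they do in data normalised
    once and then re-sampled.  Setting ``exact_standardize=True``
    re-standardises every replicate instead, which pins each
    unaffected gene's group contrast to exactly zero and makes the
    null degenerate (all null p-values equal 1) -- useful as a
    diagnostic, not as the study protocol.
    """

    topology: Topology
    signal: float
    q1_pathways: tuple[str, ...]
    s: int = 10
    n_replicates: int = 100
    n_cases: int = 46
    n_controls: int = 23
    n_permutations: int = 200
    block_corr: float = 0.0
    exact_standardize: bool = False
    seed: object = None

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if not self.q1_pathways:
            raise ValueError("q1_pathways must be non-empty")
        if self.signal < 0:
            raise ValueError("signal must be non-negative")


@dataclass(frozen=True)
class SimMetrics:
    """Rejection summaries of one simulation cell."""

    type_i_error: float
    power: float
    q0_pathways: tuple[str, ...]
    per_replicate_q0: np.ndarray
    per_replicate_q1: np.ndarray

    @property
    def type_i_mc_se(self) -> float:
        r = self.per_replicate_q0
        return float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else float("nan")

    @property
    def power_mc_se(self) -> float:
        r = self.per_replicate_q1
        return float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else float("nan")


def run_simulation(
    design: SimulationDesign,
    pathways: Sequence[PathwayGraph],
    rejection_alpha: float = 0.05,
) -> SimMetrics:
    """Run one simulation cell and estimate type I error and power.

    Every replicate regenerates the base data with a fresh sub-seed,
    injects the signed signal into the affected genes, runs the
    enrichment test over all pathways, and flags rejections at
    ``PVAL < rejection_alpha``.
    """
    ss = (
        design.seed
        if isinstance(design.seed, np.random.SeedSequence)
        else np.random.SeedSequence(design.seed)
    )
    design_child, *rep_children = ss.spawn(1 + design.n_replicates)
    affected, q0 = build_design(
        pathways, design.q1_pathways, design.topology, design.s, seed=design_child
    )
    if not q0:
        warnings.warn(
            "no true-negative (q0) pathway in this design; "
            "type I error will be NaN",
            stacklevel=2,
        )
    genes = sorted(set().union(*(g.nodes for g in pathways)))
    blocks = [sorted(g.nodes) for g in pathways] if design.block_corr else None
    q1 = set(design.q1_pathways)
    q0_set = set(q0)
    frac_q0 = np.empty(design.n_replicates)
    frac_q1 = np.empty(design.n_replicates)
    for r, child in enumerate(rep_children):
        data_seed, fit_seed = child.spawn(2)
        base = generate_base_data(
            genes,
            design.n_cases,
            design.n_controls,
            block_corr=design.block_corr,
            blocks=blocks,
            standardize=design.exact_standardize,
            seed=data_seed,
        )
        data = inject_signal(base, affected, design.signal) if design.signal else base
        res = semgsa(
            pathways, data, n_rep=design.n_permutations, seed=fit_seed
        )
        rejected = set(res.gsa.loc[res.gsa["PVAL"] < rejection_alpha, "pathway"])
        frac_q0[r] = (
            len(rejected & q0_set) / len(q0_set) if q0_set else np.nan
        )
        frac_q1[r] = len(rejected & q1) / len(q1)
    return SimMetrics(
        type_i_error=float(np.nanmean(frac_q0)) if q0_set else float("nan"),
        power=float(frac_q1.mean()),
        q0_pathways=tuple(q0),
        per_replicate_q0=frac_q0,
        per_replicate_q1=frac_q1,
    )


def dysregulation_study(
    seed=None,
    topologies: Sequence[Topology] = TOPOLOGIES,
    signals: Sequence[float] = SIGNAL_LEVELS,
    n_pathways: int = 20,
    size_range: tuple[int, int] = (30, 60),
    n_q1: int = 10,
    s: int = 10,
    n_replicates: int = 50,
    n_permutations: int = 200,
    n_cases: int = 46,
    n_controls: int = 23,
    rejection_alpha: float = 0.05,
    block_corr: float = 0.0,
    pathways: Sequence[PathwayGraph] | None = None,
) -> pd.DataFrame:
    """Full topology x signal grid of the dysregulation study.

    Generates one shared pathway collection (unless ``pathways`` is
    given), designates ``n_q1`` dysregulated pathways, and runs
    :func:`run_simulation` for every combination of topology design and
    signal level.  Returns one row per cell with type I error, power
    and their Monte-Carlo standard errors.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    gen_child, pick_child, *cell_children = ss.spawn(
        2 + len(topologies) * len(signals)
    )
    if pathways is None:
        pathways = generate_pathways(
            n_pathways, size_range=size_range, seed=gen_child
        )
    rng = np.random.default_rng(pick_child)
    names = [g.name for g in pathways]
    q1 = tuple(sorted(rng.choice(names, size=n_q1, replace=False)))
    rows = []
    cells = iter(cell_children)
    for topology in topologies:
        for signal in signals:
            design = SimulationDesign(
                topology=topology,
                signal=signal,
                q1_pathways=q1,
                s=s,
                n_replicates=n_replicates,
                n_cases=n_cases,
                n_controls=n_controls,
                n_permutations=n_permutations,
                block_corr=block_corr,
                seed=next(cells),
            )
            metrics = run_simulation(design, pathways, rejection_alpha)
            rows.append(
                {
                    "topology": topology,
                    "signal": signal,
                    "type_i_error": metrics.type_i_error,
                    "type_i_mc_se": metrics.type_i_mc_se,
                    "power": metrics.power,
                    "power_mc_se": metrics.power_mc_se,
                    "n_q0": len(metrics.q0_pathways),
                    "n_replicates": n_replicates,
                }
            )
    return pd.DataFrame(rows)
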