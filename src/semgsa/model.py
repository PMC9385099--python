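"""Model/Results interface for pathway group-effect enrichment.

:class:`PathwaySEM` fits the common-effect structural equation model of
one pathway to expression data and returns a
:class:`PathwaySEMResults` with node-level estimates and the combined
activation/inhibition evidence.  :class:`SEMGSA` runs a collection of
pathways through the same machinery, applies the across-pathway
Bonferroni adjustment, and returns a :class:`SEMGSAResults` whose
``gsa`` table mirrors the standard output columns
(pathway, No.nodes, No.DEGs, pert, pNA, pNI, PVAL, ADJP).

The convenience function :func:`semgsa` wraps construction and fitting
in one call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import combine
from .combine import BrownResult, DegList
from .data import ExpressionDataset
from .fitting import (
    FitConfig,
    NodeFit,
    fit_with_null,
    permutation_matrix,
    shrink_covariance,
)
from .graphs import (
    DEFAULT_GROUP_NODE,
    PathwayGraph,
    RegulationCall,
    augment_with_group,
    pathway_regulation,
)

logger = logging.getLogger(__name__)

GSA_COLUMNS = ["pathway", "No.nodes", "No.DEGs", "pert", "pNA", "pNI", "PVAL", "ADJP"]


def _pathway_correlation(
    data: ExpressionDataset, genes: Sequence[str], shrink: bool = True
) -> np.ndarray:
    """Pairwise gene correlation feeding Brown's dependence correction.

    Pearson correlations of expression pooled across groups after
    per-group centering (so a mean shift between groups does not
    inflate co-expression).  The pooled covariance is shrunk toward a
    well-conditioned target when it is not positive definite, which is
    the regime where the raw estimate is unreliable (p >= n).
    """
    Y = data.matrix(genes)
    n = Y.shape[0]
    for grp in (0, 1):
        rows = data.group == grp
        Y[rows] = Y[rows] - Y[rows].mean(axis=0)
    S = Y.T @ Y / max(n - 2, 1)
    if shrink:
        S = shrink_covariance(S, n)
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    R = S / np.outer(d, d)
    R = np.clip(np.nan_to_num(R, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class PathwaySEMResults:
    """Fitted group effects and combined evidence for one pathway."""

    pathway: str
    regulation: RegulationCall
    node_fits: list[NodeFit]
    brown_activation: BrownResult
    brown_inhibition: BrownResult
    pval: float
    pert: str
    degs: DegList
    config: FitConfig

    @property
    def p_activation(self) -> float:
        return self.brown_activation.p_combined

    @property
    def p_inhibition(self) -> float:
        return self.brown_inhibition.p_combined

    @property
    def n_nodes(self) -> int:
        return len(self.node_fits)

    def node_table(self) -> pd.DataFrame:
        """Per-gene estimates, null moments and p-values."""
        return pd.DataFrame(
            {
                "gene": [f.gene for f in self.node_fits],
                "beta": [f.beta_hat for f in self.node_fits],
                "null_mean": [f.null_mean for f in self.node_fits],
                "null_sd": [f.null_sd for f in self.node_fits],
                "p_two_sided": [f.p_two_sided for f in self.node_fits],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Pathway SEM results: {self.pathway}",
            f"  nodes: {self.n_nodes}   regulation: {self.regulation.status} "
            f"(weight sum {self.regulation.weight_sum})",
            f"  pNA = {self.p_activation:.4g}   pNI = {self.p_inhibition:.4g}   "
            f"PVAL = {self.pval:.4g}",
            f"  perturbation: {self.pert}   DEGs: {len(self.degs.genes)}",
        ]
        return "\n".join(lines)


class PathwaySEM:
    """Common-effect SEM of one pathway with an exogenous group node.

    Parameters
    ----------
    pathway
        Signed pathway graph.  Genes absent from the expression data
        are dropped (with a logged count) before augmentation.
    data
        Expression dataset carrying the binary group vector.
    group_node
        Reserved identifier for the added group node.
    """

    def __init__(
        self,
        pathway: PathwayGraph,
        data: ExpressionDataset,
        group_node: str = DEFAULT_GROUP_NODE,
    ):
        present = pathway.nodes & set(data.genes)
        dropped = pathway.n_nodes - len(present)
        if dropped:
            logger.info(
                "pathway %s: dropped %d gene(s) missing from the data",
                pathway.name,
                dropped,
            )
        if len(present) < 2:
            raise ValueError(
                f"pathway {pathway.name!r}: fewer than 2 genes present in the data"
            )
        self.pathway = pathway.subgraph(present)
        self.data = data
        self.augmented = augment_with_group(self.pathway, group_node)
        self.regulation = pathway_regulation(self.pathway)

    def fit(
        self,
        n_rep: int = 1000,
        seed=None,
        method: str = "BH",
        alpha: float = 0.05,
        _x_perm: np.ndarray | None = None,
    ) -> PathwaySEMResults:
        """Estimate group effects, permutation p-values and combined evidence."""
        cfg = FitConfig(n_rep=n_rep, seed=seed)
        fits = fit_with_null(self.augmented, self.data, cfg, _x_perm=_x_perm)
        genes = [f.gene for f in fits]
        corr = _pathway_correlation(self.data, genes, shrink=cfg.shrink_if_not_pd)
        p_act = [
            combine.one_sided(f.p_two_sided, f.beta_hat, "activation") for f in fits
        ]
        p_inh = [
            combine.one_sided(f.p_two_sided, f.beta_hat, "inhibition") for f in fits
        ]
        brown_a = combine.brown_combine(p_act, corr)
        brown_i = combine.brown_combine(p_inh, corr)
        pval = combine.pathway_pval(brown_a.p_combined, brown_i.p_combined)
        pert = combine.perturbation_status(
            self.regulation, brown_a.p_combined, brown_i.p_combined
        )
        degs = combine.select_degs(fits, self.pathway.name, method, alpha)
        return PathwaySEMResults(
            pathway=self.pathway.name,
            regulation=self.regulation,
            node_fits=fits,
            brown_activation=brown_a,
            brown_inhibition=brown_i,
            pval=pval,
            pert=pert,
            degs=degs,
            config=cfg,
        )


@dataclass
class SEMGSAResults:
    """Enrichment results for a pathway collection.

    ``gsa`` is the pathway summary table ordered by ascending PVAL
    (ties broken by pathway name); ``deg`` maps each pathway to its
    list of differentially expressed genes.
    """

    gsa: pd.DataFrame
    deg: dict[str, list[str]]
    pathway_results: dict[str, PathwaySEMResults]
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        header = (
            f"SEM gene set analysis: {len(self.gsa)} pathway(s), "
            f"method={self.config.get('method')}, alpha={self.config.get('alpha')}, "
            f"n_rep={self.config.get('n_rep')}, seed={self.config.get('seed')}"
        )
        with pd.option_context("display.float_format", "{:.4g}".format):
            table = self.gsa.to_string(index=False)
        return header + "\n" + table

    def save(self, outdir: str) -> None:
        from . import io as _io

        _io.write_outputs(self, outdir)


class SEMGSA:
    """Gene set analysis over a collection of signed pathway graphs.

    Each pathway is fitted as a :class:`PathwaySEM`; pathways with
    fewer than two genes present in the data are skipped with a
    warning.  A single top-level seed drives one shared set of label
    permutations used by every pathway.
    """

    def __init__(
        self,
        graphs: Sequence[PathwayGraph],
        data: ExpressionDataset,
        group_node: str = DEFAULT_GROUP_NODE,
    ):
        if not graphs:
            raise ValueError("no pathway graphs supplied")
        names = [g.name for g in graphs]
        if len(set(names)) != len(names):
            raise ValueError("pathway names must be unique")
        self.data = data
        self.n_input = len(graphs)
        self.models: dict[str, PathwaySEM] = {}
        self.skipped: list[str] = []
        for g in graphs:
            try:
                self.models[g.name] = PathwaySEM(g, data, group_node)
            except ValueError as exc:
                logger.warning("skipping pathway %s: %s", g.name, exc)
                self.skipped.append(g.name)

    @classmethod
    def from_frames(
        cls,
        graphs: Sequence[PathwayGraph],
        values: pd.DataFrame,
        group,
        group_node: str = DEFAULT_GROUP_NODE,
    ) -> "SEMGSA":
        """Build from a raw DataFrame and group vector."""
        return cls(graphs, ExpressionDataset(values, np.asarray(group)), group_node)

    def fit(
        self,
        method: str = "BH",
        alpha: float = 0.05,
        n_rep: int = 1000,
        seed=None,
    ) -> SEMGSAResults:
        """Fit all pathways and assemble the gsa/DEG outputs."""
        if not self.models:
            raise ValueError("no pathway has at least 2 genes in the data")
        cfg = FitConfig(n_rep=n_rep, seed=seed)
        rng = np.random.default_rng(seed)
        x_perm = permutation_matrix(self.data.group, n_rep, rng)
        rows = []
        results: dict[str, PathwaySEMResults] = {}
        for name, model in self.models.items():
            res = model.fit(
                n_rep=n_rep, seed=seed, method=method, alpha=alpha, _x_perm=x_perm
            )
            results[name] = res
            rows.append(
                {
                    "pathway": name,
                    "No.nodes": res.n_nodes,
                    "No.DEGs": len(res.degs.genes),
                    "pert": res.pert,
                    "pNA": res.p_activation,
                    "pNI": res.p_inhibition,
                    "PVAL": res.pval,
                }
            )
        gsa = pd.DataFrame(rows)
        gsa["ADJP"] = combine.adjust_global(gsa["PVAL"], self.n_input)
        gsa = gsa.sort_values(["PVAL", "pathway"], kind="mergesort").reset_index(
            drop=True
        )
        gsa = gsa[GSA_COLUMNS]
        deg = {name: list(results[name].degs.genes) for name in gsa["pathway"]}
        return SEMGSAResults(
            gsa=gsa,
            deg=deg,
            pathway_results=results,
            config={
                "method": method,
                "alpha": alpha,
                "n_rep": n_rep,
                "seed": seed,
                "n_input_pathways": self.n_input,
                "skipped": self.skipped,
            },
        )


def semgsa(
    graphs: Sequence[PathwayGraph],
    data: ExpressionDataset | pd.DataFrame,
    group=None,
    method: str = "BH",
    alpha: float = 0.05,
    n_rep: int = 1000,
    seed=None,
    group_node: str = DEFAULT_GROUP_NODE,
) -> SEMGSAResults:
    """One-call gene set analysis: build the model collection and fit it."""
    if isinstance(data, ExpressionDataset):
        ds = data
    else:
        if group is None:
            raise ValueError("group vector required when data is a DataFrame")
        ds = ExpressionDataset(pd.DataFrame(data), np.asarray(group))
    model = SEMGSA(graphs, ds, group_node)
    return model.fit(method=method, alpha=alpha, n_rep=n_rep, seed=seed)
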