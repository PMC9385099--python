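"""Pathway-level combination of node p-values.

Node-wise two-sided p-values are converted to one-sided activation and
inhibition p-values according to the sign of the group effect, combined
across the pathway with Brown's method (Fisher's method corrected for
dependence among the tests), and summarised as a single pathway p-value
by a Bonferroni combination of the two directions.  The module also
classifies the overall pathway perturbation by crossing the direction
of the combined evidence with the pathway's up/down regulation call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fitting import NodeFit, P_FLOOR
from .graphs import RegulationCall


@dataclass(frozen=True)
class BrownResult:
    """Brown-combined p-value with its scaled chi-square parameters.

    ``x2 = -2 * sum(log p_j)`` is referred to a chi-square with ``f``
    effective degrees of freedom after scaling by ``c``; with a single
    input or independent tests this reduces to Fisher's method.
    """

    x2: float
    c: float
    f: float
    p_combined: float


@dataclass(frozen=True)
class DegList:
    """Differentially expressed genes of one pathway (adjusted p < alpha)."""

    pathway: str
    genes: tuple[str, ...]


def one_sided(
    p: float, beta: float, direction: Literal["activation", "inhibition"]
) -> float:
    """Convert a two-sided p-value to a one-sided one given the effect sign.

    For the activation alternative (at least one positive group effect)
    the one-sided p is ``p/2`` when ``beta > 0`` and ``1 - p/2`` when
    ``beta < 0``; the inhibition alternative mirrors this.  A zero
    effect is uninformative for either direction and maps to 0.5.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"two-sided p-value {p} outside (0, 1]")
    if direction not in ("activation", "inhibition"):
        raise ValueError(f"unknown direction {direction!r}")
    if beta == 0:
        return 0.5
    favours = beta > 0 if direction == "activation" else beta < 0
    return p / 2.0 if favours else 1.0 - p / 2.0


def _kost_covariance(rho: np.ndarray) -> np.ndarray:
    """Polynomial approximation to cov(-2 log p_i, -2 log p_j).

    Standard cubic in the correlation of the underlying statistics,
    exact at rho = 0 (independence, covariance 0) and rho = 1
    (duplicated test, covariance 4).
    """
    return rho * (3.263 + rho * (0.710 + 0.027 * rho))


def brown_combine(
    p_one_sided: Sequence[float], gene_corr: np.ndarray | None = None
) -> BrownResult:
    """Combine dependent one-sided p-values by Brown's method.

    ``gene_corr`` is the pairwise correlation matrix of the underlying
    gene statistics (``None`` means independence, recovering Fisher's
    method exactly).  The chi-square scale ``c`` and effective degrees
    of freedom ``f`` are moment-matched from ``E = 2k`` and
    ``Var = 4k + 2 * sum_{i<j} cov_ij``.
    """
    p = np.asarray(p_one_sided, dtype=float)
    k = len(p)
    if k == 0:
        raise ValueError("cannot combine an empty set of p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.sum(np.log(p)))
    e = 2.0 * k
    if gene_corr is None or k == 1:
        cov_sum = 0.0
    else:
        rho = np.asarray(gene_corr, dtype=float)
        if rho.shape != (k, k):
            raise ValueError(
                f"correlation matrix shape {rho.shape} does not match {k} p-values"
            )
        rho = np.clip(rho, -1.0, 1.0)
        cov = _kost_covariance(rho)
        iu = np.triu_indices(k, 1)
        cov_sum = float(cov[iu].sum())
    var = 4.0 * k + 2.0 * cov_sum
    # strong negative dependence can push the moment-matched variance to
    # zero or below; floor it at a single test's variance to keep f > 0
    var = max(var, 4.0)
    c = var / (2.0 * e)
    f = 2.0 * e**2 / var
    p_comb = float(np.clip(stats.chi2.sf(x2 / c, f), P_FLOOR, 1.0))
    return BrownResult(x2=x2, c=c, f=f, p_combined=p_comb)


def pathway_pval(pna: float, pni: float) -> float:
    """Bonferroni combination of the activation/inhibition p-values."""
    for v in (pna, pni):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"p-value {v} outside (0, 1]")
    return min(1.0, 2.0 * min(pna, pni))


def adjust_global(pvals: Sequence[float], k: int | None = None) -> list[float]:
    """Bonferroni adjustment across the K input pathways: min(K*p, 1)."""
    pvals = list(pvals)
    if k is None:
        k = len(pvals)
    return [min(k * p, 1.0) for p in pvals]


_ADJUST_METHODS = {
    "BH": "fdr_bh",
    "bonferroni": "bonferroni",
    "holm": "holm",
}


def adjust_pvalues(pvals: Sequence[float], method: str = "BH") -> np.ndarray:
    """Within-pathway multiple-testing adjustment of node p-values."""
    if method not in _ADJUST_METHODS:
        raise ValueError(
            f"unknown adjustment method {method!r}; "
            f"supported: {sorted(_ADJUST_METHODS)}"
        )
    if len(pvals) == 0:
        return np.array([])
    return multipletests(np.asarray(pvals, float), method=_ADJUST_METHODS[method])[1]


def select_degs(
    fits: Sequence[NodeFit],
    pathway: str,
    method: str = "BH",
    alpha: float = 0.05,
) -> DegList:
    """Genes whose adjusted two-sided p-value falls below ``alpha``."""
    pvals = [f.p_two_sided for f in fits]
    if any(p is None for p in pvals):
        raise ValueError("node p-values must be computed before DEG selection")
    adj = adjust_pvalues(pvals, method)
    genes = tuple(f.gene for f, a in zip(fits, adj) if a < alpha)
    return DegList(pathway=pathway, genes=genes)


#: Overall perturbation labels: (regulation, node perturbation) -> label
PERTURBATION_TABLE = {
    ("up", "activated"): "up act",
    ("down", "activated"): "down inh",
    ("up", "inhibited"): "down act",
    ("down", "inhibited"): "up inh",
}


def perturbation_status(reg: RegulationCall, pna: float, pni: float) -> str:
    """Cross the up/down regulation call with the perturbation direction.

    The node perturbation is *activated* when the activation evidence
    dominates (``pNA < pNI``) and *inhibited* otherwise; pathways whose
    graphs carry no signed edge get the label ``NA``.
    """
    if reg.status == "not_available":
        return "NA"
    if pna == pni:
        warnings.warn(
            "activation and inhibition p-values tie exactly; "
            "classifying as activated",
            stacklevel=2,
        )
    direction = "activated" if pna <= pni else "inhibited"
    return PERTURBATION_TABLE[(reg.status, direction)]


def rank_pathways(pvals: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Dense ranks and percentile ranks of pathway p-values.

    Equal p-values share a rank; the percentile is the dense rank
    divided by the number of unique p-value categories, times 100.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int), np.array([])
    ranks = stats.rankdata(p, method="dense").astype(int)
    n_unique = len(np.unique(p))
    return ranks, ranks / n_unique * 100.0
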