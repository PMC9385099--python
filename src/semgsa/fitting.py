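"""Group-effect estimation under the common-effect linear SEM.

Given a pathway augmented with the binary group node ``X``, every gene
``j`` obeys a linear structural equation

    Y_j = sum_{k in pa(j)} beta_jk Y_k + beta_j X + U_j

with ``pa(j)`` empty for exogenous genes (sources and singletons).  The
group-effect coefficients ``beta_j`` are therefore identified equation
by equation: for exogenous genes ``beta_j`` is the case/control mean
difference, for endogenous genes the coefficient of ``X`` adjusted for
the gene parents.  With no bidirected edges, maximum likelihood
coincides with ordinary least squares per equation; when bidirected
edges (correlated errors) are present in a bow-free acyclic graph, a
residual iterative conditional fitting (RICF) loop is used instead.

Significance is assessed by label permutation: the group labels are
shuffled ``n_rep`` times, each shuffle re-estimates all ``beta_j`` with
the gene-gene columns fixed, and a two-sided p-value is read off a
normal distribution whose mean and standard deviation are the moments
of the permuted coefficients (a moment approximation that yields
accurate small p-values without an enormous number of permutations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import stats

from .data import ExpressionDataset
from .graphs import AugmentedGraph

logger = logging.getLogger(__name__)

#: numerical floor for reported p-values, avoids log(0) downstream
P_FLOOR = 1e-300

_RANK_TOL = 1e-10


class FitError(ValueError):
    """Raised for designs that cannot be estimated."""


@dataclass(frozen=True)
class FitConfig:
    """Permutation settings for the group-effect test.

    ``n_rep`` is the number of label permutations (1000 by default;
    values below 100 trigger a warning because the null moments become
    noisy).  ``shrink_if_not_pd`` enables James-Stein-type shrinkage of
    the pathway covariance when it is not positive definite (large
    p, small n).
    """

    n_rep: int = 1000
    seed: int | np.random.SeedSequence | None = None
    shrink_if_not_pd: bool = True

    def __post_init__(self) -> None:
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.n_rep < 100:
            warnings.warn(
                f"n_rep={self.n_rep} is small; permutation null moments and "
                "p-values will be unstable (recommend >= 100)",
                stacklevel=2,
            )


@dataclass
class NodeFit:
    """Per-gene group-effect estimate and its permutation null.

    ``beta_hat`` is the estimated path coefficient of the group node on
    the gene; ``parent_betas`` the adjusted coefficients of the gene
    parents.  ``null_mean``/``null_sd`` are the moments of ``beta_hat``
    under label permutation, and ``p_two_sided`` the normal-
    approximation p-value ``2 * Phi(-|beta_hat - null_mean| / null_sd)``.
    """

    gene: str
    beta_hat: float
    parent_betas: dict = field(default_factory=dict)
    null_mean: float | None = None
    null_sd: float | None = None
    p_two_sided: float | None = None


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


class _NodeDesign:
    """Fixed (gene-side) part of one node's regression.

    ``Q`` is an orthonormal basis of the span of the intercept and the
    parent columns, so the coefficient of any group column ``x`` is
    ``<x_perp, y> / <x_perp, x_perp>`` with ``x_perp = x - Q Q' x``
    (Frisch-Waugh-Lovell).  Only ``x`` changes across permutations.
    """

    __slots__ = ("gene", "parents", "y", "Z", "Q")

    def __init__(self, gene: str, parents: list[str], y: np.ndarray, Z: np.ndarray):
        self.gene = gene
        self.parents = parents
        self.y = y
        self.Z = Z
        Q, R = np.linalg.qr(Z)
        diag = np.abs(np.diag(R))
        scale = max(np.abs(Z).max(), 1.0)
        if diag.min() <= _RANK_TOL * scale * len(y):
            raise FitError(
                f"gene {gene!r}: rank-deficient design (duplicated or "
                f"collinear parent columns among {parents}); remove duplicate "
                "parents or merge perfectly correlated genes"
            )
        self.Q = Q

    def beta_x(self, x: np.ndarray) -> np.ndarray | float:
        """OLS coefficient of the group column(s) ``x`` (1-D or n x m)."""
        x_perp = x - self.Q @ (self.Q.T @ x)
        denom = np.sum(x_perp * x_perp, axis=0)
        return (x_perp * self.y.reshape(-1, 1) if x.ndim == 2 else x_perp * self.y).sum(
            axis=0
        ) / denom

    def full_solve(self, x: np.ndarray) -> np.ndarray:
        """Coefficients of [Z, x] regression (intercept, parents..., x)."""
        M = np.column_stack([self.Z, x])
        coef, *_ = np.linalg.lstsq(M, self.y, rcond=None)
        return coef


def _prepare_designs(
    g: AugmentedGraph, data: ExpressionDataset
) -> list[_NodeDesign]:
    missing = sorted(g.genes - set(data.genes))
    if missing:
        raise FitError(
            f"genes missing from the expression data: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    n = data.n_subjects
    ones = np.ones((n, 1))
    Y = {gene: data.values[gene].to_numpy(dtype=float) for gene in sorted(g.genes)}
    designs = []
    for gene in sorted(g.genes):
        parents = sorted(g.base.graph.predecessors(gene))
        Z = (
            np.column_stack([ones] + [Y[p].reshape(-1, 1) for p in parents])
            if parents
            else ones
        )
        designs.append(_NodeDesign(gene, parents, Y[gene], Z))
    return designs


def _check_groups(data: ExpressionDataset) -> None:
    if data.n_cases < 2 or data.n_controls < 2:
        raise FitError(
            "each group needs at least 2 subjects "
            f"(cases={data.n_cases}, controls={data.n_controls})"
        )


# ---------------------------------------------------------------------------
# RICF for bow-free acyclic graphs with bidirected edges
# ---------------------------------------------------------------------------


def _ricf_group_betas(
    g: AugmentedGraph,
    data: ExpressionDataset,
    x: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict[str, float]:
    """Group-effect coefficients by residual iterative conditional fitting.

    Used only for acyclic, bow-free graphs that declare bidirected
    edges.  Each node is refit in turn against its parents, the group
    column and pseudo-variables built from sibling residuals, until the
    coefficients stabilise.  Falls back to the least-squares estimates
    (bidirected edges ignored) if the loop does not converge.
    """
    genes = sorted(g.genes)
    idx = {gene: i for i, gene in enumerate(genes)}
    p = len(genes)
    n = data.n_subjects
    Y = data.matrix(genes)
    sib: dict[str, list[str]] = {gene: [] for gene in genes}
    for pair in g.base.bidirected:
        a, b = sorted(pair)
        sib[a].append(b)
        sib[b].append(a)

    designs = {d.gene: d for d in _prepare_designs(g, data)}
    beta = {gene: float(designs[gene].beta_x(x)) for gene in genes}
    coef_full = {gene: designs[gene].full_solve(x) for gene in genes}
    omega = np.eye(p)
    for gene in genes:
        d = designs[gene]
        resid = d.y - np.column_stack([d.Z, x]) @ coef_full[gene]
        omega[idx[gene], idx[gene]] = max(resid @ resid / n, 1e-12)

    for _ in range(max_iter):
        max_delta = 0.0
        # residuals under current structural coefficients
        eps = np.empty((n, p))
        for gene in genes:
            d = designs[gene]
            eps[:, idx[gene]] = d.y - np.column_stack([d.Z, x]) @ coef_full[gene]
        for gene in genes:
            d = designs[gene]
            j = idx[gene]
            sibs = sib[gene]
            if not sibs:
                continue
            others = [i for i in range(p) if i != j]
            M = np.linalg.inv(omega[np.ix_(others, others)])
            Zp_all = eps[:, others] @ M
            cols = [others.index(idx[s]) for s in sibs]
            Zp = Zp_all[:, cols]
            Xd = np.column_stack([d.Z, x, Zp])
            coef, *_ = np.linalg.lstsq(Xd, d.y, rcond=None)
            k_fixed = d.Z.shape[1] + 1
            new_beta = float(coef[k_fixed - 1])
            max_delta = max(max_delta, abs(new_beta - beta[gene]))
            beta[gene] = new_beta
            coef_full[gene] = coef[:k_fixed]
            w = coef[k_fixed:]
            for s, wv in zip(sibs, w):
                omega[j, idx[s]] = omega[idx[s], j] = wv
            resid = d.y - Xd @ coef
            o_j = omega[j, others]
            omega[j, j] = max(
                resid @ resid / n + float(o_j @ M @ o_j), 1e-12
            )
        if max_delta < tol:
            return beta
    warnings.warn(
        f"pathway {g.base.name!r}: RICF did not converge in {max_iter} "
        "iterations; using least-squares estimates",
        stacklevel=2,
    )
    return {gene: float(designs[gene].beta_x(x)) for gene in genes}


def _use_ricf(g: AugmentedGraph) -> bool:
    if not g.base.bidirected:
        return False
    directed_pairs = {frozenset((u, v)) for u, v in g.base.graph.edges}
    bow = any(pair in directed_pairs for pair in g.base.bidirected)
    acyclic = nx.is_directed_acyclic_graph(g.base.graph)
    if bow or not acyclic:
        warnings.warn(
            f"pathway {g.base.name!r}: bidirected edges ignored (graph is "
            + ("not bow-free" if bow else "cyclic")
            + "); fitting node-wise least squares",
            stacklevel=2,
        )
        return False
    return True


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def fit_common_model(
    g: AugmentedGraph, data: ExpressionDataset
) -> list[NodeFit]:
    """Estimate all group-effect coefficients on the observed labels.

    Exogenous genes are regressed on the group indicator alone (the
    estimate is exactly the case minus control mean difference);
    endogenous genes on their gene parents plus the indicator.  All
    regressions include an intercept.  Returns one :class:`NodeFit` per
    gene in sorted gene order, p-values unfilled.
    """
    _check_groups(data)
    x = data.group.astype(float)
    designs = _prepare_designs(g, data)
    if _use_ricf(g):
        betas = _ricf_group_betas(g, data, x)
        fits = []
        for d in designs:
            coef = d.full_solve(x)
            fits.append(
                NodeFit(
                    gene=d.gene,
                    beta_hat=betas[d.gene],
                    parent_betas=dict(zip(d.parents, coef[1 : 1 + len(d.parents)])),
                )
            )
        return fits
    fits = []
    for d in designs:
        coef = d.full_solve(x)
        fits.append(
            NodeFit(
                gene=d.gene,
                beta_hat=float(coef[-1]),
                parent_betas=dict(zip(d.parents, coef[1 : 1 + len(d.parents)])),
            )
        )
    return fits


def permutation_matrix(
    group: np.ndarray, n_rep: int, rng: np.random.Generator
) -> np.ndarray:
    """``n x n_rep`` matrix whose columns are permutations of ``group``.

    Labels are permuted, never resampled, so every column preserves the
    observed case/control counts.
    """
    x = np.asarray(group, dtype=float)
    out = np.empty((len(x), n_rep))
    for r in range(n_rep):
        out[:, r] = rng.permutation(x)
    return out


def permutation_null(
    g: AugmentedGraph,
    data: ExpressionDataset,
    cfg: FitConfig,
    _x_perm: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Empirical null moments of each ``beta_j`` under label permutation.

    Each of the ``cfg.n_rep`` permutations re-estimates every node's
    group coefficient with the gene-gene columns held fixed (only the
    group column of the design changes).  Returns
    ``{gene: (null_mean, null_sd)}`` with the sd computed with one
    delta degree of freedom.
    """
    _check_groups(data)
    if _x_perm is None:
        rng = np.random.default_rng(cfg.seed)
        _x_perm = permutation_matrix(data.group, cfg.n_rep, rng)
    designs = _prepare_designs(g, data)
    out: dict[str, tuple[float, float]] = {}
    if _use_ricf(g):
        all_betas = {d.gene: np.empty(_x_perm.shape[1]) for d in designs}
        for r in range(_x_perm.shape[1]):
            betas = _ricf_group_betas(g, data, _x_perm[:, r])
            for gene, b in betas.items():
                all_betas[gene][r] = b
        for gene, b in all_betas.items():
            out[gene] = (float(b.mean()), float(b.std(ddof=1)))
        return out
    for d in designs:
        betas = d.beta_x(_x_perm)
        out[d.gene] = (float(betas.mean()), float(betas.std(ddof=1)))
    return out


def fit_with_null(
    g: AugmentedGraph,
    data: ExpressionDataset,
    cfg: FitConfig,
    _x_perm: np.ndarray | None = None,
) -> list[NodeFit]:
    """Observed fit, permutation null and p-values in one pass.

    Equivalent to :func:`fit_common_model` followed by
    :func:`permutation_null` and :func:`node_pvalues`, but prepares
    each node's design (and its QR factorisation) only once.
    """
    _check_groups(data)
    if _use_ricf(g):
        fits = fit_common_model(g, data)
        moments = permutation_null(g, data, cfg, _x_perm=_x_perm)
        return node_pvalues(fits, moments)
    x = data.group.astype(float)
    if _x_perm is None:
        rng = np.random.default_rng(cfg.seed)
        _x_perm = permutation_matrix(data.group, cfg.n_rep, rng)
    fits = []
    moments = {}
    for d in _prepare_designs(g, data):
        coef = d.full_solve(x)
        betas = d.beta_x(_x_perm)
        moments[d.gene] = (float(betas.mean()), float(betas.std(ddof=1)))
        fits.append(
            NodeFit(
                gene=d.gene,
                beta_hat=float(coef[-1]),
                parent_betas=dict(zip(d.parents, coef[1 : 1 + len(d.parents)])),
            )
        )
    return node_pvalues(fits, moments)


def node_pvalues(
    fits: list[NodeFit], null_moments: dict[str, tuple[float, float]]
) -> list[NodeFit]:
    """Fill two-sided p-values from the normal moment approximation.

    ``p = 2 * Phi(-|beta_hat - null_mean| / null_sd)``, clipped to
    ``(P_FLOOR, 1]``.  A degenerate gene with ``null_sd = 0`` gets
    ``p = 1`` with a warning.
    """
    out = []
    for f in fits:
        m, s = null_moments[f.gene]
        if s <= 0.0:
            warnings.warn(
                f"gene {f.gene!r}: permutation null has zero spread; "
                "setting p = 1 (degenerate gene)",
                stacklevel=2,
            )
            p = 1.0
        else:
            z = abs(f.beta_hat - m) / s
            p = float(np.clip(2.0 * stats.norm.sf(z), P_FLOOR, 1.0))
        out.append(replace(f, null_mean=m, null_sd=s, p_two_sided=p))
    return out


# ---------------------------------------------------------------------------
# covariance shrinkage
# ---------------------------------------------------------------------------


def shrink_covariance(
    S: np.ndarray, n: int, tol: float = 1e-8
) -> np.ndarray:
    """Return a positive-definite version of the covariance matrix ``S``.

    If ``S`` already has smallest eigenvalue above ``tol`` it is
    returned unchanged.  Otherwise the correlation matrix is shrunk
    toward the identity with a James-Stein-type intensity

        lambda = sum_{i != j} var(r_ij) / sum_{i != j} r_ij**2,

    estimating ``var(r_ij)`` by ``(1 - r_ij**2)**2 / (n - 1)``, and the
    result is rescaled back to a covariance.  The intensity is raised
    further if needed so the output is numerically positive definite.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance matrix must be square")
    if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
        raise ValueError("covariance matrix must be symmetric")
    S = (S + S.T) / 2.0
    eigvals = np.linalg.eigvalsh(S)
    if eigvals.min() > tol:
        return S
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    off = R[~np.eye(len(R), dtype=bool)]
    denom = float(np.sum(off**2))
    if denom <= 0:
        lam = 1.0
    else:
        var_r = (1.0 - off**2) ** 2 / max(n - 1, 1)
        lam = float(np.clip(np.sum(var_r) / denom, 0.0, 1.0))
    R_sh = (1.0 - lam) * R + lam * np.eye(len(R))
    min_eig = np.linalg.eigvalsh(R_sh).min()
    if min_eig <= tol:
        # raise lambda just enough: eigenvalues shift affinely with lambda
        min_eig_R = np.linalg.eigvalsh(R).min()
        lam = min((tol * 2 - min_eig_R) / (1.0 - min_eig_R), 1.0)
        R_sh = (1.0 - lam) * R + lam * np.eye(len(R))
    out = R_sh * np.outer(d, d)
    return (out + out.T) / 2.0
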