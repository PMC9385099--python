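# Methods

## The model

Each pathway is a directed graph $G=(V,E)$ whose nodes are genes and
whose edges carry discrete weights in $\{-1,0,+1\}$ (repression,
neutral, activation — the convention of curated signalling databases
such as KEGG).  To test whether a binary condition $X\in\{0,1\}$
(case/control) perturbs the pathway, the graph is augmented with an
exogenous group node that points at every gene, and the joint
distribution is modelled by the linear structural equations

$$Y_j = \beta_j X + U_j, \qquad j \in V(x)$$
$$Y_j = \sum_{k\in\mathrm{pa}(j)} \beta_{jk} Y_k + \beta_j X + U_j,
  \qquad j \in V(y)$$

where $V(x)$ are the exogenous genes (sources and singletons) and
$V(y)$ the endogenous ones (connectors and sinks).  The group may
shift gene means but not the gene–gene paths or error covariances
("common" model).  Because the equations are identified one at a
time, every $\beta_j$ is estimable by ordinary least squares on
$\mathrm{pa}(j)\cup\{X\}$ plus an intercept; for $j\in V(x)$ the
estimate is exactly the case-minus-control mean difference.  This
coincides with the residual iterative conditional fitting (RICF)
maximum-likelihood solution whenever the graph has no bidirected
edges.  When bidirected edges (correlated errors from latent
confounding) are declared on a bow-free acyclic graph, an RICF loop
re-fits each node against its parents, the group column and
pseudo-variables formed from sibling residuals until the coefficients
stabilise; non-bow-free or cyclic declarations fall back to
least squares with a warning.  Cyclic directed graphs are accepted and
fitted node-wise, since each equation is defined locally.

Augmentation has a structural side effect that matters in practice:
curated pathways are often fragmented (the COVID-19 KEGG map, for
instance, has five components and over a hundred singletons), and the
group node connects all fragments so no gene is discarded.

## Permutation p-values with a moment approximation

Significance of $\hat\beta_j$ is assessed by permuting the group
labels `n_rep` times (default 1000; the simulation harness uses 200)
and re-estimating every node's group coefficient with the gene
columns held fixed — only the group column of each design changes, so
after one QR factorisation per node each permutation costs a single
projection.  Rather than counting exceedances, the empirical mean
$m_j$ and standard deviation $s_j$ of the permuted coefficients are
plugged into a normal tail,

$$p_j = 2\,\Phi\!\left(-\frac{|\hat\beta_j - m_j|}{s_j}\right),$$

which yields accurate small p-values without needing millions of
permutations.  p-values are floored at $10^{-300}$ so that downstream
logarithms are finite; a degenerate gene with $s_j=0$ is reported at
$p=1$ with a warning.  All permutations in a multi-pathway run are
drawn once from the top-level seed and shared across pathways, making
the whole analysis a pure function of (graphs, data, configuration,
seed).

## Combining node evidence: activation, inhibition, Brown's method

Two-sided node p-values are converted to one-sided ones by the sign of
the estimated effect: for the *activation* alternative
$p_j^{(+)} = p_j/2$ if $\hat\beta_j>0$, else $1-p_j/2$ (the
*inhibition* alternative mirrors this; a zero effect contributes 0.5
to both).  Within a pathway the one-sided p-values are dependent
because genes co-express, so they are combined with Brown's method:
$X^2=-2\sum_j\log p_j$, referred to a scaled chi-square
$X^2/c\sim\chi^2(f)$ with $c=\mathrm{Var}/2E$, $f=2E^2/\mathrm{Var}$,
$E=2k$ and
$\mathrm{Var}=4k+2\sum_{i<j}\mathrm{cov}(-2\log p_i,-2\log p_j)$.
The covariance terms use the standard cubic approximation
$\rho(3.263+0.710\rho+0.027\rho^2)$ in the correlation $\rho$ of the
underlying gene statistics, which is exact at $\rho=0$ (reducing to
Fisher's method) and at $\rho=1$ (collapsing duplicated tests to a
single one).  The $\rho$ fed in is the Pearson correlation of the two
genes' expression, pooled across groups after per-group centering so
that a genuine mean shift does not masquerade as co-expression; the
pooled covariance is shrunk (below) before conversion to a
correlation whenever it is not positive definite.  With strong
negative dependence the moment-matched variance could reach zero; it
is floored at a single test's variance (4) to keep $f>0$, a regime
shrunk correlations do not reach in practice.

The two combined p-values — `pNA` (activation) and `pNI`
(inhibition) — are merged by a Bonferroni combination
`PVAL = min(1, 2 min(pNA, pNI))` and adjusted across the $K$ input
pathways as `ADJP = min(K PVAL, 1)`.  Note that `PVAL` is a *valid*
but not exactly uniform null p-value: its two halves are negatively
dependent (they are built from $\Phi(-z_j)$ and $\Phi(z_j)$), so a
mass of roughly $P(pNA>\tfrac12, pNI>\tfrac12)\approx0.14$ piles up
at exactly 1 while the lower tail stays calibrated.  Tests of null
calibration therefore check that the distribution is never
anti-conservative and that the 0.05 tail matches its nominal level,
rather than two-sided uniformity, which the capped combination cannot
satisfy by construction.

Differentially expressed genes of a pathway are the nodes whose
two-sided p-values, adjusted within the pathway (Benjamini–Hochberg
by default; Bonferroni and Holm available), fall below `alpha`
(default 0.05).

## Perturbation classification

A pathway is called *up-regulated* when the grand total of its edge
weights is at least 1 and *down-regulated* otherwise; graphs with no
signed edge give `NA`.  The node perturbation direction is *activated*
when `pNA < pNI` and *inhibited* otherwise (an exact tie, a
probability-zero event, is logged and resolved to activated).
Crossing the two yields the overall label: up/activated → `up act`,
down/activated → `down inh`, up/inhibited → `down act`,
down/inhibited → `up inh`.

## Covariance shrinkage

When a pathway has more genes than there are subjects, the sample
covariance is singular.  A James–Stein-type shrinkage is then applied
to the correlation matrix toward the identity, with intensity
$\lambda=\sum_{i\ne j}\widehat{\mathrm{var}}(r_{ij})/\sum_{i\ne j}r_{ij}^2$
and $\widehat{\mathrm{var}}(r_{ij})=(1-r_{ij}^2)^2/(n-1)$, raised
further if needed for numerical positive definiteness, and the result
is rescaled to a covariance.  Well-conditioned inputs are returned
unchanged, so shrinkage never perturbs the estimate when it is not
needed.

## The decorrelated mean-difference comparator

As a self-contained multivariate baseline in the Hotelling $T^2$
family, the package also provides
$D=(\bar y_1-\bar y_0)^\top\hat\Sigma^{-1/2}u/\sqrt p$ with
$u=(1,\dots,1)$, where $\hat\Sigma$ is the pooled within-group
covariance (shrunk when not positive definite) and the inverse square
root is taken by eigendecomposition.  Its permutation test fixes the
whitening direction at the observed covariance — ancillary to the
mean difference under the null — so each permuted statistic is a
linear functional of the shuffled labels, and applies the same normal
moment approximation as the node tests.  Rejection is two-sided on
$|D|$, matching the mean-shift alternative.

## The dysregulation simulator

The harness emulates the benchmark evaluation protocol on synthetic
inputs so the whole study runs offline and in minutes.

**Pathways.**  Random weakly connected signed DAGs: a random spanning
tree oriented by a random topological order plus extra forward edges
up to ~1.5 edges per node (the sparsity of curated signalling maps;
the COVID-19 map's largest component has 54 nodes and 83 edges).
Edge weights are +1/−1/0 with probabilities 0.70/0.25/0.05,
reflecting the predominance of activating interactions in curated
databases.  Node labels are drawn from a shared gene pool holding 8×
the total node slots; this reproduces the sparse coverage regime of a
genome-wide matrix (~50-gene pathways inside ~10⁴ measured genes), in
which the ~100 dysregulated genes leak into a given null pathway with
expectation ~0.6 — the regime in which the benchmark's "at most one
dysregulated gene" rule for true negatives is meaningful.

**Affected genes.**  In each of the $q_1$ dysregulated pathways
(default 10), $s=10$ genes are chosen by one of three topology rules:
the top-$s$ directed betweenness nodes (ties broken by label); $s$
genes sampled from the largest community of the undirected skeleton
(greedy modularity maximisation); or $s$ genes sampled from the
largest order-2 neighbourhood.  Each affected gene carries a sign —
that of its summed outgoing edge weights, defaulting to +1 for sinks
and zero sums — and the deduplicated union $S \le s\,q_1$ is
retained.  Pathways outside $q_1$ containing at most one affected
gene form the true-negative set $q_0$.

**Data.**  Base expression is multivariate normal with zero mean and
unit variance per gene within each group (46 cases, 23 controls by
default, the benchmark split), optionally with a per-pathway block
equicorrelation.  The group-wise normalisation is applied at the
population scale of the generator and replicates are fresh draws from
that model; re-standardising every replicate in-sample would pin each
unaffected gene's group contrast to exactly zero, collapsing all null
p-values to 1 and making the type I error identically zero regardless
of signal — a degenerate variant kept available as
`exact_standardize=True` for diagnostics.  The signal is injected by
adding sign × magnitude (0.5, 0.6 or 0.7 per-gene standard
deviations) to case subjects of each affected gene.

**Metrics.**  Each replicate regenerates the data, reruns the
enrichment, and rejects at `PVAL < 0.05`; type I error and power are
the rejection fractions on $q_0$ and $q_1$ averaged over replicates,
with Monte-Carlo standard errors from the replicate-level spread.
The desk-scale defaults — 20 pathways of 30–60 nodes, 3 topologies ×
3 signals, 50 replicates, 200 permutations — run in about two
minutes on one CPU; the full-scale parameters (100 replicates, 1000
permutations, larger collections) remain available through the same
interfaces.

**What the generator does not emulate.**  Real expression data have
heavy tails, library-size artefacts, batch structure and
co-expression that does not follow pathway boundaries; pathway
overlap in curated collections is clumpier than pool sampling
(hub genes recur across related maps).  Passing the harness
therefore demonstrates the statistical behaviour of the method under
clean mean-shift alternatives, not robustness to those artefacts.
One visible consequence of the scale-down: null pathways that contain
exactly one genuinely dysregulated gene reject at more than the
nominal rate (the leaked gene is real signal), and with 30–60-node
pathways the dilution is weaker than in genome-scale maps, so
per-cell empirical type I error can sit a hair above the
3-standard-error band at the strongest signal while zero-leak null
pathways remain calibrated at 5%.

## Numerical and design choices

- Group coding: $X=1$ cases, 0 controls; $\beta_j>0$ means higher
  expression in cases.  Intercepts are included in every regression;
  data are not assumed centred.
- Rank-deficient node designs (duplicated or collinear parent
  columns) are fatal with a remedy hint rather than silently dropped.
- Permutations re-solve the full node regression (parent coefficients
  included) with the permuted group column; the null standard
  deviation uses one delta degree of freedom.
- Genes present in a graph but absent from the expression matrix are
  dropped with a logged count; pathways left with fewer than two
  genes are skipped with a warning.  Identifier matching is exact
  string equality — no symbol mapping is attempted.
- The `gsa` table is ordered by ascending `PVAL` with ties broken by
  pathway name; `ADJP` uses the number of *input* pathways, including
  any skipped ones.
- Self-loops and parallel edges are rejected at read time (the
  structural equations have no self-term and a duplicated ordered
  pair with two signs is ambiguous).
- Components are weakly connected components; the size filter keeps
  pathways of 30–300 nodes whose largest component covers ≥60% of
  the graph, returning the largest components of the survivors.
- All randomness descends from one seed through NumPy seed sequences
  (`SeedSequence.spawn`); identical seeds give byte-identical output
  files.

## Limitations

- The common-effect model tests mean shifts only; group-dependent
  path coefficients (two-group fits) and non-linear or
  latent-variable structure are out of scope.
- The Brown correction takes the dependence of node p-values to be
  that of the genes' expression correlation; this is the canonical
  instantiation but an approximation, flagged for sensitivity
  analysis with the block-correlated generator.
- Higher-moment (skewness/kurtosis) corrections to the permutation
  null are not implemented; the normal approximation is accurate to
  roughly a 1% Kolmogorov distance at 200 permutations in our null
  checks, improving with the permutation count.
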