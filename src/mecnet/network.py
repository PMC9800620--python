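"""Signed co-occurrence networks from ASV count tables.

The stage mirrors a standard amplicon co-occurrence workflow for communities
sampled from one habitat (e.g. all anode biofilms):

1. **Filter** — keep ASVs present in at least ``min_samples`` samples and
   exceeding a relative abundance of ``min_relabund`` in at least one sample.
2. **Merge** — collapse phylogenetically near-identical ASVs (single-linkage
   clusters of tips whose cophenetic distance is below ``epsilon``) into one
   taxon, summing counts; near-identical 16S variants (differing by a base)
   otherwise split reads of one organism across two columns and induce
   spurious correlations.
3. **Correlate** — Spearman rank correlation on relative abundances, and
   SparCC, which estimates taxon-taxon correlations from compositional data
   via log-ratio variances under a sparsity assumption.
4. **Validate** — an edge is accepted only if BOTH |Spearman rho| and
   |SparCC r| exceed a threshold (default 0.6), both p-values fall below
   alpha (default 0.05), and the two models agree in sign.  The edge weight
   and sign come from SparCC.
5. **Summarise** — node/edge counts, signed-edge percentages, edge density
   2E/(N(N-1)), module count and modularity (greedy modularity maximisation
   on the unsigned graph) and mean local clustering coefficient.

SparCC notes: per resample, taxon fractions are drawn from a
Dirichlet(counts + 1) posterior; the variation matrix
``t_ij = var(log(x_i / x_j))`` is related to the basis (log-abundance)
variances ``w_i`` by ``t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j)``.  Under
sparsity the correlation sum is ignored, giving a linear system for ``w``;
strongly correlated pairs violating the assumption are excluded one at a
time and the system re-solved.  Correlations are the median over resamples.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csgraph, csr_matrix

from .counts import CountTable

__all__ = [
    "filter_asvs",
    "cophenetic_distances",
    "merge_close_asvs",
    "spearman_matrix",
    "sparcc",
    "sparcc_pvalues",
    "build_network",
    "network_properties",
    "NetworkProperties",
    "edge_density",
    "sign_percentages",
    "run_network_stage",
]

#: Default merge radius in branch-length units: roughly one substitution over
#: the 253-bp 16S V4 amplicon (~0.004 expected substitutions per site).
DEFAULT_MERGE_EPSILON = 0.004


# ---------------------------------------------------------------------------
# filtering and phylogenetic merging
# ---------------------------------------------------------------------------

def filter_asvs(
    table: CountTable,
    min_samples: int = 2,
    min_relabund: float = 0.001,
) -> CountTable:
    """Prevalence/abundance filter.

    An ASV is retained iff it is non-zero in at least ``min_samples`` samples
    AND its per-sample relative abundance exceeds ``min_relabund`` in at
    least one sample.  The sample set is unchanged.
    """
    if table.n_asvs == 0:
        raise ValueError("empty table")
    present = (table.counts > 0).sum(axis=0) >= min_samples
    abundant = (table.relative_abundances() > min_relabund).any(axis=0)
    keep = table.counts.columns[present & abundant]
    if len(keep) == 0:
        warnings.warn("all ASVs removed by filtering", stacklevel=2)
    meta = None if table.sample_meta is None else table.sample_meta.copy()
    return CountTable(table.counts[keep].copy(), meta)


def cophenetic_distances(tree: str, asv_ids: list[str] | None = None) -> pd.DataFrame:
    """Tip-to-tip path lengths (summed branch lengths) of a Newick tree.

    If ``asv_ids`` is given, every id must be a tip of the tree (extra tips
    are allowed and dropped); unmatched ids are reported.
    """
    t = dendropy.Tree.get(file=io.StringIO(tree), schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = list(t.taxon_namespace)
    labels = [tax.label for tax in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    out = pd.DataFrame(mat, index=labels, columns=labels)
    if asv_ids is not None:
        missing = [a for a in asv_ids if a not in out.index]
        if missing:
            raise ValueError(f"tree is missing tips for ASVs: {missing}")
        out = out.loc[asv_ids, asv_ids]
    return out


def merge_close_asvs(
    table: CountTable,
    dist: pd.DataFrame,
    epsilon: float = DEFAULT_MERGE_EPSILON,
) -> tuple[CountTable, dict[str, list[str]]]:
    """Merge single-linkage clusters of ASVs at cophenetic distance <= epsilon.

    Counts are summed per sample within each cluster and the merged column is
    labelled by the most abundant member (total reads).  Per-sample read
    totals are invariant.  Returns the merged table and a map
    ``{representative: [members...]}`` for clusters of size > 1.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    ids = table.asv_ids
    missing = [a for a in ids if a not in dist.index]
    if missing:
        raise ValueError(f"distance matrix is missing ASVs: {missing}")
    d = dist.loc[ids, ids].to_numpy()
    adjacency = csr_matrix((d <= epsilon) & (epsilon > 0))
    n_comp, labels = csgraph.connected_components(adjacency, directed=False)

    totals = table.counts.sum(axis=0).to_numpy()
    merged_cols: dict[int, pd.Series] = {}
    merge_map: dict[str, list[str]] = {}
    order: list[tuple[int, int]] = []  # (first original index, component)
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        rep = members[np.argmax(totals[members])]
        rep_id = ids[rep]
        merged_cols[comp] = table.counts.iloc[:, members].sum(axis=1).rename(rep_id)
        if len(members) > 1:
            merge_map[rep_id] = [ids[k] for k in members]
        order.append((members.min(), comp))
    order.sort()
    merged = pd.concat([merged_cols[comp] for _, comp in order], axis=1)
    meta = None if table.sample_meta is None else table.sample_meta.copy()
    return CountTable(merged, meta), merge_map


# ---------------------------------------------------------------------------
# correlation models
# ---------------------------------------------------------------------------

def spearman_matrix(table: CountTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (average ranks for ties) and two-sided p-values.

    Computed on relative abundances.  Constant columns yield NaN entries and
    a warning naming the offending ASVs.
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for meaningful p-values")
    rel = table.relative_abundances()
    constant = rel.columns[(rel.nunique(axis=0) <= 1)].tolist()
    if constant:
        warnings.warn(f"constant ASV columns, correlation undefined: {constant}",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(rel.to_numpy(), axis=0)
    if table.n_asvs == 2:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    ids = table.asv_ids
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def _sparcc_basis(
    t_mat: np.ndarray,
    exclusion_threshold: float,
    max_exclusion_iters: int,
) -> np.ndarray:
    """Solve one SparCC iteration chain on a variation matrix; return rho."""
    d = t_mat.shape[0]
    include = np.ones((d, d), dtype=bool)
    np.fill_diagonal(include, False)

    def solve() -> tuple[np.ndarray, np.ndarray]:
        deg = include.sum(axis=1).astype(float)
        lhs = np.diag(deg) + include.astype(float)
        rhs = (t_mat * include).sum(axis=1)
        w = np.linalg.solve(lhs, rhs)
        w = np.maximum(w, 1e-12)
        sw = np.sqrt(w)
        rho = (w[:, None] + w[None, :] - t_mat) / (2.0 * np.outer(sw, sw))
        np.fill_diagonal(rho, 1.0)
        return w, np.clip(rho, -1.0, 1.0)

    _, rho = solve()
    for _ in range(max_exclusion_iters):
        cand = np.abs(rho) * include
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        # keep the system solvable: never strip a taxon below 3 partners
        if include[i].sum() <= 3 or include[j].sum() <= 3:
            break
        include[i, j] = include[j, i] = False
        _, rho = solve()
    return rho


def sparcc(
    table: CountTable,
    n_resamples: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusion_iters: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """SparCC correlation matrix of a count table.

    Per resample, taxon fractions are drawn from Dirichlet(counts + 1) per
    sample; log-ratio variances give the variation matrix; basis variances
    are solved under the sparsity approximation with iterative exclusion of
    the strongest pairs above ``exclusion_threshold``.  The returned matrix
    is the elementwise median over resamples (symmetric, unit diagonal,
    entries in [-1, 1]).
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if table.n_asvs < 4:
        raise ValueError("need at least 4 ASVs: basis system underdetermined")
    counts = table.counts.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rhos = []
    for _ in range(n_resamples):
        gam = rng.gamma(counts + 1.0)
        frac = gam / gam.sum(axis=1, keepdims=True)
        y = np.log(frac)
        cov = np.cov(y, rowvar=False)
        var = np.diag(cov)
        t_mat = var[:, None] + var[None, :] - 2.0 * cov
        rhos.append(_sparcc_basis(t_mat, exclusion_threshold, max_exclusion_iters))
    med = np.median(np.stack(rhos), axis=0)
    med = (med + med.T) / 2.0
    np.fill_diagonal(med, 1.0)
    ids = table.asv_ids
    return pd.DataFrame(np.clip(med, -1.0, 1.0), index=ids, columns=ids)


def sparcc_pvalues(
    table: CountTable,
    observed_r: pd.DataFrame,
    n_bootstraps: int = 99,
    seed: int | None = None,
    **sparcc_kwargs,
) -> pd.DataFrame:
    """Two-sided permutation p-values for SparCC correlations.

    Each null dataset permutes every ASV column independently (destroying
    taxon-taxon association while preserving marginals); SparCC is recomputed
    and ``p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_bootstraps)`` per pair.
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    n, d = counts.shape
    obs = np.abs(observed_r.to_numpy())
    exceed = np.zeros((d, d))
    for _ in range(n_bootstraps):
        null_counts = np.column_stack(
            [counts[rng.permutation(n), k] for k in range(d)]
        )
        null_table = CountTable(
            pd.DataFrame(null_counts, index=table.sample_ids, columns=table.asv_ids)
        )
        r_null = sparcc(
            null_table, seed=int(rng.integers(2**31)), **sparcc_kwargs
        ).to_numpy()
        exceed += np.abs(r_null) >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_bootstraps)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=table.asv_ids, columns=table.asv_ids)


# ---------------------------------------------------------------------------
# network construction and properties
# ---------------------------------------------------------------------------

def build_network(
    spearman_rho: pd.DataFrame,
    spearman_p: pd.DataFrame,
    sparcc_r: pd.DataFrame,
    sparcc_p: pd.DataFrame,
    threshold: float = 0.6,
    alpha: float = 0.05,
) -> nx.Graph:
    """Dual-criterion signed network.

    An undirected edge (i, j) is valid iff |rho| > threshold, |sparcc_r| >
    threshold, both p-values < alpha, and the two coefficients agree in sign.
    Edge weight and sign come from SparCC.  Nodes without any valid edge are
    dropped.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    ids = list(spearman_rho.index)
    g = nx.Graph()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            rho = spearman_rho.loc[i, j]
            r = sparcc_r.loc[i, j]
            if np.isnan(rho) or np.isnan(r):
                continue
            if abs(rho) <= threshold or abs(r) <= threshold:
                continue
            if spearman_p.loc[i, j] >= alpha or sparcc_p.loc[i, j] >= alpha:
                continue
            if np.sign(rho) != np.sign(r) or r == 0:
                continue
            g.add_edge(
                i, j,
                weight=float(r),
                sign=int(np.sign(r)),
                sparcc_r=float(r),
                spearman_rho=float(rho),
                p_sparcc=float(sparcc_p.loc[i, j]),
                p_spearman=float(spearman_p.loc[i, j]),
            )
    return g


@dataclass
class NetworkProperties:
    """Summary statistics of a signed co-occurrence network."""

    n_nodes: int
    n_edges: int
    positive_edges: int
    negative_edges: int
    positive_pct: float
    negative_pct: float
    edge_density: float
    n_modules: int
    modularity: float
    clustering: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def edge_density(n_nodes: int, n_edges: int) -> float:
    """Realised fraction of possible undirected edges, 2E / (N (N-1))."""
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def sign_percentages(n_positive: int, n_negative: int) -> tuple[float, float]:
    """Percentage of positive and negative edges (sums to exactly 100)."""
    total = n_positive + n_negative
    if total == 0:
        return 0.0, 0.0
    pos = 100.0 * n_positive / total
    return pos, 100.0 - pos


def network_properties(
    g: nx.Graph,
    modularity_method: str = "greedy",
    clustering_method: str = "average",
    seed: int | None = None,
) -> NetworkProperties:
    """Node/edge counts, sign split, density, modules, modularity, clustering.

    Community detection and clustering run on the unsigned graph.
    ``modularity_method``: "greedy" (Clauset-Newman-Moore) or "louvain";
    ``clustering_method``: "average" (mean local coefficient) or
    "transitivity".
    """
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        warnings.warn("empty network: all properties zero", stacklevel=2)
        return NetworkProperties(0, 0, 0, 0, 0.0, 0.0, 0.0, 0, 0.0, 0.0)
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    pos = sum(1 for s in signs if s > 0)
    neg = e - pos
    pos_pct, neg_pct = sign_percentages(pos, neg)

    unsigned = nx.Graph()
    unsigned.add_nodes_from(g.nodes)
    unsigned.add_edges_from(g.edges)
    if e == 0:
        communities = [{v} for v in unsigned.nodes]
    elif modularity_method == "greedy":
        communities = list(nx.community.greedy_modularity_communities(unsigned))
    elif modularity_method == "louvain":
        communities = list(nx.community.louvain_communities(unsigned, seed=seed))
    else:
        raise ValueError(f"unknown modularity_method {modularity_method!r}")
    q = nx.community.modularity(unsigned, communities) if e else 0.0
    if clustering_method == "average":
        clust = nx.average_clustering(unsigned)
    elif clustering_method == "transitivity":
        clust = nx.transitivity(unsigned)
    else:
        raise ValueError(f"unknown clustering_method {clustering_method!r}")

    return NetworkProperties(
        n_nodes=n,
        n_edges=e,
        positive_edges=pos,
        negative_edges=neg,
        positive_pct=pos_pct,
        negative_pct=neg_pct,
        edge_density=edge_density(n, e),
        n_modules=len(communities),
        modularity=float(q),
        clustering=float(clust),
    )


# ---------------------------------------------------------------------------
# end-to-end stage
# ---------------------------------------------------------------------------

def run_network_stage(
    table: CountTable,
    tree: str | None = None,
    min_samples: int = 2,
    min_relabund: float = 0.001,
    epsilon: float = DEFAULT_MERGE_EPSILON,
    threshold: float = 0.6,
    alpha: float = 0.05,
    n_resamples: int = 20,
    n_bootstraps: int = 99,
    seed: int | None = None,
) -> dict:
    """Filter, merge, correlate, validate and summarise in one call.

    Returns a dict with the filtered/merged table, the merge map, both
    correlation matrices and their p-values, the signed graph and its
    :class:`NetworkProperties`.
    """
    filtered = filter_asvs(table, min_samples=min_samples, min_relabund=min_relabund)
    merge_map: dict[str, list[str]] = {}
    if tree is not None and epsilon > 0 and filtered.n_asvs > 1:
        dist = cophenetic_distances(tree, asv_ids=filtered.asv_ids)
        filtered, merge_map = merge_close_asvs(filtered, dist, epsilon)
    rng = np.random.default_rng(seed)
    rho, rho_p = spearman_matrix(filtered)
    r = sparcc(filtered, n_resamples=n_resamples, seed=int(rng.integers(2**31)))
    r_p = sparcc_pvalues(
        filtered, r, n_bootstraps=n_bootstraps, seed=int(rng.integers(2**31)),
        n_resamples=n_resamples,
    )
    graph = build_network(rho, rho_p, r, r_p, threshold=threshold, alpha=alpha)
    props = network_properties(graph)
    return {
        "table": filtered,
        "merge_map": merge_map,
        "spearman_rho": rho,
        "spearman_p": rho_p,
        "sparcc_r": r,
        "sparcc_p": r_p,
        "graph": graph,
        "properties": props,
    }
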