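"""Hill-number diversity, pairwise dissimilarity, the Raup-Crick null model
and the Mantel test.

Alpha diversity is reported as Hill numbers: for a relative-abundance vector
``p`` and diversity order ``q``,

    D_q = (sum_i p_i^q)^(1/(1-q))          for q != 1
    D_1 = exp(-sum_i p_i ln p_i)           (the q -> 1 limit)

D_0 is richness; D_1 weighs taxa by abundance and can be read as the number
of "common" taxa.  Pairwise beta diversity uses the multiplicative
decomposition with equal sample weights: gamma is the Hill number of the
pooled (mean) composition, alpha the Hill mean across the two samples, and
``beta = gamma / alpha`` lies in [1, 2]; the local dissimilarity is
``d = (beta - 1) / (N - 1)`` with N = 2, so d = 0 for identical compositions
and d = 1 for disjoint ones.

The Raup-Crick null model asks whether an observed pairwise dissimilarity is
smaller or larger than expected by chance: each community is reassembled many
times preserving its observed richness and read depth, drawing taxa with
probability proportional to their occupancy frequency across the
metacommunity (and, for abundance-weighted orders, distributing reads
proportional to metacommunity mean relative abundances).  The percentile of
the observed dissimilarity within the null ensemble (ties at half weight) is
qRC; qRC < 0.05 flags pairs significantly more similar than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountTable

__all__ = [
    "hill_number",
    "alpha_diversity",
    "pairwise_dissimilarity",
    "dissimilarity_matrix",
    "raup_crick",
    "RaupCrickResult",
    "mantel",
]


def hill_number(proportions, q: float) -> float:
    """Hill diversity of order *q* of a relative-abundance vector.

    Zero-abundance entries are excluded; proportions must be non-negative and
    sum to 1 (within 1e-6; they are renormalised internally).
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("proportions must have positive sum")
    if abs(total - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    p = p[p > 0] / total
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def alpha_diversity(table: CountTable, q: float) -> pd.Series:
    """Per-sample Hill number of order *q*."""
    rel = table.relative_abundances()
    return pd.Series(
        [hill_number(rel.loc[s].to_numpy(), q) for s in rel.index],
        index=rel.index,
        name=f"hill_q{q:g}",
    )


def _pair_beta(p1: np.ndarray, p2: np.ndarray, q: float) -> float:
    """Multiplicative beta (gamma/alpha) for two relative-abundance vectors."""
    pooled = 0.5 * (p1 + p2)
    stacked = 0.5 * np.concatenate([p1, p2])  # weights w_j = 1/2
    pooled = pooled[pooled > 0]
    stacked = stacked[stacked > 0]
    if abs(q - 1.0) < 1e-12:
        gamma = np.exp(-np.sum(pooled * np.log(pooled)))
        alpha = np.exp(-np.sum(stacked * np.log(stacked))) / 2.0
    else:
        gamma = np.sum(pooled**q) ** (1.0 / (1.0 - q))
        alpha = np.sum(stacked**q) ** (1.0 / (1.0 - q)) / 2.0
    return float(gamma / alpha)


def pairwise_dissimilarity(counts1, counts2, q: float) -> float:
    """Local dissimilarity (beta - 1)/(N - 1), N = 2, of two count vectors."""
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if c1.sum() <= 0 or c2.sum() <= 0:
        raise ValueError("empty sample: dissimilarity undefined")
    p1 = c1 / c1.sum()
    p2 = c2 / c2.sum()
    d = _pair_beta(p1, p2, q) - 1.0
    return float(min(max(d, 0.0), 1.0))


def dissimilarity_matrix(table: CountTable, q: float) -> pd.DataFrame:
    """Symmetric pairwise dissimilarity matrix at order *q* (zero diagonal)."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    counts = table.counts.to_numpy(dtype=float)
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pairwise_dissimilarity(counts[i], counts[j], q)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class RaupCrickResult:
    """Pairwise qRC percentile matrix for one diversity order."""

    qrc: pd.DataFrame
    observed: pd.DataFrame
    order: float
    iterations: int


def _null_assemble(
    rng: np.random.Generator,
    richness: int,
    depth: int,
    selection_weights: np.ndarray,
    abundance_weights: np.ndarray,
) -> np.ndarray:
    """Assemble one null community: fixed richness and depth.

    Taxa are drawn without replacement with probability proportional to
    ``selection_weights``; each selected taxon gets one read and the
    remaining reads are multinomial with probabilities proportional to
    ``abundance_weights`` over the selected taxa.
    """
    n_taxa = selection_weights.size
    chosen = rng.choice(n_taxa, size=richness, replace=False,
                        p=selection_weights / selection_weights.sum())
    counts = np.zeros(n_taxa, dtype=np.int64)
    counts[chosen] = 1
    remaining = depth - richness
    if remaining > 0:
        w = abundance_weights[chosen]
        w = w / w.sum()
        counts[chosen] += rng.multinomial(remaining, w)
    return counts


def raup_crick(
    table: CountTable,
    q: float = 0.0,
    iterations: int = 999,
    seed: int | None = None,
    selection_weights: np.ndarray | None = None,
    abundance_weights: np.ndarray | None = None,
) -> RaupCrickResult:
    """Raup-Crick null-model percentiles for all sample pairs.

    For every pair the observed dissimilarity at order *q* is ranked within
    ``iterations`` dissimilarities of null communities that preserve each
    sample's richness and read depth.  By default selection weights are taxon
    occupancy frequencies across the table and abundance weights are
    metacommunity mean relative abundances; both can be supplied explicitly
    (e.g. when the metacommunity is known or larger than the table).

    qRC = (#{null < obs} + 0.5 * #{null == obs}) / iterations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    counts = table.counts.to_numpy(dtype=np.int64)
    n, n_taxa = counts.shape
    if selection_weights is None:
        selection_weights = (counts > 0).mean(axis=0)
    selection_weights = np.asarray(selection_weights, dtype=float)
    if abundance_weights is None:
        rel = counts / counts.sum(axis=1, keepdims=True)
        abundance_weights = rel.mean(axis=0)
    abundance_weights = np.asarray(abundance_weights, dtype=float)
    # taxa never selectable would make richness unsatisfiable; give them a floor
    floor = max(selection_weights[selection_weights > 0].min() * 1e-6, 1e-12)
    selection_weights = np.maximum(selection_weights, floor)
    abundance_weights = np.maximum(abundance_weights, floor)

    rng = np.random.default_rng(seed)
    richness = (counts > 0).sum(axis=1)
    depth = counts.sum(axis=1)
    # one shared ensemble of null realisations per sample, reused across pairs
    nulls = [
        [
            _null_assemble(rng, int(richness[i]), int(depth[i]),
                           selection_weights, abundance_weights)
            for _ in range(iterations)
        ]
        for i in range(n)
    ]

    obs = np.zeros((n, n))
    qrc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d_obs = pairwise_dissimilarity(counts[i], counts[j], q)
            d_null = np.array([
                pairwise_dissimilarity(nulls[i][k], nulls[j][k], q)
                for k in range(iterations)
            ])
            ties = np.isclose(d_null, d_obs, rtol=0, atol=1e-12)
            below = (d_null < d_obs) & ~ties
            score = (below.sum() + 0.5 * ties.sum()) / iterations
            obs[i, j] = obs[j, i] = d_obs
            qrc[i, j] = qrc[j, i] = score
    ids = table.sample_ids
    return RaupCrickResult(
        qrc=pd.DataFrame(qrc, index=ids, columns=ids),
        observed=pd.DataFrame(obs, index=ids, columns=ids),
        order=q,
        iterations=iterations,
    )


def mantel(
    d1,
    d2,
    permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test between two distance matrices.

    The statistic is the Pearson correlation of the off-diagonal upper
    triangles; significance comes from jointly permuting rows and columns of
    the second matrix.  Two-sided p with the add-one rule:
    ``p = (1 + #{|r_perm| >= |r_obs|}) / (1 + permutations)``.
    """
    m1 = np.asarray(d1, dtype=float)
    m2 = np.asarray(d2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("distance matrices must be square and of equal shape")
    for m in (m1, m2):
        if not np.allclose(m, m.T):
            raise ValueError("distance matrices must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrices must have zero diagonal")
    if permutations < 0:
        raise ValueError("permutations must be >= 0")
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(m1[iu], m2[iu])
    if permutations == 0:
        return r_obs, float("nan")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_perm = corr(m1[iu], m2[np.ix_(perm, perm)][iu])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return r_obs, p
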