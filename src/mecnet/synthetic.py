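"""Synthetic study data: batch-cycle current traces, compositional count
tables with planted associations, and random phylogenies.

The generators emulate the structure of a single-chamber MEC experiment fed
batchwise every 2-3 days:

* **Current traces** — zero current during a lag phase while electrogens
  colonise the anode, then sawtooth batch cycles (sharp rise on feeding,
  decay as electron donors deplete) under an envelope that rises
  logistically to a plateau density near a peak day and then declines
  linearly.  The trace is a caricature of the qualitative shape of real MEC
  startup data, not a mechanistic biofilm model.

* **Count tables** — a logistic-normal/multinomial model: per-sample log
  abundances are drawn from a multivariate normal with a *planted*
  covariance (so taxon-taxon associations of known sign and strength can be
  embedded), softmax-transformed to proportions, and sampled as multinomial
  reads.  This keeps the compositional structure that SparCC assumes.

* **Trees** — random bifurcating phylogenies with positive branch lengths;
  designated pairs of tips can be placed as cherries at a prescribed tiny
  cophenetic distance to mimic near-identical ASVs (e.g. sequences differing
  by a single base).

One seed drives independent per-stage substreams, so adding a stage does not
perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTable
from .electrochem import SECONDS_PER_DAY, CurrentTrace


@dataclass
class TraceParams:
    """Parameters of the synthetic current trace.

    Defaults follow the study conditions: 30-s sampling over a ~100-day run,
    70-ml reactor, lag of ~10 days (observed range 5-17 d), feeding every
    2-3 days, peak current density of a few A/m2 near day 30 followed by a
    modest decline.  The anode area defaults to 10 cm2 of projected carbon
    cloth.
    """

    duration_days: float = 104.0
    sample_interval: float = 30.0
    lag_days: float = 10.0
    feed_interval_days: float = 2.5
    peak_day: float = 30.0
    plateau_density: float = 3.0
    decline_fraction: float = 0.25
    noise_sd: float = 0.02
    electrode_area: float = 1e-3
    volume: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not 0 <= self.decline_fraction <= 1:
            raise ValueError("decline_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.feed_interval_days <= 0:
            raise ValueError("feed_interval_days must be positive")


def current_density_profile(params: TraceParams, t_seconds: np.ndarray) -> np.ndarray:
    """Noise-free current density (A/m2) of the synthetic trace at *t_seconds*.

    Exposed separately so that tests can evaluate the same deterministic
    signal on arbitrarily fine grids (e.g. as a high-resolution integration
    reference).
    """
    t_d = np.asarray(t_seconds, dtype=float) / SECONDS_PER_DAY
    out = np.zeros_like(t_d)
    active = t_d >= params.lag_days
    if not active.any():
        return out

    td = t_d[active]
    # batch cycle: step to 80% on feeding, brief rise to 100%, exponential
    # decay once the electron donors are depleted at 70% of the cycle
    u = np.mod(td - params.lag_days, params.feed_interval_days) / params.feed_interval_days
    cycle = (1.0 - 0.2 * np.exp(-u / 0.02)) * np.exp(-np.maximum(0.0, u - 0.7) / 0.08)

    # envelope: logistic rise from half the plateau at lag to the plateau at
    # the peak day, then linear decline by decline_fraction at run end
    if params.peak_day > params.lag_days:
        mid = 0.5 * (params.lag_days + params.peak_day)
        tau = (params.peak_day - params.lag_days) / 6.0
        rise = 1.0 / (1.0 + np.exp(-(td - mid) / tau))
    else:
        rise = np.ones_like(td)
    envelope = params.plateau_density * (0.5 + 0.5 * rise)
    if params.duration_days > params.peak_day:
        frac = np.clip(
            (td - params.peak_day) / (params.duration_days - params.peak_day), 0.0, 1.0
        )
        envelope = envelope * (1.0 - params.decline_fraction * frac)

    out[active] = envelope * cycle
    return out


def simulate_current_trace(params: TraceParams) -> CurrentTrace:
    """Simulate a batchwise MEC current trace.

    Returns a :class:`CurrentTrace` in amperes with Gaussian measurement
    noise of standard deviation ``noise_sd`` (A/m2) added to the density
    profile.  Reproducible under a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration_days * SECONDS_PER_DAY, params.sample_interval)
    density = current_density_profile(params, t)
    if params.noise_sd > 0:
        density = density + rng.normal(0.0, params.noise_sd, size=t.size)
    current = density * params.electrode_area
    return CurrentTrace(t, current, params.electrode_area, params.volume)


@dataclass
class CommunityParams:
    """Parameters of the logistic-normal/multinomial community generator.

    ``planted_covariance`` is the covariance of per-sample log abundances
    (symmetric PSD, ``n_asvs`` x ``n_asvs``); associations are planted as
    off-diagonal entries.  ``base_log_abundance`` sets mean log abundances
    (default: a geometric ladder giving a few dominant and many rare taxa).
    ``near_identical_pairs`` lists ASV index pairs to be placed on the tree
    as cherries separated by ``near_identical_distance`` branch-length units.
    """

    n_samples: int = 60
    n_asvs: int = 30
    library_size: int = 20_000
    base_log_abundance: np.ndarray | None = None
    planted_covariance: np.ndarray | None = None
    habitat_labels: list[str] | None = None
    near_identical_pairs: list[tuple[int, int]] = field(default_factory=list)
    near_identical_distance: float = 0.002
    habitat_effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_asvs < 2:
            raise ValueError("need n_samples >= 1 and n_asvs >= 2")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.base_log_abundance is None:
            # dominant-to-rare ladder spanning ~4 natural-log units
            self.base_log_abundance = np.linspace(4.0, 0.0, self.n_asvs)
        self.base_log_abundance = np.asarray(self.base_log_abundance, dtype=float)
        if self.base_log_abundance.shape != (self.n_asvs,):
            raise ValueError("base_log_abundance must have length n_asvs")
        if self.planted_covariance is None:
            self.planted_covariance = np.eye(self.n_asvs)
        self.planted_covariance = np.asarray(self.planted_covariance, dtype=float)
        if self.planted_covariance.shape != (self.n_asvs, self.n_asvs):
            raise ValueError("planted_covariance must be n_asvs x n_asvs")
        if not np.allclose(self.planted_covariance, self.planted_covariance.T):
            raise ValueError("planted_covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.planted_covariance)
        if eigvals.min() < -1e-8:
            raise ValueError("planted_covariance must be positive semi-definite")
        if self.habitat_labels is not None and len(self.habitat_labels) != self.n_samples:
            raise ValueError("habitat_labels must have length n_samples")


def planted_covariance(
    n_asvs: int,
    planted_pairs: list[tuple[int, int, float]],
    variance: float = 1.0,
) -> np.ndarray:
    """Covariance with unit-scale log variances and planted pairwise correlations.

    ``planted_pairs`` is a list of ``(i, j, rho)``; pairs must be disjoint so
    the matrix stays positive semi-definite for any ``|rho| <= 1``.
    """
    used: set[int] = set()
    cov = np.eye(n_asvs) * variance
    for i, j, rho in planted_pairs:
        if i == j:
            raise ValueError("planted pair must involve two distinct ASVs")
        if {i, j} & used:
            raise ValueError("planted pairs must be disjoint")
        used |= {i, j}
        cov[i, j] = cov[j, i] = rho * variance
    return cov


def simulate_count_tables(params: CommunityParams) -> tuple[CountTable, str]:
    """Simulate a compositional count table and a matching Newick tree.

    Per sample: log abundances ~ N(base, planted_covariance) (plus a habitat
    offset boosting a habitat-specific block of taxa when ``habitat_labels``
    are given), softmax to proportions, then multinomial reads summing to
    ``library_size``.  The returned tree has one tip per ASV;
    ``near_identical_pairs`` sit at cophenetic distance
    ``near_identical_distance`` while all other tip pairs are far apart.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    asv_ids = [f"ASV{i + 1}" for i in range(params.n_asvs)]
    sample_ids = [f"S{i + 1}" for i in range(params.n_samples)]

    mean = np.tile(params.base_log_abundance, (params.n_samples, 1))
    if params.habitat_labels is not None:
        habitats = sorted(set(params.habitat_labels))
        block = max(1, params.n_asvs // (2 * len(habitats)))
        for h_idx, h in enumerate(habitats):
            rows = [k for k, lab in enumerate(params.habitat_labels) if lab == h]
            cols = slice(h_idx * block, (h_idx + 1) * block)
            mean[np.ix_(rows, range(*cols.indices(params.n_asvs)))] += params.habitat_effect

    z = rng.multivariate_normal(
        np.zeros(params.n_asvs), params.planted_covariance,
        size=params.n_samples, method="eigh",
    )
    logits = mean + z
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(params.library_size, p[k]) for k in range(params.n_samples)])

    meta = None
    if params.habitat_labels is not None:
        meta = pd.DataFrame({"location": params.habitat_labels}, index=sample_ids)
    table = CountTable(pd.DataFrame(counts, index=sample_ids, columns=asv_ids), meta)

    tree = simulate_tree(
        params.n_asvs,
        seed=int(np.random.SeedSequence(params.seed).spawn(2)[1].generate_state(1)[0] % (2**31)),
        tip_labels=asv_ids,
        near_identical_pairs=params.near_identical_pairs,
        near_identical_distance=params.near_identical_distance,
    )
    return table, tree


def simulate_tree(
    n_taxa: int,
    seed: int = 0,
    tip_labels: list[str] | None = None,
    near_identical_pairs: list[tuple[int, int]] | None = None,
    near_identical_distance: float = 0.002,
    min_branch: float = 0.01,
    mean_branch: float = 0.05,
) -> str:
    """Random bifurcating tree as a Newick string.

    Built by random sequential joining with branch lengths drawn as
    ``min_branch + Exp(mean_branch)``, so every tip pair not listed in
    ``near_identical_pairs`` is at cophenetic distance >= 2*min_branch.
    Listed pairs are joined first as cherries with total tip-to-tip distance
    ``near_identical_distance``.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    if tip_labels is None:
        tip_labels = [f"ASV{i + 1}" for i in range(n_taxa)]
    if len(tip_labels) != n_taxa:
        raise ValueError("tip_labels must have length n_taxa")
    near_identical_pairs = near_identical_pairs or []

    def blen() -> float:
        return float(min_branch + rng.exponential(mean_branch))

    clusters = [str(lab) for lab in tip_labels]
    merged: set[int] = set()
    # cherries for near-identical tips first
    for i, j in near_identical_pairs:
        if i in merged or j in merged:
            raise ValueError("near_identical_pairs must be disjoint")
        half = near_identical_distance / 2.0
        clusters[i] = f"({clusters[i]}:{half:.8g},{clusters[j]}:{half:.8g})"
        clusters[j] = ""
        merged |= {i, j}
    clusters = [c for c in clusters if c]

    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        node = f"({a}:{blen():.8g},{b}:{blen():.8g})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(node)
    return clusters[0] + ";"
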