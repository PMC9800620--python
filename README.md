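# mecnet

Analysis pipeline for microbial electrolysis cell (MEC) experiments that
track both reactor performance and microbial community assembly.  In a
single-chamber MEC, electrogenic bacteria on the anode oxidise organic
substrates (acetate, propionate, butyrate) and transfer the liberated
electrons to the electrode, driving hydrogen evolution at the cathode.  Who
colonises the anode, the cathode and the bulk liquid — and which taxa
co-occur or exclude one another — shapes how much of the consumed substrate
ends up as current.

`mecnet` covers the computational chain such a study needs, from the raw
potentiostat signal to a signed co-occurrence network:

* **Electrochemistry** — 5-min rebinning of 30-s current readings, peak
  current, lag time before substantial current production (> 1 A/m²), total
  charge `Q = ∫ I(t) dt`, and coulombic efficiency

  `CE = ∫ I dt / (F · V · Σ_s b_s ΔC_s)`

  with `F = 96 485.3` C/mol e⁻, liquid volume `V` (L), consumed substrate
  concentrations `ΔC_s` (mol/L) and electrons per mol `b_s` (8 for acetate,
  14 for propionate, 20 for butyrate, from the balanced half-reactions).

* **Diversity** — Hill numbers `D_q = (Σ p_i^q)^{1/(1−q)}` for any order
  `q ≥ 0`, pairwise dissimilarity `(β − 1)/(N − 1)` from the multiplicative
  gamma/alpha decomposition, the Raup–Crick null model (richness- and
  depth-preserving reassembly; qRC < 0.05 flags pairs significantly more
  similar than chance) and the Mantel test.

* **Networks** — prevalence/abundance filtering of ASVs (≥ 2 samples,
  > 0.1 % in at least one), merging of phylogenetically near-identical ASVs
  by cophenetic distance, Spearman and SparCC correlations, dual-criterion
  edge validation (|ρ| and |r| > 0.6, both p < 0.05, concordant sign) and
  summary statistics: signed edge counts, edge density `2E/(N(N−1))`,
  modules, modularity and clustering.

* **Synthetic data** — batch-cycle current traces with a lag phase and a
  logistic-normal/multinomial community generator with *planted*
  associations and near-identical ASV pairs, so the full chain is testable
  without sequencing data.

## Worked example

```python
import mecnet as m

# a 60-day run: 10-day lag, batch feeding every 2.5 days, peak near day 30
params = m.TraceParams(duration_days=60, lag_days=10, peak_day=30, seed=1)
trace = m.simulate_current_trace(params)
print(m.lag_time(trace))                                   # 10.0  (days)
print(m.peak_current(trace) / params.electrode_area)       # 2.944 (A/m2)
print(m.total_charge(trace))                               # 8249.4 (C)

deltas = [m.SubstrateDelta("acetate", 6.1e-3),             # mol/L consumed
          m.SubstrateDelta("propionate", 3.47e-3),
          m.SubstrateDelta("butyrate", 2.42e-3)]
window = m.TimeWindow(30 * 86400, 32.5 * 86400)            # one batch cycle
print(m.coulombic_efficiency(trace, window, deltas))       # 0.496

# a 60-sample community with two planted associations
cov = m.planted_covariance(30, [(0, 1, 0.8), (2, 3, -0.8)])
table, tree = m.simulate_count_tables(
    m.CommunityParams(n_samples=60, planted_covariance=cov, seed=2))
result = m.run_network_stage(table, tree, seed=3)
print([(u, v, d["sign"]) for u, v, d in result["graph"].edges(data=True)])
# [('ASV1', 'ASV2', 1), ('ASV3', 'ASV4', -1)]
```

The trace metrics say: current stayed near zero for 10 days (the lag while
electrogens colonise the anode), peaked at ~2.9 A/m², and 49.6 % of the
electrons in the substrate consumed over the day 30–32.5 cycle were
recovered as charge.  The network stage recovers exactly the two planted
associations with their correct signs and no spurious edges.

A CLI wraps the same stages:

```sh
mecnet all --seed 7 --out demo_run      # simulate + every analysis stage
mecnet network --counts counts.tsv --tree tree.nwk --out net_out
```

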