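# pollennet

Plant–pollinator network specialization and stigma pollen-load analysis
for generalized pollination communities.

When co-flowering plants share pollinators, stigmas receive heterospecific
pollen (HP) alongside conspecific pollen (CP). Species can evolve **HP
avoidance** (floral or behavioural mechanisms that keep HP off stigmas) or
**HP tolerance** (accepting large HP loads while buffering their cost),
and the two strategies leave different statistical fingerprints in the
relationship between per-stigma CP and HP loads: independence (avoidance)
versus a significant linear or exponential coupling (tolerance).
`pollennet` implements the full analysis for asking which strategy
prevails in a community — originally motivated by stigma surveys of the
Yongxing Island oceanic-island community (29 plant species, 45 flower
visitors) — for ecologists working with interaction edge lists and stigma
pollen counts.

## What it computes

* **Network metrics** (`pollennet.network`) — on the bipartite plant ×
  pollinator matrix: network-level specialization
  `H2′ = (H2_max − H2_obs)/(H2_max − H2_min)` (two-dimensional Shannon
  entropy, standardized between its marginal-constrained extremes; the
  integer minimum is found by branch-and-bound and verified against
  exhaustive enumeration), species-level specialization
  `d′ = (d − d_min)/(d_max − d_min)` with
  `d_i = Σ_j p′_ij ln(p′_ij/q_j)`, species strength `Σ_j a_ij/A_j`,
  closeness centrality, and Chao1 sampling completeness.
* **Pollen summaries** (`pollennet.summaries`) — per-species and
  community means, SEs and CVs of CP/HP load and HP donor diversity,
  pooled HP proportion `100·ΣHP/(ΣCP+ΣHP)`, empty-stigma exclusion, and
  flower areas from shape formulas.
* **CP–HP pattern classification** (`pollennet.patterns`) — the core
  model objects: `CPHPPatternModel(cp, hp).fit(alpha)` fits
  `HP = b0 + b1·CP` (OLS) and `HP = exp(c0 + c1·CP)` (nonlinear least
  squares) and labels each species *increasing linear*, *increasing /
  decreasing exponential*, or *no pattern* by a
  significance-then-adjusted-R² decision rule.
* **Cross-species statistics** (`pollennet.comparative`) — standardized
  transforms, multiple regressions with standardized coefficients
  `b·SD(x)/SD(y)`, and one-way ANOVAs across pattern or strategy groups.
* **Synthetic communities** (`pollennet.simulate`) — seeded generators
  for visitation networks and stigma loads in four accrual regimes, with
  ground truth for benchmarking.
* **Published reference tables** (`pollennet.published`) — the printed
  per-species trait/HP% and pattern tables of the motivating survey, for
  recomputing its community statistics.

## Worked example

```python
import pollennet as pn

ds = pn.simulate_dataset(pn.SimulationConfig(seed=42))   # 29 x 45 community
net = pn.build_network(ds.edges, binarize=True)
print("links:", net.n_links, "links/species:", round(pn.links_per_species(net), 1))
print("H2' =", round(pn.h2_prime(net).h2_prime, 3))

print(pn.classify_species(ds.stigmas, species="P25").summary())

patterns = pn.classify_all(ds.stigmas)
print(pn.pattern_tallies(patterns))

c = pn.summarize_community(ds.stigmas)
print(f"{c.n_stigmas} stigmas, {c.total_grains} grains, "
      f"{c.pct_cp:.1f}% CP / {c.pct_hp:.1f}% HP")
```

prints

```
links: 494 links/species: 6.7
H2' = 0.239
CP-HP accrual pattern for P25
  stigmas: 50 analyzed of 50 collected
  pattern: increasing_linear (alpha = 0.05)
  linear       b =  0.11807  adjR2 =  0.691  F =  110.341  p =  4.936e-14 <- chosen
  exponential  b =  0.0083703  adjR2 =  0.642  F =  88.903  p =  1.675e-12
{'linear': 4, 'exponential': 7, 'no_pattern': 18}
1450 stigmas, 153019 grains, 95.7% CP / 4.3% HP
```

The simulated community is generalized (low H2′, 6.7 links per species).
Species P25 was generated under the linear-tolerance regime and is
recovered as such: both fits are significant, and the line wins the
adjusted-R² comparison (slope 0.118 ≈ the regime's HP:CP deposition ratio).
A majority of species (18/29) show no CP–HP relationship — the
avoidance-dominant structure the generator emulates.

The same stages are available as a command-line pipeline:

```sh
pollennet simulate --seed 42 --out-dir data/
pollennet netmetrics --edges data/interactions.csv --out-dir out/
pollennet classify --stigmas data/stigmas.csv --out-dir out/
pollennet report --edges data/interactions.csv --stigmas data/stigmas.csv \
    --traits data/traits.csv --out-dir out/
```

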