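# infodemic

Centrality analysis for health-misinformation networks: who spreads false
health claims, who amplifies them, and what happens when they are removed.

During health crises, misinformation travels through directed interaction
graphs (retweets, mentions) whose structure decides which false claims go
viral.  Classical centrality metrics — degree, closeness, betweenness,
eigenvector — find densely connected hubs, but they are static: they miss
users whose audiences are unusually susceptible, and users whose influence
accumulates and resurges over time.  `infodemic` implements three metrics
built for exactly those gaps, alongside the four classical baselines, for
analysts and researchers studying infodemic dynamics:

* **Propagation centrality (PC)** — the fixed point of the damped
  propagation equation
  `x(v) = (1 − d)/n + d · Σ_{u ∈ N_in(v)} x(u)/d_out(u)` with d = 0.85:
  steady-state influence where being pointed at by influential accounts
  makes you influential.
* **Misinformation vulnerability centrality (MVC)** — exposure times
  susceptibility: from an initial vulnerability `vul_0(v) ∈ [0, 1]` (from
  data, susceptibility features, or a seeded uniform draw), iterate
  `vul_{t+1}(v) = degree(v) · vul_t(v)` (in-degree by default, a few steps),
  then min-max normalise.  High scores mark well-reached, credulous
  amplifiers.
* **Dynamic influence centrality (DIC)** — cumulative influence
  `DIC_{t+1}(v) = DIC_t(v) + Σ_{u ∈ N_in(v)} DIC_t(u)` from an all-ones
  start over ~10 timesteps, normalised; its per-step trajectory exposes
  "long-tail" spreaders that stay prominent across snapshots.

Around the metrics sit a top-k comparison framework (overlap partitions,
coverage gain, exclusivity), proxy-ground-truth validation (Spearman rank
alignment with retweet and emotion-word counts), an independent-cascade
node-removal simulator with common random numbers, and a seeded synthetic
generator of retweet-style networks with planted hubs, vulnerable
amplifiers and persistent spreaders.

## Worked example

Metrics follow a model/results pattern: build a model over an
`InteractionNetwork`, call `fit()`, inspect the results.

```python
from infodemic import (
    CascadeConfig, PropagationCentrality, SyntheticSpec, evaluate_intervention,
    generate_network, initialise_vulnerability,
    misinformation_vulnerability_centrality,
)

net, attrs, manifest = generate_network(SyntheticSpec(seed=7))
res = PropagationCentrality(net).fit()
print(res.summary(top=5))
```

```
pc centrality results
==============================================
nodes: 809    edges: 3671
params: damping=0.85, dangling_mode=literal, max_iter=100, tol=1e-09, weighted=False
dominant eigenvalue: 0.846981   iterations: 52   residual: 8.47e-10   converged: True
----------------------------------------------
rank  node              score
   1  u00000            0.0891143
   2  u00001            0.0441411
   3  u00002            0.0383626
   4  u00003            0.0254264
   5  u00004            0.0100824
```

The PC top-5 are exactly the generator's five planted hubs
(`manifest["planted_hubs"]`).  The vulnerability metric surfaces a different
cohort — the five planted amplifiers, whose exposure and susceptibility are
both high even though they are not propagation hubs:

```python
init = initialise_vulnerability(net, attrs=attrs)   # vul0 attribute column
mvc, _ = misinformation_vulnerability_centrality(net, init)
print(mvc.ranking()[:5])
# ['u00168', 'u00167', 'u00166', 'u00169', 'u00170']
```

Removing the PC top-10 and re-running the cascade under shared random
numbers quantifies the intervention:

```python
cfg = CascadeConfig(seed_nodes=frozenset(manifest["misinfo_seeds"]),
                    p=0.1, runs=500, seed=7)
print(evaluate_intervention(net, cfg, set(res.ranking()[:10]), "pc-top-10"))
# pc-top-10: baseline 50.00 ± 0.13 -> 42.23 ± 0.10 (15.54% reduction, |removal|=10)
```

A baseline spread of 50 activated accounts drops to 42 after removing the
ten top-ranked spreaders — a 15.5% reduction from neutralising 1.2% of the
network.

The same workflow is available from the shell:

```bash
infodemic generate --n 500 --seed 7 --out-dir data/
infodemic compute --edges data/edges.tsv --metric pc --out pc.csv
infodemic compute --edges data/edges.tsv --metric mvc --attrs data/attributes.tsv --out mvc.csv
infodemic compare pc.csv mvc.csv --k 10
infodemic simulate --edges data/edges.tsv --seeds-from-attrs data/attributes.tsv \
    --rank pc.csv --remove-top 10 --p 0.1 --runs 1000 --seed 7
infodemic pipeline --edges data/edges.tsv --attrs data/attributes.tsv --out-dir report/
```

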