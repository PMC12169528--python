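# Methods

`infodemic` analyses how health misinformation propagates through a directed
interaction network G = (V, E) — nodes are users, an edge (u, v) with weight
w_uv records that u's activity reaches v (e.g. retweets), and the adjacency
matrix A has a_uv = w_uv.  The package computes four classical centrality
baselines and three purpose-built metrics, compares their top-k influencer
lists, validates them against observable proxies, and quantifies the effect
of removing highly ranked nodes on simulated misinformation cascades.

## Metrics

### Classical baselines

* **Degree** C_D(v): raw edge counts, split into in-/out-/total degree on
  the directed graph.  No normalisation is applied, so scores are directly
  interpretable as interaction counts.
* **Closeness** C_C(v) = 1 / Σ_{u≠v} d(v, u) over hop-count shortest-path
  distances.  The standard form is undefined whenever some node cannot reach
  all others, which is the norm in fragmented misinformation networks, so a
  harmonic variant H(v) = Σ_{u≠v} 1/d(v, u) (unreachable terms contribute 0)
  is available; `formulation="auto"` picks standard only when every ordered
  pair is reachable and records the choice in the result parameters.
  Distances can be taken along outgoing or incoming edges.
* **Betweenness** C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st over *ordered* pairs,
  endpoints excluded, no normalisation.  Ordered pairs are the natural
  directed reading of the formula on a retweet graph.  The computation uses
  the Brandes accumulation (via networkx); the tests verify it against an
  exhaustive shortest-path enumeration on all small random digraphs.  In
  weighted mode the edge distance is 1/weight, because weights encode
  interaction strength, not cost; default is unweighted hop counts.
* **Eigenvector centrality** is obtained by power iteration on
  M = Bᵀ + (ε/n)·11ᵀ, where B is the binary adjacency and ε (default 10⁻⁶)
  is a uniform teleport perturbation.  The perturbation makes M strictly
  positive, so the Perron–Frobenius theorem guarantees a unique positive
  dominant eigenvector even on disconnected or reducible graphs.  The
  transpose orientation means incoming links confer status, consistent with
  the propagation metric; an out-link orientation is available.  Scores are
  L2-normalised; iteration stops when the successive-iterate L1 difference
  falls below `tol`, and failure to converge within `max_iter` raises an
  error carrying the residual.  Note that with a tiny ε the spectral gap of
  M can be nearly zero (e.g. long directed cycles, whose leading eigenvalues
  are complex with near-equal modulus), making power iteration very slow;
  the dense-eigensolver cross-check therefore uses a larger teleport.

### Propagation centrality (PC)

The damped steady-state propagation ranking

    x(v) = (1 − d)/n + d · Σ_{u ∈ N_in(v)} x(u) / d_out(u),

with damping d = 0.85, solved by fixed-point iteration from the uniform
vector 1/n until the L1 change is ≤ `tol` (default 10⁻⁹) or `max_iter`
(default 100) is reached — hitting the iteration cap is flagged in the
diagnostics, not fatal, since a bounded iteration regime is part of the
metric's definition.  Two choices were genuinely open:

* **Dangling nodes.**  The update as printed gives zero-out-degree nodes no
  outgoing term, so total mass leaks ("literal" mode, the default).  A
  "redistribute" mode adds the dangling mass back uniformly, which restores
  the mass-conservation property of conventional damped ranking; both are
  verified against a direct linear solve of the fixed-point system.
* **Divisor.**  The default divides by the out-degree (edge count); a
  weighted variant divides each contribution w_uv by the out-strength.

Diagnostics report the iteration count, final L1 change and an estimate of
the Perron root of the folded update operator (exactly 1 in redistribute
mode on any graph).

### Misinformation vulnerability centrality (MVC)

Each node starts with a susceptibility score vul_0(v) ∈ [0, 1], sourced in
priority order from (i) an explicit `vul0` attribute column, (ii) the
min-max-rescaled equal-weight mean of whichever susceptibility feature
columns are present (`low_credibility`, `retweet_count`,
`emotion_word_count`), or (iii) U(0, 1) draws from a seeded generator,
consumed in ascending node-id order so runs reproduce across platforms.
Partial attribute coverage is an error rather than silently mixed sources.

The vulnerability recurrence vul_{t+1}(v) = degree(v) · vul_t(v) is iterated
`steps` times (default 5, ceiling 10).  The degree is fixed on the static
snapshot, so the raw score has the closed form degree(v)^steps · vul_0(v);
the default `degree_mode="in"` reads degree as exposure — the number of
sources that can reach v.  The final vector is min-max normalised to [0, 1].
Numerical notes:

* the recurrence grows geometrically for degree > 1 (it does not
  stabilise), so when degree^steps would overflow float64 the normalised
  scores are computed from the closed form in log space;
* a degenerate min-max (all raw scores equal, e.g. an edgeless graph) maps
  every node to 0.5 — the midpoint avoids asserting either universal
  vulnerability or universal immunity;
* the *ranking* induced by MVC genuinely depends on `steps`: raw scores are
  deg^s·vul_0, and increasing s re-weights degree against susceptibility
  (deg 1/vul 0.9 outranks deg 2/vul 0.1 at s = 1 but not at s = 5).  Step
  invariance holds only in restricted cases (constant vul_0, or constant
  degree), which is what the tests assert.

### Dynamic influence centrality (DIC)

Influence accumulates from an all-ones start:

    DIC_{t+1}(v) = DIC_t(v) + Σ_{u ∈ N_in(v)} DIC_t(u),

equivalently DIC_t = (I + Bᵀ)ᵗ·1 on the binary adjacency.  The default runs
10 steps; values are exact 64-bit integers and a guard refuses any step that
could push them past 2⁵³ (the exact-integer range of float64), recommending
fewer steps.  The final vector is normalised — divide-by-max by default
(rank-preserving and scale-free), min-max optionally.  The full trajectory
is returned; `persistence_profile` ranks nodes by the number of timesteps
they spend in the per-step top-k (boundary ties all count, so the
uninformative all-equal step 0 does not discriminate), breaking ties by
final influence and then node id.  This surfaces "long-tail" spreaders that
stay prominent across snapshots instead of peaking once.

## Top-k comparison and proxy validation

Rankings use competition order with deterministic ties (descending score,
then ascending node id), so top-k lists are reproducible.  The overlap
partition assigns every node in the union of named top-k lists to the exact
subset of lists containing it; coverage gain is 100·(|extended| − |base|)/
|base| (reported to two decimals) over explicit node sets — the published
combined-pool total is carried as data, never hard-coded into the
arithmetic.  Proxy validation computes overlap@k and a Spearman rank
correlation (midranks for ties, via scipy) between a metric and a
higher-is-better proxy column: retweet counts proxy influence, emotion-word
counts (counted by whole-token lexicon matching; the bundled 30-term
fear/outrage/conspiracy word list is a convenience fixture, not a canonical
psycholinguistic resource) proxy vulnerability.

## Intervention simulation

The spread model is the independent cascade: every newly activated node
makes one attempt per inactive out-neighbour, succeeding with probability p
(uniform by default, min(1, p·w) per edge in weighted mode), until
quiescence; spread counts activated nodes including seeds.  Monte-Carlo runs
use the live-edge coupling — one uniform threshold per edge of the full
network per run, an edge being live iff its threshold is below its
transmission probability — so that (i) p = 1 reduces exactly to
reachability, (ii) baseline and post-removal arms share thresholds (common
random numbers), and (iii) spread is exactly monotone under nested removal
sets, not merely in expectation.  Removed nodes are neutralised: removed
seeds cannot activate (modelling deplatforming) and removing every seed
yields a flagged 100% reduction.  Defaults: p = 0.1, 1000 runs, seed 7;
standard errors use the sample standard deviation over runs.

The two printed case-study reduction figures are treated as dataset-bound
outcomes: their underlying spread model and seed set were never specified,
so only their arithmetic relation (a 25% relative improvement) is
reproducible, and the simulator makes no attempt to match them.

## Synthetic networks

The generator emulates a retweet-style misinformation graph at a scale where
every experiment runs in seconds (default n = 500 organic accounts, 3
out-edges per arriving account): directed preferential attachment (targets
chosen ∝ in-degree + 1) produces the heavy-tailed in-degree profile of real
retweet graphs.  Planted structure provides ground truth for recovery
experiments:

* **Hubs** (default 5) sit on the earliest, organically richest accounts
  and receive 150 extra in-edges from distinct ordinary users — dominating
  the propagation ranking because each booster has low out-degree.
* **Vulnerable amplifiers** (default 5, vul_0 ∈ [0.9, 1] against a
  background capped at 0.5) are mid-growth accounts that receive 300
  in-edges from dedicated bot-like amplifier accounts.  Those sources have
  no incoming standing and their propagation contribution is diluted by
  their own out-degree, so the amplifiers hold the highest raw exposure
  (hence the top degree^steps·vul_0 products) without displacing hubs from
  the propagation top ranks.  Consequently, when amplifiers are planted they
  — not the hubs — hold the very top in-degrees; with no planted amplifiers
  the hubs do.
* **Persistent spreaders** (default 3) sit in reciprocal 4-cliques with
  dedicated partners (geometric influence growth) primed by 15 ordinary
  feeders, so they enter the per-step top-k early and stay there.

Attributes are generated by rank-matching with bounded noise rather than
parametric copulas: retweet counts are heavy-tailed draws matched to the
in-degree order (±10% multiplicative noise), emotion-word counts are
Poisson draws matched to the vul_0 order, and misinformation-seed flags are
Bernoulli at the configured fraction.  An `islands` option adds disconnected
reciprocal pairs for fragmented-graph scenarios.  Everything is reproducible
bit-for-bit from (spec, seed), and the manifest records all planted
identities.

What the generator does **not** emulate: real retweet timing, community or
topical structure, reciprocity patterns of organic conversations, or the
scale of production datasets.  Passing the recovery tests shows that each
metric responds to the structural signal it was designed for — not that it
would isolate the same actors in a real platform crawl.

## Published-case-study fixtures

The FibVID COVID-19 case study printed its top-10 lists (four traditional
metrics, the propagation top-10, three vulnerability-exclusive amplifiers,
the dynamic-influence top-10), the overlap partition, the coverage totals
(29 traditional, 42 combined) and a five-node worked example of metric ranks
against retweet/emotion counts.  These are rebuilt as data fixtures (no
graph exists for them) so the overlap, coverage and rank-alignment
arithmetic can be exercised exactly as tabulated.  One inconsistency is
preserved rather than repaired: the printed exclusive blocks sum to 43
distinct nodes while the printed combined total is 42; the arithmetic
operations take explicit sets/counts and report whatever the inputs imply.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` use the package's study
conditions directly: oracle agreement on 50–100 random digraphs (n ≤ 50 for
the propagation solve, n ≤ 8 for exhaustive betweenness, n ≤ 30 for the
exact influence recurrence), planted recovery and intervention dominance on
20 independently seeded default networks, and cascade calibration with
10,000 Monte-Carlo runs on the single-edge fixture (E[spread] = 1 + p).
MVC exactness is asserted on instances with dyadic vul_0 and small degrees,
where every float product is exact, so the comparison against the rational-
arithmetic oracle is equality rather than approximation.
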