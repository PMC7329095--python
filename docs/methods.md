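# Methods

This document describes the statistical model behind `cimaps`, every tunable
parameter with its default and rationale, the scope of the synthetic-data
generators, numerical choices, and known limitations.

## Data model

All learning operates on a `DiscreteDataset`: N rows of category indices
over p categorical variables. Continuous tables (e.g. metabolite peak
intensities) enter through equal-frequency quantile discretisation
(`discretize_quantiles`), with values tied to a cut point assigned to the
lower bin and a binary target column passed through unchanged.

`category_budget(n, cond_depth)` pre-computes the largest per-variable
category count c such that the worst-case test keeps at least five
observations per degree of freedom, using `df = (c−1)² · c^cond_depth`. The
default `cond_depth=0` budgets for the unconditional pairwise test only,
because the same five-per-df rule is re-applied to every individual test at
run time; a positive depth budgets conservatively for conditional tests as
well (at n = 239, depth 0 allows 7 categories, depth 2 allows 3).

## Independence machinery

* **Statistic.** `G = 2 Σ O ln(O/E)` summed over the cells of the
  (x, y | conditioning-cell) contingency table, expected counts formed
  independently within each conditioning cell. Zero observed cells
  contribute zero. Degrees of freedom are the unconditional formula
  `(|X|−1)(|Y|−1)·Π|A_k|`; empty conditioning cells do not reduce df (a
  deliberate, conservative convention — the alternative inflates rejection
  rates on sparse tables).
* **Mutual information.** Plug-in conditional MI in bits from the same
  table. The identity `G = 2 N ln(2) I` holds exactly for the plug-in
  estimates and is enforced to 1e-9 relative accuracy by the test suite.
* **p-values.** Asymptotic χ² upper tail, computed by `scipy.special.chdtrc`
  (chosen over `stats.chi2.sf` purely for speed; identical values).
* **Reliability gate.** A test with `N/df < 5` is not performed; the verdict
  is `untested-keep-edge`. Keeping the edge is the conservative PC default:
  an unreliable acceptance of independence would delete an edge
  irreversibly.
* **FNR gate** (`FnrConfig`, default disabled; `alpha=0.05`, `beta=0.05`,
  `effect_size w=0.3`). For sample size N the gate computes the largest df
  at which a level-α χ² test has power ≥ 1−β against noncentrality
  `λ = N·w²` (the standard χ²-power model with Cohen's effect size w), by
  monotone binary search on df with `scipy.stats.ncx2.sf`; any test with
  larger df is skipped, keeping the edge. `w = 0.3` is Cohen's conventional
  "medium" effect; smaller w makes the gate stricter (more tests skipped,
  fewer false negatives, more false positives). `effect_size_scan` maps this
  trade-off empirically.

## Skeleton search

`learn_skeleton` runs the level-wise PC adjacency search:

* **Ordering.** Nodes are ranked by ascending average pairwise unconditional
  MI ("test weakest first", TWF); candidate edges at each level are visited
  weakest-first and conditioning subsets are enumerated over each endpoint's
  neighbourhood in TWF rank order, with duplicate subsets across the two
  endpoints tested once. All orderings derive from data statistics and
  variable names only, so results are invariant to column order (tested).
* **α** (default 0.05): the per-test significance level. The acceptance
  experiments that demand *exact* skeleton recovery on n = 20 000 samples
  use α = 0.01: PC is consistent only if α shrinks as n grows, and at
  α = 0.05 the per-pair type-I error alone caps the exact-recovery rate of a
  10-pair graph near 1 − (1 − 0.05·k)… ≈ 90 %, regardless of implementation.
* **FDR schedules** (`FdrPolicy`, default `basic`). The Benjamini–Hochberg
  step-up runs over each surviving edge's largest observed p-value:
  `basic` once after the search converges, `interleaved` additionally after
  every conditioning-set size, and `mini` as the *only* pruning mechanism
  (individual verdicts never remove an edge). Discoveries are dependences;
  non-discovered edges are pruned with the conditioning set that produced
  the recorded p-value as their sepset.
* **Outputs.** A `CIMap` with MI edge weights, a sepset for every removed
  pair, and a policy log (tests performed/skipped, FDR/FNR configuration,
  maximum level reached) serialisable as JSON alongside GraphML.

Constant columns are rejected with an error naming the column: no
independence test is defined for a one-category variable, and silently
dropping it would change the graph's node set.

## Orientation and scoring

* **Colliders.** Every unshielded triple X–Z–Y with Z outside sepset(X, Y)
  is oriented X→Z←Y. Triples are processed in sorted order,
  first-processed-wins under conflicts, and an orientation that would close
  a directed cycle is skipped — on noisy data sepsets can be mutually
  inconsistent, and the PDAG invariant (acyclic directed part) must survive.
* **Rule closure.** The four standard orientation rules are applied to a
  fixpoint, each orientation again cycle-guarded. On sepsets generated from
  a true DAG, collider detection plus closure provably yields the
  equivalence-class graph; the test suite checks equality with an
  exhaustive-enumeration oracle on every DAG of up to four nodes.
* **Extension.** Remaining undirected edges are oriented by sweeping nodes
  in a chosen order — strongest-first (TSF, default), weakest-first (TWF),
  or a seeded random permutation — pointing edges away from the current
  node, and reversing any single orientation that would create a cycle.
* **BIC.** `Σ_cells N ln(N_cell/N_parent-cell) − ln(N)/2 · Dim_G` with
  `Dim_G = Σ (card−1)·Π parent-cards`; zero-count parent configurations
  contribute nothing. The score is likelihood-equivalent, so
  Markov-equivalent DAGs score identically (tested).
* **Search** (`cimap_to_dag`, default `max_iter=100`, `seed=0`): the TSF
  extension is the baseline; `max_iter` random node orders are tried and the
  best BIC kept, so the result never scores below the baseline. On 5-node
  problems 2000 restarts reliably attain the optimum over all 120 node
  orders (tested); 100 restarts is a pragmatic default for the 8–40-node
  range where exhaustion is impossible.

## Bootstrap stability selection

`bootstrap_cimaps` draws B N-out-of-N resamples (default B = 400 in
`most_representative_cimap`; the faster acceptance protocol uses B = 50),
learns one CI-map per replicate, and records the resampled row indices in
each map's policy log. Replicate seeds come from
`numpy.random.SeedSequence(seed).spawn(B)`, so enlarging B never changes
earlier replicates.

`association_histogram` tallies, per non-target node, the percentage of maps
in which it lies at BFS distance exactly 1 (first order) or exactly 2
(second order) from the target.

`hierarchical_filter` (defaults `min_freq=0.10`, `max_order=3`) repeatedly
takes the most frequent not-yet-used connection at the current order —
skipping frequencies of 0 or 1, which cannot discriminate, and frequencies
below `min_freq`, which are noise — and keeps only the maps exhibiting it,
moving to the next order when no candidate remains, and stopping when one
map survives or all survivors share the same edge set. If no connection ever
reaches `min_freq`, the modal map by edge-set frequency is returned with a
warning.

## Synthetic generators and their scope

* `demo_network()` — a fixed 8-node, 9-edge network (chain, fork, three
  colliders; cardinalities 2–3) whose CPT rows are hand-specified and
  bounded away from 0/1. It exists so recovery experiments have a fixture
  whose every edge is detectable at n = 10 000.
* `random_network(n_nodes, max_parents, (lo, hi), concentration, seed)` —
  parents drawn only from earlier nodes of a random permutation (acyclic by
  construction), CPT rows from a symmetric Dirichlet. Low concentrations
  give near-deterministic rows; such draws routinely contain effectively
  vacuous edges or near-constant nodes, so raw draws are *not* suitable as
  recovery ground truth.
* `identifiable_random_network(...)` — rejection-samples `random_network`
  until every edge retains ≥ 0.01 bits of exact conditional MI under every
  conditioning subset and every marginal category probability is ≥ 0.05
  (both computed by exact enumeration, so this is limited to small
  networks). These are the fixtures used for oracle-agreement experiments.
* `synth_mrs_table(n_subjects=239, n_features=10, class_fraction=0.25,
  effect, latent_corr=0.3, seed)` — correlated Gaussian "metabolite"
  intensities with a binary class label shifting selected feature means, in
  within-class standard-deviation units. It emulates the *shape* of a
  single-voxel MRS cohort (sample size, feature count, class imbalance,
  shared correlation); it does not model spectral physics, heteroscedastic
  noise or nonlinear class effects.

## Numerical choices

* Counting is `np.bincount` over flattened joint indices — exact integer
  counts, no floating accumulation.
* `0 · ln 0` terms are excluded by masking rather than by adding epsilons,
  keeping G and MI exact on sparse tables; both are clamped at 0 against
  −1e-16-scale rounding.
* CPT rows whose sums deviate from 1 by ≤ 1e-6 are renormalised (repository
  files carry rounded decimals); larger deviations are errors.
* χ²-power search caches per (n, α, β, w) with `lru_cache` and caps df at
  1e8.
* All experiment drivers derive replicate seeds as
  `SeedSequence(master, spawn_key=...)` reduced mod 2³¹, so adding
  replicates or policies never perturbs existing ones and every consumed
  seed is a valid 31-bit integer.

## Limitations

* The χ² reference distribution and the power model are asymptotic; the
  five-per-df rule is a heuristic guard, not a guarantee, and with few
  observations per cell the G-test is conservative.
* PC-style search assumes causal sufficiency (no latent confounders) and
  faithfulness; violations produce extra or missing edges no stabiliser can
  repair.
* `orient_v_structures`/`rule_closure` resolve conflicting sepset evidence
  first-wins rather than by score, so on noisy data different tie-breaking
  could yield different (equally defensible) PDAGs.
* BIC comparisons are only meaningful between DAGs sharing a skeleton
  learned from the same data; the restart search optimises orientation, not
  adjacency.
* The exhaustive identifiability screen and the enumeration oracles scale
  exponentially and are restricted to ≤ 5–6 nodes; on larger graphs
  correctness is checked only through invariants (acyclicity, skeleton
  preservation, baseline dominance).
* Bootstrap percentages are frequencies under resampling of one dataset;
  they are stability measures, not posterior edge probabilities.
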