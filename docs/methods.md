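# Methods

## The model

`cpv` models clinical-pathway variance — postpartum hemorrhage (PPH) after
cesarean section — as a three-layer discrete Bayesian network. The variance
node *A* has the four primary risk factors *B₁–B₄* as parents; each primary
factor has secondary root factors among *C₁–C₁₁* as parents; three secondary
factors feed two primary factors each (effect of oxytocin C₃ and macrosomia
C₄ → uterine atony B₁ and birth-canal laceration B₂; complications of
pregnancy C₆ → B₂ and coagulopathy B₄). Every node is binary with states
`State0` (absent) and `State1` (present). The joint distribution is the
chain-rule product of one conditional probability table (CPT) per node; the
engine accepts arbitrary discrete DAGs, with the layering constraint
(variance ← primary ← secondary roots) enforced only for networks declaring
`metadata["layered"]`.

Assumptions inherited from this model family: risk factors act through the
layer structure only (no secondary→variance edges, no edges within a layer),
states are binary presence/absence, and CPTs are stable across the cohort.
A naive-Bayes classifier is the special case of a single class node with
conditionally independent children; the engine implements the general
network, of which that is a restriction.

### Bundled network content and derived priors

The published content of the PPH network comprises the structure, root
priors P(C₁)=0.505, P(C₂)=0.369, P(C₃)=0.268, P(C₄)=0.41 (State1), and the
full coagulopathy CPT P(B₄ | C₆, C₁₁) = 0.1 / 0.4 / 0.264 / 0.78 (State1,
rows in lexicographic parent order). Two further priors are *derived*, not
published: inverting the worked value P(B₄=1 | C₁₁=1) = 0.49 through the
CPT gives P(C₆=1) = 0.438, and inverting the worked marginal
P(B₄=1) = 0.3636 then gives P(C₁₁=1) = 0.5112. Both carry provenance notes
in the fixture metadata.

Everything else — the CPTs of A and B₁–B₃ and the priors of C₅, C₇–C₁₀ —
was never published. These ship as uniform rows flagged `unspecified`.
Inference whose relevant sub-network touches an unspecified table raises
`UnspecifiedTableError` unless `allow_unspecified=True`, and then warns;
the pipeline copies every such warning into its reports. This is deliberate:
headline quantities that depend on the unpublished region (the overall
variance probability, individual-case predictions through B₁–B₃, and the
full diagnostic ranking table) cannot be reproduced from published content,
and the package refuses to fake them silently.

### Inference

Two exact algorithms share one interface. The default is variable
elimination over dense numpy factors with a greedy min-degree elimination
order; the reference path is direct summation of the joint over all free
variables. Both operate after **barren-node pruning**: only the ancestral
closure of the query and evidence nodes is retained, since any other node
sums out of the posterior. Pruning is what makes queries confined to the
published region of the bundled network (e.g. the coagulopathy CPT row
under full parent evidence) exact and warning-free even though the network
as a whole contains placeholders. Networks here are ≤ 16 binary nodes, so
exactness costs microseconds; approximate inference is out of scope.

Numerical conventions: CPT rows must sum to 1 within 1e-9; returned
distributions are normalized and checked; evidence with probability zero
raises a typed `ZeroEvidenceError` rather than producing NaN; ranking ties
break lexicographically by node id so reports are deterministic. Reports
round to four decimals; internal values are full double precision.
Serialization is one JSON document per network, table rows keyed by
parent-state strings (e.g. `"C6=State1,C11=State0"`) enumerated
lexicographically with `State0` first — the convention is stated so tables
are unambiguous under permutation of parents.

### Prior elicitation

`elicit_prior` implements the multiplicative rule p(cᵢ) = R(cᵢ) · Pd(cᵢ)
combining an expert occurrence degree and a data-derived possibility, both
in [0, 1]; the product is monotone in each argument and symmetric. The
bundled priors are stored as final probabilities; whether the published
State1 values are such products or raw frequencies is not stated in the
source material, so the fixture treats them as final and exposes the
elicitation rule separately for users with raw R/Pd inputs.

## Association-rule mining

Transactions are item sets per case; labels are normalised (case-fold,
trim, collapse whitespace) because free-text treatment descriptions vary
across recording physicians. Frequent itemsets are found level-wise
(Apriori): candidates of size k join frequent (k−1)-sets sharing a prefix
and are pruned by the anti-monotonicity of support before counting; counts
use bitmask containment and are exact. Rules take a single-item consequent —
the shape of every published rule — with support, confidence and lift
computed exactly from the transactions (support as a fraction by default;
counts via `count_support`).

Preset protocols: `double-factor` (min support 0.05, confidence 0.5,
lift 0.9; one-item antecedent), `triple-factor` (0.12 / 0.5 / 0.9;
exactly two-item antecedents), `treatment` (0.05 / 0.15 / 1; antecedents
restricted to cause-class items and consequents to treatment-class items
via a user-supplied item-class map, antecedents up to two items, matching
the shapes in the published treatment tables). Presets mine freely over the
eligible items; a fixed consequent can be imposed through
`MiningConfig.consequent_items` since the source protocol is ambiguous on
this point. Output ordering is support desc, confidence desc, then
lexicographic — fully deterministic.

## Synthetic data

No per-case data are deposited, so all statistical checks run on synthetic
data with known ground truth. Sample sizes below were chosen for
statistical power (tolerances ≈ 3 binomial standard errors), not as a
reconstruction of the original 200/295-case cohorts, whose per-stratum
composition is unknown.

* **Cohorts.** `sample_cohort` draws full configurations by ancestral
  sampling in topological order through one seeded
  `numpy.random.default_rng`; identical (network, n, seed) gives identical
  cohorts. At n = 10⁵ the empirical coagulopathy frequency sits within
  3·SE ≈ 0.0046 of the exact marginal 0.3636.
* **CPT recovery.** `fit_cpts` estimates each entry as
  (count + s) / (row + s·k) with Laplace smoothing s = 1 by default (small
  clinical strata would otherwise yield 0/0 rows); s = 0 gives the MLE with
  unobserved rows set uniform under a warning. Recovery is checked at
  n = 50 000 (all entries within ±0.02) and n = 500 (±0.1); for these
  bands to test the estimator rather than empty strata, the test networks
  use ≤ 2 parents per node and Dirichlet(4) CPT rows so every parent
  stratum keeps appreciable mass.
* **Planted rules.** `synthesize_transactions` uses a mixture: with
  probability equal to the target support a transaction carries
  antecedent ∪ consequent; with probability support·(1−c)/c (c = target
  confidence) the antecedent alone; all remaining transactions draw
  background items independently at `background_item_rate` (default 0.2).
  Background draws exclude antecedent items (so confidence is not diluted)
  and each rule's own consequent in antecedent-only transactions; empty
  background draws are retried. Realized support and confidence therefore
  converge to the targets; at n = 2000 a rule planted at 0.15 / 0.80 is
  mined within [0.13, 0.17] and [0.75, 0.85]. Multiple rules require
  pairwise-disjoint antecedents, a shared background rate and total planted
  mass ≤ 1.
* **Random networks.** `random_network` (random DAG, Dirichlet CPT rows)
  and `random_layered_network` (three-layer shape with one primary cause
  given a dominant additive effect of 0.82 on the variance node against
  background effects ≤ 0.04) drive the oracle-equivalence and
  ranking-recovery checks. Since the dominant cause's effect exceeds the
  background by an order of magnitude while priors stay in [0.3, 0.6], its
  posterior under the observed variance leads the ranking essentially
  always.

### What passing tests do and do not show

The synthetic generators emulate the *statistical* structure the analysis
assumes: binary factors generated by the network, transactions with stable
item co-occurrence. They do not emulate real obstetric records — no ages,
labs, free text, missingness, coding drift, or confounding outside the
network structure. Passing tests therefore establish correctness of the
algorithms and the recoverability of parameters/rules under the model's own
assumptions, not clinical validity of the bundled network.

## Verification strategy

Inference is verified against an independent brute-force oracle (direct
summation of the fully enumerated joint, written separately in the test
suite) on 200 random DAGs of ≤ 10 nodes to 1e-9, plus closed-form toy
networks; mining against a powerset-scan miner on 50 random datasets of
≤ 12 items and ≤ 200 transactions with exact metric agreement; property
tests cover normalization, anti-monotonicity, the lift identity
(lift · support(consequent) = confidence), threshold monotonicity,
elicitation monotonicity/symmetry, serialization round-trips and
determinism of reports.

## Known limitations

* The unpublished region of the bundled network is a placeholder; forward
  prediction of the variance node and full 15-factor rankings on `pph` are
  only meaningful once a user supplies those tables (e.g. via `fit_cpts` on
  their own cohort).
* Structure learning is out of scope; the network structure is fixed by
  domain knowledge.
* Mining implements Apriori only (datasets here are small); no FP-growth,
  multi-item consequents, quantitative rules, or significance testing.
* Continuous or > 2-state nodes pass the generic validator but the bundled
  model and generators are binary.
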