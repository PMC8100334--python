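# Methods

## Model

`nemtar` infers a signaling hierarchy among m regulators ("S-genes":
kinases, transcription factors, miRNAs) from two binary matrices over the
same l patients: a perturbation-state matrix S\* (s_kj = 1 iff regulator j
carries a qualifying genetic or epigenetic aberration in patient k) and an
effect-observation matrix D (e_ki = 1 iff reporter gene — "E-gene" — i is
differentially expressed in patient k).  The network G is a transitively
closed DAG: the nested-effects assumption says the downstream effect set
of a regulator contains the effect sets of everything it signals to, which
forces closure.  Self-reachability is implicit; the diagonal is never
stored.

Each E-gene is attached to at most one S-gene, or to an artificial null
S-gene that predicts no effects and absorbs uninformative reporters.  The
patient-level effect prediction is: E-gene i shows an effect in patient k
iff some perturbed S-gene of patient k reaches i's attachment point
(reachability includes self).  This is the unique extension of the classic
expected-profile product GΘ that reduces to it under single-perturbation
designs.

Observations are corrupted by two independent error rates: a type-I rate
α (probability of observing an effect where none is predicted) and a
type-II rate β (probability of missing a predicted effect).  The marginal
likelihood of a network integrates the attachments out under a uniform
prior over the m+1 candidates (the m S-genes plus null):

    log P(D | G, S*) = Σ_i log [ (1/(m+1)) Σ_j Π_k P(e_ki | attach i to j) ]

computed in log space with a log-sum-exp kernel that tolerates −∞ terms
from zero rates.  The per-E-gene attachment posterior is the row
normalization of the same per-attachment likelihoods (the uniform prior
cancels).  The m+1 convention is used consistently — in the likelihood
prior, the posterior, and the WIG reference distribution.

## Structure search

* **Exhaustive** (m ≤ 5): scores every transitively closed DAG (4231 on
  five labeled nodes, enumerated by vectorized Floyd–Warshall filtering of
  all off-diagonal digraphs).  Ties within 1e-9 go to fewest edges, then
  lexicographic edge order.
* **Pairwise**: each unordered pair is classified into unconnected, A→B,
  A←B, or A↔B by marginal likelihood restricted to the pair's two
  perturbation columns (full D); directed verdicts are assembled and
  closed.  The ↔ verdict contributes no edge.
* **Triples**: every node triple is scored against the 29 quasi-orders on
  three labeled nodes; an edge enters the final graph iff it appears in a
  strict majority of the MAP models of the (m−2) triples containing both
  endpoints (the majority threshold is a parameter; thresholding happens
  before closure).
* **Greedy hill climbing**: add-only edge search from an initial graph
  (default empty).  Every addable off-diagonal edge that keeps the graph
  acyclic is scored after re-closure; the largest gain above 1e-9 is
  committed, ties to the lexicographically smallest (source, target)
  pair.  Deletion/reversal moves are deliberately absent.
* **MCMC**: Metropolis–Hastings over skeleton graphs.  A proposal toggles
  one uniformly chosen off-diagonal edge; cycle-creating proposals are
  rejected outright; the score is the marginal likelihood of the
  proposal's closure; acceptance is min(1, exp(Δ)).  Defaults: 10000
  iterations, 2000 burn-in.  After burn-in the edge frequencies of the
  visited closures are accumulated and the consensus network is the
  closure of edges at frequency ≥ 0.5.  Scores are memoized per closure,
  which makes long chains cheap once the mode is found.

Locally inferred verdicts (pairwise, triples, MCMC consensus) can
assemble into directed cycles that the final DAG cannot represent; edges
internal to a strongly connected component are dropped (recorded in
diagnostics) before closure.  Every returned network is validated as a
transitively closed DAG and its reported score is recomputed from
scratch.

## Target scoring (WIG)

Given the inferred network and the attachment posterior, the Weighted
Information Gain of a target j (an S-gene, or an unordered pair) over a
pathway signature is

    WIG(j) = Σ_{i ∈ signature ∩ regulon(j)}  P(j→E_i) · ln[(m+1) · P(j→E_i)]

with P(j→E_i) the posterior attachment mass of E-gene i summed over every
S-gene reachable from j (union of reaches for a pair).  Natural
logarithms are used: the maximal single-E-gene gain with 15 S-genes is
ln 16 ≈ 2.77, which matches the scale of published per-gene scores,
whereas base-2 would not.  Regulon membership is decided by MAP
attachment (so regulon sizes are integers and pair regulons are exact
unions), while the score itself uses the full posterior.  A pair with one
member reachable from the other collapses onto the ancestor's regulon and
reproduces the ancestor's WIG exactly — the signature of nestedness.

Significance: the null model draws signature-sized subsets of the
target's regulon uniformly without replacement, recomputes WIG on each,
and reports p = (1 + #{resampled ≥ observed}) / (B + 1).  Defaults are
B = 100000 for singles and B = 50000 for pairs.  Resampling without
replacement (subset sampling) is used; the add-one correction keeps p
strictly positive.  p-values across targets of the same arity are
Benjamini–Hochberg adjusted (statsmodels), with the adjusted value floored
at the raw p.

## Preprocessing

E-genes: log2FC > 1 and BH-adjusted p < 0.01 (strict inequalities;
relaxable to 0.5 when the subtype yields too few reporters).  S-genes:
kinases/TFs need upregulation plus mutation frequency > 5% or CNV-gain
frequency > 5%; miRNAs need downregulation plus promoter hypermethylation
(Δβ > 0.1, BH p < 0.001); a keep-list bypasses the filters for regulators
retained on prior knowledge.  The perturbation matrix is the logical OR of
qualifying events across omics layers; a patient absent from a layer is
treated as unperturbed there (logged), not missing-at-random.

Discretization is anchored on control patients: positive controls are
in-subtype patients with no aberration in any selected S-gene, negative
controls are out-of-subtype patients with none.  The per-E-gene threshold
is t_i = σ·μ_i⁺ + (1−σ)·μ_i⁻ over plain control means (σ = 0.5 by
default; 0.6 is a documented alternative).  A `direction` flag chooses
whether an effect is called below or above the threshold.  The default
follows the printed rule ("below"), but for subtypes defined by
*upregulated* reporters the biologically coherent choice is "above";
both are supported and the flag is prominent because the printed
inequality contradicts the upregulation semantics.

Noise rates are estimated from the discretized control blocks: α is the
fraction of negative-control cells called 1, β the fraction of
positive-control cells called 0; estimates are clamped to
[1e-6, 1−1e-6] because the likelihood is undefined at exact 0/1 rates.

## Synthetic-data generator

The generator emulates a tumor-cohort natural-perturbation screen at the
gastric-cohort scale and is the basis of every benchmark here:

* network: random topological order, independent forward edges at
  pre-closure probability 0.25, then closure;
* states: per-S-gene aberration frequency uniform on [0.05, 0.30] (the 5%
  selection floor up to typical cohort aberration frequencies), then
  independent Bernoulli patient states; 177 patients by default;
* attachment: exactly `egenes_per_sgene` E-genes per S-gene (default 80 ≈
  1194/15); an optional fraction of null-attached E-genes is off by
  default;
* observations: predicted effects with independent flips, 0→1 at
  alpha_sim and 1→0 at beta_sim.

What the generator does **not** emulate: correlated aberrations between
regulators, E-genes shared by several regulators, expression-level
(non-binary) effects, batch structure, or misspecified attachments.
Passing benchmarks therefore demonstrate correct inference under the
model's own assumptions, not robustness to everything real cohorts do.

Edge recovery is scored on the ordered off-diagonal entries of the truth
and inferred closures (TPR, TNR, Accuracy, Precision; an empty-vs-empty
comparison counts as perfect, an empty inference against a non-empty
truth scores precision 0).

## Numerical and design choices

* Improvement and tie tolerances are 1e-9 throughout; likelihoods live in
  log space.
* All stochastic operations take explicit seeds; nested seeds derive from
  a single `SeedSequence`, so benchmark tables reproduce bit-for-bit.
* Benchmark problem sizes used by the repository's own checks: 50
  networks per condition (30 at m=20) and 30 E-genes per S-gene for the
  high-noise robustness arm — the package's chosen defaults for routine
  verification at desk scale.
* The MCMC design here is a standard single-edge-toggle
  Metropolis–Hastings; it is substantially more accurate on the benchmark
  than the MCMC numbers published for this model family (its m=20 mean
  precision is ≈0.79), so published MCMC figures should be compared only
  loosely.
* Under the default study conditions the greedy robustness arm
  (alpha_sim=0.5) measures mean TPR ≈ 0.94 and mean precision ≈ 0.68–0.70.
  Precision under severe false-positive noise is sensitive to the
  generator's pre-closure edge density (denser truths leave fewer
  false-positive slots), which is a property of the simulated cohorts,
  not of the model itself; `SimulationConfig.edge_prob` exposes it.

## Known limitations

* Binary observations only; no log-odds/continuous effect model.
* Each E-gene attaches to at most one S-gene; no mixture or dynamic
  variants.
* Greedy is add-only and can stall in local optima on large, dense
  networks; exhaustive search is capped at five S-genes.
* The pairwise/triples cycle-dropping rule discards genuinely
  undistinguishable regulator pairs rather than merging them into a node.
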