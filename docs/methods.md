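# Methods

## Model and conventions

The model is the pairwise maximum-entropy ("inverse Ising", unrestricted
Boltzmann machine) distribution over configurations σ ∈ {−1, +1}^n,

    p(σ) = exp(E(σ)) / Z(θ),    E(σ) = Σ_{a<b} J_ab σ_a σ_b + Σ_a h_a σ_a.

Conventions fixed once and used everywhere:

* **positive exponent** — higher energy means more probable (so the
  Metropolis acceptance is min(1, exp(E_new − E_old)) and flow rates are
  Γ_ij = exp((E_i − E_j)/2));
* YES = +1, NO = −1; unknown answers are NaN;
* pairs (a, b), a < b, are indexed in row-major upper-triangle order; the
  flat parameter vector is [J, h];
* a state index is an integer in [0, 2^n); bit a (least-significant first)
  holds question a, bit value 1 ↔ +1;
* KL divergences are reported in **nats** (a `base` switch exists). The
  package settled on natural log after checking both bases against the
  reference simulation magnitudes; log2 values are larger by 1/ln 2;
* exact enumeration (distributions, moments, partition function, held-out
  likelihood) is allowed up to n = 25 (2^25 ≈ 3.4e7 states); beyond that the
  enumeration-dependent operations refuse and point to sampling.

## MPF estimation

The flow objective is

    K′(θ) = Σ_{j∈D} Σ_{i∈N(j)} w_j Γ_ij(θ) + λ/(|D||N|) · Σ_k θ_k²/2,

a sum of exponentials of linear functions of θ, hence convex; it is
minimized by L-BFGS from θ = 0 (projected-gradient tolerance 1e−8, maximum
2000 iterations, deterministic). Neighbourhoods are all states within
Hamming distance 1 (N1, the default) or 2 (N2) of a data state; flow into
states that appear elsewhere in the data is allowed by default (an
`include_data_states=False` switch restores the original exclusion rule,
which biases against states near occupied peaks). Flow differences are
precompiled into a sparse matrix of sufficient-statistic differences, so an
objective/gradient evaluation is two sparse mat-vecs.

Two scaling rules keep the objective well-behaved under data reweighting:
|D| is the **sum of weights**, not the record count, so duplicating a record
and doubling its weight are exactly equivalent (tested to 1e−12); and |N| is
the nominal neighbourhood size (n for N1), also for rows whose neighbourhood
is restricted by missing data. The penalty **adds** under minimization
(log P(θ) = −Σθ²/2); the regularized objective with the sign as sometimes
printed (subtracting the penalty from K) would reward arbitrarily large
parameters, contradicting the stated intent that smaller values be
preferred — we use the sign consistent with that intent.

With a single (or otherwise degenerate) observation and λ = 0, K has no
finite minimizer — θ drifts until progress stalls. This is the concrete
failure mode regularization exists to arrest, and it is covered by a test.

## Partial-MPF

A record with m unknown answers (m ≤ 10, hard cap: completions are
enumerated) is expanded into its 2^m completions c, weighted by the exact
conditional probability of the missing assignment given the known answers,

    w_c(θ) = W · softmax_c(E_c(θ)),

computed with log-sum-exp stabilization. Completions re-use the record's
weight mass W, so inconsistency expansion, bias reweighting, and missingness
compose. Neighbourhoods of a completion are restricted to flips of *known*
questions. Because w_c moves with θ, the gradient has two terms,

    dK/dθ = Σ_c w_c dΓ/dθ + Σ_c (Σ_i Γ_ic) · w_c (φ_c − Σ_{c′} u_{c′} φ_{c′}),

the second being the softmax derivative through the completion weights
(φ are sufficient statistics, u the normalized weights). Finite-difference
tests on random instances — including a negative control that drops the
second term — pin this down; it is the part of the estimator most easily
got wrong.

The default is a single joint minimization of this smooth objective.
An `alternating` mode (freeze weights → fit → re-infer weights → repeat)
is provided for comparison; because the flow objective only approximates
likelihood while the completion weights are exact, the two fixed points
differ slightly, and tests bound (not eliminate) that gap.

## Error models for inconsistent coding

Entities coded more than once are resolved before fitting:

* **shared** — each of the k distinct records keeps weight 1/k (answers
  assumed dependent on each other within an observer's reading);
* **independent** (default) — disagreement on d questions is read as
  independent per-question uncertainty: all 2^d combinations of the disputed
  answers are emitted with weight 2^−d, so disputed questions carry implied
  marginals of exactly 1/2.

Records of one entity must agree on *which* questions are unknown
(otherwise the expansion is ambiguous and the ingest errors out). Unknowns
are never expanded here — they belong to Partial-MPF — so both mechanisms
can apply to the same entity. Expansion is refused beyond d = 10 disputed
questions, mirroring the missing-data cap.

## Regularization strength by cross-validation

λ is chosen to maximize the exact held-out log-likelihood: for a complete
record, log p(σ) under the normalized fitted model; for a partial record,
the log *marginal* over its completions; for an expanded entity, the
weight-averaged log-probability of its components. The fold unit is the
source entity, so all expansion products leave together. Leave-one-out is
the default; a k-fold switch handles large |D|. The fold partition is drawn
once per run from the settings seed and shared across the grid, so results
are bit-reproducible. Ties on the grid resolve to the smaller λ.

The default grid is 13 log-spaced values from 1 to 1e6. The range follows
from the penalty scaling: with penalty λ/(|D||N|)·Σθ²/2, the prior starts to
compete with the data term around λ ≈ |D||N| (≈2.5e3 for 128 records of 20
questions) and the cross-validation optimum in the reference simulations
sits near 1e5; grids capped at O(10) leave the penalty numerically inert.

## Synthetic-data generator and what it emulates

The generator reproduces the benchmark conditions the estimator was designed
for: n = 20 questions; J and h drawn i.i.d. N(0, σ²) with σ setting the
regime — dispersed (0.01–0.125), ordered (0.125–0.25, where real survey
data tends to live), near-critical (0.25–0.5), critical (0.5–1.0); samples
drawn by single-site Metropolis–Hastings (burn-in 2000 sweeps, thinning 10
sweeps, one chain per dataset; a sweep is n proposed flips — the schedule
was chosen for near-independence at n = 20 in the ordered regime and is
verified against exact moments in tests). Corruption processes: uniformly
random masking of a fixed number of answers per row; stratified conditional
sampling for a 50/50 marker question with a 128:64 Type-A/Type-B biased
draw (the marker site is clamped during sampling, which realizes "split
evenly" as conditioning the sample rather than constraining the landscape);
inconsistent duplicates via the data module.

What the generator does **not** emulate: real questions are neither
independent of the observer nor missing at random; real inconsistency is
not symmetric noise; and real landscapes are not Gaussian in their
couplings. Passing benchmarks therefore demonstrates correct and
well-behaved inference under the stated generative assumptions, not that
any particular historical dataset satisfies them.

## Benchmark harness and problem sizes

`isingmpf.simulate.run_table` reproduces the three simulation comparisons on
shared per-replicate datasets (paired comparisons, which tightens ordering
tests): (1) oracle-λ / CV-λ / unregularized on 128 samples; (2) ideal /
naive-biased / reweighted on balanced-vs-2:1 samples, with the log-odds bias
exp(⟨log p_B/p_A⟩) − 1 of the minority marker; (3) 128-full-only /
Partial-MPF on 128 full + 128 quarter-masked / modal imputation / 256-full.
Everything is reproducible from a master seed (replicate generators are
keyed [seed, replicate]).

`scripts/acceptance.py` runs these at full n = 20 with 5 replicates per
cell, 3-fold cross-validation over a 7-point λ grid (1e3–1e6) — the
harness's documented speed configuration; the package defaults (LOO, the
13-point grid) remain available through the library and CLI. Monte-Carlo
standard errors across replicates are reported alongside means by
`run_benchmark`.

## Numerical choices and degenerate inputs

* log-sum-exp stabilization for the partition function and completion
  weights; probabilities stay strictly positive for finite θ;
* modal imputation (the baseline only) breaks ties toward +1, fixed and
  documented; columns with no known answers cannot be imputed (error);
* Pearson correlations in the couplings-vs-correlations summary are
  pairwise-complete over known answers; constant columns are excluded with
  a logged note;
* top-k ties break toward the smaller state index; clustering is a
  hand-rolled probability-weighted average-linkage agglomeration on Hamming
  distances (scipy's linkage has no case weights), with merge ties broken
  toward smaller cluster indices;
* the focal "move table" normalizes single-flip probabilities over the
  radius-1 neighbours only — the most probable single-answer reformation is
  a share of all single-answer changes;
* completions are exposed only as weighted distributions; there is
  deliberately no output mode that commits to a single completion.

## Known limitations

Exact enumeration bounds held-out-likelihood scoring (hence CV) and the
landscape analytics at n ≤ 25. No approximate partition-function estimators
(AIS, TAP), no pseudolikelihood/mean-field baselines, no hidden-variable
(restricted) extensions, and no Monte-Carlo fallback for records with more
than 10 unknowns. Graph exports carry probabilities but no layout; drawing
is left to external tools.
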