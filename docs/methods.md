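# Methods

## The interaction score

A trained sequence-to-activity model maps a one-hot encoded DNA sequence
X (4 x L, rows A, C, G, T) to a scalar Y — a regression value, or for a
binary classifier the pre-sigmoid logit.  Working on the logit rather
than the probability keeps gradients informative where the sigmoid
saturates.

An attribution backend assigns each observed nucleotide a contribution
C_X[b, p] to Y.  The feature interaction score (FIS) of a target
feature with a source feature is the change in the target's attribution
when the source alone is perturbed:

    FIS((beta, t) | (alpha, gamma, s)) = C_X[beta, t] - C_X'[beta, t]

where X' switches the observed source base alpha at position s to the
mutant gamma and beta is the base observed at t (unchanged by the
mutation).  FIS is directional: FIS(t|s) and FIS(s|t) are computed
independently and generally differ.  A positive score means the source
supports the target's contribution (synergy); a negative score means it
masks it (buffering).  Note the sign convention relative to the
output-level pairwise in-silico-mutagenesis (ISM) interaction, defined
as joint-mutation effect minus the sum of single effects: that quantity
equals minus the mixed second difference of Y, so on a pure AND model
(Y = X[A,0]*X[A,1]) FIS is +1 while the pairwise ISM interaction is -1.
The two agree in magnitude there and always in "is there an
interaction"; their signs are opposite conventions.

Because one backend evaluation yields attributions for every position
at once, one source mutation prices all targets at two evaluations, an
all-pairs L x L map costs exactly 3L + 1 evaluations (three mutant
bases per source, one shared evaluation of the unperturbed sequence),
and F pre-specified sources cost F + 1.  The engine asserts these
counts; pairwise ISM at the output level, the O(F^2) alternative, is
kept as a comparison oracle.

maxFIS marginalizes over the three mutant bases.  Two policies are
exposed: `signed` (the literal maximum) and `abs` (largest magnitude,
sign retained).  `abs` is the default for maps because magnitude is
what the maps display; ties break alphabetically.  The diagonal of a
map is masked: after mutating s the observed base at s is no longer the
target feature the score was defined for.

Motif-resolution scores sum the target attributions over a span.  A
motif source is not enumerated over per-base mutants; the whole span is
mutated once to the expected background composition — C and G rows set
to f_GC/2, A and T rows to (1 - f_GC)/2 — so columns still sum to 1 and
the span's expected G+C content equals the background f_GC.

## Attribution backends

`grad_input` is gradient-times-input: the first-order Taylor
decomposition of Y around X.  On a one-hot sequence only observed bases
can be non-zero.

`ref_diff` computes reference-based contributions by integrated
gradients: the midpoint Riemann sum (m steps) of the gradient along the
straight path from a neutral reference to X, multiplied elementwise by
(X - reference), averaged over references.  References are either
dinucleotide-preserving shuffles of the sequence (n_references of them,
seeded; a fractional input is shuffled via its argmax string) or the
constant fixed-GC composition matrix.  On a linear model this collapses
exactly to w * (X - mean reference) for any m.  Defaults: 10 shuffled
references, m = 50 steps; the benchmark uses the fixed-GC reference
with m = 50 because its sequences are generated from a fixed-GC
background.  Both backends satisfy the same interface, and external
attribution implementations (a DeepLIFT port, say) can be registered as
plug-ins; the package deliberately does not re-implement DeepLIFT's
layer rules.

Backend evaluations are batched internally.  Chunk size cannot change
results beyond floating-point kernel dispatch: different batch shapes
select different BLAS kernels, so equality is guaranteed to ulp level
(asserted at rtol 1e-12), not bit level.

## Significance

The null distribution of FIS is empirical: input sequences are
dinucleotide-shuffled (Euler-path construction after Altschul &
Erickson — all 16 dinucleotide counts and both terminal bases are
preserved exactly), the same scoring procedure is applied to the
shuffles, and a Gaussian is fitted to the pooled null scores by maximum
likelihood.  Records receive two-sided p-values (both synergy and
buffering are biologically meaningful), Benjamini-Hochberg q-values,
and a significance call at q <= alpha (default 0.05).

Choices the source procedure leaves open, fixed here: the Gaussian is
fitted to signed (not absolute) null scores, matching the two-sided
test; the default null scope subsamples 50 source positions per
shuffled sequence (the full all-pairs scope costs 3L + 1 evaluations
per shuffle and is available by flag); 10 shuffles per sequence, pooled
across sequences.  The BH family is whatever one `significance()` call
receives — callers control it by batching.  In the motif-pair benchmark
the two claims ("true pairs interact", "decoy pairs do not") are
corrected within their own pair categories by default: padding the
null-heavy decoy family with thousands of near-certain true discoveries
would relax its BH threshold to roughly alpha times the overall
discovery rate and overstate decoy significance.  A single mixed family
remains available (`family="all"`).

The null σ estimate deserves care: scores from the same shuffled
sequence are correlated, so the effective sample size is far below the
raw count.  The benchmark null therefore uses several hundred sequences
with repeated shuffles.

## The reference networks

No deep-learning framework is part of the package's dependency set; the
two trainable architectures are implemented directly in numpy with
analytic forward/backward passes, verified against central finite
differences (max relative error under 1e-3, typically 1e-6).

The motif-classification CNN is conv(24 filters, width 15) -> ReLU ->
global pooling -> dense(48, ReLU) -> linear logit.  Pooling is the
log-sum-exp soft maximum (temperature 1 by default).  The choice is
load-bearing for interpretation: a hard global max sees only the single
best match per filter, so when a motif occurs twice, mutating one
instance changes nothing — the duplicate fully buffers it and the
planted interaction is genuinely absent from the model's logit for that
instance.  Log-sum-exp is equally translation invariant but pools two
equal peaks to peak + log(2)/tau, keeping a dependence on every
instance; the temperature trades duplicate sensitivity (small tau)
against gradient leakage onto background windows (large tau approaches
the hard max).  Position-
sensitive alternatives (local pooling with a dense head) would also
keep instance resolution but underfit badly at the benchmark's training
size.  Binary cross-entropy on the logit, Adam (2e-3, second stage at
a quarter of the rate), weight decay 5e-4 on weight matrices (shrinks
spurious dependence on the label-independent decoy motifs), batch 128,
up to 40 epochs with early stop once held-out accuracy is perfect twice
in a row.  A 95% held-out accuracy gate is enforced because
attribution is only meaningful for correctly predicted examples.

The flank-library regressor is a dense net (flattened one-hot -> 64 ->
32 -> 1, ReLU) fitted by Adam on mean squared error with an R^2 > 0.9
gate.

Models serialize to JSON; multi-task variants expose `task_index` and
`clone_task`, and the clone's input gradients are identical to the
parent's selected task.

## Synthetic benchmarks

The motif-pair benchmark emulates a co-occurrence detection task: three
equal sets of 200-bp sequences with i.i.d. background at G+C = 0.46,
set 1 carrying 1-2 ELF1 consensus instances, set 2 carrying 1-2 SIX5,
set 3 (the positive class) both; AP1 and TAL1 decoys are planted 0-1
times each in every sequence independently of the label.  Embeddings
are uniform among non-overlapping placements; ground truth spans are
recorded.  Consensus strings are shipped as config data (ETS GGAA core
for ELF1, TGACTCA for AP1, E-box CAGATG core for TAL1); they are
consensus approximations, and instances are planted as exact consensus
rather than PWM samples so ground-truth spans are unambiguous.  Default
scale is 2,000 sequences per set; the evaluation scores motif-pair FIS
on 300 positive sequences and builds the null from 150-400 shuffled
positives — sizes chosen to keep a full run in minutes on one CPU while
leaving binomial error well below the margins being tested.

What passing shows, and does not: recovery is demonstrated for exact
consensus plants in i.i.d. background with a near-perfect model.  Real
regulatory sequence has degenerate motifs, positional and compositional
structure, and imperfect models; the benchmark validates the
interpreter, not the biology.  A further honest limitation: a ~99%
accurate classifier can implement the co-occurrence task with a purely
additive logit (evidence summation plus threshold), in which case the
planted interaction is genuinely absent from the model and FIS
correctly reports nothing — observed for some training seeds.  The FIS
machinery reports what the model learned, not what the simulator
planted.

The flank-library benchmark emulates an in-vitro binding-affinity
landscape: 10 variable positions (5 per side of an implicit fixed
core), responses from random small additive per-position energies plus
one strong planted pairwise term ((position 4, T) x (position 5, A),
weight 2.0) and Gaussian noise (sd 0.1).  The marginalized aggregate
map groups nucleotide-resolution |FIS| by (source base, source
position, target base, target position), averages within the matching
sequence subset per mutant base, and takes the maximum over the three
mutants, giving a 40 x 40 matrix.  The planted pair must surface as
the top off-diagonal cell; note that any observed source base at the
planted source position identifies the pair (for a non-T observed base
the argmax mutant T creates the pair; for observed T every mutant
destroys it), so the recovery check accepts the position pair with the
planted target base, in either direction.

## Numerical and degenerate-input policy

Float64 throughout.  Non-finite predictions, gradients or importances
raise a contract error naming the sequence.  Self-interaction (t == s)
is rejected rather than returned as 0.  Overlapping source/target spans
are rejected (the score is undefined).  Ambiguity codes (N) in input
sequences are rejected rather than imputed.  A null fit with zero
spread raises with advice to increase shuffles.  The dinucleotide
shuffle preserves the first and last base by construction — it is not
full randomization — and a sequence whose dinucleotide graph has a
single successor per base (e.g. ACGTACGT...) has exactly one valid
arrangement: itself.

## Known limitations

- Attribution leakage: with soft pooling every position carries a small
  gradient share, so mutating a strong source slightly perturbs the
  attribution of irrelevant spans.  Against a shuffled-sequence null
  (which contains no strong sources) this inflates the tail of decoy
  scores; the per-category BH family keeps the decoy false-call rate
  near alpha, but the effect is visible and documented rather than
  removed.
- The Gaussian null is a parametric convenience fitted to an empirical
  distribution that is mildly heavy-tailed; permutation-exact p-values
  are out of scope.
- Single strand only; reverse-complement features are the caller's
  responsibility.
- The benchmark CNN and its training schedule are this package's
  choices; any architecture passing the accuracy gate is a valid
  substrate for the engine, and interaction recovery depends on the
  learned solution, not only on the data (see above).
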