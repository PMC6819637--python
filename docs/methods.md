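# Methods

This note documents the models, numerical choices and limitations behind
`morfmpm`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

MoRFs (molecular recognition features) are short binding segments — in the
curated benchmarks this package mirrors, 5–25 residues — embedded in longer
intrinsically disordered regions. They differ in residue composition both
from ordered sequence and from their disordered flanks, so a per-residue
classifier over windowed compositional features can locate them from
sequence alone. MoRF residues are rare (about 2% of residues in curated
corpora), which motivates a classifier whose decision rule depends only on
per-class first and second moments rather than on resampling tricks.

## Window preprocessing

For window length N and sequence length L, the sequence is padded with
N₀ = ⌊(N−1)/2⌋ zeros on each side (L₀ = L + 2N₀) and a window slides with
step 1, giving L₀ − N + 1 windows. Each window's feature vector is
assigned to every residue the window covers; a residue's final vector is
the mean of its assigned vectors. The per-residue coverage count follows
the closed form |[max(1, j+N₀−N+1), min(L₀−N+1, j+N₀)]|; for odd N this is
the familiar three-regime expression (j+N₀ on the left edge, N in the
interior, L₀−j−N₀+1 on the right), while even N shifts the left boundary
by one, which the interval form handles exactly. The implementation
accumulates window vectors into residue rows and divides by the counts —
deliberately the same element-wise operation order as the naive oracle, so
the equivalence test can demand bit-exact equality rather than a
tolerance.

Two consequences worth knowing:

- Padding is *not* confined to edge rows: windows containing pads are
  averaged into every residue within 2N₀ of a sequence end. Only residues
  deeper than 2N₀ are exactly pad-free.
- Sequences shorter than a window clamp the effective window length to L
  (logged per sequence). Real proteins are routinely shorter than the
  90-residue long window, so erroring out is not an option, and clamping
  preserves the long-context intent.

Default window sizes are (10, 45, 90): a short window to isolate
MoRF-local composition, a long window for the disordered flanking context,
and a middle window fixed at half the long window to damp long-window
noise. With 16 features this yields the 48-column per-residue layout.

## Features

Three feature kinds exist:

- **Scale average** — the mean of an amino-acid property scale over the
  window, with zero pads counted in the denominator and contributing
  nothing to the numerator (the literal reading of zero-padding for a
  numeric feature). Non-standard residues (mapped to X on input) take the
  scale mean, which leaves window averages unbiased.
- **Shannon entropy** (bits) of the residue composition of the window's
  residue part. Pads and X are excluded — a pad "symbol" has no meaning
  for an alphabet distribution.
- **Topological entropy**, a subword-complexity measure. For a window of
  length ℓ over the 20-letter alphabet, the word length is
  n = max{n ≥ 1 : 20ⁿ + n − 1 ≤ ℓ}; windows shorter than 20 admit no such
  n and fall back to n = 1 — unavoidable with a 10-residue short window
  over a 20-letter alphabet. Counting the p distinct n-subwords of the first
  min(ℓ, 20ⁿ + n − 1) characters gives
  H = log p / (n · log min(20ⁿ, ℓ − n + 1)), clamped to [0, 1] so the
  three windows remain comparable. Homopolymers score 0 and maximally
  diverse windows score 1.

The default feature set has 16 entries in a fixed order — 13 property
scales, then topological entropy and the Remark-465 and Deleage/Roux
disorder propensities — and that order, together with ascending window
size, defines the reproducible column layout of feature matrices and model
files.

**The vendored scale registry is synthetic.** The published values of the
13 AAindex scales and the GlobPlot propensity tables are external data;
`data/scales_synthetic.aaindex1` ships stand-in values (a thematic base
vector per scale — hydropathy, helix/sheet propensity, disorder propensity
— plus seeded noise) under the accession codes the default set references,
and says so in each entry's description. No test depends on specific scale
values; the registry exists so every stage runs self-contained. For real
predictions, load a genuine AAindex1 file via `ScaleRegistry.from_files`
or the `--scales` CLI flag.

## Feature selection

A column subset is scored by J_d = tr(S_w + S_b) with empirical priors
P_i = N_i/N, S_b the between-class scatter and S_w the prior-weighted
within-class scatter. **Note:** tr(S_w) + tr(S_b) is algebraically the
pooled total scatter around the grand mean — the criterion as stated is
label-independent and rewards high-variance columns. It is implemented
verbatim (the identity is verified in tests rather than silently "fixed"),
and a genuinely label-dependent alternative, tr(S_w⁻¹ S_b), is available
via `criterion="trace_ratio"`.

The annealer performs one single-feature swap per temperature level,
accepts improvements always and worsenings with probability exp(−|ΔJ|/T),
cools geometrically (defaults T_max = 1, T_min = 10⁻⁴, r = 0.9995, about
18 400 levels), and returns the best state visited — strictly better than
returning the final state and standard practice for simulated annealing.
Because the trace criterion is additive over columns, per-column
contributions are precomputed once and each move is O(1); the tests tie
this fast path to the literal matrix formulas. Selection-time features use
a single short window of length 10. Sweeps over subset sizes derive one
child seed per run from the master seed, so the whole sweep is
reproducible.

## The minimax probability machine

Given per-class moments (μ₁, R₁), (μ₂, R₂), the MPM minimizes the
worst-case misclassification probability over all distributions with those
moments. After fixing the scale of W by Wᵀ(μ₁ − μ₂) = 1, this is the
convex problem min √(WᵀR₁W) + √(WᵀR₂W) subject to that constraint. The
solver eliminates the constraint (W = w₀ + F·u with w₀ the minimum-norm
solution and F an orthonormal null-space basis) and iterates least
squares: each step minimizes WᵀR₁W/g₁ + WᵀR₂W/g₂ at the current norms
g_k, a majorize-minimize scheme for the sum of norms. Convergence is
declared at relative objective change ≤ 10⁻⁹ (at most 1000 iterations);
an independent SLSQP solve of the same convex program pins the optimum in
tests to ≤ 10⁻⁶ relative. From the optimum,
κ* = 1/(g₁ + g₂), b* = Wᵀμ₂ + κ*g₂ = Wᵀμ₁ − κ*g₁ (both expressions are
computed and must agree to 10⁻⁸), and α = κ²/(1+κ²) bounds worst-case
per-class accuracy from below — a bound that applies in particular to the
empirical training distribution, which the tests check.

Numerical choices:

- **Standardization.** Columns are z-scored before moment estimation;
  mixed-unit property scales make raw covariances ill-conditioned and
  would leave scores scale-dependent. Zero-variance columns are dropped
  with a warning and recorded in the model so scoring stays aligned.
- **Ridge.** Class covariances are unbiased estimates plus
  δI, δ = 10⁻⁶ × mean diagonal (or 10⁻⁶ for an all-degenerate class), so
  they are always positive definite. The ridge only inflates the
  covariance, which makes the worst-case bound conservative, never
  optimistic.
- **Class imbalance.** Training uses all residues with no subsampling:
  the MPM consumes only per-class moments, so imbalance affects moment
  estimation quality, not the decision rule's form.
- **Score scale and threshold.** Scores are s = Wᵀz − b on standardized
  features with default decision threshold 0. Thresholds for fixed
  false-positive rates are calibrated as the smallest threshold whose
  achieved FPR does not exceed the target, under the strict s > t call
  rule used everywhere (a residue scoring exactly the threshold is not
  called).

## Evaluation

ACC = (TP+TN)/(N_MoRF+N_non), TPR = TP/N_MoRF, FPR = FP/N_non. The source
describing this family of predictors prints FPR as TN/N_non in one
equation; that form is specificity and is inconsistent with every jointly
reported (TPR, FPR, ACC) triple, so the standard definition is
implemented and the printed form treated as a typo. The ROC curve groups
tied scores into single vertices, so its trapezoidal area equals the
pairwise probability that a random positive outscores a random negative
with half credit for ties (verified against brute-force pair counting and
scikit-learn). Metrics-at-fixed-TPR pick the largest threshold whose TPR
meets the target. Evaluation supports a third mask state (−1 = ignored),
used when restricting scoring to short (≤ 30 residues) or long MoRF
regions; ignored residues count as neither positives nor negatives.

## Synthetic corpora

The generator plants MoRF segments whose composition differs from the
background:

- **Sizes.** Defaults: 100 sequences of 150–1000 residues, one MoRF of
  5–25 residues each — matching the scale of curated MoRF corpora
  (average sequence length near 580, ~2% MoRF residues).
- **Compositions.** Background = Swiss-Prot average residue frequencies;
  MoRF target = the background reweighted toward hydrophobic/aromatic
  residues (W, F, Y ×3; I, L, M ×2.5; V ×2; R ×1.3) and away from
  disorder-promoting ones (P, S, G, E, K ×0.5; Q ×0.7), reflecting the
  known enrichment of binding segments relative to disordered context.
- **Effect size** is an exponential-tilt exponent between background and
  target: 0 gives the exact null (a sanity anchor — held-out AUC must sit
  at chance), 1 the realistic default contrast, and the
  `STRONG_EFFECT_SIZE = 2` preset an unambiguous contrast used by the
  end-to-end recovery checks.
- **Placement** is uniform, non-overlapping with at least one background
  residue between segments (touching segments would merge into one
  over-long region), and ≥ 10 residues from sequence ends when length
  permits. Residues are i.i.d. within each region.

What the generator does **not** emulate: Markov or secondary-structure
sequence structure, flank-specific composition gradients, length-dependent
disorder profiles, or homology between sequences. Passing the end-to-end
tests therefore demonstrates that the pipeline recovers a planted
compositional signal — the signal class the method is built around — not
that it reaches any particular accuracy on real proteomes, and the
synthetic scale registry means absolute scores are not comparable to runs
with published scales.

## Problem sizes used in checks

The oracle and recovery checks run at deliberately modest sizes chosen to
exercise every code path: 200 random sequences × 5 window sizes for the
exact averaging equivalence; 10 random instances (d = 2–5) for the convex
oracle; 50 random datasets for the scatter identity; a 12-column pool with
220 enumerable subsets × 100 seeded runs for annealer optimality; 100
score sets for the AUC oracle; and 100 + 100 sequences for the end-to-end
recovery runs.

## Known limitations

- The shipped scale values are synthetic stand-ins; scientific use
  requires real AAindex1/GlobPlot tables.
- The J_d criterion, implemented as specified, cannot distinguish
  labelings; users wanting discriminative selection should pass
  `criterion="trace_ratio"`.
- The MPM is linear; compositional signals that are only separable in a
  nonlinear feature space will be missed.
- Threshold calibration and the worst-case bound both refer to training
  moments; neither guarantees test-set rates under distribution shift.
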