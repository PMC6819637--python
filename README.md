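# morfmpm

Per-residue prediction of **molecular recognition features (MoRFs)** from
protein sequence alone, using a **minimax probability machine (MPM)**.

MoRFs are short segments (typically 5–25 residues) inside longer
intrinsically disordered regions that fold upon binding a partner protein.
Because they are compositionally distinct from both ordered sequence and
their disordered flanks, they can be recognized from sequence features
without structure, alignments, or the output of other predictors — which
keeps the predictor fast, linear, and fully reproducible. This package is
aimed at computational biologists who want a transparent, testable MoRF
pipeline: feature extraction, feature selection, training, scoring and
evaluation are all ordinary library calls with a thin CLI on top.

## Method

**Features.** For each window placed on a zero-padded sequence, 16 feature
values are computed: 13 amino-acid property-scale averages (pads count in
the denominator and contribute zero), a topological entropy of the residue
text normalized to [0, 1], and two disorder propensities. Each residue's
vector is the average of the vectors of all windows covering it; doing
this for a short (10), middle (45) and long (90) window and concatenating
gives a 48-dimensional vector per residue — the short window isolates
MoRF-local composition, the long one captures the flanking context, the
middle one damps long-window noise.

**Feature selection.** Candidate scale subsets are scored by the scatter
criterion J_d = tr(S_w + S_b) and searched by simulated annealing (one
single-feature swap per temperature level, geometric cooling with
T_max = 1, T_min = 10⁻⁴, r = 0.9995, downhill moves accepted with
probability exp(−|ΔJ|/T), best-visited state returned).

**Classifier.** With per-class moments (μ₁, R₁) for MoRF residues and
(μ₂, R₂) for the rest, the MPM minimizes the worst-case misclassification
probability over *all* distributions with those moments:

    min_W  √(WᵀR₁W) + √(WᵀR₂W)   s.t.  Wᵀ(μ₁ − μ₂) = 1

solved by iterative least squares after eliminating the constraint; then
κ* = 1/(√(WᵀR₁W) + √(WᵀR₂W)) and b* = Wᵀμ₂ + κ*√(WᵀR₂W), with
α = κ²/(1+κ²) a guaranteed lower bound on worst-case per-class accuracy.
A residue is called MoRF when its score Wᵀx − b exceeds the threshold
(default 0); thresholds for fixed false-positive rates can be calibrated
on the training set.

The shipped property-scale registry contains **synthetic stand-in values**
(see `docs/methods.md`); point `--scales` at a real AAindex1 file for
production use.

## Worked example

Generate a synthetic corpus with planted MoRF segments, train, predict and
evaluate:

```sh
morfmpm simulate --n 40 --length-range 150 400 --effect-size 2.0 --seed 11 \
    --fasta-out train.fasta --labels-out train.tsv
morfmpm simulate --n 10 --length-range 150 400 --effect-size 2.0 --seed 12 \
    --fasta-out test.fasta --labels-out test.tsv
morfmpm train --fasta train.fasta --labels train.tsv --model-out model.json \
    --calibrate-fpr 0.05 --calibrate-fpr 0.1
morfmpm predict --model model.json --fasta test.fasta --out scores.tsv
morfmpm eval --model model.json --fasta test.fasta --labels test.tsv --tpr 0.5
```

which prints:

```
wrote 40 sequences, 10638 residues (587 MoRF, 5.52%)
wrote 10 sequences, 2663 residues (128 MoRF, 4.81%)
trained on 10638 residues (587 MoRF); kappa=1.6516, worst-case misclassification bound=0.2682
FPR target 0.050: threshold 0.0002 (achieved TPR 0.937, FPR 0.050)
FPR target 0.100: threshold -0.1323 (achieved TPR 0.978, FPR 0.100)
scored 10 sequence(s) -> scores.tsv
residues evaluated	2663
AUC	0.9480
threshold 0	ACC 0.9072	TPR 0.7812	FPR 0.0864
TPR>=0.500	threshold 0.2084	TPR 0.5000	FPR 0.0355	ACC 0.9422
```

`kappa` is the MPM margin: the bound 0.2682 says no distribution with the
training moments can misclassify either class more than ~27% of the time.
The held-out AUC of 0.948 reflects the strong planted contrast
(`--effect-size 2.0`); the calibrated thresholds trade sensitivity for a
fixed training false-positive rate. `scores.tsv` holds one row per residue
(1-based position, score, binary call), suitable for plotting per-protein
score traces.

Feature selection on a labelled corpus (single short window, as used at
selection time):

```sh
morfmpm select-features --fasta train.fasta --labels train.tsv \
    --nfea-range 10 20 --seed 1
```

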