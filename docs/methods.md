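# Methods

## Problem setting

Cell-penetrating peptide identification is a positive-unlabeled problem:
a few hundred verified CPPs against an effectively unlabeled pool of short
protein fragments a thousandfold larger. The package models it as binary
classification at a configurable positive:negative ratio (up to 1:1000),
with the unlabeled pool treated as negative during training and evaluation
focused on ranking quality (AUPR) and precision-side metrics at fixed
recall rather than accuracy.

## Data curation

Inputs are FASTA or id/sequence tables. Curation applies, in order: a
length filter (≤ 50 residues, the working definition of a peptide), a
natural-residue filter (the 20 proteinogenic letters), and a greedy
redundancy filter. The redundancy filter is an approximate stand-in for
CD-HIT clustering: pairwise identity is the number of matched columns in a
global Needleman–Wunsch alignment (match 1, mismatch 0, linear gap −1)
divided by the shorter sequence's length, retention is greedy
longest-first (ties broken lexicographically by sequence then id), and a
sequence is dropped when it reaches the identity threshold (default 0.80)
against any retained sequence. This is reproducible and oracle-checkable;
matching CD-HIT's word-filter heuristics bit-for-bit is a non-goal. The
filter is O(n²·L²) and intended for curated positive sets (hundreds to a
few thousand sequences), not for million-scale pools.

## Feature branches

All three branches end in a `branch_dim`-wide embedding (default 512) and
are concatenated in the fixed order sequential → local → pretrained.

**Sequential.** Residues map to integer tokens through a fixed table
(padding id 0); sinusoidal positional encodings
(`sin/cos(pos / 10000^{2i/d})`) are added to a learned token embedding and
passed through transformer encoder layers (post-norm residual blocks). The
encoder equations and the 512-wide output are fixed by the design, but
depth and head count are free choices; the defaults here are one layer, 8 heads,
d_model 512, feed-forward 2048 — the smallest faithful instantiation —
all overridable. Pooling is mask-aware mean pooling over real positions —
standard, padding-invariant, and consistent with the pretrained branch.
When `d_model ≠ branch_dim` (scaled-down configurations) a linear
projection closes the gap; at the defaults the pooled vector is used
directly.

**Local.** The peptide is assembled as a linear molecule (N→C backbone,
free neutral termini, canonical L-residues, no modifications) via RDKit,
and fingerprinted by the iterative Morgan procedure: initial connectivity
invariants per atom, then per layer a 32-bit hash of the centre label with
its sorted (bond-type, neighbour-label) pairs, out to radius 2, with
duplicate bond-environments suppressed; emitted labels are folded modulo
1024 into a binary vector. The implementation reproduces RDKit's
`MorganGenerator` bit-for-bit (verified on random peptide panels at radii
2 and 3), so RDKit can serve as an independent oracle without being the
implementation. The bit vector is read by a 1-D convolution (kernel 8, 64
channels — a small kernel so the filters capture interactions between
adjacent bits; exact values are tuning), global max-pool, and a dense
projection.

**Pretrained.** A pluggable embedder maps a sequence to an `l × d` matrix
of per-residue states; the branch mean-pools over the true length `l`
(padding never enters) and projects densely. The production backend is
frozen ESM-2 (650M, d = 1280), loaded only if the optional `fair-esm`
package is present; the in-repo backend is a deterministic mock whose row
for position i is seeded by a stable hash of the residue window
`[i−1, i+1]`, giving reproducible, context-sensitive embeddings with no
downloads. The embedder is frozen in both cases; only the projection
trains.

## Classifier and training loop

Concatenated features feed an MLP (input → 256 → 64 → 2, ReLU, softmax);
the 64-wide penultimate layer is exported for embedding visualisation.
Loss is 2-class cross-entropy. Per batch of positives the sampler draws
`K·|P_batch|` candidate negatives uniformly from the pool, scores them
with the **current** model under no-grad (scoring with a stale per-epoch
snapshot would lag the decision boundary the mining is meant to track),
keeps the top `M·|P_batch|` by positive
probability (ties broken by ascending id), and updates on the disjoint
union. Candidate pools are redrawn independently every batch, so a
negative may recur across batches; pools smaller than `K·|P_batch|` clamp
with a warning so small runs stay viable. No class weighting is applied —
the sampler already fixes the 1:M ratio. Uniform mode replaces the
selection with a seeded uniform draw and never invokes scoring.

The optimizer is Adam (lr 1e-3, batch 32 positives, epoch budget 100 by
default). With a validation set, training stops after 10 epochs without a
1e-4 improvement in validation loss and restores the best parameters;
otherwise the final state is returned. On balanced data hard mining is
pointless, so cross-validation trains with uniform 1:1 per-batch sampling
(K = M = 1), bypassing candidate scoring entirely.

All neural components run on a numpy reverse-mode autodiff core written
for this package (no GPU framework is assumed): float64 throughout,
deterministic given seeds, gradients validated against central finite
differences in the test suite. Checkpoints round-trip bit-identically.

## Evaluation conventions

* Prediction rule: positive iff `score ≥ threshold` (ties positive), which
  makes threshold-at-recall well-defined under tied scores.
* `threshold_for_recall` returns the **largest** threshold achieving the
  target recall, i.e. the precision-maximising operating point; candidate
  thresholds are the distinct positive scores.
* AUPR is interpolation-free step summation over distinct thresholds
  (the average-precision convention), verified against exhaustive
  enumeration to 1e-12 and against scikit-learn.
* FP-per-correct is FP/TP (≡ (1−precision)/precision for TP > 0); TP = 0
  reports an `inf` sentinel with a warning. All derived metrics are
  computed from unrounded counts.
* MCC with a zero denominator factor is reported as 0 with a warning,
  avoiding NaN poisoning of cross-validation means.
* Cross-validation aggregates per-fold metrics by unweighted mean (fold
  sizes differ by at most one, so weighting is immaterial).

## Synthetic data

The generator plants the signal that motif analyses report for real CPPs:
positives draw residues from `(1−s)·uniform + s·motif`, where the motif
distribution concentrates on R (0.45), K (0.25), W (0.20) and F (0.10) and
`s ∈ [0, 1]` is the signal strength, with a ≥ 2-arginine constraint
enforced by rejection sampling (forced placement as a fallback). Negatives
are i.i.d. uniform over the 20 residues — an "unlabeled" pool with an
optional label-noise knob that seeds it with latent positives. Lengths are
uniform on (5, 30), the typical CPP range. The benchmark suite fixes 200
train / 50 test positives at ratio 1:100 with full signal strength,
disjoint seeds and id spaces — the independent-test-at-the-same-ratio
protocol at a size that runs on one CPU.

What passing on this generator does and does not show: the positives
differ from the background in residue composition and motif content, which
is the signal the real benchmarks reward, but real peptides have
autocorrelated composition, homology structure and an unknown fraction of
latent positives in the pool; synthetic results therefore validate the
machinery (sampling, optimisation, calibration of the metrics), not
real-data accuracy.

## Scaled-down run configuration

Benchmark and acceptance runs use a desk configuration chosen once for
one-CPU work: d_model 64, 4 heads, feed-forward 128, branch width 64, 16
conv channels, 128-dim mock residue states, MLP 64 → 32, pad length 30,
batch 32 positives, 12 epochs, 3 seeds. The architecture, sampler and
training loop are identical to the full-size defaults; only widths and
epoch counts shrink. The separable-toy check (50 poly-R vs 500 poly-G
10-mers) uses the same configuration with pad length 10.

## Known limitations

* Linear peptides over the 20 natural residues only — no modified,
  cyclic or bicyclic topologies.
* The redundancy filter approximates CD-HIT; cluster assignments can
  differ near the threshold.
* The mock embedder shares the real backend's contract but not its
  biology; conclusions about the pretrained branch's contribution require
  the real ESM-2 weights.
* Training negatives are treated as true negatives; the positive-unlabeled
  bias is mitigated by hard mining but not modelled explicitly.
* The numpy training stack is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not the million-sequence regime.
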