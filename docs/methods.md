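# Methods

## The model

`motifnet` predicts per-region functional readouts (e.g. ATAC-seq open
chromatin region activity across cell types) from DNA sequence through five
blocks whose every trainable parameter has a direct biological reading.

For a one-hot sequence `x ∈ {0,1}^{4×L}`:

1. **Input transform.** `x ← x + p`, with `p ∈ R^L` a learned positional
   profile broadcast across the four nucleotide rows (TFs bind
   preferentially near peak summits). With attention enabled,
   `x_out = x_input + selfAttention(x_input + p)`: the attention term is
   computed on the embedded input but added to the *raw* input, so a
   zero-initialized output projection makes the block start as the
   identity. Attention is scaled dot-product over sequence positions with
   the 4-channel columns as tokens, projected to `attention_dim` (default
   8, single head by default).

2. **Motif scan and calibration.** Valid (no padding) cross-correlation
   with `m` fixed log-odds kernels derived from database PWMs
   (`log((p + ε·bg) / ((1+ε)·bg))`, pseudocount ε = 1e-3, uniform
   background by default). Both strands are scanned and the position-wise
   maximum taken (TF binding is strand-agnostic; `strands="forward"`
   disables this). Raw scores `s` then pass through a per-motif sigmoid
   `σ(a_i s + b_i)`, mapping match scores to occupancy-like probabilities
   in [0,1]. Kernels of different widths are right-padded with exact zeros,
   which are score-neutral under log-odds scoring; all motifs share the
   output length `L' = L − max_width + 1`.

3. **Trainable pooling.** Per-motif softmax pooling over positions:
   weights `w_i = softmax(α_i · q_i)`, pooled value `Σ_j w_ij q_ij`.
   `α_i → 0` is average pooling (site counting), `α_i → ∞` is max pooling
   (strongest-site readout); `α` is initialized at 0.

4. **Interaction gate.** `gate = σ(A · pooled)`, output
   `gate ⊙ pooled`, `A ∈ R^{m×m}`. Entry `A[i,j]` lets motif j's occupancy
   up-/down-weight motif i's effective contribution; column sums of `|A|`
   are a motif's total interaction influence. Applied after pooling, so it
   carries no positional information by construction.

5. **Linear read-out.** `y = B · gated + γ`, `B ∈ R^{c×m}`. `B` *is* the
   motif-by-output effect map; no attribution analysis is needed.

Loss is mean squared error; targets may be raw, per-region z-scores
(population SD across outputs; constant rows are dropped with a warning so
the loss stays defined), or lineage "tree-diff" columns (child minus parent
along a cell-differentiation tree; one column per tree edge).

### Initialization

Every nonlinearity starts in its identifiable, unsaturated regime:
embedding 0; attention output projection 0 (residual identity); `α = 0`
(average pooling); `A = 0` (gate 0.5, a pure rescaling); `B, γ = 0`. The
calibration pair `(a_i, b_i)` is set per motif so that the *expected
background score* maps to σ = 0.1 and the *best attainable score* to
σ = 0.9. Log-odds scores span tens of units, so a unit scale would place
essentially every position — background included — deep in the sigmoid's
saturated tail and erase the match/background contrast before training
begins; anchoring the two ends of the attainable score range fixes this
while keeping the calibration trainable.

## Training protocol

ADAM (β = 0.9/0.999, δ = 1e-8), batch size 128, initial learning rate
0.01, decayed ×0.1 whenever validation loss fails to improve (relative
improvement < 1e-6) for 10 consecutive epochs; training stops once the
rate falls below 5e-7 — with a constant validation loss that is exactly
five decays. The incoming parameter state counts as the incumbent best, so
warm-started refits can never end worse than they started. A fresh
(all-zero) intercept is centered at the training-target mean before
optimization — pooled features are all positive, so without centering the
coefficient matrix has to absorb any common offset in the targets and the
early optimization trajectory distorts badly when per-output means are far
from zero. Kernels are
frozen to the database PWMs in phase 1; optional fine-tuning unfreezes
them for ~10 further epochs under the same validation monitoring, and the
best-validation checkpoint is returned.

Cross-validation splits regions into k = 10 random, balanced folds; each
fold serves once as test, the cyclically next fold as validation, the rest
as training; per-output R² (1 − SS_res/SS_tot around the held-out mean) is
reported as mean ± standard error across folds.

**Small-data adaptation.** The patience schedule presumes epochs of
thousands of minibatch steps. On few-thousand-region datasets an epoch is
a handful of steps, and patience expires while the zero-initialized
read-out is still escaping its plateau. `benchmarks.small_data_schedule`
therefore uses batch 32, lr 0.015, patience 6, stop 1e-6, and a
`warmup_epochs = 40` window during which patience does not count. The
headline defaults are untouched.

## Sparsity: proximal ADAM and the penalty path

Sparsity is imposed on `B` only. After each ADAM update the candidate
iterate passes through a proximal operator with threshold
`τ_i = lr·λ/(√v̂_i + δ)` (the same preconditioner as the step; a config
switch uses raw `v̂` instead). L1 soft-thresholds; MCP (concavity b,
default 3) firm-thresholds — exact zero below τ, a linear b/(b−1)
rescaling in the middle zone, no shrinkage beyond b·τ, which leaves large
selected coefficients nearly unbiased. Note the MCP map is expansive
(slope b/(b−1)) in its middle zone; only the L1 map is globally
1-Lipschitz.

The **penalty path** runs over an increasing λ grid (default log-spaced,
1e-3 to 10, 20 points — the top of the default grid empties the support on
the bundled benchmarks), warm-starting each step from the previous fit.
Because the penalty touches only the final layer, each path step by
default refits `(B, γ)` against the trained model's *fixed* gated features
with a deterministic proximal-gradient iteration (fixed 1/Lipschitz step,
ISTA-style). Two measured failure modes motivated this over continuing
full-model SGD: (i) continued training drifts the network off its
early-stopped optimum, adding validation noise that swamps the sparsity
signal; (ii) the gradient-adaptive threshold degenerates on a converged
batch problem (`v̂ → 0 ⇒ τ → ∞`), making the support oscillate. Features
are standardized inside the linear fit (the usual penalized-regression
convention, and the batch analogue of the preconditioner scaling) so one
threshold is commensurate across motifs; coefficients are mapped back to
the original scale. `final_layer_only=False` restores the full-model path.

**Selecting λ.** `PathResult.best_index(tol)` returns the validation-loss
minimizer (tol = 0), or with tol > 0 the largest λ within a relative
`tol` of the minimum — the parsimony idea behind the one-standard-error
rule, appropriate because validation profiles along these paths are flat
until the penalty starts removing real effects. Benchmarks use tol = 0.02.

## Interpretation reports

All reports are direct functions of trained parameters: row-normalized
final-layer coefficients (scaled to [−1,1] preserving zeros), top-k motif
lists, the fold inclusion ratio (fraction of CV folds where a motif ranks
in the top-k |coefficients|; ties break by stable library order, which
matters once thresholding produces exact-zero ties), pooling temperature
vs. motif information content with a Spearman correlation (flagged
degenerate when either vector is constant), interaction influence (column
sums of |A|), kernel drift after fine-tuning (per-entry MSE over valid
positions and the nearest initial kernel by ungapped correlation), and
median motif redundancy along the penalty path (per selected motif, the
maximum similarity to the other selected motifs; undefined for supports
smaller than two). Motif similarity uses external TOMTOM log10(E-values)
when provided, otherwise a built-in fallback — best ungapped-alignment
Pearson correlation over all offsets and both orientations, with a
minimum-overlap of 4 columns so a single coincidental column cannot claim
a perfect match. The two conventions have opposite orientations; the
`SimilarityMatrix` carries an explicit flag and reports stay on the input
scale.

## Synthetic data generator

Background sequences are i.i.d. uniform ACGT (a GC-skewed background is a
config option). Each planted motif receives, per region, an insertion
count that is 0 with probability 0.5 and otherwise uniform on
{1..max_count} (default 3); sites are *sampled from the PWM* (not the
consensus), placed at non-overlapping uniform offsets on a random strand,
and every insertion is logged (region, motif, offset, strand, bases).
Activity is `Σ_i effect_i · signal_i + Σ interactions + N(0, noise_sd)`,
where a motif's signal is its presence indicator ("max" mechanism) or its
insertion count ("count"), and an interaction term multiplies a gated
motif's signal by a gater's presence. Sampling sites from the PWM gives
graded match scores, so the calibration layer is genuinely exercised.

What the generator does *not* emulate: real peak-length and accessibility
distributions, GC/repeat structure, co-occurring motif grammars with
positional syntax, or chromatin context. Passing recovery tests therefore
demonstrates that the architecture and optimizer identify planted effects,
mechanisms, interactions and redundancy under realizable conditions — not
that they will do so on any particular real dataset.

## Recovery benchmarks (and the sizes they run at)

Problem sizes are chosen so each study runs in minutes on one CPU while
staying in the regime where training converges reliably.

- **Effect recovery** — m = 20 random motifs (width 8), n = 2000 regions
  of L = 200 bp, c = 3 outputs, two planted motifs per output with effects
  ±1, noise SD 0.3; standard schedule, then the MCP path (b = 3). At the
  selected λ the top-2 |B| per output must be the planted motifs with
  planted signs (precision@2 and sign agreement of 1.0); motifs whose
  fallback similarity to a planted motif exceeds 0.8 collapse into it, so
  database-style redundancy is not counted as error.
- **Mechanism recovery** — m = 6, n = 800, L = 100, noise SD 0.1; the
  causal motif is the library's highest-IC motif; two arms identical up to
  the activity rule (count × 0.5 vs presence × 1.0). Across 5 seeds the
  median learned α of the causal motif is smaller in the count arm.
- **Interaction recovery** — m = 8 (width 10, pairwise similarity < 0.5),
  n = 1000, L = 140, max_count 2; direct effects ±1 on two motifs; one
  gater with no direct effect gating two motifs with strengths ±1.2 (its
  marginal effect cancels). The gate matrix trains in a second phase after
  the direct pathway converges. Across 5 seeds (majority): |A[gated,
  gater]| exceeds the 95th percentile of non-interacting |A| entries, the
  gater's interaction influence ranks in the top 3 (median), and its |B|
  stays below the direct-effect motifs'.
- **Redundancy pruning** — a library of five near-duplicate pairs
  (`perturbed_copy`, 15% uniform mixture; exact copies would give
  identical gradients and never break symmetry), two pair-members planted
  (+1/−1), n = 1000, L = 120; MCP path over 12 λ. Median max-similarity
  among selected motifs is non-increasing along the path (majority of
  seeds) and ends below its start; at the selected λ a planted pair is
  pruned to one member (majority).

## Numerical notes and degenerate inputs

- Strand-max ties route gradients to the forward strand; softmax pooling
  is computed with the max-subtraction trick; sliding windows turn the
  motif scan into one matrix product per batch.
- Zero-variance activity rows are dropped at z-scoring (logged); constant
  pooled features get coefficient zero in the path's linear refit (they
  are unidentifiable next to the intercept).
- All-zero coefficient rows are left untouched by normalization; top-k
  ties break by library order and the behavior is documented rather than
  randomized, so fold inclusion ratios are reproducible.
- Fits are bit-reproducible given a seed (single-threaded numpy,
  `default_rng` throughout; the run seed drives shuffling, attention
  initialization, and the generator).

## Known limitations

- The interaction gate is global (post-pooling): it cannot represent
  distance- or orientation-dependent motif syntax, and it is shared across
  outputs.
- Desk-scale training of a model whose read-out starts at exactly zero has
  a real plateau; the warmup window mitigates but does not eliminate it —
  an occasional seed still converges to the intercept-only solution, which
  is why multi-seed benchmarks assert medians/majorities.
- The built-in similarity fallback is a correlation score, not a match
  *statistic*; it orders motif pairs sensibly but its scale is not
  comparable to TOMTOM E-values.
- With kernels frozen, model capacity is bounded by the motif library;
  effects of motifs absent from the library are invisible by construction.
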