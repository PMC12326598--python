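# Methods

This note documents the models, parameters, numerical choices and known
limitations of `toxembed`, in the spirit of a model-description appendix.

## Problem setting

We model molecules against P binary toxicity endpoints with labels
y_np ∈ {0, 1, missing}. Assay panels are sparse: a molecule is typically
measured against a small subset of tasks, so every count, loss and metric
in the package is defined over *observed* entries only. Endpoints are
rare-positive (prevalences of a few percent are normal for liver
endpoints), which drives three design pillars: an imbalance-aware loss
family, precision–recall-first evaluation, and diagnostics that expose
majority-class bias.

## The loss family

The training objective for binary heads is the weighted focal loss

    w⁺_p = α · N_p⁻ / N_p⁺ + (1 − α),  α ∈ [0, 1]
    ℓ_np = w⁺_p (1 − σ(f_np))^γ y_np (−log σ(f_np))
         + σ(f_np)^γ (1 − y_np)(−log(1 − σ(f_np)))

with logits f_np, per-task positive weights derived from observed counts,
and focusing exponent γ ≥ 0. The family collapses exactly (to machine
precision, tested) to focal loss at α = 0, class-weighted BCE at γ = 0,
and plain BCE at α = γ = 0.

Sign convention: the per-entry quantity is the *negated* log-likelihood
term, so losses are non-negative and the BCE reduction holds; a raw
(unnegated) sum of log-probabilities would be ≤ 0 and could not reduce to
the usual cross-entropy.

Reduction: the default is the mean over observed entries, which makes the
loss magnitude invariant to batch size and missingness pattern;
`reduction="sum"` gives the literal double sum. Missing labels contribute
zero loss and zero gradient. Tasks with no observed positives have an
undefined inverse-ratio weight; they are reported with weight NaN and a
warning (weight 1 is used inside training so that their negatives still
contribute).

Numerical safety: all log-probabilities go through the stable
log-sigmoid (−softplus(−f)); probabilities are never clipped. For γ > 0
the focal factor is computed as a plain power; its derivative at a
saturated probability is flushed to zero rather than propagated as
inf · 0.

## Pretraining

The encoder is a pre-norm bidirectional transformer over SMILES tokens
(regex tokenization: bracket atoms, two-letter halogens and %nn ring
closures as single tokens), with learned token and position embeddings.
Full-scale geometry is the conventional BERT-base 12 layers / 12 heads /
768 hidden / 128 max length; the desk-test preset is 2 layers / 4 heads /
64 hidden. The sentence-level summary is either a learned tanh pooling of
the first position (full-scale default) or the mean over non-pad
positions. At desk scale the learned first-position pooler is a
measurable optimization bottleneck (it roughly halves the in vitro
training AUPR reachable in a few epochs compared with mean pooling), so
the desk-scale experiments use mean pooling; both are config options.

Each batch is processed twice. The corrupted pass masks each non-special
token independently with probability 0.15 (every selected token becomes
the mask token; the BERT-style 80/10/10 split is available behind a
flag) and feeds the masking head: linear → GELU + layer norm → one
further encoder layer → vocabulary projection. The clean pass feeds the
pooled vector to the physicochemical head (one hidden layer, regression
on z-scored RDKit descriptors, squared-error loss summed over properties
and averaged over molecules) and the in vitro head (one hidden layer,
binary logits per assay). The in vitro head is trained with the weighted
focal loss at fixed α = 1, γ = 2. The total loss is the arithmetic mean
of the enabled head losses. Disabling the in vitro head recovers the
purely chemical (mask + physchem) pretraining mode; the encoder is
otherwise identical.

Optimization is Adam with linear warmup over the first 1% of steps and
global gradient-norm clipping at 1.0. Full-scale defaults (lr 3e-5,
batch 32) follow BERT practice; desk-scale runs use lr 1e-3 to 1.5e-3.
Training aborts with a diagnostic on a non-finite loss. A scaffold-
disjoint validation fold is reserved before training and the per-epoch
history records masked-token accuracy, physchem loss and in vitro AUPR
on it. Checkpoints embed the encoder config and vocabulary, so they are
self-describing. Loading external pretrained weights is supported
through the same checkpoint mechanism but the tested path is random
initialization.

The whole neural stack (reverse-mode autodiff, transformer, Adam) is
implemented in NumPy inside the package. Graph tensors default to
float32 for CPU throughput; the engine can be switched to float64, which
the test suite uses for finite-difference gradient verification of every
layer type.

## Downstream protocol

Downstream molecules are embedded once with the frozen encoder (eval
mode, deterministic). The head is a multitask MLP with one hidden layer
(batch norm, ReLU, dropout), a skip connection that concatenates the
input with the hidden activations, and a sigmoid output per task.

Hyperparameters — the loss-family point (α, γ) shared across tasks, and
weight decay — are selected by inner K-fold cross-validation on the
non-test scaffold folds, scored by mean validation AUPR, with early
stopping (patience 10) on the same quantity. The winning setting is
retrained on all non-test data for the mean best-epoch count, and the
scaffold test fold is scored exactly once. Scrambling the test-fold
labels provably changes nothing about selection (tested).

Baselines follow the identical protocol on 1024-bit ECFP fingerprints
(diameter 6 / radius 3): a Random Forest per task with task-specific
settings chosen by inner-CV AUPR, and the same multitask MLP head.

## Scaffold splitting

Molecules are grouped by Bemis–Murcko scaffold (canonical SMILES of the
scaffold; acyclic molecules share the empty scaffold and therefore one
group). Groups are packed greedily, largest first with seeded tie order,
each into the currently smallest fold — so scaffolds never straddle
folds and fold sizes are near-equal. The test fold is the one with the
most *distinct* scaffolds, i.e. the most chemically diverse; ties break
toward the lowest fold index.

## Evaluation

AUPR is the area under the step-wise precision envelope over recall
(precision interpolated as the maximum over higher recalls), the
standard choice that avoids the optimism of linear PR interpolation.
ROC-AUC uses the trapezoid rule; MCC thresholds probabilities at 0.5.
Single-class tasks are flagged, not scored. Two diagnostics accompany
the metrics: per-task positive/negative log-losses (whose gap exposes
majority-class bias; summarized by a 95% covariance ellipse over tasks
— a covariance ellipse, not a bootstrap region), and the Spearman
correlation of per-task AUPR with positive ratio (imbalance
sensitivity).

## The synthetic generator

The generator emulates the statistical structure of sparse bioassay
panels, not their chemistry:

- **Molecules** are assembled from ~35 ring cores (benzene, pyridine,
  pyrimidine, five-membered heteroaromatics, saturated rings,
  ring-linker-ring systems, a few acyclic cores) × ~28 substituents,
  validated and canonicalized with RDKit; duplicates are discarded. This
  guarantees chemical validity and enough Bemis–Murcko diversity
  (roughly 30 scaffold groups) for scaffold-split testing.
- **In vitro tasks** follow a logistic model on a sparse random subset
  (default 8) of circular-fingerprint bits with weight scale β = 4. The
  planted bits are radius-1 bits in a mid-frequency window (5–95%):
  atom-neighborhood substructures that recur across scaffolds, which a
  2-layer encoder can genuinely recover at desk scale; radius-3
  environments are too scaffold-specific for transfer to be measurable
  at this size. The logistic intercept is bisected against the realized
  Bernoulli draw so the observed prevalence lands on the target; label
  noise then flips an exact fraction of each class (the pre-noise target
  is compensated accordingly), and missingness hides an exact fraction
  of each class. Together these keep observed prevalence within ±0.02
  of the target even at n = 500.
- **In vivo endpoints** have log-odds equal to a coupling-weighted sum
  of a few standardized latent in vitro activities plus Gaussian noise
  (sd 0.5), thresholded at the task's prevalence quantile (defaults
  0.02–0.2, mimicking rare liver endpoints). A dose/time readout table
  is emitted whose any-exceedance binarization against the shipped
  expert thresholds reproduces the binary labels exactly.
- Latent activities and planted bits are stored with the corpus so tests
  can probe the coupling directly.

What the generator does *not* emulate: real potency distributions,
assay-panel correlation structure beyond the planted bits, dose–response
monotonicity, severity ontologies, or inter-laboratory noise. Passing
the embedding-utility experiment on these fixtures demonstrates the
pipeline's mechanics — that in vitro supervision injects transferable
signal into embeddings when the downstream endpoints are genuinely
coupled to it — not that the same margin would be observed on any
particular real assay panel.

## Desk-scale problem sizes

The test suite runs the full pipeline at reduced scale, chosen so the
whole suite completes on one CPU core in well under half an hour: corpora
of 300–2,000 molecules, the 2-layer/64-hidden encoder preset, 8
pretraining epochs, and a disjoint 400-molecule downstream panel for the
transfer experiment (pretraining and downstream compound sets are
disjoint, mirroring the intended use where pretraining corpora dwarf the
labeled endpoint sets). The embedding-utility comparison averages over 5
seeds of the full pretrain → embed → probe pipeline on a fixed corpus.

## Expert thresholds

Default biochemistry binarization thresholds ship as an editable YAML
(fold-of-control elevation: ALT/AST/GTP 2.0; ALP/TC/TG/TBIL/DBIL 1.5).
They are deliberately user-facing configuration, not constants: real
studies set these per protocol. The histopathology pooling reducer
(any-exceedance vs max-severity) is likewise configurable; endpoint
columns are kept only when positive in at least 5 unique compounds.

## Known limitations

- The NumPy training stack is single-core and float32; it is meant for
  desk-scale encoders (≤ a few hundred thousand parameters), not the
  85M-parameter full-scale geometry, which the config nevertheless
  describes faithfully.
- The downstream transfer margin at desk scale is small: about half an
  AUPR point averaged over 5 seeds, with individual seeds swinging by
  ±0.02. An oracle analysis (logistic probes on the true latents,
  perfect binary in vitro calls, untrained embeddings and raw
  fingerprints) bounds the achievable advantage at roughly +0.04 AUPR
  under the default generator conditions — at these corpus sizes purely
  chemical embeddings already carry most of the recoverable fragment
  signal, so the in vitro advantage is a shift, not a leap, and only
  the seed-averaged comparison resolves it.
- Tokenization covers organic-subset SMILES; stereochemistry tokens are
  carried but no stereochemistry-aware augmentation is done.
- `imbalance_sensitivity` requires ≥ 3 scored tasks; with constant AUPR
  the rank correlation is undefined and flagged.
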