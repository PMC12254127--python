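# Methods

## The prediction problem

CRISPR/Cas9 editing efficiency depends jointly on the guide (sgRNA) and on
which engineered Cas9 variant performs the cut.  Models trained per variant
need large per-variant screens and transfer poorly to new variants.
`casguide` implements a dual-input regression model: the guide sequence and
the variant's full protein sequence are encoded by separate branches, mixed
by a learned per-sample gate, and mapped to a predicted activity.  Because
the variant enters through its amino-acid sequence, a single cross-variant
model can pool guides from every variant and make predictions for variants
with few or zero labelled guides.

## Model

**Guide branch.**  A guide record is 59 nt: a 20-nt protospacer, a 3-nt
PAM (NGG), and a constant 36-nt scaffold.  It is one-hot encoded over
(A, C, G, T, N) into a 59x5 matrix and passed through a dual-path CNN: one
single convolution and one stack of three convolutions, each kernel 5,
padding 2, 64 filters, sigmoid activation, so both paths preserve the 59
positions and emit 59x64 maps.  The two maps are concatenated (59x128),
flattened (7552), passed through a 2048-unit sigmoid layer and linearly
projected to the 256-wide representation `H_RNA`.

**Protein branch.**  A variant's protein sequence (1368 aa for SpCas9
variants) is embedded per residue into an L x D matrix (D = 1280 by
default, the per-residue width of the ESM2-650M protein language model)
and condensed by a multi-scale TextCNN: parallel convolutions of widths
{5, 9, 13}, 128 ReLU filters per scale, global max pooling per filter, a
384-wide concatenation, and a sigmoid fully connected layer to the
256-wide `H_pt`.  `H_pt` must be 256 wide because the fusion below is a
convex combination with `H_RNA`.

**Fusion and head.**  The concatenation `[H_RNA, H_pt]` (512) feeds a
two-layer gate (hidden width 128, ReLU; output sigmoid) that produces one
scalar weight `w` per sample, and the fused representation is
`w * H_RNA + (1 - w) * H_pt` — coordinatewise between the two branch
vectors by construction.  A 256→128→1 head with a final sigmoid yields the
predicted activity on a [0, 1] scale.  Activity targets are min-max scaled
to [0, 1] per training set (the sigmoid head bounds the output); the
scaler is stored in the checkpoint and inverted at prediction time.

**Training.**  MSE loss, Adam, cosine-annealing learning-rate schedule
with warm restarts (the rate returns to its maximum at the start of each
cycle).  Full-scale defaults: learning rate 1e-4, batch 256, 100 epochs,
cycle 5.  Records from all variants are pooled and shuffled into every
batch; per-variant protein representations are computed once per batch for
the variants present.  When a validation split is provided, the checkpoint
with the best validation Spearman is kept.  An exhaustive grid search over
learning rate {1e-4, 5e-4, 1e-3, 5e-3} x batch {64, 128, 256, 512} x
epochs {50, 100, 200} is available and ranks configurations by validation
Spearman; a diverging configuration is scored -inf instead of aborting the
search.

## Embedder backends

The protein embedder is pluggable.  The default `StubEmbedder` maps each
residue (optionally a k-residue context window) through a seeded hash to a
fixed pseudo-random 1280-vector; it is deterministic across machines,
needs no network or checkpoint, and satisfies the only contract the
architecture relies on (an L x D per-residue matrix in which sequence
changes change the corresponding rows).  `Esm2Embedder` wraps a real ESM2
checkpoint when the `esm` package is installed.  Embeddings can be cached
on disk keyed by backend name and sequence digest.  The stub embedding
carries no biophysics: passing tests with it demonstrates the machinery
(variant-conditioned pooling, gating, training), not that real
evolutionary embeddings transfer — that claim needs the real backend and
real screens.

## Variant construction

Variants are ordered lists of point substitutions in `R661A` notation
(1-based, case-normalized).  Application validates the reference residue
at every position against the parental template and fails hard on
mismatch, which catches a wrong parent early.  `diff_sequences` inverts
the operation and is used as the round-trip verification.  The seven
built-in SpCas9 variants (wild type, SpCas9-HF1, eSpCas9(1.1), HypaCas9,
SniperCas9, evoCas9, xCas9) carry their published mutation lists; none of
their positions overlap, so application order is immaterial (asserted for
disjoint positions only).  The real wild-type SpCas9 sequence is not
bundled; synthetic parents carry the correct reference residues at all
registered positions.

## Evaluation protocols

Spearman rank correlation is the primary metric, computed with
average-tie ranks (reducing exactly to the classical
`1 - 6*sum(d^2)/(n(n^2-1))` form when tie-free).  Datasets are split
7:1:2 (train/validation/test) by a seeded permutation with
floor-then-largest-remainder allocation — deterministic sizes, e.g. 1000
-> 700/100/200.  Three deployment scenarios are modelled over a
collection of per-variant datasets, with "small" meaning a total below a
configurable threshold (default 1500): well-established (train and test
on large datasets), newly-identified (train on all training splits, test
on small-variant test splits), newly-discovered (train on large-variant
training splits only, test on the *same* small-variant test splits, so
the two scenarios are directly comparable).  Per-dataset split seeds are
derived from the run seed and the dataset name, which is what guarantees
that shared test memberships coincide.

## Feature descriptor

The 175-feature handcrafted descriptor per guide: 4 mononucleotide +
16 dinucleotide + 64 trinucleotide raw counts on the protospacer
(frequency switch available), GC content, six melting-temperature
features, and 84 position-specific indicators (4 nucleotides x 21
positions: protospacer 1-20 plus the variable PAM base).  The exact
grouping reproduces the named families and is versioned; it is flagged
provisional in the sense that other groupings also sum to 175.  Tm uses
nearest-neighbor thermodynamics with the unified DNA stack parameter set
(SantaLucia 1998): stack enthalpies/entropies summed over adjacent
dinucleotides, terminal initiation terms, the 0.368*(N-1)*ln[Na+] entropy
salt correction, and Tm = 1000*dH/(dS + R ln(C_T/x)) - 273.15 with
defaults 25 nM per strand and 50 mM Na+.  The sixth Tm feature is the
empirical Marmur-Doty GC-corrected estimate.  An 'N' in the analysed
region is an error by default (configurable zero-fill).

## Motif enrichment

Guides are split at the median activity; strictly-above goes high, ties
fall low (deterministic, robust to the skewed activity distributions of
editing assays).  For each position and nucleotide the low group supplies
the background frequency and the high group is the foreground; the score
is the signed log10 binomial tail probability (positive -log10 P(X >= k)
for enrichment, negative log10 P(X <= k) for depletion), with a
Bonferroni line at alpha = 0.05 over positions x 4 tests and probabilities
floored at 1e-300.  A zero background frequency for an observed foreground
nucleotide falls back to a +1 pseudocount with a warning.  The default
analysis window is the 23-nt protospacer+PAM region, where activity
determinants concentrate; the scaffold is constant in generated data and
carries no signal.  This statistic is the same family as pLogo-style
sequence-logo tools but is computed in-package; exact numeric parity with
any external service is not claimed.

## Synthetic data

The generator emulates a multi-variant activity screen with known ground
truth: protospacers uniform over {A,C,G,T}, PAM = N + GG, constant
scaffold, and activity = logistic(beta_gc*(GC - 0.5) + planted motif
effects + per-variant shift + Gaussian latent noise).  Defaults — 500
guides per variant, beta_gc = 4, a four-position motif with effects
+-0.8, variant shifts spread over [-1, 1], noise_sd = 0.3 — give a
realistic signal-to-noise regime: the rank-correlation ceiling between
noiseless and observed activity is about 0.96.  What it does *not*
emulate: chromatin/position effects, assay-specific measurement error,
non-additive sequence epistasis, and any real coupling between protein
mutations and guide preference (variant effects are additive shifts).
Passing recovery tests therefore shows the estimator recovers planted
additive structure, not that it predicts real screens.

## Numerical choices

All network arithmetic is float32.  Weights use uniform fan-in
initialization with activation-dependent gain (4 for sigmoid — the
classical slope compensation without which a deep sigmoid stack contracts
inter-sample signal geometrically; sqrt(2) for ReLU; 1 for linear),
biases start at zero, and the gate's output layer starts at exactly zero
so fusion begins neutral (w = 0.5).  Sigmoid pre-activations are clipped
at +-15: outputs then stay strictly inside (0, 1) in float32 and the
derivative never vanishes exactly, so a saturated unit — in particular a
collapsed fusion gate, which otherwise severs the guide branch — remains
recoverable by Adam.  Global max pooling breaks ties by first index
(NumPy argmax).  Training aborts with a diagnostic on a non-finite loss.
Determinism: a single integer seed fixes initialization, batch shuffling
and the generator; repeated runs on one machine are bit-identical.

## Desk-scale benchmark conditions

The acceptance-level model runs use the fixed conditions in
`casguide.benchmarks`: four toy variants on a 240-aa synthetic parent,
stub embeddings of width 128, 500 guides per variant (the small-variant
regime subsamples one variant to 150 guides, leaving a 30-guide test
split), and optimization settings selected once by a small
validation-Spearman grid in the spirit of the full-scale grid search.
These sizes keep a full recovery run in minutes on one CPU while leaving
the planted structure comfortably recoverable.

## Known limitations

* The stub embedder is a determinism device, not a protein model;
  zero-shot transfer to unseen variants is only as meaningful as the
  embedder, and with the stub it only demonstrates the machinery.
* The all-sigmoid guide CNN (as specified) trains slowly under small
  learning rates; memorization-style fits need either more steps or a
  larger rate than the full-scale defaults.
* The fusion weight is a scalar per sample, not per-dimension.
* Insertions/deletions in variant definitions are out of scope; only
  substitutions are supported.
* The 175-feature list reproduces the named families and the total; the
  segment boundaries of the Tm features are a documented package choice.
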