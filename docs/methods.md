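# Methods

## The SND transform

Each sample is treated as a self-contained measurement: only the ordering
of its own gene values is trusted, never their absolute scale. For a
sample measuring n genes, the transform (i) builds a sorted n-element
standard-normal reference set, (ii) ranks the sample's values, and
(iii) assigns the gene of rank r the r-th reference value. The intuition
is the one behind ΔΔCt-style relative quantification: a gene's standing
relative to the rest of the same sample is the portable signal.

Two reference-set modes exist. `quantile` (default) uses the
mid-probability quantiles Φ⁻¹((i + ½)/n), which are deterministic,
symmetric about 0, and make the transform bit-reproducible — the mode all
tests and invariants use. `sampled` sorts n standard-normal draws from a
seed, which matches the idea of literally generating an N(0, 1) value
array; it is retained for fidelity but nothing in the package depends
on it.

After the rank mapping, genes are re-ordered onto a fixed reference gene
list (RGL) so that coordinate i means the same gene in every sample. The
RGL is built by sorting genes ascending by their aggregate (mean by
default) expression in an anchor subtype of a reference cohort; ties
break lexicographically by gene ID so the list is unique. RGL genes
absent from a sample receive 0 — the N(0, 1) median, so fills sit
mid-distribution rather than at an extreme — and sample genes absent from
the RGL are discarded. When a sample shares only m < n genes with the
RGL, the reference set is rebuilt at size m (same mode and seed), so a
short targeted panel still spans the full N(0, 1) range instead of a
truncated slice of it. The order of operations is rank → map → re-order →
fill.

Ties are ranked ordinally with RGL position as the tie-break. This keeps
the transform deterministic and preserves the exact-multiset property
(every complete sample carries precisely the reference values); mid-rank
averaging would trade that property for tie symmetry, and with continuous
expression values ties are rare enough that the trade is not worth it.
Non-finite inputs are rejected rather than silently ranked.

Properties the test suite asserts: bit-identical invariance under any
strictly increasing per-sample map; Spearman correlation 1 with the input
for tie-free samples; idempotence on complete samples; and exact
conservation of the reference multiset.

## Expression images

A unified vector of n genes is reshaped row-major into a side × side
array with side = ⌈√n⌉; the unused tail is padding (0 by default). The
11,234-gene transcriptome intersection gives 106 × 106 with 2 pads, a
770-gene panel 28 × 28 with 14 pads. Row-major RGL order is a convention,
not a claim — any fixed fill order works, but it must be the *same* order
for every sample and every model, which is why the embedding refuses
nothing except empty or non-finite vectors and guarantees exact
round-trip on the first n entries.

## Classifiers

**Dense (DNN).** A standard MLP: ReLU hidden layers, softmax output,
cross-entropy loss, SGD with momentum, fitted by scikit-learn's
`MLPClassifier`. The default spec records the full-transcriptome
configuration (hidden layers 760 and 120, learning rate 0.005, 2 epochs ×
5 iterations — "iterations" is exposed as an integer multiplier on
epochs, the reading that matches optimizer frameworks which count the two
separately). For the 200-gene synthetic cohorts the experiments use a
proportionally smaller spec (64/32 hidden units, learning rate 0.01,
40 total passes); input width always follows the data. The spec's
`dropout` field is accepted for configuration compatibility but only 0 is
supported by this backend; a positive value raises rather than being
silently ignored.

**Convolutional (CDNN).** A 5-layer stack — two valid convolutions with
ReLU, one 2 × 2 max-pool (stride 2), one dense ReLU layer, one softmax
output — implemented in numpy with minibatch SGD + momentum. Defaults:
5 × 5 × 16 then 3 × 3 × 32 kernels, dense width 120, learning rate 0.02,
60 epochs, momentum 0.9, He-normal initialisation. These defaults were
fixed on the separable synthetic cohort (below), where the net reaches
≥ 0.95 held-out accuracy against a nearest-centroid oracle at ≈ 1.0; a
narrower 8/16-channel stack plateaued just below that bar. Kernels are
clipped to the current feature-map size and pooling is skipped when the
map is smaller than the window, so degenerate inputs (single-gene 1 × 1
images) still train — and, as a sanity check, score at chance.

**Protocol.** Splitting follows the validation-first convention: a 10%
validation set (when requested) is drawn before the remaining samples are
shuffled 70/30 into train/test. Sizes are round-half-up of the fractions;
stratified mode applies the same arithmetic within each class, keeping
proportions within ±1 sample. All splits, initialisations and minibatch
orders derive from explicit seeds; `MLPClassifier` and the numpy convnet
are both exactly reproducible given the seed on a fixed BLAS.

Models serialize with a format tag, a version number and their spec;
loading verifies all three, and a dense model cannot be loaded as a
convolutional one.

## Evaluation

Per-subtype accuracy is the row-normalized diagonal of the true ×
predicted confusion matrix, reported in percent: a subtype with row
(52, 1, 0, 4) scores 52/57 = 91.23%. Classes with no evaluated samples
are reported as undefined (None), never as 0. Aggregates over model or
dataset collections use the arithmetic mean and the *sample* standard
deviation (n − 1 denominator) — the convention that reproduces published
mean ± SD rows from their per-dataset values, which the population SD
does not. Inter-labeling consistency is the fraction of common samples
assigned the same label by two independent labelings; per-class values
condition on the first labeling (of the samples study A called c, the
share study B also called c), matching how such comparisons are reported.
All values are kept at full precision internally and rounded to two
decimals only for presentation.

The multi-model report evaluates every model on every dataset, averages
per-class accuracies over all cells in which the class occurs, and flags
the class with the lowest model-averaged accuracy. That weakest-class
readout is the incompatible-subtype detector: a label whose samples are
drawn from other classes' distributions cannot be learned, so it
surfaces as a persistent per-class accuracy floor rather than a random
dip.

## The synthetic cohort simulator

**Latent model.** Gene g in a sample of class c is

x_g = μ_g + Δ·σ·1[g ∈ S_c] + ε,  ε ~ N(0, σ²),

with per-gene baselines μ_g ~ N(8, 1) on a log2-intensity-like scale,
noise σ = 1, disjoint 20-gene signatures S_c, and effect size Δ = 1.5
(in units of σ) by default. This is the simplest structure that yields
unimodal, roughly Gaussian per-sample distributions — the regime in which
mapping ranks onto a normal reference preserves the overall shape and the
original-vs-SND scatter is a monotone S-curve — while giving classifiers
a realistic many-weak-features signal. At Δ = 1.5 a nearest-centroid
oracle on the latent data scores ≈ 1.0, so classifier failures are
attributable to the platform distortions, not to inseparability; Δ = 0
collapses everything to chance, and oracle accuracy is monotone in Δ.
The default cohort is 4 classes × 60 samples over 200 genes.

**Platform views.** A view is a strictly increasing map of the latent
values plus additive Gaussian noise. The map families are affine, power
on shifted positives, saturating logistic, and monotone piecewise-linear;
non-monotone parameterisations are rejected at construction. Noise is
specified *relative* to the mapped values' SD (default 0.2), because the
maps change output scale by orders of magnitude — an absolute noise level
would silently give each platform a different signal-to-noise ratio. The
three default platforms emulate the ways real pipelines actually differ —
in offset, scale and curvature at once: a rescaled log intensity
(affine, a ≈ 0.7, b = −2), an unlogged intensity riding on a large
additive background ((x − x_min + 40)^2.5, values in the thousands), and
a sharply saturating bounded score (logistic at the baseline midpoint,
scale ≈ 0.5). The magnitudes were chosen so the simulator reproduces the
qualitative regime the method addresses: nets trained on one platform's
raw features fail on another (large offsets and scale changes defeat a
ReLU net far more reliably than curvature alone, which a scale-robust
network can shrug off), while the SND route is unaffected by
construction. With zero noise, every view's SND equals the latent SND
bit-for-bit — the simulator's central test.

**Incompatible subtype.** `inject_mixture_subtype` appends samples that
carry a new label but are *generated from the existing classes' models*
(donor class drawn per mixing weight, uniform by default; 60 samples by
default). The new label thus has no distribution of its own — which is
precisely what makes it incompatible with the classification system, and
reproduces the phenomenon of a subtype that every trained model
classifies poorly while the remaining subtypes stay accurate. The
construction is recorded in `truth_meta` (label and per-sample donors) so
tests can audit it.

**What the simulator does not emulate.** Real gene identities and
signature sizes, correlated (co-expressed) gene modules, copy-number or
mutation structure, class imbalance, batch effects that are *not*
monotone per sample (e.g. per-gene centering, which breaks the rank
premise), and any clinical covariate structure — the IDH-status metadata
column is exercised only as a generic binary filter. Passing tests
therefore show that the pipeline behaves as designed under its own
assumptions (per-sample monotone distortions of a rank-separable signal),
not that those assumptions hold for any particular real cohort.

## Study protocols and problem sizes

The three end-to-end readouts in `sndsubtype.experiments` run on the
default suite — 200 genes, 4 × 60 samples (+ 60 mixture samples where
noted), 3 platforms, Δ = 1.5, platform noise 0.2 — sizes chosen so each
protocol completes in seconds-to-minutes on one CPU while the qualitative
orderings remain stable across seeds:

* **Cross-platform transfer** trains the same dense architecture twice on
  platform 1 (stratified 70% split): once on raw features, once on
  SND-unified features (RGL anchored on class C1, from the training split
  only), and scores both on all of platform 2. The SND arm sits near
  100%; the raw arm ranges from chance to ~70% depending on the seed's
  optimizer trajectory, a 30–75-point gap.
* **Incompatible-subtype detection** unifies the mixture cohort, embeds
  15 × 15 images, trains three seeded convolutional nets on a stratified
  70% split, and averages per-class test accuracies over models. The
  mixture label scores ~10–25% against ~75–85% for the real classes, and
  is the strictly weakest class in every development seed.
* **Pooling** compares one dense net trained on platform 1's SND view
  against one trained on platforms 1+2 pooled, both scored on held-out
  platform 3, on the mixture-containing cohort (like the real
  multi-subtype datasets; without the incompatible class the synthetic
  task saturates and leaves nothing to improve). Because the pooled views
  are the same latent samples under different distortions and noise,
  pooling acts as data augmentation. Accuracies are averaged over three
  seeded trainings per condition, as in the multi-model protocol;
  the improvement is ≈ +0.3 to +2 points and was positive in every
  development seed.

`scripts/acceptance.py` runs all three (suite seeds derived from
`--seed`), plus the worked accuracy example, the published-aggregate
reproduction, the invariance residual and the embedding arithmetic, in
about half a minute.

## Known limitations

* The SND transform discards all magnitude information; signals carried
  by absolute expression level rather than rank are invisible to it.
* Average-rank tie handling is intentionally unsupported; heavily tied
  data (e.g. zero-inflated counts) will have ties resolved by RGL
  position, which is deterministic but arbitrary.
* The dense backend has no dropout; regularisation is limited to early
  stopping by epoch budget.
* The numpy convnet is adequate for the tens-of-pixels images used here
  but makes no performance claims at 106 × 106 transcriptome scale with
  thousands of samples.
* Model files are Python pickles: versioned and type-checked on load,
  but not a cross-language interchange format, and (like all pickles)
  only to be loaded from trusted sources.
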