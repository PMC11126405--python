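# Methods

`cnclust` assigns breast-cancer Integrative Cluster (IntClust) labels 1–10 to
tumor samples from copy-number data alone. The pipeline has four stages:
feature-region derivation, cohort-wise feature scaling, intra-class outlier
cleaning, and a hierarchical boosted-tree classifier. This note records the
model, its assumptions, the tunable parameters, and the design choices made
where the design was genuinely open.

## Feature regions from class-average segmentation

For a labeled reference cohort sharing one probe grid, the per-class average
log-ratio profile is computed locus by locus (arithmetic mean over the class's
samples, ignoring missing probes; a median option exists). Each class average
is segmented per chromosome with an exact penalized piecewise-constant fit
(PCF): over all partitions of the ordered signal into contiguous segments of
length ≥ `kmin`, the fit minimizes

    sum over segments of SSE(segment) + gamma * (number of breakpoints),

where SSE is the within-segment sum of squared deviations from the segment
mean. The optimum is found by Bellman dynamic programming in O(n²) with O(1)
cost queries from prefix sums, so it is exact and testable against exhaustive
enumeration. Ties are broken toward fewer segments, then toward the earlier
last breakpoint, which makes the output deterministic. Missing probes are
skipped in the cost but keep their grid positions. Segmentation never crosses
a chromosome boundary.

Breakpoints live between probes; the base-pair cut is the floored midpoint of
the flanking probes, which makes the derived regions grid-independent and
therefore applicable to cohorts profiled on other platforms. The union of all
classes' internal breakpoints, deduplicated per chromosome, cuts the observed
chromosome extent into abutting regions (per chromosome: #unique internal
breakpoints + 1 regions). No telomere/centromere masking is applied. A
sample's feature vector is the mean of its non-missing probe values per
region; a region containing no observed probe is a missing feature, which the
classifier accepts natively.

**Penalty default.** `gamma` trades off fidelity and parsimony on the scale of
the *class-average* profile, whose probe noise is the per-sample noise shrunk
by 1/√(class size). The pipeline default is `gamma = 0.5`, `kmin = 3`: with
per-probe noise sd around 0.2 log-ratio units and classes of ≥ 40 samples, a
spurious breakpoint buys an SSE reduction well below 0.1, while a genuine
aberration boundary of height Δ ≥ 0.4 spanning ≥ 10 probes gains ≥ 1.4. Both
parameters are exposed everywhere; noise-free validation runs use
`gamma = 0.01`, `kmin = 1` to recover breakpoints exactly.

## Cohort-wise scaling

Platform, assay chemistry and tumor cellularity rescale and shift measured
log ratios roughly affinely at cohort level. Each cohort — including the
training cohort — is therefore z-scored per region with its *own* mean and
standard deviation (population sd; zero-spread regions are flagged and given
spread 1). For any cohort-wide transform `a·x + b` with `a > 0` the scaled
feature matrix is unchanged up to floating-point error, so downstream
predictions are platform-invariant in exactly that sense. The cost of this
choice is that scaling needs a cohort: classifying a single sample is
unsupported (a floor of 3 samples is enforced, and reliable moments need
more).

## Intra-class outlier cleaning

Before training, each class's samples are scored with the Local Outlier
Factor (LOF, k = 20 neighbors, Euclidean metric on scaled region features;
delegated to scikit-learn, verified against a naive all-pairs reference in
the tests) and samples with LOF > 1.5 are removed. Scoring is strictly within
class, so removal in one class never alters another's scores. Classes with
≤ k + 1 members are skipped. Missing features are median-imputed per class
for the distance computation only. Defaults k = 20 and threshold 1.5 are
conventional LOF settings; on clean synthetic cohorts nothing is removed,
which is the expected behavior of a filter.

## The 6-class + binary-reclassification cascade

Four pairs of IntClusts with near-identical copy-number profiles — (1,5),
(3,8), (4,7), (9,10) — are merged, giving six levels
{"1/5", "2", "3/8", "4/7", "6", "9/10"}. A 6-class gradient-boosted tree
model (XGBoost, softmax, multiclass log-loss) predicts the merged level; a
sample landing in a merged pair is resolved by that pair's binary model,
trained only on the pair's samples with the lower-numbered class encoded 0.
The binary decision threshold is 0.5; an exact tie goes to the
higher-numbered class (documented, arbitrary). A flat 10-class model is
provided as the architectural comparator.

Composed 10-class probabilities distribute each merged probability over its
pair as (1 − p, p) from the binary model and copy singleton probabilities;
they sum to 1 by construction. The final label is defined by the cascade
decision path, not by the composed argmax: when the merged argmax is weak,
the two can disagree (a merged winner resolved near p = 0.5 can compose below
a singleton runner-up). On well-separated data they coincide, and that
consistency is asserted empirically in the tests.

**Hyperparameters.** Defaults: max_depth 4 (multiclass) / 3 (binary),
learning rate 0.1, 200 rounds, subsample 0.8, colsample_bytree 0.5, L2 1.0.
The aggressive row/column subsampling is deliberate: because features are
cohort-wise z-scored, their absolute location drifts slightly from cohort to
cohort (different realized class mixtures move the per-region moments), and
an ensemble that pins one region against a tight threshold misroutes samples
under that drift, whereas one that spreads its votes over correlated regions
does not. Optional random search (default 50 trials; depth 2–10, learning
rate 0.01–0.3 log-uniform, 50–500 rounds, subsampling 0.5–1, L2 0–5) selects
configurations by stratified 5-fold cross-validation — per class, samples are
shuffled and dealt round-robin, so each fold holds out 20% with equal class
distribution — minimizing mean multiclass log-loss, or RMSE of the predicted
probability for the binary models (selection metric only; the binary training
objective is logistic, both recorded in bundle metadata). All seeds (split,
folds, search, model) are explicit, and results are byte-reproducible on one
platform with a single thread.

## Evaluation

The confusion matrix (rows = true, columns = predicted) is reported as counts
and as a row-normalized percentage view whose diagonal equals per-class
recall. Per class, one-vs-rest recall, precision, specificity, balanced
accuracy ((recall + specificity)/2) and F1 are computed, with 0/0 reported as
undefined (excluded from macro averages with a count) rather than coerced to
zero. Overall summaries report micro (pooled counts), macro and
support-weighted variants side by side, each labeled — for single-label
multiclass prediction micro recall, precision and F1 all equal accuracy, so
a "micro" precision differing from "micro" recall signals a different
averaging convention, and the package refuses to guess one. The multiclass
Matthews correlation coefficient uses the K-class marginal formula with
degenerate denominators reported as 0.

## Synthetic cohorts

The generator emulates the statistical geometry the classifier targets, not
breast-cancer biology. A deterministic grid of 2,000 probes spans 23
chromosomes (autosomes + X) proportionally to length — a desk-scale stand-in
for array resolution. Each merged group receives 8 mutually disjoint aberrant
segments of 10–60 probes with levels ±1.0 (sd 0.1 jitter) in log-ratio units;
paired classes share that backbone and the higher-numbered class adds
`pair_delta = 0.4` on 3 extra disjoint segments, so `pair_delta = 0` makes a
pair statistically indistinguishable. Segments within a class are disjoint by
construction so every realized level change is large, which is what makes
noise-free breakpoint recovery exact. Samples are
`a · (archetype + N(0, σ)) + b` per probe with σ = 0.2 by default,
`pair_delta = 2σ`; attenuation applies to signal and noise together, so a
re-measured cohort is an exact affine image of the original under the same
seed (the invariance cohort scaling removes). Missing probes are masked
uniformly at random (2%). Class proportions default to an uneven mixture of
the shape seen in large breast-cancer cohorts; the pair-degenerate control
uses balanced proportions so that within-pair chance is exactly 0.5 (under an
uneven mixture a prior-learning binary model scores the majority prior
instead). A second platform is emulated by thinning the grid 2× and jittering
probe positions, with its own attenuation/offset/noise.

What the generator does **not** emulate: real driver loci and their
correlation structure, heavy-tailed or wavy (GC-driven) noise, segment-length
distributions of real arrays, cellularity mixtures within a cohort. Passing
tests therefore demonstrate the pipeline's correctness and its platform- and
pair-structure behavior, not clinical accuracy on real cohorts.

## Problem sizes used in validation

Simulation-based checks train on 1,000 samples and classify 500 (1,000 for
the degenerate-pair control), across five generator seeds for the recovery
check; segmentation exactness is verified against exhaustive enumeration for
signals up to length 12, and LOF against a naive reference up to n = 200.
These sizes were chosen so the whole validation runs in minutes on one CPU
while keeping every class populated under the uneven mixture.

## Known limitations

* Cohort-wise scaling precludes single-sample classification.
* Exact PCF is O(n²) per chromosome — appropriate for array-resolution or
  binned profiles, not for multi-million-probe grids.
* The merged pairs are fixed to the published four; other pairings would
  require retraining and a code-level change of the label scheme.
* Composed 10-class probabilities are a derived diagnostic, not calibrated
  posteriors.
* Region boundaries depend on the reference cohort's labels, grid and the
  segmentation penalty; they are not uniquely recoverable quantities.
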