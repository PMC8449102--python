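# Methods

## The encoding model behind the synthetic data

The analyses in this package test a linear-encoding hypothesis: that the
neural response to a word is, in some set of cortical sources and some time
window, a linear function of that word's position in a semantic feature
space. The synthetic generator realizes exactly this hypothesis so that the
decoder and the RSA have a known signal to recover.

For word *w* with embedding vector `e_w ∈ R^D`, the clean source signal at
vertex *v* and time bin *t* is

    s(v, t, w) = g(t) · (W e_w)_v

where the encoding weights `W` (vertices × D, standard normal on the active
vertex set, zero elsewhere) are **shared across subjects** and the temporal
gain `g(t)` is an indicator of the active time window. Each subject's data
adds independent unit-variance Gaussian noise at every (word, vertex, bin).
Sharing `W` while drawing noise independently is what lets the group-level
one-sample *t* statistic accumulate over subjects; with subject-specific
weights the group RSA would have no common signal to average.

A single scalar **snr** controls difficulty: the clean signal is rescaled so
that its standard deviation over the active vertices × active bins × words
equals `snr` against the unit noise. `snr = 0` produces pure noise (the
weights are zeroed, so the ground-truth invariant "inactive rows are zero"
extends to everything), and `snr = inf` produces noiseless data with unit
signal s.d. No claim is made that any particular snr matches the effect
size of real recordings — the published analyses give no estimate of it —
so the defaults are conventions chosen to exercise both the chance regime
and the recovery regime.

Sensor data is `L @ source` per bin, upsampled to the sampling rate by
zero-order hold, where the leadfield `L` has standard-normal gains
attenuated by `exp(−d/4 cm)` with `d` the sensor–vertex distance; sensors
sit on a sphere 20% outside the head. Sensor noise s.d. is the projected
signal s.d. in the active window divided by snr. This is deliberately not a
physical forward model (no dipole orientations, no volume conduction): it
preserves the two properties the decoder cares about — linear mixing and
distance-dependent channel selectivity — and nothing else.

The mesh places vertices on two hemispheric half-sphere caps (head radius
9 cm) with a Fibonacci spiral, the left hemisphere an exact mirror of the
right about the mid-sagittal plane; adjacency is symmetrized 6-nearest
neighbours within hemisphere. Embeddings are two isotropic Gaussian
clusters (abstract/concrete) whose centroids are separated by
`cluster_separation` within-cluster standard deviations along a random
direction; ratings are 7-vs-1 category-typicality values with Gaussian
jitter clipped to [1, 7].

### What the generator does not emulate

Real evoked responses have temporally autocorrelated, spatially structured
noise, subject-specific anatomy and leadfields, amplitude non-stationarity
and artefacts; real embedding spaces have heavy-tailed, anisotropic cluster
structure. Passing recovery tests on this generator therefore shows the
*inference machinery* is correct (calibrated under the null, able to locate
a genuinely linear signal), not that real data contains such a signal or
that real effect sizes are attainable.

## Decoder

Features are channel × bin values, binned into half-open 20-ms bins
`[start, start + 20)` (the defaults 0–800 ms give 40 bins; a sample at
exactly 800 ms falls outside), concatenated per item and column z-scored
with the population (1/n) standard deviation; constant columns map to zero
columns rather than being dropped, preserving feature geometry. Following
the emulated pipeline, scaling statistics are computed on the full item set
before the leave-two-out splits — a known leakage concern that we reproduce
deliberately; `fold_safe_scaling=True` recomputes them inside each training
fold.

The ridge solution is computed in closed form from the SVD of the centered
feature matrix (spectral filter `s/(s² + α)`; at `α = 0` the minimum-norm
pseudoinverse). The penalty defaults to `α = 1.0` on z-scored features —
the published analysis does not state its value, and a fixed default keeps
runs reproducible — with `alpha="gcv"` selecting it per training fold by
generalized cross-validation over a log grid `1e-3 … 1e3`.

Because the held-out predictions are linear in the training targets, each
pair's fit reduces to two target-independent "hat" vectors
(`ŷ_i = h_i @ Y_train`). These are computed once per feature matrix and
reused across label permutations, so the 1,000-permutation chance
calibration costs one matrix product per permutation instead of
n(n−1)/2 refits.

Scoring ties (the two assignments exactly equal) count 0.5, keeping the
chance expectation exactly 50%. The permutation p-value uses the add-one
estimator `(1 + #{null ≥ observed}) / (1 + n_perm)`, which can never be 0;
the chance threshold reported is the empirical 95th percentile of the null.
The "overall" (non-time-resolved) accuracy uses all 40 bins concatenated.
Sliding windows move in steps of one bin and are reported at the mean of
their bin centers.

## RSA

Neural DSMs use `1 − Pearson r` between the single-bin spatial patterns of
a searchlight patch (Euclidean, same-hemisphere, radius 2 cm by default);
model DSMs use `1 − r` between embedding vectors or `|s_i − s_j|` for the
1-D abstractness score. DSM invariants (symmetry, zero diagonal, metric
range) are asserted on construction. Comparisons are Spearman correlations
of the vectorized upper triangles; the partial variant applies the
three-variable partial-correlation formula to the triangle ranks.

Degenerate patterns: requesting a DSM of a constant row raises an error
naming the item (surfacing misconfigured simulations), but the searchlight
map assembly records undefined correlations as NaN markers instead —
noiseless simulations legitimately produce all-zero patches outside the
active set, and a map with undefined margins is more useful than a crash.
NaN elements contribute t = 0 and can never enter a cluster.

Cluster inference follows the standard sign-flip scheme: one-sample *t*
over subjects per (vertex, bin); suprathreshold elements (one-sided
`cluster_p = .01` quantile of the t distribution) joined by mesh edges
within a bin and consecutive bins within a vertex (no diagonal moves);
cluster statistic = summed *t*; null = maximum cluster statistic under
independent per-subject sign flips (5,000 by default). Only positive
clusters are formed. Retention uses the add-one permutation p ≤ alpha,
which is marginally more conservative than pruning at the empirical
1 − alpha null quantile. Sums of squares are sign-invariant, so all
permutation t maps are obtained with a single matrix product.

Small-subject caveat: with *S* subjects there are only 2^S distinct flip
patterns, so attainable p-values are coarse — below ~8 subjects a genuine
cluster often cannot reach p ≤ .05. Demonstrations that should retain
clusters use 8+ subjects; the study-scale default is 20.

The Mantel test permutes rows and columns of the second DSM jointly. A
joint permutation only reindexes the triangle entries, so their ranks are
computed once and gathered per permutation; the p-value is two-sided on
|rho| with the add-one estimator.

## Reduced problem sizes

The test suite and the acceptance script run everything at desk scale as
the package's own choice of default verification sizes: decoding
calibration at 40 items × 200 features (20 noise realizations),
family-wise-error simulation on a 24-vertex mesh × 5 bins × 20 subjects
with 400 sign flips per run, Mantel uniformity at 200 items × 200
permutations, and signal recovery at 24 words / 64 vertices per hemisphere
/ 4 subjects. The study-scale defaults (118 words, 300 dims, 20 subjects,
204 channels, 2 × 2,562 vertices) remain the config defaults and run
through the identical code paths.

## Known limitations

* The searchlight feature vector spans a single time bin; a multi-bin
  temporal extent is not implemented (the per-bin maps plus temporal
  clustering cover the same inferential ground).
* No geodesic patch distances, no anatomical labelling, no inter-subject
  morphing: synthetic subjects share one mesh by construction.
* The permutation calibration permutes labels of the dataset it is given;
  group-level designs that permute within a randomly chosen subject can be
  composed from it but are not built in.
* `alpha="gcv"` is unavailable inside the permutation calibration: the
  penalty choice would otherwise depend on the permuted labels and bias the
  null.
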