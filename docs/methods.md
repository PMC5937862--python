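# Methods

## Scope and data flow

`chlorosom` implements the analysis chain used in nutrient-deficiency
phenotyping from fast chlorophyll *a* fluorescence: raw OJIP transients →
JIP-test parameters → difference bands → multivariate grouping (PCA,
hierarchical k-means, ANOVA + Tukey letters) → multilayer SOM
classification. A synthetic-cohort generator stands in for measured data;
it is first-class, tested code, and its defaults define the conditions
under which the test suite's end-to-end claims hold.

## Acquisition grid

The timing grid mirrors a Handy-PEA-class instrument: 10 µs sampling from
10 µs to 0.3 ms inclusive (30 points), then logarithmically decreasing
frequency to the 1 s recording end (88 points), 118 points in total. The
2 ms, 30 ms and 300 ms marker times are snapped onto the nearest
logarithmic grid members so that all five OJIP anchors (20 µs, 300 µs,
2 ms, 30 ms, 300 ms) are exact grid points; marker intensities are
therefore read by exact lookup, never interpolated. Off-grid input files
are resampled onto this grid by linear interpolation at read time.

## JIP test

The standard Strasser formula set (see README) with these conventions:

* **F_M** is the curve maximum (first occurrence), not the value at a
  fixed 300 ms; the time of the maximum is kept for QC and serves as the
  P anchor of the I–P phase.
* **M_o** is reported per millisecond (the factor 4 corresponds to the
  0.25 ms separation between the O and K steps).
* **Area above the curve** is the trapezoid of (F_M − F(t)) from 20 µs to
  t(F_M) on the non-uniform grid; it feeds only S_m and the turnover
  number N, both of which are convention-dependent and excluded from any
  cross-study comparison.
* Degenerate inputs fail loudly: a non-rising transient (F_M ≤ F_o), a J
  step at F_o or F_M (V_J ∈ {0, 1}), or V_I = 1 raise typed errors;
  batch processing reports failed samples alongside the parameter table
  rather than dropping them.

## Difference bands

Double normalisation W = (F − F_start)/(F_end − F_start) between marker
pairs O–K, O–J, J–I, I–P; the I–P end anchor is the per-sample time of
maximum. Group curves are normalise-then-average (the pointwise mean of
member W curves, restricted to the shortest member window for I–P), and a
difference band is W_group − W_control with positive values meaning the
group rises earlier than the control. The K step is fixed at 300 µs, the
standard JIP convention.

## Multivariate stages

* **PCA** operates on the correlation matrix (features are z-scored with
  sample SD), because element contents, soil properties and JIP parameters
  have incommensurable units. Loadings are reported as feature–component
  correlations (biplot arrows); each component's sign is fixed so its
  largest-magnitude loading is positive.
* **Hierarchical k-means** initialises Lloyd iterations from the centroids
  of a Ward-tree cut (Euclidean distance), runs to a 1e-10 relative WSS
  change or 300 iterations, breaks ties toward the lowest centroid index
  and re-seeds an emptied cluster with the farthest point. `k="auto"`
  maximises the Calinski–Harabasz index over k = 2..8. The pipeline
  clusters the PC scores of the components with eigenvalue > 1 (at least
  two).
* **ANOVA/Tukey** uses the classical one-way F test and Tukey HSD adjusted
  p-values; compact letters are assigned by insert-and-absorb in
  descending group-mean order, and an invariant test checks letters
  against the full adjusted-p matrix.

On realistic cohorts the Calinski–Harabasz choice frequently returns 3
rather than 5: the element table genuinely contains two to three
macro-clusters (the Mn- and Fe-rich classes versus the rest), with the
finer severity structure emerging only at the SOM stage. This matches how
such experiments typically unfold and is why the pipeline's class count is
a separate setting (`class_k`, default 5) applied to the SOM codebooks,
not to the element table.

## Multilayer SOM

A 9×4 hexagonal grid (36 units, odd rows offset by half a unit, so all six
neighbours of a unit sit at planar distance 1; units are named 1A…9D by
column digit and row letter). Each data layer — LEC (9 elements), ChlF
(8 parameters), one-hot class — has its own codebook; a sample's BMU
minimises Σ_l w_l · d_l / n_l where d_l is the squared Euclidean distance
on z-scored features and n_l is the layer's mean pairwise training
distance. The normalisation keeps a layer's influence independent of its
dimensionality and scale; the class layer's conventional weight is 0.5 and
it is never used at prediction time.

Training is online Kohonen learning: 100 epochs, learning rate decaying
linearly 0.05 → 0.01 per presented sample, presentation order reshuffled
each epoch from the model seed. The neighbourhood is a truncated Gaussian
h = exp(−d²/(2(r/2)²)) for d ≤ r (0 beyond), with the radius r decaying
linearly from ⅔ of the grid diameter to 1; the truncation and the σ = r/2
scale make the final phase sharpen the map rather than smooth it.
Codebooks initialise from training rows sampled without replacement
(seeded); with fewer samples than units the fallback is uniform draws
within feature ranges, with a warning. Training lowers the quantization
error below its initialisation value in the intended regime (samples well
in excess of 36 units); when n is comparable to the unit count the
sampled-row initialisation is already a near-memorisation of the data and
no topology-preserving map can match it — the test suite asserts the
contract at cohort scale (300 samples).

Codebook classification runs hierarchical k-means on the concatenated
codebooks, each layer scaled by √(w_l/n_l) (the BMU metric). With k = 5
the clusters are named by two heuristics, both overridable: the
Fe-specific class is the nutrient-rich cluster (above-average N and K
cluster means, z-scored across clusters) whose Fe is lowest relative to
that richness; the remaining clusters are named no / slight / moderate /
strong in descending order of codebook-mean PI_total. A simpler
"lowest absolute Fe among rich clusters" rule misassigns whenever cluster
boundaries straddle the generating groups, which is why the relative
(z-score) form is used.

## Synthetic cohorts

Five frozen class profiles (reference values for young greenhouse
rapeseed) give mean ± SD for nine leaf elements and eight ChlF parameters
per class. Per sample, a latent severity factor g ~ N(0,1) enters every
feature with loading 0.6 and sign matching the feature's deficiency
direction; the residual loading 0.8 keeps marginal SDs at the profile
values. This single-factor structure is what gives cohorts their PCA /
clustering / SOM gradient; real leaf data has richer covariance
(element-specific antagonisms, measurement batch effects) that the
generator does not emulate, so passing tests demonstrate pipeline
correctness and recoverability of a planted structure, not field
performance. Truncations keep samples physical: element contents positive,
φ_Po in [0.15, 0.90] (below ~0.15 there is essentially no variable
fluorescence and every JIP ratio estimator is ill-conditioned), yields in
(0, 1), δ_Ro < 1 jointly with V_I < 1.

Raw transients are synthesised by inverting the JIP formulas: targets
F_o, F_M = F_o/(1 − φ_Po), V_J = 1 − φ_Eo/φ_Po, V_I = 1 − δ_Ro(1 − V_J)
come from the sampled yields. The initial slope cannot simultaneously
honour the profile's tabulated ΔV/Δt₀ and PI_total under the standard
formula set (the two are mutually inconsistent there, as the tabulated
ABS/RC magnitudes already suggest); the generator derives M_o from the
sampled PI_total — the severity axis of the entire analysis — rescaled by
a common factor 8 into the instrument's typical per-ms range and floored
at 0.5/ms for numerical conditioning. The common scale preserves the
PI_total severity ordering exactly (a noiseless transient's recomputed
PI_total is the sampled value divided by the scale); the tabulated
ΔV/Δt₀ group pattern is the one profile entry not reproduced.

The curve itself is four smooth saturating segments
s(x; c) = (1 − e^{−cx})/(1 − e^{−c}) in log-time fraction between
consecutive anchors, flat at F_M beyond 300 ms. The O–K curvature c rises
with class severity (2.0 → 6.0) and the I–P curvature falls (2.0 → 0.8),
encoding the antenna-connectivity loss (positive, growing L bands) and the
slower PSI-acceptor refilling (negative I–P bands) that stressed leaves
show. Multiplicative Gaussian noise (default SD 0.5%, a realistic SNR for
this instrument class; 2% is used in the test suite as a stress level)
is applied per point.

## Pipeline

Stage order: ingest → SNR screen → JIP parameters → standardise → PCA →
h-k-means element grouping → ANOVA/Tukey per element → SOM training
(LEC + ChlF + class layers) → codebook classification → ChlF-only
per-sample prediction → difference bands of each predicted class against
the predicted no-deficiency class → report. The SNR screen rejects
transients whose O–K rise is below 4× the plateau-noise estimate (SD of
first differences at t ≥ 0.4 s): such curves — in practice moribund
leaves — make 1/M_o and the O–K normalisation denominators heavy-tailed,
and field protocols discard them too. Noise-free curves always pass.
Every stage writes its intermediate table; failures abort with the stage
name; reruns refuse to overwrite without `--force`; a JSON-lines log
carries seed, versions and timings (the only non-deterministic output).

## Problem sizes and determinism

The test suite's end-to-end checks run the full pipeline on 5×30 cohorts
over ten fixed seeds and the recovery checks use 200 synthetic transients;
these sizes make the whole suite complete in about a minute on one core
while leaving the stochastic margins well clear of their thresholds. All
randomness flows from single integer seeds through `numpy`'s Generator;
identical seed and data give byte-identical reports, codebooks and class
maps.

## Known limitations

* The generator's single-latent-factor covariance is a stated stand-in;
  no claim is made about real within-group element covariance.
* ChlF-only classification separates the extreme classes cleanly
  (strong-deficiency recovery ≈ 95–100%), but the no-deficiency,
  Fe-specific and slight-deficiency profiles overlap substantially in
  fluorescence space at the profiles' stated dispersions; even a
  supervised discriminant trained on the true labels stays below ~70%
  for the no-deficiency class alone. Reported accuracies for the extremes
  are therefore pooled.
* S_m and N depend on the area convention and should not be compared
  across implementations.
* No PAM/quenching analysis (φ_PSII, qP, NPQ, ETR) and no instrument
  drivers or proprietary binary formats; input is delimited text.
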