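# Methods

## The model

`icawave` extracts heartbeat features by independent component analysis in a
wavelet coordinate system.  The generative picture is

    X = A S H + E

where the rows of `X` (|D| × d) are beat windows of `d` samples aligned on
the R wave, `H` (r × d) is a coefficient matrix derived from a Daubechies
wavelet transform, the rows of `S` (q × r) are component patterns expressed
in those coordinates, the columns of `A` (|D| × q) are per-beat mixing
coefficients, and `E` is residual noise.  `A` is what a classifier sees:
the feature vector of a beat is its row of `A`, computed per class and
concatenated in the fixed order N, S, V, F (the four AAMI beat groups —
normal, supraventricular ectopic, ventricular ectopic, fusion).

Fitting proceeds per class:

1. express the class's beats in the wavelet coordinates, `Y = X H⁺`
   (the exact transpose when `H` has orthonormal rows);
2. centre and whiten `Y` to `q` dimensions across the beat axis
   (equivalently, Hotelling PCA of the r coordinates);
3. maximize the negentropy of the per-beat scores by the symmetric
   fixed-point iteration with the log-cosh contrast
   (`J(x) = (E[log cosh x] − E[log cosh ν])²`, ν standard normal, the
   reference expectation computed once by quadrature to 1e-12), with
   symmetric decorrelation each step;
4. store the composed linear map `projection = H⁺ · unmixing`, so a test
   beat's features cost one `d × q` product — no wavelet transform is
   evaluated at test time, which is the source of the method's
   `n · C · max_c(q_c)` inference cost.

Maximizing output negentropy is equivalent to minimizing the mutual
information of the outputs; both estimators (histogram mutual information
with Freedman–Diaconis binning, and the log-cosh negentropy) are exposed and
tested independently.

### Orientation of the factorization

The matrix equation above does not by itself say which axis carries the
independence assumption.  This package computes independence **across
beats**: the columns of `A` are the independent variates (with as many
samples as the class has beats), and `S` holds the component patterns.  This
is the standard orientation of ICA-based feature extraction — each beat gets
a score per component — and it is the orientation under which blind-source
recovery is statistically well-posed here: the alternative (independence
across the `r` wavelet coordinates) leaves only `r ≈ 162` samples to
estimate the contrast and measurably cannot reach the recovery accuracy the
package's own tests demand.  The synthetic mixture generator draws both
factors from the chosen source family (Laplace by default) so that the
factorization is identifiable along the beat axis.

### How H injects information

A square orthogonal wavelet matrix would be a pure rotation of the beats;
whitening absorbs rotations, so ICA under such an `H` is *identical* to
plain ICA up to initialization.  For the wavelet to contribute, `H` must be
information-bearing.  The default `H` is therefore the **truncated**
level-ordered transform: the approximation band (all rows except the finest
detail band) of the `J`-level Daubechies-6 pyramid.  The fit then runs in a
smooth wavelet subspace aligned with beat morphology; the finest-scale
coefficients — which at 360 Hz carry mostly broadband noise — never enter
the component estimation.  `wavelet_feature_basis(..., keep="all")` restores
the square transform for experiments that need a pure rotation (e.g. the
mixture-recovery tests).

## Wavelet machinery

Filters db1–db10 are the standard orthonormal Daubechies pairs (taken from
PyWavelets' coefficient tables; the high-pass is constructed as the
quadrature mirror `g_k = (−1)^k h_{L−1−k}` and both invariants
`Σh = √2`, `‖h‖ = 1` are asserted).  The transform matrix `L` stacks
stride-2 circular shifts of `h` over shifts of `g`; levels compose as a
pyramid and are densified in level order (approximation first, details
coarse to fine) — the package's fixed, invertible reading of the sparse
banded form.  Boundary handling is periodic, keeping `L` square and
orthogonal, so `L Lᵀ = I`, perfect reconstruction and Parseval hold to
rounding error and are enforced in tests.

Exactness requires `2^J | d`; the default depth is the largest `J ≤ 3` the
window length supports (`J = 1` for the default `d = 162`).  Padding
schemes that force deeper decompositions were rejected because truncating
padded coefficients breaks orthogonality, and every downstream guarantee
(dimensionality of `H`, energy conservation, clean pseudo-inverses) leans
on it.

### Density-window alternatives

Six unimodal density shapes can replace the wavelet taps in the same
two-band construction (`density_basis`): Poisson (continuous argument,
factorial via Γ), double-exponential, Student-t, normal, lognormal
(evaluated from `t = 1`; the first window index cannot be 0) and
log-logistic.  Parameters are auto-fitted so the mode sits on the R wave;
shapes are rescaled to unit maximum before entering the basis because only
the shape matters in the mixing-matrix role.  Two of the printed source
formulas are not usable as densities (one multiplies a Gaussian kernel by a
chi-square draw, one is a CDF); the package implements the corresponding
standard densities and keeps the verbatim variants behind a
`garbled=True` flag for reproducibility.

## Preprocessing

All filters are zero-phase (forward–backward Butterworth): any phase lag
would displace the R apex from the window centre and corrupt the phase
shift α, to which feature quality is demonstrably sensitive.  Two separate
concerns are split deliberately: the 5–15 Hz band-pass is the detector's
QRS-enhancement filter, while the analysis path removes baseline wander by
subtracting a < 0.5 Hz low-pass estimate, preserving QRS amplitudes within
a few percent.

R waves are found by the Pan–Tompkins cascade: band-pass → derivative →
squaring → 150 ms moving-window integration → adaptive dual thresholds with
search-back (refractory period 200 ms, search-back at half the signal
threshold — standard constants).  Detections are refined to the apex of the
baseline-removed signal within ±50 ms, because the window is centred on the
apex itself.  Thresholds adapt multiplicatively, making detection invariant
to amplitude scaling.

Beats are half-open slices `[r − ⌊d/2⌋, r − ⌊d/2⌋ + d)` in 0-based sample
coordinates; windows that cross the record boundary, and peaks without an
annotation within 150 ms, are dropped with logged counts.  The phase-shift
coefficient is `α = |t_R − t_{d/2}| / ⌊d/2⌋` — zero when the R wave sits at
the window middle, symmetric in early/late shifts.

## Synthetic data

The generator emulates the study conditions, not physiology.  Beats are
sums of Gaussian bumps for P, QRS and T with class-specific modifications
(S: no P wave; V: widened QRS — width scale 2.5 — and inverted T; F:
intermediate between N and V), sampled at 360 Hz with `d = 162` windows.
Default conditions, chosen once: 0.05 mV additive white noise, 5 % per-wave
amplitude jitter, 20 subjects with individual amplitude/width/T-wave
multipliers (so subject-aware cross-validation has real subject structure),
and class probabilities from the reference corpus imbalance
(N : S : V : F = 90632 : 2779 : 7129 : 803).  Records place beats at
lognormal RR intervals around 0.8 s clipped to 0.4–1.5 s, plus sinusoidal
baseline wander (0.1 mV around 0.2 Hz), 60 Hz powerline interference and
optional white noise at a target SNR.

What this does *not* reproduce: real morphology variation within a class,
inter-beat correlation (e.g. bigeminy), non-stationary noise, electrode
artefacts, or the pathology-dependent relation between rhythm and shape.
Passing results on this generator therefore demonstrate correctness of the
machinery and the *direction* of the method's claims, not clinical
performance; absolute scores here are higher than on real data.

The mixture simulator draws `X = A S H + E` directly with unit-variance
Laplace (super-Gaussian, the identifiable default) or uniform
(sub-Gaussian) factors and records the ground truth, enabling Amari-index
and source-correlation recovery checks.

## Evaluation harness

Metrics are the confusion-derived percentages (accuracy, recall,
specificity, precision and BAC = (recall + specificity)/2, the primary
score under imbalance).  Ratios with empty denominators are reported as
missing, never as zero, so macro averages on small sets are not silently
deflated.  Cross-validation folds partition subjects greedily
(largest-first, minimizing class-proportion divergence with a size-balance
penalty; the first k subjects seed one fold each), and no subject ever
appears on both sides of a split.  Five folds is the default.  Paired
feature-extraction variants are compared with the two-sided Wilcoxon
signed-rank test on per-fold macro BAC (exact null for ≤ 25 pairs, zero
differences dropped); pairing per fold, rather than per beat, is the
package's choice of comparison unit.

Classifier families follow the usual small grids (kNN with k ∈ {3,5,7} and
three metrics; SVC over C/kernel/gamma; CART; Gaussian naive Bayes; MLP
with depth 3–10, standard activations and the usual alpha/momentum sets —
the grid is a cleaned-up version of the study's list, which mixes loss and
activation names).  Hyperparameters are selected inside the training fold
only.  The package's own comparison experiments fix kNN (k = 3) across all
feature variants: the comparison is between feature spaces, and a
fixed simple classifier keeps the experiment inside a desktop time budget
without favouring any variant.

### Alignment sensitivity

The sensitivity experiment fits the extractor on aligned beats and measures
the mean per-component negentropy of its outputs when every evaluation beat
is displaced by exactly `α · ⌊d/2⌋` samples (direction random per beat),
for α ∈ {0, 0.1, …, 1.0}.  Fitting once and varying the input matches how
misalignment arises in deployment (the model is trained on well-detected
beats; detector error happens at test time) and makes α = 0 the negentropy
maximum by construction.  Curves are averaged over 5 replicate
fit/evaluation draws (5 000 fit beats, 20 000 evaluation beats) before rank
correlation, because single-fit negentropy estimates at the flat tail of
the curve are noisy.  The companion recall experiment re-runs the full
pipeline (fit and classify) at a fixed misalignment level under
subject-aware CV.

## Feature-count defaults

Per-class component counts default to q = (6, 5, 5, 5) for the proposed
extractor (21 features), (8, 5, 5, 5) for plain ICA (23), 26 selected
coefficients for plain DWT, and (3, 3, 3, 3) for the density variants (12).
The totals match the study's printed feature counts; the split across
classes is this package's choice (slightly more components for the
majority class).  The plain-DWT baseline selects the coefficients with the
largest training variance — selection, not rotation, because reducing DWT
coefficients by PCA would be mathematically equivalent to PCA on the raw
beats and would duplicate a different baseline.

## Numerical choices

* FastICA convergence: tolerance 1e-4 on the maximum absolute change of
  the unmixing rows (sign-insensitive), iteration cap 200; deflation with
  Gram–Schmidt as fallback if the symmetric update does not converge.
  Initialization is an orthonormalized Gaussian matrix from the run seed;
  all randomness flows through explicit seeds and results are bitwise
  reproducible.
* Whitening uses the singular value decomposition of the centred data —
  the same decomposition Hotelling deflation produces, computed stably;
  the literal power-iteration-plus-deflation route is implemented and
  cross-checked against the SVD route in tests.
* Rank guards: component requests beyond the attainable rank raise; PCA
  requests beyond rank truncate with a warning.
* `log cosh` is evaluated as `|z| + log1p(e^{−2|z|}) − log 2` to avoid
  overflow.
* Ties in density-window modes (the discrete argmax may sit on either
  neighbour of the continuous mode) are accepted within one sample.

## Known limitations

* WFDB support covers the subset this package writes (format 16) plus
  format 212 and standard MIT annotations for reading; multi-segment
  records, calibrated baselines other than the header fields used here,
  and compressed formats are out of scope.
* The synthetic generator's classes are far more separable than real
  arrhythmia data; see the caveats above.
* Decomposition depth is limited by `2^J | d`; deep decompositions of the
  default 162-sample window require resampling the window length.
* The density-window variants are implemented faithfully but are known
  (and expected) to underperform the wavelet basis.
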