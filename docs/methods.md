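# Methods

This note records the model, the numerical choices, and what the
synthetic experiments do and do not establish.

## Frequency scheme and spectral estimation

The analysis grid is 11 contiguous bins in 1–45 Hz: a fixed 1–4 Hz delta
bin, then ten bins log-spaced between 4 and 44.8 Hz
(`edge(k+1)/edge(k) = (44.8/4)^(1/10)`). Edges are rounded to one
decimal for display only; computations use the unrounded values. Bins
group into five canonical bands: δ = bin 1, θ = bins 2–4, α = bins 5–6,
β = bins 7–8, β-γ = bins 9–11. The bins are treated as authoritative and
canonical bands defined as unions of bins, so a canonical edge such as
θ/α is the unrounded bin edge (8.31 Hz).

PSDs use Welch's method with a Hamming window, segment length = FFT
length = 10 · fs samples and 50 % overlap (floored), giving a 0.1 Hz
grid; density scaling makes the spectral integral match signal variance
(verified to 5 % on white noise). Band integration is trapezoid
quadrature with the PSD linearly interpolated at the exact bin edges, so
adjacent bins share endpoint values and the bin integrals tile the full
range without gaps or double counting. Absolute power is `10·log10` of
the band integral (unit reference); relative power divides by the full
1–45 Hz integral and is reported in percent. Because the bins tile only
1–44.8 Hz, per-parcel relative powers sum slightly below 100 % on
broadband signals (≈ 99.5 % for white noise); on 1/f-shaped EEG-like
spectra the shortfall is negligible.

## Band-pass filtering and envelopes

Band-pass filters are Hamming-windowed FIR designs with transition width
25 % of the lower band edge (`numtaps ≈ 3.3 · fs / transition`, forced
odd). The symmetric taps are applied by a single centered FFT
convolution, which is exactly zero-phase and — unlike forward–backward
filtering — does not square the magnitude response. Amplitude envelopes
are the magnitude of the analytic (Hilbert) signal, with one filter
length trimmed per side to suppress edge transients. The delta filter is
long (≈ 13 s at 250 Hz), so full 11-bin envelope analysis needs signals
comfortably above two filter lengths.

## DFA

The series is mean-centered and cumulatively summed; for each of 10
log-spaced window sizes between 2 and 20 s, 50 %-overlapping windows are
linearly detrended and the RMS residual pooled across windows; the
exponent is the least-squares slope of log10(fluctuation) against
log10(window size), with the fit residual reported. The fit range,
window count, overlap and detrend order are configuration, not
constants. Estimates below 20 s of data are refused; 20–100 s produce a
warning, as estimates at those lengths are noisy. On 50 000 samples the
estimator is unbiased for white noise with a standard deviation of about
0.04, so single-realization checks against 0.5 are averaged over
independent realizations.

## Aggregation

Power is aggregated across bins by summation — in linear power units for
dB-scaled absolute power (summing dB directly is meaningless), directly
in percent for relative power since the bins partition the range. DFA
exponents aggregate by median. Parcels collapse to networks by the
median across a network's parcels within each hemisphere, then the
arithmetic mean of the two hemisphere medians (medians only across
parcels). The packaged 100-parcel map is synthetic with balanced network
sizes (7–8 parcels per network per hemisphere); a real atlas table can
be supplied as CSV with the same columns.

## Normative space

Scaling is per-feature median/IQR estimated on the reference cohort only
and applied unchanged to every other cohort; a zero-IQR feature is an
error, not a silent drop. The sparse decomposition is the elastic-net
dictionary-learning formulation of sparse PCA (scikit-learn's solver,
LARS updates, deterministic under the recorded seed). The sparsity
parameter (default 1.5) is the ℓ1 penalty weight; at zero the solution
coincides with classical PCA (verified at cosine similarity > 0.99 per
component), and at 1.5 loadings on realistic synthetic cohorts are
qualitatively sparse. Because sparse components are not exactly
orthogonal, explained variance uses the adjusted-variance convention:
component scores are sequentially orthogonalized (QR) and each component
is credited only with variance unexplained by its predecessors, after
ordering components by individual projected variance. Sign convention:
each loading vector is flipped so its largest-magnitude entry is
positive. Fitting requires more reference subjects than features
(35 < n), the stability condition for the downstream covariance
estimates.

## Deviance

Robust centers use the Minimum Covariance Determinant with the default
support fraction `(n + p + 1)/(2n)`, consistency correction and
reweighting, under a fixed recorded seed. The Mahalanobis distance is
reported as the square root of the quadratic form so it carries score
units; downstream statistics are rank-based and indifferent to this
monotone choice. Reference subjects are scored leave-one-out: the
subject is removed, the MCD refitted, and the held-out point scored —
in-sample distances are optimistic. Age-matched centers use reference
subjects within ±12 months; if fewer than `min_n` (default 10) match,
the computation raises rather than silently widening the window, because
widening would change the estimand. Distances enter statistics untransformed.

## Clinical severity

The EEG-abnormality rubric maps each distinct abnormality type to a
weight (focal transient 2; epileptiform discharge 3; diffuse beta 4;
slow posterior dominant rhythm, disrupted anterior–posterior gradient,
and burst suppression 5 each) and sums weights over the distinct types
present; no abnormalities is rank 1. Each abnormality type carries the
weight of its severity class, so two co-occurring weight-5 types sum to
10; where a printed clinical table disagrees with a rubric recomputation
from free-text descriptions, the printed rank in the packaged table is
authoritative.

The clinical PCA rank-transforms the five scales (average ranks for
ties), eigendecomposes the Spearman correlation matrix of the ranks, and
projects z-scored ranks (unit sample variance) onto the eigenvectors.
Eigenvalues sum to the number of scales; explained variance is
`100 · λ_k / 5`. Axis signs are anchored clinically: GMFCS loads
positively on PC1_clin (higher = more severe) and the EEG-abnormality
rank loads negatively on PC2_clin. Sampling-adequacy diagnostics (KMO
from anti-image partial correlations; Bartlett's sphericity
`χ² = −(n − 1 − (2p + 5)/6)·ln det R`) are computed on the Pearson
correlation matrix of the raw scores — the matrix on which those
diagnostics are conventionally quoted for this cohort — while the PCA
itself uses the Spearman matrix; both matrices are exposed on the fitted
model. Overall displacement in the clinical plane is
`sqrt(Σ_k score_k²/λ_k)`, scaling each axis by its inverse eigenvalue so
low-variance components are not systematically under-weighted.

## Statistics

Paired state contrasts use Wilcoxon signed-rank tests with zero
differences dropped, the exact null where scipy's default provides it,
and effect size `r = |Z|/√n` from a tie-corrected normal-approximation Z
over all n pairs (this convention is stated because r depends on it);
Shapiro–Wilk on the differences is reported alongside, motivating the
rank-based choice. Benjamini–Hochberg FDR is applied independently
within each declared block (e.g. the 10 component-pair tests of one
biomarker). Spearman correlations use average ranks; the permutation
test shuffles the second variable and uses the add-one estimator
`p = (1 + #{|ρ_perm| ≥ |ρ|})/(1 + n_perm)`, which cannot return zero;
permuting either variable is equivalent under exchangeability.
Confidence intervals are unstratified paired-bootstrap percentile
intervals with within-resample re-ranking; degenerate (constant)
resamples are dropped. Defaults are 15 000 permutations and 15 000
bootstraps with the seed recorded in every result.

## Synthetic data

The signal generator writes each parcel as a 1/f^slope background
band-limited to 1–45 Hz plus, per canonical band, a band-pass-filtered
white-noise carrier multiplied by a positive envelope
`exp(a · z)`, where z is fractional Gaussian noise (Davies–Harte
circulant embedding) with Hurst parameter equal to the target DFA
exponent, low-passed at 2 Hz and standardized. The low-pass keeps the
modulation sidebands inside the band and the crossover well below the
2 s lower end of the DFA fit range; the lognormal form guarantees
positivity without clipping distortion. Carrier variances are solved
from the measured background band shares so the *total* band power hits
the target fraction, then refined by two fixed-point corrections against
the measured spectrum. Planted relative powers are recovered within
±0.05. Planted DFA exponents are recovered with a small attenuation
(≈ −0.05 at H = 0.8, with parcel-averaged estimates inside ±0.08)
because the measured Hilbert envelope mixes the planted modulator with
the carrier's own uncorrelated Rayleigh fluctuations; targets near 0.5
are conversely inflated slightly by the modulator's band limit. The
generator emulates band structure and envelope persistence only — no
cross-parcel connectivity, nonstationarity, artifacts, or volume
conduction — so passing tests establish the correctness of the
estimators, not realism of any particular EEG phenotype.

Cohort features follow a latent factor model `x = L z + slope·(age − ā)
+ ε`; the reference-like default plants five band-aligned components
(variances 2.0, 1.5, 1.2, 1.0, 0.8 against noise 0.3), sized so five
components explain over 70 % of variance, mirroring the organization of
a typically developing cohort. Ages default to uniform on 4.3–18.2
years; the pipeline's reference cohort uses stratified (jittered
equal-width) sampling, emulating age-matched recruitment so every ±12
month window in range holds at least the minimum support. Eyes-closed
states multiply alpha (default ×1.5) and theta (×1.2) relative-power
features and renormalize each network's five-band block to 100 %, the
canonical alpha enhancement of eye closure. Clinical cohorts come from a
Gaussian copula with a target latent correlation matrix, discretized at
explicit thresholds (default equiprobable levels).

## Orchestration and problem sizes

The pipeline derives every stage's seed from one master seed via named
SHA-256 substreams and writes a manifest (stages, config, config hash,
seed) with every run; fixed config and seed reproduce outputs
byte-identically. The simulate stage defaults to feature-level cohort
generation (96 reference subjects, 15 patients, three biomarkers); the
time-series mode, which pushes parcel waveforms through the full
spectral/LRTC/aggregation stack, is exercised at small sizes (single
subjects, 100 parcels, 150 s) since its cost is dominated by per-bin
envelope analysis. Test-suite simulations use reduced resampling
(hundreds of permutations) where only wiring is under test; calibration
checks use 500 replicates at 1 000 permutations, enough to bound the
type-I error within the stated [0.03, 0.07] band.

## Known limitations

- The sparse-PCA penalty scale is solver-specific; "sparsity 1.5" is
  calibrated qualitatively (a substantial fraction of exactly-zero
  loadings), not asserted to match any other implementation's parameter
  of the same name.
- The chi-square reference for jackknifed MD² holds only approximately
  under MCD reweighting; the test tolerance is correspondingly loose.
- The severity rubric encodes the scoring arithmetic only; identifying
  abnormality categories from EEG remains a clinician's judgment.
- Raw (untransformed) MDs are right-skewed by construction; all
  downstream inference is rank-based for that reason, and parametric
  summaries of MDs should not be added without revisiting this.
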