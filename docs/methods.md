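# Methods

## The screening problem

Benzoic acid (BA) is a common preservative in pickled vegetables;
regulation caps it at 600 ppm. Confirmatory HPLC is accurate but slow
and expensive, so the method implemented here uses a handheld SERS
spectrometer (gold-nanoparticle substrate, 785 nm excitation, 1,024
channels over 204–1,986 cm⁻¹, 8 cm⁻¹ resolution) as a triage
instrument: samples whose spectral score crosses a threshold go to
HPLC; the rest are released. For screening, false negatives are
unacceptable and false positives merely cost a confirmatory run, which
drives every operating-point choice below.

## Baseline model (AirPLS)

SERS spectra of food extracts carry a large, smooth
fluorescence-like background that the nanoparticles amplify along with
the analyte. AirPLS estimates it as the curve z minimizing

    Σᵢ wᵢ (yᵢ − zᵢ)² + λ Σⱼ (Δᵏ z)ⱼ² ,

solved each iteration from the banded normal equations
(W + λ DᵀD) z = W y (bandwidth k, Cholesky via `solveh_banded`).
Weights start at 1; after each fit the residual d = y − z is split and
s = Σ|d⁻| computed over the negative part. Points at or above the
baseline (signal) get weight 0; points below get exp(t·|dᵢ|/s); the
two endpoints get exp(t·max|d⁻|/s) to anchor the fit at the spectrum
edges (a "zero" endpoint mode is also available). Iteration stops when
s < tol·Σ|y| or at `max_iter`.

Defaults: λ = 100, max_iter = 15, tol = 0.001, difference order 2 —
the defaults of the algorithm's original formulation. Two numerical
properties worth knowing:

* **λ versus peak width.** λ = 100 leaves the baseline flexible at the
  ~2 cm⁻¹ channel pitch: it removes a full-spectrum drift to <1% but
  bulges into narrow peaks, costing a 6 cm⁻¹-wide Lorentzian roughly a
  quarter of its apex after subtraction. Apex-faithful correction of
  such peaks needs λ ≈ 10⁴–10⁵. The screening statistics are
  insensitive to this (Z-standardization rescales, and the band maxima
  of analyte and background shrink together), so the flexible default
  is kept; users quantifying peak heights should stiffen λ.
* **Sign convention.** The asymmetric weighting treats upward
  excursions as signal. If all peaks point downward, the baseline
  tracks the upper envelope and dips partially into the peak cores;
  the corrected signal is then non-positive over ~90% of channels
  rather than everywhere. Stiffening λ makes this *worse* (the heavily
  weighted peak cores drag a stiff baseline down globally).

The corrected signal is never clipped at zero: the Z-scoring step
recentres the distribution, and clipping would distort it.

## Scoring statistics

Each corrected spectrum is standardized against its own 1,024
channels using the sample standard deviation (n−1; at n = 1,024 the
difference from the population convention is <0.05%). Per species the
band statistic is the **maximum** z inside the closed wavenumber
interval — not a mean or integral — because the adsorption geometry of
BA on nanogold shifts peak positions, and a max over the interval is
shift-tolerant. The tabulated single-wavenumber dimer band
(1,025 cm⁻¹) is widened to ±8 cm⁻¹, one instrument resolution unit,
for the same reason; the window is configurable.

The Z-ratio divides the naphthenic-band max by the carboxylic-band
max. Two gates keep it defined:

* **Detection floor** (default 1.0 standard score): if neither band
  reaches it, the species is undetected and scores 0. The reference
  cohort's many exact-zero dimer entries force *some* such gate; the
  floor is one consistent reconstruction and is configurable.
* **Division guard** (10⁻⁶): a detected species whose carboxylic max
  is numerically zero scores 0 rather than ±∞.

Negative ratios pass through unmodified — the reference table itself
contains −15.7 at 30 ppm, an instance of the quotient's intrinsic
instability when the carboxylic z sits near zero.

Decisions: sum ≥ 1.5 declares BA present; sum ≥ 5 (Rule 5) flags
high risk. Rule 5 is applied **inclusively** (≥ 5): the reference
cohort contains a sample scoring exactly 5.00, and only the inclusive
reading reproduces the documented count of 11 referred samples. A
strict (> 5) mode is available.

## Evaluation

A sample is truly positive when its HPLC concentration strictly
exceeds the regulatory limit (600 ppm; no reference sample sits on the
boundary, so the convention is untestable there). The ROC is built
from one operating point per unique score; AUC is the Mann–Whitney
pair count with ties at ½ — identical to the trapezoid on the
empirical curve but exactly auditable against brute-force enumeration,
which the tests do for every cohort up to 50 samples. The
screening-optimal threshold is the largest threshold keeping
sensitivity exactly 1.0 (maximal specificity among such thresholds),
verified by exhaustive scan.

On the bundled 40-sample cohort this yields AUC = 105/111 ≈ 0.946 and
Rule-5 specificity 29/37 ≈ 78.4%. The study the cohort comes from
prints AUC 0.978 and specificity 90.9%; those values cannot be
reconstructed from the printed table under any labeling or threshold
convention we tested (strict/inclusive flagging, limit variants,
outlier exclusion). The package therefore reports only quantities its
own data reproduce, and treats the printed pair as a documented
discrepancy rather than a calibration target.

The Monte Carlo triage analysis is a nonparametric bootstrap: each of
n_iter (default 10,000) iterations resamples the cohort with
replacement, applies the threshold, and records the false-negative
rate among resampled positives and the flagged fraction among
resampled sub-limit samples (iterations lacking the relevant class are
skipped for that rate). Means and 2.5/50/97.5% quantiles are reported;
a single seeded generator drives each call. On the reference cohort
the false-negative rate is structurally zero — every over-limit sample
scores above 5, so no resample can produce one — and the flagged
fraction among compliant samples converges to the plug-in 8/37 ≈ 21.6%,
the "about 20% of compliant samples still go to HPLC" cost of the
screen. The original study's simulation design is not described in
enough detail to replicate; the bootstrap is this package's own
reconstruction.

## Synthetic data generator

The generator exists so that every stage has known ground truth; it
emulates the measurement's structure, not any particular instrument's
noise physics.

A spectrum is baseline + analyte peaks + interference peaks + noise:

* **Baseline** b(ν) = b₀ + b₁ν + b₂·exp(−ν/θ), defaults
  (0.2, 2·10⁻⁴, 2.0, 300): a linear tilt plus a fluorescence-like
  decay, amplitude ~0.8 a.u. across the grid.
* **Analyte peaks** are Lorentzians (half-width γ = 6 cm⁻¹, near the
  8 cm⁻¹ instrument resolution; Gaussian selectable) centered inside
  the four read-out windows with Gaussian position jitter
  (sd 3 cm⁻¹) truncated to the window — emulating the documented
  adsorption-angle peak drift. Naphthenic-band height is
  gain·conc (gain 0.0008 a.u./ppm per species share); the
  carboxylic-band height saturates, gain·0.5·conc/(1 + conc/400),
  so the Z-ratio rises with concentration (≈ 2·(1 + conc/400) once
  detected) instead of being amplitude-free. A per-sample binding-mode
  draw φ ~ Beta(0.4, 0.4), quantized to monomer-only / even mix /
  dimer-only, allocates amplitude between the species; the dimer
  contributes nothing below 350 ppm (the reference cohort shows dimer
  signal only at ≥380 ppm). The quantization reflects the observed
  pattern that samples present either one species or both strongly;
  it also avoids the regime where a weak species passes the detection
  floor on its naphthenic band while its carboxylic band drowns in
  noise, which makes the quotient blow up. That instability is real —
  the reference table's −15.7 is one such event — and the generator
  still produces it occasionally at low concentrations.
* **Interference** (matrix) peaks: 5 Lorentzians at uniform positions
  outside the analyte windows (±15 cm⁻¹ margin), heights
  uniform(0.09, 0.3) a.u. They set the spectrum's variance scale so
  that blank spectra standardize to band maxima below the detection
  floor, as blanks should.
* **Noise**: additive Gaussian, sd 0.002 a.u. Real SERS noise mixes
  shot and detector components; that structure is not modeled.

Cohorts draw concentrations from a point mass at 0 ppm (weight 0.55)
plus a log-normal (median 350 ppm, σ_log 0.6) for contaminated
samples, mirroring the reference cohort's composition, and score every
spectrum through the full pipeline. With these defaults a
2,000-sample cohort yields end-to-end AUC ≈ 0.95–0.97 and Rule-5
sensitivity ≈ 100% against the true >600 ppm labels — the same
operating regime as the reference study. Passing these tests shows the
chain recovers known structure under this idealized model; it does not
certify performance on real vegetable matrices, whose interference is
neither Lorentzian nor band-avoiding.

Calibration fits are ordinary least squares of score on concentration
inside a stated linear range (default 380–820 ppm), with
LOD = 3.3·sd(blanks)/|slope| and LOQ = 10·sd(blanks)/|slope| — the
standard blank-deviation conventions, supplied because the source
study states values but not its formula.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use the full printed
40-sample reference cohort, 10,000 bootstrap iterations, 100 seeds per
concentration for dose-response checks and a 2,000-spectrum synthetic
cohort (~4.5 ms per spectrum through the full pipeline). Every
stochastic routine takes an explicit seed; one `--seed` drives the
acceptance script, which derives per-stage child seeds from it.

## Known limitations

* The detection floor producing the reference table's 0.00 entries is
  a reconstruction; the original gate is unstated.
* The Z-ratio is unstable when the carboxylic z approaches zero;
  outliers (both signs) are passed through by design.
* The band-interval definitions assume the instrument grid; spectra
  on other axes must be resampled first, and bands falling between
  channels of a coarser grid would need rewidening.
* Per-vegetable-type summaries are not computable: the bundled table
  carries no vegetable labels.
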