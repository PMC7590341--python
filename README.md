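# serscreen

Rapid screening of benzoic acid (BA) residues in food extracts from
surface-enhanced Raman spectra (SERS), built for the "screen first,
test later" workflow: a handheld Raman readout decides within seconds
which samples must go to confirmatory HPLC, so that the bulk of
compliant samples never occupy a chromatograph.

The package implements the full decision chain for pickled-vegetable
extracts measured on a 1,024-channel spectrometer (204–1,986 cm⁻¹):

1. **AirPLS baseline correction** — adaptive iteratively reweighted
   penalized least squares. The fitted baseline *z* minimizes
   Σᵢ wᵢ(yᵢ−zᵢ)² + λ‖Δ²z‖², with weights re-estimated each iteration so
   that points above the baseline (signal) get weight 0 and points
   below pull it down with weight exp(t·|dᵢ|/s). The inner Whittaker
   solve uses a banded Cholesky factorization.
2. **Z-scoring and band Z-ratios** — the corrected spectrum is
   standardized against its own 1,024 channels,
   zᵢ = (xᵢ − x̄)/s_x. For each BA species (monomer, hydrogen-bonded
   dimer) the screening statistic is the ratio of in-band maxima,
   Z-ratio = max z(naphthenic band) / max z(carboxylic band), read over
   the intervals monomer 944–1,005 & 1,366–1,373 cm⁻¹, dimer
   1,025 ± 8 & 1,465–1,482 cm⁻¹. A species with neither band above a
   detection floor (default 1.0) scores 0.
3. **Decision rules** — sum = Z-ratio(monomer) + Z-ratio(dimer).
   Sum ≥ 1.5 declares BA present ("significant fluctuation");
   sum ≥ 5 ("Rule 5") flags the sample as high-risk for exceeding the
   600 ppm regulatory limit and refers it to HPLC.
4. **Evaluation** — empirical ROC with Mann–Whitney pair-count AUC,
   the screening-optimal threshold (sensitivity 1.0, maximal
   specificity), Pearson correlation of score vs HPLC concentration,
   and a seeded bootstrap quantifying triage risk.
5. **Synthetic spectra** — a generator with Lorentzian analyte peaks,
   fluorescence-like drift, matrix interference and noise, so every
   stage is testable against known ground truth; plus calibration fits
   with 3.3σ/10σ limit-of-detection conventions.

A 40-sample reference cohort (per-sample monomer/dimer Z-ratios and
HPLC concentrations, 0–820 ppm) ships with the package as a
checksummed fixture.

## Worked example

```python
from serscreen import load_table2, empirical_roc, pearson_correlation
from serscreen import confusion_at_threshold, monte_carlo_triage

cohort = load_table2()                       # 40 samples, limit 600 ppm
print(round(pearson_correlation(cohort), 3)) # 0.737
roc = empirical_roc(cohort)
print(round(roc.auc, 4))                     # 0.9459
conf = confusion_at_threshold(cohort, 5.0)   # Rule 5, inclusive
print(conf.sensitivity, round(conf.specificity, 3))  # 1.0 0.784
mc = monte_carlo_triage(cohort, 5.0, n_iter=10_000, seed=17)
print(round(mc.fp_triage_mean, 3))           # 0.216
```

Reading: the summed Z-ratio correlates with the HPLC concentration at
r = 0.737; Rule 5 catches all three samples above 600 ppm
(sensitivity 1.0) while referring about 22% of the compliant samples
to HPLC — 11 of 40 samples in total go to confirmatory analysis
instead of all 40.

From the shell, the same workflow is:

```sh
serscreen pipeline --input table2 --outdir out --seed 1
serscreen simulate --n 40 --seed 7 --outdir sim      # synthetic cohort
serscreen pipeline --input sim --outdir sim_report --seed 1
```

`serscreen baseline`, `serscreen score` and `serscreen evaluate` expose
the individual stages; `serscreen table2 export` writes the bundled
reference table.

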