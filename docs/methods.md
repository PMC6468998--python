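# Methods

`liquidlens` implements four liquid-biopsy computations — a cfDNA
copy-number-instability score, a Raman plasma classifier, circulating
tumour-cell (CTC) enumeration statistics, and an RNA blood-signature
filter — together with seeded generators that emulate the data structure
each computation consumes. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic fixtures do and
do not establish.

## Copy-number instability (CNI) scoring

### Model

Shallow whole-genome sequencing of plasma cfDNA is reduced to read counts
in a fixed panel of genomic windows. The default window set tiles the hg19
autosomes with **701** windows; window counts are apportioned to
chromosomes in proportion to length (largest-remainder rule) and each
chromosome is tiled with near-equal windows (integer edges `i·L/k`), so
the emitted count is exact and coverage is complete. Sex chromosomes are
excluded by default because mixed-sex reference panels make X/Y ratios
bimodal; `include_sex=True` restores them. Coordinates are 0-based,
half-open throughout.

For a sample with counts `c_w` and total `N`, the per-window log2 read
ratio is

    r_w = log2((c_w + 0.5) / (e_w + 0.5)),   e_w = N · len_w / Σ len

(pseudocount 0.5 keeps empty windows finite). A reference panel of `n`
normal cfDNA profiles supplies per-window mean `µ_w` and SD `σ_w`
(sample SD, floored at 1e-4 against degenerate panels), giving
`z_w = (r_w − µ_w) / σ_w`.

Windows are rejected two-sided at false-positive rate α (default
**0.002**). The CNI is the sum over rejected windows of Φ(|z_w|)
(`cdf_sum`, default) or |z_w| (`abs_z_sum`); both conventions are exposed
because published descriptions are ambiguous between them, and the score
is zero exactly when no window is rejected.

### Rejection threshold

When the panel size is known (the default in `score_sample`), the
threshold is the predictive-distribution quantile
`t_{n−1}(1 − α/2) · sqrt(1 + 1/n)` rather than the standard-normal
quantile. For a fresh null sample standardised by a mean and SD estimated
from `n` normals, `z / sqrt(1 + 1/n)` is exactly t-distributed with
`n − 1` degrees of freedom; using the normal quantile with `n = 133`
inflates the realised false-positive rate to ≈0.25% instead of the nominal
0.2%. `cni_score` without `panel_n` falls back to the normal quantile
(`Φ⁻¹(0.999) ≈ 3.09`).

A separate panel-free "tissue mode" (`tissue_profile`) normalises counts
to the per-sample median and flags `log2 > 0.15` as gain and
`log2 < −0.15` as loss.

Deliberately out of scope: GC/mappability correction (an extension point;
the pipeline applies none), segmentation, and tumour-fraction estimation.

### cfDNA generator

`gen_cfdna` draws, per sample, window rates
`len_w · 2^{N(0, s)} · m_w` with `s = window_noise_sd = 0.05` log2 units
(biological inter-sample variability; no published noise model exists, so
a lognormal rate multiplier was chosen once as the standard multiplicative
model for count data) and `m_w = 1 + tf·(ρ_w − 1)` for implanted
aberrations of copy ratio ρ at tumour fraction `tf`; counts are Poisson at
`depth_reads` total (default 1e6 — desk-scale; the study-scale 30e6 is a
parameter away, and at 1e6 the Poisson component of the per-window log2 SD
is ≈0.038, so the window-noise term dominates as it would at full depth).
The panel (default `n = 133`) is drawn from the same model without
aberrations. `expected_counts` returns the noise-free expectation profile,
used for deterministic dose-response checks.

Two consequences worth knowing:

* a single-copy gain (ρ = 1.5) at tumour fraction 0.2 produces a log2
  shift of 0.138 against a per-window SD of ≈0.063 — z ≈ 2.2, below the
  0.2% threshold. Detection of such gains becomes reliable from roughly
  `tf ≈ 0.4`; the recovery test operates at `tf = 0.5`.
* under `cdf_sum` the per-window contribution saturates at 1 for |z| ≳ 8,
  so monotonicity of the score along a tumour-fraction grid is exercised
  with a mixed-amplitude aberration fixture (segments at ρ = 1.5, 2.5, 4)
  in which each fraction step pushes new windows across the threshold.

## Raman classification

### Pipeline

Each spectrum (one map average) passes through, in order: baseline
subtraction, standard-normal-variate (SNV) normalisation, PCA, Fisher
LDA. Baseline and SNV are per-spectrum transforms with no training
statistics; PCA and LDA are fitted on training data only.

* **Baseline** — default asymmetric least squares (smoothness λ = 1e5,
  asymmetry p = 0.01, 10 iterations), the standard choice for the broad
  fluorescence background of NIR-excited biofluid spectra; a polynomial
  fit (order 5) is available by config. ALS is equivariant under positive
  affine intensity transforms, which together with SNV makes the whole
  pipeline invariant to per-spectrum gain and offset.
* **SNV** — `(x − mean x)/sd x`; exact zero mean, unit SD; rejects
  constant spectra.
* **PCA** — scikit-learn PCA on training spectra; the component count is
  the smallest explaining ≥95% of training variance, capped at 20
  (recorded per fold); a fixed `k` can be forced.
* **LDA** — Fisher discriminant `w = Sw⁻¹(µ_cancer − µ_control)` with the
  pooled within-class scatter regularised by `1e-6 · trace(Sw)/dim` on the
  diagonal so small folds stay invertible; the threshold sits at the
  midpoint of the projected class means, and a score exactly at the
  threshold predicts control (conservative tie-break).

Cross-validation is leave-one-**participant**-out: all six spectra of one
participant (3 drops × 2 maps) form the test fold, so within-participant
correlation cannot leak into the model. With the default 20 cancer + 10
control design this gives 30 folds and 180 per-spectrum predictions;
sensitivity is cancer-class recall, specificity control-class recall.
Spectra whose wavenumber grids differ by less than 1 cm⁻¹ are linearly
interpolated onto the first spectrum's axis; larger mismatches are errors.

### Raman generator

`gen_raman` builds each participant's clean spectrum as a fixed set of
Gaussian biological bands plus three carotenoid bands at **1008, 1158 and
1524 cm⁻¹** (canonical carotenoid Raman bands, chosen as fixture
constants; the study this design emulates highlights three depleted bands
without printing wavenumbers). Cancer participants have their carotenoid
amplitudes multiplied by `1 − depletion_effect` (default **0.30**). Each
participant carries an independent per-band fractional amplitude jitter
(SD **0.08**) shared by all six of their spectra — this participant-level
effect is what makes per-participant cross-validation meaningfully harder
than per-spectrum splits; on top come a per-drop intensity factor (SD
0.03), a per-spectrum random fluorescence background, and white map noise
(SD 0.02 on a peak scale of ~1). The default jitter is calibrated so the
default depletion is reliably detectable by the pipeline at the 30-
participant design (cross-validated sensitivity/specificity in the
90–100% range across seeds); larger jitter (≥0.15) moves the fixture into
a regime where single control participants flip and specificity becomes a
coarse 10-points-per-participant variable.

What the fixture does **not** emulate: cosmic-ray spikes, detector
etaloning, wavenumber miscalibration between sessions, within-map spatial
heterogeneity, and realistic biochemical covariance between bands. Passing
tests therefore show the pipeline is correct and leakage-free, not that
real plasma spectra separate this cleanly.

## CTC enumeration

An event is a CTC when AF488 (pan-cytokeratin) is above threshold, CD45
(leukocyte marker) at or below threshold (inclusive, so the rule
partitions events), and DRAQ5 (nuclear stain) above threshold. Numeric
gates are instrument-specific and not published; the defaults
(300/300/200) are calibrated to the synthetic generator's planted
populations, which are separated from them by >4 SDs — they are fixture
values, not biological constants. An optional area filter (µm²; 1 pixel =
0.25 µm²) is off by default. Counts are reported per 10,000 captured
cells; spike-in recovery is `100 · retrieved/spiked` (retrieved > spiked
warns of double counting but still computes). ROC curves sweep thresholds
over per-sample values with trapezoidal AUC (tie handling equivalent to
Mann–Whitney U / n₁n₂). Group comparison is one-way ANOVA with Tukey HSD;
a two-group Mann–Whitney alternative is available for skewed counts.

## Expression signature

Gene tables (Cuffdiff-style columns accepted) are tiered as: strict
(p < 5×10⁻⁵ and |log2FC| > 2), moderate (p < 0.05 and |log2FC| > 2, not
strict), unchanged (the rest) — a partition. The per-compartment
"differentially expressed" set is strict ∪ moderate. The blood signature
keeps genes with `fpkm_case > 5`, `p < 0.05` and `log2FC > +2`
(up-regulation only); the significance gate uses p by default, with
q (FDR) selectable, since the published filter states significance without
specifying FDR control. Venn arithmetic over the tissue and blood DE sets
is by exact set operations.

`gen_expression` plants, by default, 356 blood-DE and 293 tissue-DE genes
sharing 21 (all down-regulated), of which 18 blood-only genes satisfy all
three signature gates; remaining blood-DE genes fail at least one gate by
construction (down-regulated, or case FPKM < 5), and null genes have
|log2FC| ≤ 1.9. The planted-truth split is deliberately clean — in the
real data two of the 18 signature genes were also among the 21 shared
genes; the fixture keeps the sets disjoint so every selector has an exact
expected answer.

## Reproducibility and problem sizes

Every generator is a pure function of its parameter object including the
seed; the pipeline runner writes the resolved configuration and package
version next to its outputs, and summary JSON is byte-identical across
reruns. The test suite and the acceptance script run at desk scale by
design: cfDNA at 1e6 reads with a 133-profile panel and 200 null samples,
the full 30-participant Raman design at 601 spectral points, event tables
of 10⁴ rows, and 2000-gene expression tables. These sizes were chosen so
the Monte-Carlo error of each calibration check is small relative to its
tolerance while the whole suite stays interactive.

## Known limitations

* The CNI window set has no mappability masking; real genomes need one.
* The predictive-t threshold assumes approximately Gaussian log2 ratios;
  strong overdispersion or GC waves would need explicit modelling. At the
  default depth the residual skew of log-Poisson ratios drifts the
  realised false-positive rate a few percent above nominal — visible only
  at the third decimal in percent.
* LDA's midpoint threshold is optimal for equal class covariances; the
  cancer class in the fixture has slightly smaller variance, which costs
  specificity before sensitivity.
* ANOVA on CTC counts is the stated default; counts are typically
  overdispersed, which is why the Mann–Whitney alternative exists.
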