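# liquidlens

Analytics for multi-modal liquid biopsies of lung cancer. A single blood
draw supports several independent read-outs, and this package implements
the computational side of four of them, each as a separately usable
module:

* **`genome_cni`** — copy-number instability (CNI) scoring of shallow
  whole-genome cfDNA sequencing. Read counts in 701 genome-tiling windows
  are turned into log2 ratios, standardised against a reference panel of
  normal cfDNA profiles (per-window mean µ_w and SD σ_w), and windows with
  `|z_w| = |(r_w − µ_w)/σ_w|` beyond a two-sided 0.2% false-positive
  threshold contribute `Φ(|z_w|)` to a single instability score. A
  panel-free tissue mode flags per-window gains/losses at ±0.15 log2
  against the sample median.
* **`raman_classify`** — classification of dried-plasma Raman spectra:
  map averaging, asymmetric-least-squares baseline subtraction, standard
  normal variate (SNV) normalisation, then PCA score reduction and a
  Fisher linear discriminant, cross-validated by leaving every spectrum of
  one participant out per fold.
* **`ctc_quant`** — circulating-tumour-cell enumeration from imaging
  flow-cytometry event tables: the AF488+/CD45−/DRAQ5+ positivity rule,
  counts per 10,000 captured cells, spike-in recovery, pixel→µm² area
  conversion, ROC/AUC, and one-way ANOVA with Tukey HSD across groups.
* **`expression_signature`** — three-tier differential-expression grouping
  of gene statistics tables and the blood-signature filter
  (FPKM > 5, p < 0.05, log2FC > +2), plus Venn arithmetic between tissue
  and blood DE gene sets.

Because the underlying patient cohort is not public, **`synthetic_data`**
provides seeded generators that emulate each stage's data structure with
planted ground truth (aberrant windows at a chosen tumour fraction,
carotenoid-depleted cancer spectra, spiked CTC-like events, planted DE
genes), so every computation is testable end to end. `cli_io` supplies the
file formats (BED-dialect genomic tables, two-column spectra with a
manifest, TSV event/gene tables) and a pipeline runner.

The scientific background and every numerical choice are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Score a simulated cfDNA sample carrying a 10-window single-copy gain
(copy ratio 1.5) and a 5-window amplification (copy ratio 3) at tumour
fraction 0.4 against a simulated 133-sample normal panel, then
cross-validate the Raman classifier on the default 20 cancer + 10 control
participant design:

```python
from liquidlens import genome_cni as gc, raman_classify as rc, synthetic_data as sd

params = sd.CfdnaSimParams(
    aberrations=(sd.Aberration(100, 110, 1.5), sd.Aberration(400, 405, 3.0)),
    tumour_fraction=0.4, n_samples=1, seed=7,
)
sim = sd.gen_cfdna(params)
panel = gc.build_reference(
    [gc.log2_ratio_profile(c, sim.windows) for c in sim.panel]
)
result, zp = gc.score_sample(sim.samples[0], sim.windows, panel)
print(f"CNI = {result.cni:.3f}  rejected windows = {len(result.rejected)}  "
      f"z_critical = {result.z_critical:.3f}")

data, _ = sd.gen_raman(sd.RamanSimParams(seed=7))
res = rc.loocv_by_participant(data)
print(f"folds = {res.n_folds}  sensitivity = {res.sensitivity:.2%}  "
      f"specificity = {res.specificity:.2%}")
```

prints

```
CNI = 12.999  rejected windows = 13  z_critical = 3.165
folds = 30  sensitivity = 100.00%  specificity = 90.00%
```

Thirteen windows are rejected — the 15 implanted ones minus marginal
single-copy windows plus chance rejections, each contributing
Φ(|z|) ≈ 1 — while a null sample (tumour fraction 0) scores ≈ 0. The
Raman run makes one fold per participant (30), predicts each of the 180
map-average spectra exactly once, and reports per-spectrum recall of the
cancer (sensitivity) and control (specificity) classes.

The same stages are available from the shell:

```sh
liquidlens cni windows --out windows.bed
liquidlens simulate cfdna --seed 7 --out sim/
liquidlens cni score --counts sim/sample000.counts.tsv \
    --windows sim/windows.bed --panel panel.tsv --out sample000.cni.tsv
liquidlens raman --manifest spectra/manifest.tsv --out raman_out/
liquidlens ctc --events events.tsv --out ctc_out/
liquidlens signature --blood blood.genes.tsv --tissue tissue.genes.tsv --out sig_out/
liquidlens run --config pipeline.yaml --seed 1 --out run_out/
```

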