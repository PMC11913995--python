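# spoteval

Pre-analytic evaluation of **dried blood spot (DBS)** and **dried plasma
spot (DPS)** microsampling for LC-MS metabolomics and lipidomics.

Before a microsampling device (Capitainer, Whatman 903, Telimmune DUO) can
be used for untargeted metabolomics/lipidomics, three pre-analytic
questions must be answered: *which extraction solvent recovers the most
analytes*, *how reproducible is the extraction*, and *how long do the
analytes survive at room temperature on the card*. `spoteval` implements
the full evaluation workflow on wide feature-intensity tables (annotated
LC-MS features × extracted samples), and ships a synthetic-data generator
that emulates the device × solvent × replicate study design so the whole
pipeline is testable without instrument data.

## The statistics at the core

**Extraction score.** For feature *i* and sample *j* within a scope *S*
(by default all samples of one device and assay),

```
rel_ij = 100 · x_ij / max_{k∈S} x_ik          (relative intensity, %)

score_ij = 0            if x_ij = 0 (not detected)
           1            if rel_ij < 25
           2            if 25 ≤ rel_ij < 50
           3            if 50 ≤ rel_ij < 75
           4            if rel_ij ≥ 75
```

The **total score** of an extraction condition is `Σ_i score_ij` per
sample, averaged over replicates (mean ± SD, n−1). Class-level heatmaps
average `score_ij` over all features of one compound class (6 polar
classes, 8 lipid classes) per (device, solvent) cell.

**Reproducibility.** Per-feature `CV% = 100·SD(n−1)/mean` over extraction
replicates, bucketed into `CV < 10`, `10 ≤ CV ≤ 30` and `CV > 30` percent;
the fraction with CV ≤ 30 % is the conventional reproducible share.

**Short-term stability.** Per class *c* and storage day *d*,
`variation(c, d) = mean_i 100·(m_i(d) − m_i(0))/m_i(0)` over the class's
features (replicate means); a class is *stable* at day *d* when
`|variation| ≤ 20 %`.

**Consecutive extraction.** A two-step extraction (methanol, then water on
the same spot) is compared against single methanol extraction by a volcano
analysis: Welch t-test on log10 intensities plus linear fold change of
sum-normalized means, significant when `p < 0.05` and `|FC| ≥ 1.5`.

Supporting stages: sum normalization + log10 transform, PCA overview
(PC1+PC2 variance %), and BCA protein calibration (562 nm absorbance vs
0–2000 µg/mL standards, inverted for unknowns).

## Worked example

```python
import spoteval as sv

config = sv.SyntheticConfig(seed=0)   # 3 devices x 5 solvents x 3 replicates,
                                      # 27 features in each of 14 classes
table, truth = sv.generate_extraction_experiment(config)

report = sv.score_table(table)
print(report.condition_totals
      .query("device == 'Capitainer' and assay == 'polar'")
      [["solvent", "mean_score", "sd_score"]].to_string(index=False))
```

```
 solvent  mean_score  sd_score
CH3OH100  484.666667  5.131601
 CH3OH80  560.333333  5.131601
 CH3OH50  614.666667  1.154701
     ISO  174.000000  3.000000
    BuMe  312.000000  7.549834
```

Each row is one extraction condition: the sum of 0–4 per-feature scores of
the 162 polar features, averaged over the three replicates. Aqueous
methanol wins for polar metabolites (CH3OH 50 % highest, pure isopropanol
worst), mirroring the configured class yields. The class heatmap shows why
— the water-loving classes drive it:

```python
print(report.heatmaps[("Capitainer", "polar")].round(2).to_string())
```

```
solvent                   CH3OH100  CH3OH80  CH3OH50   ISO  BuMe
compound_class
purine/pyrimidines            3.20     3.54     3.77  0.90  2.01
carboxylic acids              3.11     3.63     3.88  0.96  2.00
amino acids                   3.28     3.62     3.75  1.05  2.14
sugars                        3.22     3.67     3.77  0.96  2.02
carnitines                    3.46     3.54     3.75  1.73  2.36
phosphorylated compounds      1.68     2.75     3.85  0.84  1.02
```

Reproducibility of the same table:

```python
prof = sv.reproducibility_profile(table)
row = prof.buckets.query("device=='Capitainer' and solvent=='CH3OH100'").iloc[0]
print(f"CV%<10: {row['cv_lt_10']:.1f}%  10-30: {row['cv_10_to_30']:.1f}%  >30: {row['cv_gt_30']:.1f}%")
# CV%<10: 40.5%  10-30: 56.9%  >30: 2.6%
```

i.e. 97.4 % of features extract with CV ≤ 30 % at the generator's 15 %
replicate noise.

The same workflow runs from the shell on simulated or user data:

```bash
spot-eval all --simulate --seed 7 --out report/
spot-eval score --in matrix.csv --meta samples.tsv --anno annotations.tsv --out report/
spot-eval bca --standards std.csv --unknowns unk.csv --out conc.csv
```

`report/` contains the score report, CV buckets, stability table, volcano
table, PCA summary and a run manifest recording every parameter and the
seed; a fixed seed gives byte-identical bundles.

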