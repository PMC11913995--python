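# Methods

This note documents the models and procedures `spoteval` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the methodology was
genuinely open.

## Data model

The unit of analysis is a wide feature table: non-negative LC-MS
intensities, rows = annotated features, columns = extracted samples. Each
feature carries an assay (`polar` or `lipid`) and a compound class — six
polar classes (purine/pyrimidines, carboxylic acids, amino acids, sugars,
carnitines, phosphorylated compounds) and eight lipid classes (Cer, LPC,
PC, PE, PI, PS, SM, TG). Each sample carries device (Capitainer, Whatman,
Telimmune), solvent (CH3OH 100/80/50 %, ISO, BuMe), replicate, storage
day, extraction mode (single/consecutive) and an optional per-sample assay
restriction (`both` by default, since one extract is typically split over
both platforms). The design key (device, solvent, replicate, day, assay,
extraction mode) must be unique; the per-sample assay field is part of the
key so that assay-split exports of the same physical samples remain valid
tables.

A zero intensity means "not detected". Blank matrix cells are read as 0;
no distinct "not measured" state exists, because the workflow has no use
for one. Validation is total: malformed input raises a typed
`ValidationError` naming the offending id or value, never a silent
coercion.

## Extraction score

Relative intensity is computed per feature against the feature's maximum
over the in-scope samples, as a percentage, then binned
lower-inclusive/upper-exclusive: `<25 → 1`, `[25,50) → 2`, `[50,75) → 3`,
`≥75 → 4`, with score 0 reserved for raw intensity exactly 0. Keying
score 0 to non-detection (rather than to 0 % relative intensity) means a
detected-but-tiny signal scores 1; the max-anchoring property guarantees
every detected feature has at least one score of 4 in its scope.

The scope of the maximum defaults to *device × assay* — all solvents,
replicates and days of one device pooled — because devices are evaluated
and ranked independently. `scope="assay"` pools devices for users who
want a global anchor. Whether zero-intensity cells enter the per-class
heatmap averages was an open choice; they are included (as score 0), since
failing to extract is information about the solvent. A class with no
features yields a missing (NaN) heatmap cell, never 0.

Condition totals use the sample standard deviation (n−1) over replicate
totals; single-replicate groups report SD 0 with an explicit
`single_replicate` flag rather than NaN.

## Reproducibility (CV %)

`CV% = 100·SD(n−1)/mean` over the raw replicate intensities of one
condition. A feature needs at least two detected (positive) replicate
values; otherwise its CV is undefined (NaN), flagged, and excluded from
the bucket denominators. The printed bucket labels `<10`, `10–30`, `>30`
leave the boundary values unassigned, so the buckets are implemented as
`[0,10)`, `[10,30]`, `(30,∞)`: every defined CV lands somewhere and
"greater than 30 %" keeps its plain meaning. Bucket percentages always sum
to 100 % of defined-CV features. CV is computed on raw intensities — it is
scale-invariant per feature, so per-sample normalization would only
distort it; the profiling function rejects normalized tables.

## Short-term stability

Per feature, replicate means at day *d* are compared to the day-0 mean:
`v_f(d) = 100·(m_f(d) − m_f(0))/m_f(0)`. Class variation is the mean of
`v_f(d)` over the class's features (aggregation `feature_mean`, the
default) so a few high-abundance features cannot mask class-wide
degradation; `class_sum` (variation of the class-summed signal) is
available as the alternative. Features undetected at baseline are excluded
from the class aggregate and counted. Day-0 variation is exactly 0 by
construction. A class is stable at day *d* when `|variation| ≤ band`, the
band defaulting to ±20 %, inclusive — a class sitting exactly on −20 % is
still stable. For geometric decay at rate *r* the first unstable day has
the closed form `min { t : (1−r)^t − 1 < −band/100 }`, exposed as
`first_unstable_day_analytic` and used as the oracle in tests (r = 0.1
crosses the 20 % band between days 2 and 3).

## Volcano comparison

Consecutive (methanol + water) vs single methanol extraction, unpaired:
the two extraction arms come from different spots, so a paired test would
be wrong. Per feature, a two-sided Welch (unequal-variance) t-test on
log10 intensities and a linear fold change of sum-normalized group means
(positive = higher in consecutive). Zeros are floored at half the smallest
positive value across both groups before the log; features undetected in
both groups are excluded and reported. Significance is the joint call
`p < 0.05` and `|FC| ≥ 1.5`; thresholds are parameters. No
multiple-testing correction by default (the thresholds are conventional
raw-p volcano settings); Benjamini–Hochberg adjustment is available via
`fdr=True`. NaN p-values (zero variance in both groups with equal means)
map to 1.

Note that sum normalization couples features: boosting one class deflates
every other feature's normalized mean by the ratio of column sums. The
fold changes reported are therefore *relative to total signal*, which is
the quantity the normalization is meant to deliver; when the boosted class
is a large share of total signal its apparent FC shrinks accordingly.

## PCA

Samples × features, mean-centered per feature (autoscaling optional;
zero-variance features dropped under autoscaling), full SVD via
scikit-learn. Variance-explained percentages sum to 100 over all
components; the PC1+PC2 sum is reported as the clustering summary.
Centering (not autoscaling) is the default: the inputs are already
sum-normalized and log-transformed, and unit-variance scaling would
inflate near-constant features.

## BCA calibration

Ordinary least squares of absorbance (562 nm) on standard concentration
(default standards 0–2000 µg/mL), inverted as
`C = DF·(A − intercept)/slope`. A non-positive slope raises `AssayError`
(the reaction failed). Estimates whose undiluted concentration falls
outside the standard range are flagged as extrapolation. Because BCA can
curve at the top of its range, a quadratic fit (`degree=2`) is available;
its inversion picks the real root closest to the working range.

## Synthetic-data generator

The generator emulates the *statistical* structure of a device × solvent
screen, not chromatography:

```
x_fij = base_f · yield(class_f, solvent_j, device_j) · decay^day · ε,
ε ~ Lognormal(0, σ),  σ = sqrt(ln(1 + cv²)),  then x < LOD → 0
```

* `base_f` — per-feature latent abundance, log-uniform over
  `10^4…10^7` (typical Q-TOF peak-intensity range).
* `class_yield` — relative extraction yield per (class, solvent, device)
  in [0, 1]. The defaults encode the expected solvent chemistry: polar
  classes extract best with aqueous methanol (most strongly for
  phosphorylated compounds, which gain with every % of water) and worst
  with pure isopropanol; lipid classes lose yield with water content and
  extract well with the pure organic solvents.
* `noise_cv` — target replicate CV; the lognormal σ is derived so the
  realized CV equals it exactly. Default 0.15, a typical technical
  replicate CV for this kind of workflow (most features land in the
  10–30 % bucket). `noise_cv=0` disables noise for analytic limits.
* `detection_limit` — absolute censoring threshold applied *after* noise
  (default 2000), so low-yield conditions produce realistic non-detects
  that exercise the score-0 branch.
* `decay_rate` — fractional loss per day per class, i.e. geometric decay,
  the simplest model producing monotone variation-to-baseline curves.
  Quantitative decay rates are not published for these devices, so the
  defaults are illustrative: 0.03/day for most classes (stays inside the
  ±20 % band through day 5) and 0.10/day for the labile classes
  (purine/pyrimidines, sugars, Cer, PE), which then cross the band between
  days 2 and 3 — a qualitative pattern expected of room-temperature
  storage. All rates are user-configurable.
* Design sizes default to the study layout: 3 devices × 5 solvents × 3
  replicates for the extraction screen, days 0–5 for stability, n = 3 per
  arm for the single/consecutive pair, 27 features per class.

One `numpy` Generator seeded from the config drives everything, consumed
in a fixed documented order (feature draws first, then samples in
canonical device → solvent → replicate/day order), so identical
seed + config gives byte-identical tables. Every generator returns the
ground truth (base abundances, yields, decay rates) for
parameter-recovery tests.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chromatographic drift and peak-shape artifacts,
hematocrit-dependent spreading on non-volumetric cards, inter-subject
biological variance (the emulated design used one donor), correlated
noise between features, and matrix effects/ion suppression. Results on
synthetic tables validate the *computations*, not the biology.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use deliberately compact
designs chosen to make every check sharp: oracle comparisons on 200 random
matrices up to 10 × 15 with integer intensities (integer grids force exact
bin-boundary hits at 25/50/75 %); solvent-ranking recovery with one class
of 30 features over 100 seeds; CV calibration with 1000 replicates of 100
features; volcano error rates with 500 features × 200 seeds. For the
zero-noise ranking check the five solvents must occupy five distinct score
strata, but there are only four positive bins — so the configured yields
(0.005/0.2/0.4/0.6/1.0 with detection limit 1000 on a 10^4–10^5 base
range) push the lowest solvent below the detection limit (stratum: score
0) and place the remaining four in relative-intensity bins 1–4. That makes
the ranking deterministic for any seed rather than a property of one lucky
draw.

Float comparisons in I/O round-trips use 1e-9 relative tolerance (matrix
values are written with 12 significant digits). Scoring bin edges are
compared with plain `>=` on the exact ratios; since `v/max·100` is exact
for equal values (100 %) and for representable ratios, boundary behaviour
is deterministic.

## Known limitations

* The workflow starts from annotated feature tables; peak picking,
  annotation and QC-pool drift correction are upstream concerns.
* The stability call is per class at the experiment's horizon (days 0–5);
  no extrapolation beyond the observed series is attempted.
* The volcano analysis assumes two independent groups of ≥ 2 replicates;
  with n = 3 per arm its power rests on the low technical CV of the
  platform, as the acceptance checks quantify.
* Sum normalization makes fold changes relative to total signal (see
  above); absolute recoveries require spiked standards, which the
  workflow does not model.
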