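# Methods

This note documents the models, parameter choices and numerical conventions
behind `aggrescreen`, and what the synthetic-data validation does and does
not establish about real instrument data.

## Flow-cytometry model and gating

**Event model.** Each well is a two-component mixture: FRET-negative cells
and FRET-positive (aggregate-bearing) cells, mixed at the well's true
positive fraction `f`. Channel intensities are log-normal per channel and
subpopulation — the standard first-order model for cytometer fluorescence,
which is multiplicative-noise dominated. Defaults (natural-log location,
scale):

| channel  | negative | positive | rationale |
|----------|----------|----------|-----------|
| fret     | ln 100, 0.45 | ln 1000, 0.45 | ~10× sensitized emission in aggregate-bearing cells |
| donor    | ln 1000, 0.35 | ln 600, 0.35 | partial donor quenching under FRET |
| acceptor | ln 800, 0.35 | ln 800, 0.35 | acceptor level unaffected |
| viability| live ln 50, 0.5 | dead ln 5000, 0.4 | dead-cell dye stains bright; 5% dead cells |

Units are arbitrary cytometer intensities; only relative separations matter.
A compound's effect is a multiplicative factor on `f` per concentration tier
(1 = inert, <1 inhibitor, >1 exacerbator), clamped into [0, 1]. Study
defaults: 80 library compounds, tiers 2/4/10 µM, 10,000 events/well, induced
baseline fraction 0.30, 6 wells per control role. The 80/3-tier/10,000-event
geometry mirrors a kinase-inhibitor screen of this design; the 0.30 baseline
is a mid-dynamic-range choice so both inhibition and exacerbation are
observable.

**Gating.** Gates are rectangular: a viability cutoff (keep-below for a
dead-cell dye), donor/acceptor minima (the double-positive reporter gate),
and a FRET-positive threshold. The FRET threshold defaults to the 99.5th
percentile of the pooled gated negative-control wells — control-anchored
gating is reproducible and implies a known ~0.5% gate leakage on true
negatives. Consequently the *expected measured* positive fraction of a well
is `f·P(pos ≥ t) + (1 − f)·P(neg ≥ t)`, which is closed-form under the
log-normal model (`expected_gated_fraction`) and is the correct recovery
oracle; comparing against bare `f` would mistake designed leakage for error.

**Score.** Normalized FRET = `%FRET⁺ × FRET MFI` with %FRET⁺ on the 0–100
scale and MFI the *median* FRET intensity of the FRET-positive subpopulation
(median is the cytometry convention behind "MFI"; an all-gated-events scope
is selectable via `fret_mfi(..., scope="gated")` since the narrower
convention is not universal). Wells with no positive events score 0 rather
than erroring so negative controls flow through the screen. Because hit
calling standardizes scores, the %-vs-fraction scale choice provably cannot
change hits (tested as an invariant). Event tables are CSV (one per well);
FCS support was considered and left out — the analysis consumes channel
tables, and conversion is a pre-processing concern.

## Screen statistics

z-scores standardize each compound's score against the compound wells of the
same concentration tier, SD with ddof = 1. Control wells are *excluded* from
the standardization sample and scored against it (`score_against`); this is
what places no-induction controls at strongly negative z rather than at 0,
matching how such screens report control separation. A hit must clear the
±1.5 threshold at every tier by default (the conjunction suppresses
single-tier flukes — under null Gaussian z the three-tier same-side rate is
≈ 2·Φ(−1.5)³ ≈ 6·10⁻⁴ per compound); a single-tier mode (`tiers=10.0`)
covers the alternative convention of calling hits at the top concentration
only. Replicated screens are z-scored per replicate, then averaged per
compound × tier. Z′ uses the standard definition
`1 − 3(σ_p + σ_n)/|µ_p − µ_n|` over maximal-induction vs no-induction
control bands. Waterfall ranking sorts ascending z at a chosen tier with
alphabetical tie-break for determinism.

**Stand-in screen table.** The published score table of the screen this
package's statistics mirror is not redistributable here, so
`synthdata.standin_screen` *constructs* a synthetic 80-compound table whose
z-structure matches the documented outcome (4 named inhibitors beyond −1.5
at all tiers, 5 exacerbators beyond +1.5, rapamycin at mean z 4.49, negative
controls at −1.88). Per tier, pinned z-values for the named compounds are
completed with null compounds solved to give the vector exactly mean 0 and
sample SD 1, then mapped affinely onto a positive score scale; z-scoring's
affine invariance makes the pipeline recover the embedded structure exactly.
It validates the z-score → hit-call → control-scoring machinery, not the
original measurements.

## Image quantification

**Colocalization.** Pearson correlation over all pixels by default (an
optional mask restricts it; Otsu-based foreground masking is provided).
Both r and r² are reported because colocalization literature quotes either.
Constant channels raise rather than return NaN.

**Puncta detection.** Gaussian blur (σ = 1 px) → white top-hat with a disk
of radius 5 px (removes structures larger than the element, flattens
background) → binarize at mean + k·SD of the filtered image (k = 3; the rule
is offset-adaptive, so global additive shifts cannot change counts; an
absolute threshold is available) → 8-connected labeling → keep areas in
[4, 10 000] px². All parameters are exposed; the defaults are package
choices for ~2-px-σ spots, not physical constants. Known limitation: two
Gaussian spots packed near 4 spot-σ apart can merge into one component,
because the blur widens each to σ_eff = √(σ² + σ_blur²) and the midpoint
saddle stays above the adaptive cut; counting studies in this package space
spots ≥ 5 σ apart, where recovery is exact, and note that aggregate-free
noisy frames need a higher k (≈ 6) since with no signal present the adaptive
cut tracks pure noise statistics and admits false clusters.

**Translocation.** Nuclei from the DAPI channel: global Otsu → hole filling
→ distance-transform watershed (peak minimum distance 10 px) → discard
nuclei < 50 px². Each cell's cytosol is the annulus from expanding nucleus
labels by 5 px (`expand_labels` assigns contested pixels to the nearest
nucleus, so annuli never overlap) minus all nuclei. Readout: per-cell
mean(nuclear)/mean(cytosolic) intensity, aggregated as the arithmetic mean
over cells; cells with zero cytosolic mean are excluded and flagged.
Coordinates are 0-based (row, col); areas px² — no physical calibration.

**Area fraction.** Puncta pixels (from the detector's label image) inside a
cell mask over the mask area, in [0, 1]. Area accuracy is boundary-limited:
each object contributes up to ~a one-pixel ring of uncertainty, which is the
tolerance the recovery tests use (disk-shaped planted puncta give exact
truth areas).

**Synthetic frames.** Nuclei are non-overlapping disks placed by rejection
sampling (1000 retries, then a placement error); puncta are Gaussian spots
(truth area = FWHM-disk pixel count) or hard disks (exact truth area). The
correlated channel is `ρ·standardized(aggregates) + √(1−ρ²)·noise`, affinely
rescaled positive — exact target correlation in expectation, exact at ρ = ±1.
The translocation channel assigns cytosolic level c inside each cell disk and
`nc_ratio·c` inside the nucleus, plus Gaussian noise.

## Omics post-processing

Normalization is log2 followed by subtracting each sample's median over
observed values (post-condition: sample medians exactly 0). The container
tracks whether values are already on the log scale, so normalization is
idempotent — re-normalizing centers again (a no-op) instead of double-logging.
log2FC is the difference of group means on normalized values; features seen
in < 2 replicates of either group become NaN and drop out downstream.
Altered sets require an external significance flag AND |log2FC| ≥ 0.5
(boundary inclusive). The internal stand-in — per-feature Welch t-test
(treatment vs control) with Benjamini–Hochberg adjustment at 0.05 — exists
so synthetic recovery tests can run end to end; it is not a replacement for
a real differential-testing framework, and at 3 replicates it has limited
power unless effects are large (recovery studies use planted |log2| shifts
of 2–3 with residual SD 0.1–0.2). Overlap between altered sets is Venn-style
`100·|A∩B|/|A∪B|` (per-set fractions also provided). Replicate correlation
is pairwise-complete Pearson with pairs under 3 shared features flagged NaN.
Clustering is average linkage on 1 − r over log2FC profiles; linkage and
metric are package choices where only "unsupervised clustering" is
conventionally specified. Missing values are never imputed.

The generator plants signed log2 shifts of fixed magnitude on chosen feature
sets over a feature baseline ~N(20, 2) log2 units with i.i.d. N(0, noise_sd)
residuals — group effects and noise only; it does not emulate
missing-not-at-random dropout, intensity-dependent variance, or batch
structure, so passing tests demonstrate correctness of the computations, not
robustness to those real-data pathologies.

## Randomness, determinism and I/O

Every generator derives all randomness from a single config seed through
`numpy.random.SeedSequence` spawning (plates: one child stream per well in
layout order; frames: separate streams for placement/noise/correlated
channel/translocation channel), so outputs are bit-reproducible and locally
stable under config changes. The end-to-end screen runner is deterministic
given inputs + config and records a config hash in its JSON report. Tables
are CSV/TSV with a version header; images are written as 16-bit TIFF
(rounded/clipped on write — round-trips are lossless at integer precision);
reports are JSON.

## Validation scales

Test and acceptance workloads are sized for a laptop-class single core:
20 simulated screens at full per-well depth (10,000 events) for flow
recovery, 50 frames for detection recovery, 5 frames each for
translocation/colocalization/area readouts, and 20 small matrices for
clustering separation. These sizes give binomial/Monte-Carlo error well
inside the asserted tolerances.
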