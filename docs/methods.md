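# Methods

## Scope and data flow

drylysim implements a multi-level drought-response analysis for inbred
legume diversity panels.  Stages are independent library modules joined by
plain-text tables: `synth` (ground-truth simulation of every input) →
`lysimetry` → `water_response`, and `phenotypes` → `association` →
`expression` → `coloc`, orchestrated by `pipeline.run_all`.  Population
structure (Q) and kinship (K) are *inputs*: the package consumes them, it
does not estimate them.  Probe-level array summarization, GO enrichment and
sequence alignment are likewise upstream/downstream of the package, which
ingests gene-level intensity matrices and 12-column tabular alignment hits.

## Lysimeter model and trace processing

The gravimetric model assumes a pot–container system whose weight is
tare + pot water + plant biomass.  The soil surface and container are
covered, so daytime weight decline is transpiration; nightly irrigation
overfills the container and a drainage hole restores a fixed water level, so
consecutive post-drainage morning weights differ by biomass gain alone.
Transpiration is modeled as rate = ETW(s) · W_plant · VPD during daylight
(stomata closed at night), where ETW(s) is the hinge response to relative
soil water content s.  In the simulator the day's assimilate
(wue × transpired water, the carbon side of the gas exchange) is booked into
biomass at midnight: at the daily resolution of PDT and ΔPW this is
gravimetrically equivalent to continuous growth and keeps the daytime weight
decline identically equal to water loss, so the trace-processing identities
(Σ PDT = simulated transpiration; ΔPW = daily gain) hold to 1e-6 g on
noise-free input.

Processing choices:

* **Smoothing** for the rate series: centered moving average, 30-min window
  (Savitzky–Golay order 2 as a config alternative).  Both preserve the daily
  integral to first order.  Irrigation-to-drainage intervals, padded by half
  the window, are masked before differentiation.
* **Windows**: predawn 04:30–05:00, evening 19:30–20:00, midday 11:00–14:00
  local time, all config-overridable.  A day is valid when ≥ 90% of the
  expected samples fall in each window and no irrigation event intrudes;
  invalid days are flagged, not dropped.
* **Plant weight for ETW**: morning weight = configured initial weight plus
  cumulative ΔPW.  During drought there is no irrigation cycle, hence no
  measurable ΔPW; growth does not stop, so the running gain is extrapolated
  as WUE × PDT using the pretreatment WUE fit.  Without this the weight
  estimate freezes and the ETW plateau drifts upward as the plant grows.
* **VPD floor** 0.1 kPa: ETW is undefined at night where dividing by
  near-zero demand would blow up; no analysis uses nocturnal ETW.
* Sign convention: transpiration positive when weight falls.

## Segmented water response

The hinge etw(s) = E_max for s ≥ θ_cr, E_max − slope·(θ_cr − s) below, is
continuous at the breakpoint.  For fixed θ the model is linear in
(E_max, slope) and solved by least squares with slope constrained
nonnegative; θ is located by grid search (step 0.005 SWC units) over
candidates leaving ≥ 2 points on each side, followed by bounded local
refinement.  RSS ties are broken toward the smallest θ (the earliest
stomatal response — conservative).  The tie tolerance scales with Σy² so
exact data recover the truth rather than the tie-break.  When no admissible
candidate exists or the best segmented fit degenerates, a flat model with
θ_cr = None is returned.  Grid search was chosen over derivative-based
segmented regression for robustness at the 7–14 points per plant typical of
a drought phase.  Per-plant fits are aggregated to genotype as mean ± SE;
pairwise Welch t-tests at α = 0.05 feed an insert-and-absorb compact-letter
display.

## Ordinal scores and correlations

The unifoliate-senescence index maps the senesced leaf-area fraction f to
0–5: 0 iff f = 0; 1 for f ≤ 20%; 2 for 20% < f ≤ 40%; 3 for 40% < f ≤ 60%;
4 for 60% < f ≤ 80%; 5 otherwise or when the plant is dead/fallen.  The
printed bins leave 80% < f ≤ 100% unassigned; the implementation assigns 5,
consistent with the "complete senescence" anchor.  Wilting and stem-greenness
scales have only endpoint anchors and enter as validated integers.  RWC =
(FW − DW)/(TW − DW) × 100.  Cross-year trait correlations are Pearson by
default (Spearman available given the ordinal scale), computed on
replicate-mean scores per accession; cells with p > 0.05 are masked, and
pairs sharing fewer than 10 accessions are skipped.

## Association scan

Replicate scores are averaged per accession and year before scanning; raw
0–5 means are used untransformed.  Missing genotype calls are mean-imputed
per marker.  The GLM is trait ~ intercept + Q (last column dropped, since
memberships sum to one) + dosage, with a 1-df partial F-test and partial R²
as variance explained.  The MLM uses the P3D/EMMAX approximation: δ =
σ_e²/σ_g² is estimated once on the null model by REML, profiling the
likelihood over log δ on a grid with bounded refinement, using the spectral
decomposition of K; each marker is then tested by GLS in the whitened
rotated basis.  With K = I the weights are constant and the MLM reproduces
the GLM exactly (regression-tested to 1e-6 relative).  Both scans are
vectorized closed-form least squares (residualize against covariates, form
F from cross-products); statsmodels OLS serves as an independent oracle in
the tests, never as the implementation.  P-values are capped at 1e-16 for
perfect fits and flagged.  Significance: −log₁₀P > 3 in at least 2 distinct
(model, year) combinations — the threshold is config-exposed (an equivalent
P < 0.01 convention exists in the literature) and the consistency rule
mirrors how published marker tables list ≥ 2 supporting detections.  The
published 41-row marker–trait table (39 distinct loci; 26 Scu, 4 Wt, 11 Stg,
two dual-trait loci) is bundled as a TSV fixture for bookkeeping tests and
comparisons.

## Expression

Quantile normalization equalizes column distributions exactly (mean of
order statistics; ties averaged).  The per-contrast test is a Welch
two-sample t on log₂ intensities — the FDR procedure's base test is a
package choice, documented here, since array pipelines vary — with
Benjamini–Hochberg step-up adjustment *within* each genotype × tissue
contrast (contrast-wise DEG sets are what downstream Venn bookkeeping
consumes).  Genes with zero variance in both arms fall back to a pooled
test and are flagged.  DEG thresholds are inclusive: |log₂FC| ≥ 1 and
FDR ≤ 0.01.  Venn counts compare two genotypes per direction with genes
pooled over tissues.  Family profiles (e.g. aquaporins) report per-member
regulation cells plus tissue-specific / genotype-specific tallies; family
ids absent from the matrix are listed as not assayed.

## Co-localization

Genetic route: same linkage group and coincident (0 cM) or strictly
< 2 cM — the panel's average LD decay distance; the strict inequality
follows the "coincident with or < 2 cM" convention.  Physical route: best
ortholog hit per sequence (aligned length ≥ 80 bp, e-value ≤ 1e-10; best =
lowest e-value, ties by bitscore then length), then same chromosome and
interval *edge gap* ≤ 1.8 Mb inclusive (the stated maximum distance,
equivalent to ~2 cM); overlap counts as gap 0 and the midpoint distance is
reported alongside.  Edge gap was chosen over midpoint distance because
unigene hits are intervals and the window is an LD argument — conservative
inclusion.  The union of routes is deduplicated by (unigene, SNP) with the
evidence labels concatenated.

## Synthetic data: what it emulates, what it does not

* **Climate**: sinusoidal diurnal temperature between 15 and 34 °C peaking
  at 14:00, RH 30–85% in anti-phase; optional Gaussian noise.  Daylight
  06:00–19:30.
* **Lysimeter**: 4 L pots with 1000 g plant-available water (pot capacity
  and initial 20 g plant weight are config defaults chosen as
  greenhouse-realistic; no published values exist for them), nightly 22:00
  irrigation with 20% overfill and 23:00 drainage-complete markers,
  measurement noise on the load cell.  Default truths
  (E_max = 1e-3 g·g⁻¹·kPa⁻¹·min⁻¹, θ_cr = 0.35, slope = 4e-3 per SWC unit,
  WUE = 0.05 g/g) give ~45–130 g/day transpiration and a drydown that
  crosses θ_cr in the middle of a 10-day drought, as in the study design of
  5–7 pretreatment, 10–14 drought days with ≥ 7 plants per genotype.
  `simulate_midday_points` runs the same water-balance model at day
  resolution for fast Monte-Carlo recovery studies (noise = 5% of E_max by
  default); the minute-resolution trace simulator backs the end-to-end
  zero-noise identities.  Not modeled: soil physics (Richards equation),
  canopy energy balance, soil evaporation (surface covered).
* **Panel**: 95 accessions × 1127 SNPs by default, two subpopulations
  (Balding–Nichols allele frequencies, Fst = 0.15), inbred 0/2 coding
  (selfing crop), soft Q memberships, VanRaden K from the genotypes.
  Liabilities = Σ marker effects + structure shift + Gaussian noise scaled
  to the stated h²; replicate-level noise at 30% of the accession noise;
  scores via equal-probability normal bins to 0–5.  No linkage
  disequilibrium beyond structure — markers are exchangeable, so positional
  clustering of hits is not emulated.
* **Expression**: log-normal intensities (log₂ baseline N(8, 1.5²)),
  planted DEGs shifted in the stressed samples of their condition,
  replicate noise 0.13 on the log₂ scale — calibrated so replicate Pearson
  r falls in the 0.94–0.99 band reported for high-quality array replicates.
  No probe effects, batch structure, or intensity-dependent variance, so
  passing recovery tests demonstrates the statistics, not robustness to
  array artifacts.
* **Maps/orthologs**: 11 linkage groups (100 cM) and 20 pseudo-chromosomes
  (50 Mb); exactly `planted_pairs` DEG–SNP pairs are placed inside each
  co-localization window and every other placement is rejection-sampled to
  stay outside by ≥ 1.5× the window, making the planted truth an exact
  oracle.

All generators are deterministic given their seed; derived stage seeds come
from SHA-256 of the run seed and a stage label (kept below 2³¹).

## Numerical and validation notes

* Problem sizes in the test suite (e.g. 200-seed recovery studies at 7
  plants × 10 days, 500 × 200 permutation calibration, 95 × 200 panels) were
  chosen to give stable Monte-Carlo verdicts at interactive runtimes.
* The segmented-fit recovery criterion is evaluated on pooled per-genotype
  midday points (7 plants × 10 days), the same pooling offered for
  genotype-level fits.
* Degenerate inputs: monomorphic markers are flagged and skipped, not
  scanned; all-one-side breakpoint data return the flat model; days with
  missing windows are flagged invalid; queries without surviving ortholog
  hits simply have no physical route.
* Known limitations: no multi-breakpoint water-response models; no
  genome-wide FDR for the scan (fixed threshold by design); recovery-phase
  physiology is simulated but not analyzed; ordinal traits are scanned as
  replicate-mean scores rather than via ordinal models.
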