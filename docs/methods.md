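# Methods

## Scope and model of the data

`lipidshift` analyses targeted lipidomics experiments with a paired
before/after design: each subject is sampled once before and once after a
treatment, two independent treatment arms are processed separately, and
each arm carries its own pooled process-QC (PQC) samples and extraction
blanks.  Measurements arrive as raw MRM/SIM peak areas, long format, one
record per (sample, species), spread over four analytical panels
(phospholipid/CE/DG, sphingolipid, S1P, TG).

The package treats integrated peak areas as the atomic unit.  Peak
detection, retention-time assignment and chromatography are upstream
concerns and outside its scope.

## Quantification

Single-point internal-standard quantification with an implicit response
factor of 1:

* normalised area `= analyte area / ISTD area` (same sample, same panel),
* relative concentration `= normalised area x ISTD molar concentration`
  (µmol/L).

The resulting values are *relative* abundances: they are proportional to
the true molar concentration per species, which is sufficient for the
ratio-based statistics downstream but not for cross-species absolute
comparisons.  Blanks are quantified against their own ISTD areas — the
ISTD is spiked during extraction, so normalisation is defined there too.

### S1P isotope interference

S1P d18:0 is two mass units heavier than S1P d18:1 and co-elutes with its
M+2 isotopologue.  Before quantification the pipeline subtracts
`fraction x area(S1P d18:1)` from the S1P d18:0 area in every sample.  The
default fraction is the carbon-only binomial M+2/M+0 ratio for an
18-carbon backbone, `C(18,2) (p/(1-p))^2 ≈ 0.0179` at `p(13C) = 0.0107`;
contributions of 2H/15N/18O are ignored.  The fraction is a configuration
parameter (`isotope_fraction`) so an empirically measured cross-talk
factor can replace the theoretical one; the choice is echoed in the run
manifest.  Negative corrected areas are clamped to zero with a warning
rather than raising — blanks legitimately sit below the interference
level.

## QC filter cascade

Per treatment group, a species is excluded when any of the following
holds, with the *first* failing rule in this order recorded as the
decision (the kept/excluded outcome itself is order-independent because
the rules are conjunctive; a property test verifies this indirectly via
monotonicity):

1. `excluded_missing` — not quantified (non-finite) in every study sample
   of the group, or its PQC CV is not estimable (mean ≤ 0);
2. `excluded_area_floor` — median raw PQC area `< 250` counts;
3. `excluded_blank_ratio` — median raw PQC area `< 5 x` median blank area.
   A blank median of exactly 0 passes (ratio treated as +∞): absent
   background cannot justify exclusion;
4. `excluded_cv` — percent CV of the *normalised* area over the group's
   PQC replicates strictly `> 25%` in **any** group (a high CV in one arm
   removes the species from both, keeping the arms comparable).  The
   comparison is strict: a CV of exactly 25.0% passes.  CVs use the
   sample standard deviation (n−1).

Species on the override list survive rule 4 with the distinct decision
`kept_by_override`, with both groups' CVs recorded in the report; this is
the documented escape hatch for borderline species that must stay in the
dataset for cross-arm comparison.

The final cross-group dataset is the set of species kept (or
override-kept) in *all* groups with finite values in every study sample.
Species kept in only one arm remain in that arm's reporting set and are
flagged not-quantified for the other.

Thresholds (250 counts, ratio 5, CV 25%) are the conventional defaults for
this assay family and are configurable (`FilterConfig`).

## Differential statistics

The unit of analysis is the per-subject log2 fold change
`log2(after/before)`.  Per species and group:

* paired two-tailed t-test on log2-transformed concentrations
  (`df = n − 1`); a zero-variance difference vector yields an undefined
  (NaN) p-value, flagged degenerate, never "significant";
* Benjamini–Hochberg FDR across the group's reporting set (one family per
  treatment group by default; `fdr_scope="class"` restricts families to
  lipid classes).  NaN p-values are excluded from the family size `m`;
* the reported fold change is the back-transformed mean log2FC (the
  geometric mean of the per-subject ratios) under the signed display
  convention: decreases appear as negative reciprocals, so −2.0 means
  halved, and log2FC −1 maps exactly to −2.0;
* significance at `p_FDR ≤ 0.05`, with a second tier at ≤ 0.01.

Clinical-chemistry analytes (cortisol, lipase, total TG, ...) are
summarised per analyte with the median of the per-subject *signed* fold
changes and an unadjusted paired-t p-value on log values — single-analyte
tests form no family.  Note the median is taken after the signed
transform; because the transform is monotone this matters only for even
n, where the median interpolates between two subjects.

Covariate adjustment (sex, age, weight) is deliberately absent; sex
effects are surfaced descriptively through the fold-change PCA.  Subjects
can be excluded for sensitivity analyses via `drop_subjects`.

## Saturation-class analysis

Within an acyl class (PC, PE, PI by default) species are stratified by
total double bonds: ≤ 3 vs ≥ 4.  Sphingolipid totals include the
sphingoid-base unsaturation (Cer d18:1/18:0 counts 1 double bond); this
convention keeps the carbon/double-bond sums consistent and is inert for
the stratified analysis, which targets glycerophospholipids.  Ether (-O),
plasmalogen (-P) and lyso subclasses carry distinct class tokens and never
enter the acyl totals.  Per sample the strata are summed — the two totals
add up exactly to the class total, an identity the tests check to
numerical precision.

Four tests per class and group:

* paired t on log total (≤ 3 stratum), likewise for ≥ 4;
* paired t on `log(total_GE4 / total_LE3)` — invariant to per-sample
  dilution;
* an **unpaired** two-sample Welch t comparing per-species mean log2FCs
  between the strata.  Species are the experimental units here and there
  is no pairing structure across strata; Welch (unequal variances) is the
  default because stratum sizes and spreads differ.  A paired variant
  across subjects is not offered; the species-level contrast is the one
  the stratified display motivates.

## Multivariate views

* PCA of concentrations: log2 transform, centre and unit-variance scale
  each species column (correlation-mode PCA), SVD of the preprocessed
  matrix, components up to `min(n − 1, p)`.  Percent variance sums to 100
  over the reported components.  Component orientation is fixed
  deterministically: the largest-magnitude loading of each component is
  made positive.
* PCA of log2 fold changes: same machinery on the subjects × species
  fold-change matrix (no log transform — the input is already on log
  scale).
* Hierarchical clustering: per-species autoscaling (z-scores of log2
  values, sd with n−1), Pearson correlation distance `1 − r` between
  species and between samples (on the autoscaled rows), Ward
  agglomeration via an explicit Lance–Williams recurrence.  Both common
  Ward variants are exposed: `D2` (recurrence on squared dissimilarities,
  square-rooted heights — the default, and the variant consistent with
  SciPy's `ward`) and `D` (recurrence on the dissimilarities as given).
  Ties break deterministically on the lowest cluster-id pair.  Dendrograms
  are emitted as Newick text with height-difference branch lengths.

Degenerate inputs fail loudly: constant species columns (scale undefined),
non-positive concentrations (log undefined), all-identical fold-change
rows (zero total variance) each raise an error naming the offender.

## Synthetic experiment generator

The generator produces complete experiments — peak-area table, sample
metadata, ISTD map, ground truth — with the structure the pipeline
assumes.  Defaults encode the study design the package targets: arms of 8
(3 female) and 6 (2 female) subjects, paired sampling, 8 PQC injection
replicates and 3 blanks per arm, 263 species over 20 classes in 4 panels
(species counts per class mirror a typical canine plasma panel: 16 Cer,
10 Hex1Cer, 12 PI, 4 S1P, 1 PS, ...).

Generative model, per arm:

* species baseline = per-class abundance scale × a species-level lognormal
  spread (log10 sd 0.5), shared by both arms;
* per-subject baseline offset: lognormal, CV 35% (between-subject);
* per-timepoint residual: lognormal, CV 20% (within-subject) — this is
  what limits paired power;
* treatment effect: multiplier on the after sample, resolved per species
  from `species name > class±double-bond stratum > class`;
* areas = concentration / ISTD concentration × panel ISTD area × a
  per-sample injection factor (lognormal, CV 8%, cancelled by
  normalisation) × technical noise (lognormal, per-panel CV: 5% PL/CE/DG,
  11.5% sphingolipid, 10% S1P, 18% TG — chosen so panel median PQC CVs
  land in the range typical for these assay types);
* PQC pool = arithmetic mean of all of the arm's study-sample
  concentrations (equal-volume pooling of plasma before extraction), then
  re-measured per injection replicate with fresh technical noise;
* blanks = 1% of the pool signal (0.5 for planted blank-ratio failures);
* S1P d18:0 areas receive `+0.0179 × area(S1P d18:1)` so the pipeline's
  isotope correction has real work to do.

All lognormal noise uses `CV² = exp(σ²) − 1` and mean-1 parameterisation.
Identical configs are reproduced byte-for-byte; different seeds share the
catalog and draw fresh noise.

Planted QC failures serve as ground truth for filter fidelity: 3
area-floor species (baseline forced to ≈100 counts), 2 blank-ratio species
(blank fraction 0.5 → ratio ≈ 2), 4 high-CV species.  The planted
technical CV is 80% with 8 PQC replicates: a CV *estimate* from k
replicates has a relative sampling error of roughly `1/sqrt(2(k−1))
≈ 27%`, so the planted failures must sit far above the 25% threshold for
the planted decision to be recovered deterministically; 80%/8 leaves the
misclassification probability well below 1% per species.  The two
override species are planted at 40% true CV in one arm — above threshold,
but realistically borderline, so at rare seeds their *estimated* CV can
fall under 25% and they are then simply "kept"; tests assert the override
path conditionally on the observed CV.  Planted species always carry
multiplier 1.0 so the QC rule alone determines their fate (a treatment
effect would otherwise shift the pooled-PQC median).

The study preset (`preset_glucocorticoid_study`) encodes the headline
glucocorticoid effect pattern: Hex1Cer up (~2×) in both arms; PI down and
S1P up in the short-term arm; ether/plasmalogen PC and lyso-PAF down, TG
up (~4×), S1P d16:1 down, and a polyunsaturation shift in acyl PC/PE/PI
(≥4 double bonds ×0.55, ≤3 ×1.4–1.6) in the long-term arm, plus a few
single-species effects.

### What the generator does *not* emulate

Chromatographic drift and batch order, missingness/censoring at the
detection limit, correlated noise between co-eluting species, subject
covariates (age, weight) influencing response, heavier-tailed biological
variation, and absolute abundance scales (per-class scales are
order-of-magnitude placeholders).  Passing tests therefore demonstrate
that the pipeline's rules and statistics behave correctly under the
assumed noise model — not that the model captures every property of real
plasma data.

## Problem sizes used in tests and the acceptance script

Type-I error is estimated from 4000 vectorised paired tests per n ∈ {6,
8} on lognormal null draws; FDR control under the global null from 100
seeded full-pipeline runs (both arms each, ~250 species); parameter
recovery from a single seeded run of the full design (n = 8, 10-species
class, residual CV 15%).  These sizes give Monte-Carlo standard errors
comfortably inside the asserted bands (e.g. ±0.35% on a 5% rejection
rate at 4000 replicates).

## Known limitations

* Single-point ISTD quantification assumes response factor 1 per species;
  no calibration curves or species-specific response correction.
* The BH procedure assumes independence/PRDS across species; lipid
  species within a class are correlated, so FDR control is approximate on
  real data (exact under the generator's independent-noise null, as the
  Monte-Carlo test shows).
* With n = 6–8 subjects the per-species tests have limited power for
  effects under ~1.5×; the package reports effect sizes alongside p-values
  for this reason.
* The QC CV estimate from 8 PQC replicates is itself noisy (±27%
  relative); borderline species near the 25% threshold are filtered
  stochastically on real data.  The override list is the explicit remedy.
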