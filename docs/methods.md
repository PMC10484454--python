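# Methods

## Scope and data model

`wormscore` analyzes per-animal measurements from five assays commonly
used to phenotype *C. elegans* lamin-variant strains: viability (brood
size and embryonic lethality), swimming motility (body bends per second,
BBPS), hyp7 nuclear migration, nuclear morphology (bleb counts) and
nuclear-envelope fluorescence. Every assay travels as an `AssayDataset`
(tidy DataFrame + assay tag); all statistics and the scoring rubric
consume that one container, so data can enter from tidy CSVs, from a
per-figure workbook of raw values, or from the built-in simulator
interchangeably.

## Synthetic data generator

The generator exists so that every downstream stage has ground truth. Its
defaults encode the study conditions of a twelve-variant lamin panel:

* **Brood size** ~ negative binomial with mean `brood_mean` and dispersion
  `k` (`var = mu + mu²/k`), zero-inflated by `sterile_fraction`. Counts of
  eggs per mother are overdispersed animal-to-animal; a Poisson would be
  far too narrow. Wild type uses mean 280, k = 8 (a typical
  self-fertilizing hermaphrodite brood); severe-class variants use means
  ~35% of wild type.
* **Embryonic lethality**: unhatched ~ Binomial(brood, `lethality_prob`);
  1% for wild type, 26–28% for the severe class, 100% for the
  inviable-egg strain, irrelevant for the fully sterile strain.
* **Swimming** ~ two-component mixture of normals truncated at 0:
  an unimpaired component (wild type mean 1.86 bends/s, SD 0.35) and an
  impaired component (mean 0.35–0.5), mixed by `impaired_fraction`. The
  truncation honors BBPS ≥ 0 and the observed near-zero swimmers; the
  mixture reproduces the wide within-strain spread from normal swimming
  to near-paralysis. Mixture weights for the affected strains were set so
  the population means land on the published strain means (wild type
  1.86, Y59C 1.10, L535P < 1) and the population defect fractions sit
  clearly on the correct side of the 30% rule at n = 40.
* **Migration**: mislocalized nuclei ~ Binomial(`nuclei_per_animal`,
  `mig_fail_prob`). The number of scorable dorsal-cord hyp7 nuclei per
  animal is not a published constant; the default is 16 and configurable.
  Failure probabilities: ~0.005 wild type, 0.27 for the two
  migration-defective severe variants (20–35% of nuclei), 0.75 for the
  separation-of-function variant.
* **Blebs** ~ Poisson(`bleb_rate`) per animal side; **fluorescence** ~
  Normal per nucleus, already on the background-corrected (CTCF) scale.

Randomness: one global integer seed; each (assay, genotype) pair draws
from `default_rng([seed, crc32(assay), crc32(genotype)])`, so adding an
assay or strain never perturbs another's draws, and every dataset is
byte-reproducible.

What the simulator does **not** emulate: day-to-day batch effects,
within-animal correlation across assays (the same worm being both slow
and bleb-rich), balancer-chromosome genetics, plate-position or
temperature covariates, measurement error in egg counting. Passing tests
therefore validate the statistical machinery and rubric logic under the
stated generative models, not robustness to those real-world
complications.

### Swim videos

`generate_swim_video` renders each animal as a thickened
sinusoid-backboned polyline (length 70 px, amplitude 8 px, thickness
3 px) on a noisy 8-bit background (base 10, Gaussian SD 5, default
512×512 — larger frames for bigger cohorts), 30 fps for 30 s by default.
The amplitude envelope oscillates so the animal straightens once per
bend.

*Bend convention.* One body bend is one one-sided flex — two bends per
full left–right cycle, the usual thrashing-assay count. Any
chirality-blind shape scalar (such as the elongation used by the
tracker) repeats twice per full mirror-symmetric cycle, so under this
convention the bend signal oscillates exactly once per bend and a worm
with `bend_freq_hz = f` has true BBPS `f`.

Worms are placed on a randomized non-overlapping grid and drift slowly
(1 px/s) perpendicular to their body axis. The drift is deliberate: a
purely in-place thrasher occupies its backbone nodes in every frame, and
a median background model would absorb those pixels and split the animal
on subtraction.

## Video processing chain

1. **Background**: per-pixel median over at most 64 evenly spaced frames
   (`median_stack`; subsampling keeps memory flat and the median stable),
   or a centered rolling-window median. Subtraction is clipped at 0.
2. **Threshold**: global Otsu computed from a streamed histogram of the
   subtracted stack, or a fixed level. A constant stack has no Otsu
   threshold and raises. Each frame then gets 2 iterations of
   8-connected morphological closing to bridge the small holes the
   background model leaves where an animal lingers.
3. **Tracking**: connected components (8-connected) per frame; components
   whose centroids fall within 45 px are merged exactly (raw moment
   addition) as fragments of one animal — distinct animals never approach
   that closely. Components below `min_area` (20 px²) are dropped; the
   rest are linked to the nearest live track head (greedy in label order,
   lower label wins ties) within 25 px; tracks idle for more than
   `max_gap` (2) frames are closed.
4. **Bend counting**: the per-frame bend signal is the normalized
   elongation `(l1 − l2)/(l1 + l2)` of the component's inertia-tensor
   eigenvalues — near 1 when straight, dipping as the body curls. The
   signal is mean-centered; crossings are counted with a hysteresis band
   of ±0.25 SD; BBPS = crossings/2/duration. A signal SD below 5×10⁻³
   (motionless animal) counts 0. Tracks shorter than 1 s are not scored.

Closed-loop validation recovers 20/20 worms within 10% (typically < 2%)
relative error at 0.5, 1.0, 1.5 and 2.0 Hz over 30 s.

## Statistics

* Brood size = sum of the (up to three) daily egg counts. Percent
  lethality = 100 × unhatched/brood; undefined (missing, flagged sterile)
  when brood = 0, never coerced to 0. Sterile mothers stay in brood-size
  means but are excluded from lethality means.
* **Dunnett** (viability vs control): pooled one-way ANOVA t statistics;
  adjusted p from `scipy.stats.dunnett`'s multivariate-t integration with
  a fixed internal rng (deterministic reruns; group order is sorted so
  record order cannot shift the quadrature). A family of one collapses
  analytically to the pooled two-sample t and is computed exactly that
  way — the integration's ~3×10⁻⁵ noise would otherwise dominate.
  Relabeling genotypes can reorder the integration and move adjusted
  p-values at the ~10⁻⁴ level; decisions at any sane alpha are unaffected.
* **Tukey** (migration, all pairs): `scipy.stats.tukey_hsd`
  (studentized-range distribution, analytic).
* **Chi-squared** (swimming): Pearson on the 2×2 defective-by-strain
  table, no continuity correction. The defect threshold is 1.1 bends/s —
  the corroborated mean swimming rate of the Y59C strain — and ties at
  the threshold count as defective ("at or below"). A zero-margin table
  returns statistic 0, p = 1, flagged degenerate rather than erroring.
* **Benjamini–Hochberg** (blebs): step-up implemented directly
  (`min_{j≥i} m·p_(j)/j`, reverse cumulative minimum, capped at 1) so it
  matches the textbook definition to the last float; the underlying
  per-strain test is Mann–Whitney (counts are small and skewed).
* **t test** (fluorescence): two-sided pooled Student's t. CTCF is the
  plain arithmetic `IntDen − Area × mean background`, negatives
  preserved.
* Degenerate inputs (zero variance everywhere, identical constant groups)
  return statistic 0 / p = 1 with a note instead of NaNs.
* Base alpha is 0.05 everywhere; FDR 5% for the bleb screen.

## Scoring rubric

Viability: 2 for homozygous inviable — operationally, every mother
sterile OR eggs laid but zero hatch (this single rule covers both the
fully sterile strain and the dead-egg strain); 1 when brood is
significantly reduced OR lethality significantly elevated
(Dunnett-adjusted p ≤ 0.05, direction required); else 0. Swimming: 2 when
the defective fraction strictly exceeds 30% (a fraction of exactly 0.30
scores 0); the χ² test is reported as evidence but is not an additional
gate — the published rule is the fraction cutoff alone. Migration: 1 for
a Tukey-significant excess over control; a strain without migration data
gets N/A, which contributes 0 to the total and is printed as such.
Total = sum of available components; ≥ 2 classifies severe
skeletal-and-cardiac, < 2 mild/cardiac-only. Heterozygous balanced
genotypes are scored only if present as their own genotype labels.

## Calibration experiments

The rubric is always applied in a panel context — Dunnett and Tukey
families span all strains of an experiment — so its calibration is
measured the same way: each replicate simulates a control plus 11
variants (one severe template, ten wild-type-identical) at the published
sample sizes (22/10 mothers, 100/40 swimmers, 20 animals for
migration/blebs). Over 200 replicates, wild-type-identical strains score
a total of 0 in ≥ 95% of cards and severe-template strains classify
severe in ≥ 95%. (Scored as isolated one-variant experiments the null
zero-score rate would be structurally lower — three independent
5%-level families — which is not how the assay batteries are run.)

The χ² type-I calibration draws both groups from the same
moderately-defective mixture (defect probability ≈ 0.5, n = 40 per
group), where the 2×2 Pearson statistic's nominal level is meaningful; at
the wild-type defect rate (~1.5%) expected cell counts are below 1 and
any test is dominated by discreteness.

Printed-value checks (strain mean BBPS, brood ratio) use cohorts of
n = 2000 simulated animals so the Monte-Carlo error (~0.02 bends/s) is
small against the reported precision; the score-table concordance check
runs at the published sample sizes.

## Known limitations

* The tracker assumes non-touching animals (enforced by the simulator;
  real videos with collisions would need occlusion handling).
* The elongation-based bend counter needs the whole animal segmented;
  partial occlusion at the frame edge biases BBPS for those frames.
* Dunnett adjusted p-values carry ~10⁻⁴ integration noise (see above).
* Migration scoring needs ≥ 2 animals per strain; the per-animal nucleus
  denominator (default 16) is a convention, not a measured constant.
* The workbook reader pairs brood and hatch-percentage columns
  positionally per genotype; files that sort the two sections differently
  per animal would silently mispair mothers.
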