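# wormscore

Quantitative phenotyping and pathogenicity scoring for *Caenorhabditis
elegans* models of striated-muscle laminopathy.

Missense variants of the human lamin gene *LMNA* cause diseases ranging
from dilated cardiomyopathy to severe congenital muscular dystrophy, and
hundreds of variants of unknown significance (VUS) await classification.
One way to triage them is to engineer each variant into the single worm
lamin gene *lmn-1* and measure the consequences across a battery of
organismal and cellular assays. `wormscore` implements the full analysis
side of that strategy for researchers running such panels: it takes tidy
per-animal assay tables (or a per-figure workbook of raw values), runs the
per-assay statistics, and condenses them into a per-variant score card.

## The assays and the rubric

| assay | measurement | statistic |
|---|---|---|
| viability | brood size (eggs/mother over 3 days) and % embryonic lethality | one-way ANOVA + Dunnett vs wild type |
| swimming | body bends per second (BBPS) in a 30 s thrashing video | fraction of animals ≤ 1.1 BBPS; χ² vs wild type |
| nuclear migration | hyp7 precursor nuclei stranded in the dorsal cord | ANOVA + Tukey all-pairs |
| nuclear morphology | nuclear blebs per animal side | rank test + Benjamini–Hochberg (FDR 5%) |
| nuclear envelope | corrected total nuclear fluorescence, CTCF = IntDen − Area × mean background | Student's t |

Per variant, the score card is

* **viability** — 2 if homozygous inviable (all mothers sterile, or no egg
  hatches), 1 if brood size or lethality is significantly worse than wild
  type (Dunnett-adjusted p ≤ 0.05), else 0;
* **swimming** — 2 if > 30% of animals swim at or below 1.1 BBPS, else 0;
* **migration** — 1 for a significant excess of mislocalized nuclei
  (Tukey-adjusted p ≤ 0.05), else 0; N/A when the assay wasn't run.

Total ≥ 2 classifies the variant as modeling severe skeletal-and-cardiac
disease; < 2 as mild / cardiac-only.

The package also ships an original swim-video tracker (background
subtraction → binarization → component tracking → bend counting from the
oscillation of each animal's normalized elongation) and a fully
ground-truthed synthetic data generator — per-animal assay draws for every
genotype template and rendered swim videos with known bend frequencies —
so the entire pipeline is testable with no external data.

## Worked example

```python
from wormscore import RunConfig, simulate_panel, run_pipeline, scorecards_to_frame

datasets = simulate_panel(seed=1)          # 12 variants + wild type, all assays
results, cards = run_pipeline(datasets, RunConfig())
print(scorecards_to_frame(cards).to_string(index=False))
```

```
human_label worm_label  viability  swimming migration  score              classification
       N39S       N53S          2         0         1      3 severe_skeletal_and_cardiac
       Y45C       Y59C          1         2         1      4 severe_skeletal_and_cardiac
       R50P       R64P          1         2         0      3 severe_skeletal_and_cardiac
      E358K      E358K          1         0         0      1        mild_or_cardiac_only
      L530P      L535P          2         2         0      4 severe_skeletal_and_cardiac
       E82K       E96K          0         0         0      0        mild_or_cardiac_only
      E161K      E175K          0         0         0      0        mild_or_cardiac_only
      R190W      R204W          0         0         1      1        mild_or_cardiac_only
      K270Q      K284Q          0         0         0      0        mild_or_cardiac_only
      R331Q      K331Q          0         2         0      2 severe_skeletal_and_cardiac
      S407D      G407D          0         0         0      0        mild_or_cardiac_only
      G523R      G528R          0         0        NA      0        mild_or_cardiac_only
```

Each row is one engineered variant (worm residue label plus the homologous
human residue). N53S is inviable as a homozygote (viability 2) and has a
nuclear-migration defect; Y59C adds a swimming defect on top of reduced
viability (total 4); R204W is the separation-of-function case — healthy
fitness and motility but a severe migration defect; K331Q is the VUS the
rubric flags as pathogenic (total 2, severe); G528R was not assayed for
migration, so that cell prints NA and contributes 0.

The same pipeline runs from the shell:

```
wormscore run --seed 1 --out results/demo      # simulate → analyze → score → report
wormscore score --data my_data/ --out results/ --control "wild_type"
```

`wormscore score` accepts a directory of tidy CSVs (`viability.csv`,
`swimming.csv`, ...) or a per-figure workbook (`*.xlsx`, one column per
genotype per assay section). Swim videos (multi-page TIFF or frame
stacks) can be converted to swimming records with
`wormscore.records_from_video`.

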