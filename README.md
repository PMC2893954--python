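# hrscreen

Analysis pipeline for genome-scale DR-GFP homologous-recombination RNAi
screens: plate-based z-scoring, dual-trigger hit validation with
counterscreen and viability exclusions, graded secondary-assay phenotype
classification, hypergeometric category enrichment, AP-MS background
filtering, coding-indel frameshift annotation, and a seeded synthetic-screen
generator with ground truth.

## The problem

In a DR-GFP screen, a reporter cell line carries two non-functional GFP
alleles; an I-SceI-induced double-strand break repaired by homologous
recombination (HR) reconstitutes functional GFP, so the percentage of
GFP-positive cells measures the frequency of HR-mediated double-strand-break
repair. Knocking down each gene with esiRNAs in 384-well plates and reading
percent GFP-positive by flow cytometry turns that readout into a genome-scale
screen for repair genes. Each plate carries four Rad51 esiRNA wells (positive
control, at C3, C21, M5, M18) and twelve Rluc esiRNA wells (non-targeting
negative control).

The statistics are deliberately simple and the package implements them
exactly:

- **Primary screen** — per-plate z = (x − μ)/σ with μ, σ over the plate's
  sample wells (controls excluded), averaged over duplicates; |avg z| > 2
  (strict) calls a primary hit.
- **Validation** — z against the Rluc wells, averaged over 4 replicates, for
  two independent silencing triggers per gene; one trigger beyond ±2 and the
  second beyond ±1.5 in the same direction validates the gene (a gene with a
  single usable trigger needs |z| > 4).
- **Counterscreen** — knockdowns that also dim GFP in constitutively
  GFP-expressing cells (z < −4) are confounds and are excluded.
- **Phenotype grades** — arrow grades on the validation z (±4/±2/±1.5
  bands), viability from the relative untreated cell-number decrease
  (>50% → "++", >25% → "+"), drug/IR sensitivity from the double-normalised
  drug-specific decrease d = 1 − (treated/untreated)_gene ÷
  (treated/untreated)_Rluc (≥40/30/10% → "+++"/"++"/"+"), and gamma-H2AX
  kinetics by two-sided Student's t test vs Rluc at 1 h and 6 h post-IR
  (p < 0.05 annotates an arrow).
- **Enrichment** — fold = (k/n)/(K/N) with the exact upper-tail
  hypergeometric p, Benjamini–Hochberg adjusted across categories.
- **AP-MS filters** — ≥3 peptides with MASCOT ions score > 20 per
  experiment; proteins in >15% of 193 control immunoprecipitations are
  common background (baits exempt).
- **Variant consequences** — HGVS-style c. indels applied to a CDS,
  translated, and rendered as p.\<ref\>\<pos\>\<alt\>fsX\<k\> frameshift
  nomenclature (retained anchor: stop at pos + k).

## Worked example

The package ships the published 62-gene candidate table as a programmatic
fixture. Transcribing its per-trigger arrow grades into representative z
values and running the funnel:

```python
from hrscreen.datasets import hit_funnel
funnel = hit_funnel()
```

prints (via `python examples/hit_funnel.py` or `hrscreen funnel`):

```
validated decreasers : 45
validated increasers : 17
after counterscreen  : 61  (excluded: MKNK2)
decreasers characterised : 44
viability '++' exclusions: 13
secondary-assay cohort   : 31
```

45 + 17 genes validate with two independent triggers; one gene is excluded
because its knockdown reduces GFP levels directly, and of the 44 remaining
decreasers the 13 with severe viability loss do not enter the
drug-sensitivity and gamma-H2AX assays, leaving 31 fully characterised rows.

Frameshift arithmetic on the notation of a 14-bp coding deletion:

```python
from hrscreen.variants import stop_position_from_fs
stop_position_from_fs("p.L471LfsX56")   # -> 527
```

More narrative scripts live in `examples/` (simulation and scoring,
phenotype grading, enrichment, AP-MS filtering, variant consequences), and a
thin CLI exposes the same stages (`hrscreen layout|simulate|score|call|
phenotype|enrich|apms-filter|variant|run`).

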