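# clonescape

Clonality analysis for tumor genomes: estimate tumor purity from SNP-array
B-allele frequencies, quantify which copy-number alterations and somatic
point mutations are clonal versus subclonal, summarize point-mutation
signatures, and test methylation–mutation-signature associations. The
package targets the single-sample setting of a lung-adenocarcinoma-style
cohort study — whole-exome mutation calls, array-based copy-number segments,
and Infinium-style methylation — and ships a synthetic-cohort generator with
full ground truth so every stage can be validated by parameter recovery.

## The models

**Purity from BAF (CNA clonality).** Heterozygous SNP probes inside a
hemizygous deletion (CN1) or copy-neutral LOH show two BAF bands symmetric
about ½. If a fraction *c* of all cells carries the event, the bands sit at

- CN1: (1−c)/(2−c) and 1/(2−c)
- LOH: (1−c)/2 and (1+c)/2

Per segment, the band positions (μ₁, μ₂) are fitted by EM under a symmetric
two-component Gaussian mixture and inverted: c = 2d/(1+d) for CN1 and c = d
for LOH, with d = μ₂−μ₁. The kernel density of the per-CNA fractions π = c
has one peak per clone; the rightmost peak is the primary clone and defines
tumor purity α. A CNA is clonal iff c ≥ (1−rel_tol)·α.

**SNV clonality.** Under the null that a mutation is clonal (all tumor cells
carry it, so it predates any overlapping deletion/LOH carried by a fraction
β of tumor cells), the expected mutant-allele fraction is

| state | allele configuration | expected MAF |
|---|---|---|
| CN2 | — | α/2 |
| CN1 | wild type deleted | α/(2−αβ) |
| CN1 | mutant deleted | α(1−β)/(2−αβ) |
| LOH | mutant duplicated | α(1+β)/2 |
| LOH | wild type duplicated | α(1−β)/2 |

The observed mutant read count is tested against this expectation with a
one-sided exact binomial lower tail; p < 0.05 calls the mutation subclonal.
Mutations in amplified or homozygously deleted regions are excluded. The
fraction of subclonal mutations (FSM) is aggregated per gene and per sample
and compared by Fisher's exact test.

**Signatures.** Nine point-mutation types ({C→A, C→G, C→T}×{CpG, nonCpG} ∪
{T→A, T→C, T→G}) after pyrimidine-strand collapse; APOBEC-mediated =
C→T/C→G in TCW; per-sample TNSM, transversion fraction FT, APOBEC fraction
FA, and rate per Mb; Wilcoxon/Fisher covariate association.

**Methylation.** Per-CpG-probe OLS of a mutation trait on methylation with
covariate adjustment (smoking, age, stage, sex), Bonferroni thresholding,
per-annotation-category enrichment fold changes, and
fraction-of-positive-association summaries.

## Worked example

```python
import numpy as np
from clonescape import (SimulationConfig, simulate_tumor_sample,
                        analyze_sample_cnas, call_clonality, fsm,
                        enrichment_fold_change)

sample, truth = simulate_tumor_sample(SimulationConfig(seed=11), 0)
est = analyze_sample_cnas(sample.segments)
print(f"true purity: {truth.alpha:.3f}   estimated: {est.alpha:.3f}")
print(f"clone peaks: {np.round(est.density_peaks, 3)}")

for snv in sample.snvs:
    seg_c = next((s.cell_fraction_c for s in sample.segments
                  if s.chrom == snv.chrom and s.start <= snv.pos < s.end
                  and s.cell_fraction_c is not None), None)
    if snv.segment_state in ("CN1", "LOH") and seg_c is not None:
        snv.beta = float(np.clip(seg_c / est.alpha, 0, 1))
    call_clonality(snv, est.alpha)
print(f"fraction of subclonal mutations: "
      f"{fsm([s.clonality for s in sample.snvs]):.3f}")

res = enrichment_fold_change(12339, 110542, 22337, 338739, category="open-sea")
print(f"open-sea enrichment: {100*res.k_cat/res.n_cat:.1f}% / "
      f"{100*res.k_all/res.n_all:.1f}% = {res.fold_display}")
```

prints

```
true purity: 0.290   estimated: 0.288
clone peaks: [0.119 0.288]
fraction of subclonal mutations: 0.392
open-sea enrichment: 11.2% / 6.6% = 1.7
```

The sample has two clones (cell-fraction peaks at 0.119 and 0.288); purity
is the rightmost peak and lands within 0.002 of the simulated truth. The
called FSM (0.392) is below the simulated subclonal fraction (0.545)
because the binomial test only calls a mutation subclonal when its allele
fraction is demonstrably depressed — mutations in most tumor cells are
indistinguishable from clonal at 100× depth. The last line reproduces the
open-sea probe enrichment arithmetic: 11.2% of open-sea probes versus 6.6%
of all probes significant gives a 1.7-fold enrichment.

## Command line

```sh
clonescape simulate --out cohort/                 # synthetic cohort + truth
clonescape purity --segments cohort/segments.tsv --probes cohort/probes.tsv \
    --out cohort/purity.tsv
clonescape snv-clonality --mutations cohort/mutations.tsv \
    --segments cohort/purity_segments.tsv --purity cohort/purity.tsv \
    --out cohort/mutations_annotated.tsv
clonescape signatures --mutations cohort/mutations_annotated.tsv --out cohort/sig.tsv
clonescape run --out full_run/ --seed 1           # all stages end to end
```

Tables are tab-separated with `#` comment headers and `.` for missing
values; file coordinates are 1-based inclusive (0-based half-open
internally). VCF input is supported read-only via the AD format field.

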