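# aretools

Tools for asking how AU-rich elements (AREs) in 3′UTRs shape gene
expression programs — in particular the repression of neural transcripts
by the ARE-binding protein tristetraprolin (TTP/Zfp36) and its release
during neural differentiation. The package is aimed at computational
biologists who work with 3′-end sequencing (3′READS-style) libraries,
microarray/expression matrices and multi-tissue expression atlases, and
who want each analysis step as a small, testable, scriptable unit.

## What it computes

**ARE annotation.** For each 3′UTR the pipeline counts overlapping
`AUUUA` pentamers and `UAUUUAU` heptamers and classifies each heptamer
as *clustered* (contained in a maximal A/U run of ≥ 12 nt, the context
characteristic of functional AREs) or *isolated*. Genes are binned by
pentamer count (default bins 0, 1–2, 3–5, ≥ 6) and the bins' log₂
fold-change distributions are compared by two-sided Kolmogorov–Smirnov
tests on their ECDFs. A label-permutation z-score ranks k-mer
(default pentamer) enrichment between UTR sets.

**PASS-read quantification.** An aligned 3′-end read is *polyadenylation
site-supporting* (PASS) when ≥ 2 non-genomic A's immediately follow the
genome-encoded part — i.e. the mRNA-sense 3′ soft-clip starts with ≥ 2
A's. After a MAPQ ≥ 10 filter, PASS reads whose 3′ ends fall in annotated
3′UTRs are counted per gene; expression is RPM (reads per million of
total PASS reads) and condition contrasts are
`log2((rpm_a + 1)/(rpm_b + 1))`.

**Differential-expression hits.** Per-row Welch's *t* between replicate
groups (e.g. knockout vs wild-type), Benjamini–Hochberg adjustment, and
a hit filter requiring > 10-fold change, adjusted *p* < 0.05 and
same-direction deviation of every treatment column from the control
mean; probe-level hits collapse to gene sets.

**Tissue-specificity ranks.** Against a *T*-tissue atlas (*T* = 81 by
default), a gene's rank for a focal tissue is that tissue's position in
the ascending ordering of the gene's expression (1 = lowest anywhere,
*T* = highest anywhere). A gene set's shift towards high ranks is
measured by the one-sided KS statistic D⁺ = sup(F_background − F_set)
with p = exp(−2 D⁺² nm/(n+m)); the scan over all tissues is summarised
by a one-sided Wilcoxon rank-sum comparison of neural vs non-neural
per-tissue *p* values.

**Synthetic data.** Seeded generators produce every input with known
ground truth: UTRs with exact planted motif counts, SAM alignments with
planted poly(A) junction reads and decoys, atlases with a planted
neural-enriched gene set, and KO/WT matrices with planted fold changes.

## Worked example

```python
from aretools import are_annotation as are, synth_data as sd

cfg = sd.SimConfig(seed=1)
utrs, beds, truth = sd.gen_utrs(cfg)            # 600 UTRs, 4 motif bins
anns = [are.annotate_ares(u) for u in utrs]
fc = sd.gen_fold_changes(cfg, anns)             # motif-dependent log2 shifts
groups = are.group_by_pentamer_count(anns)
print(are.compare_motif_groups(fc, groups).to_string(index=False))
```

```
group_a group_b  n_a  n_b        D            p
      0     1-2  150  150 0.260000 7.893761e-05
      0     3-5  150  150 0.500000 1.035111e-16
      0     >=6  150  150 0.673333 5.835928e-30
    1-2     3-5  150  150 0.353333 1.472794e-08
    1-2     >=6  150  150 0.546667 6.808572e-20
    3-5     >=6  150  150 0.233333 5.679260e-04
```

Each row compares the log₂ fold-change ECDFs of two pentamer-count bins:
*D* is the maximal ECDF separation and *p* its two-sided KS p-value.
The monotone growth of *D* with the motif-count gap (0.26 for 0 vs 1–2
up to 0.67 for 0 vs ≥ 6) is the planted signature that ARE-rich
transcripts shift most strongly — the pattern expected when an
ARE-directed decay pathway is switched off.

The same analyses run from the shell; an end-to-end simulated run is

```sh
printf 'simulate:\n  seed: 7\n' > demo.yaml
aretools run --config demo.yaml --outdir demo_out
```

which writes seven TSV tables (ARE annotation, per-condition PASS
quantification, log₂ ratios, group KS tests, differential hits, tissue
rank scan) plus a provenance manifest. Stage subcommands
(`annotate-ares`, `enrich-kmers`, `quantify-3reads`, `compare-3reads`,
`diffexpr`, `tissue-rank`, `tissue-rank-scan`, `simulate`) operate on
real files in the same formats.

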