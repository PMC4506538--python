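# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, the assumptions of the synthetic-data generators,
and what the test suite does and does not establish about real data.

## Coordinate and alphabet conventions

All genomic intervals are 0-based half-open internally. BED6 is native;
SAM `POS` is converted from 1-based on load. Sequences are normalised
to the RNA alphabet (T→U, uppercase) so motifs are spelled as they are
in the RNA-biology literature (`AUUUA`, `UAUUUAU`). A UTR's genomic
span may differ from its sequence length (spliced UTR models are
allowed); read assignment uses only the read 3′-end coordinate, so a
single-interval UTR model is assumed there. Expression matrices must be
complete: rows with missing cells are dropped at load time with a
logged count, because every downstream statistic assumes a full matrix.

## ARE annotation

Motifs are counted at every start position (overlapping). Tandem
arrays such as `UAUUUAUUUAU` therefore contribute each heptamer copy;
disjoint counting would undercount exactly the dense AU repeats that
matter most for ARE function. A heptamer is *clustered* when its 7-nt
span lies inside a maximal A/U run of length ≥ `min_run` (default 12
nt, exposed as a parameter); any other heptamer is *isolated*,
regardless of the length of its shorter run. Two invariants hold by
construction and are property-tested: `n_clustered + n_isolated =
n_heptamer` and `n_heptamer ≤ n_pentamer` (every `UAUUUAU` contains an
`AUUUA`).

Pentamer-count bins default to boundaries (1, 3, 6), i.e. 0, 1–2, 3–5,
≥ 6; the boundaries are configurable since different studies cut the
distribution differently. Bin-vs-bin fold-change comparisons use the
two-sided KS test (below).

### k-mer enrichment

Classic UTR motif-discovery programs implement proprietary statistics;
here enrichment is a transparent label-permutation test. Each UTR
contributes a length-normalised occurrence rate `count / (len − k + 1)`
per k-mer; the statistic is the difference of set means
(foreground − background). Shuffling set labels `n_perm` times
(default 999) gives a null per k-mer; we report `z = (obs − null
mean)/null sd` and the one-sided permutation p-value `(1 + #{null ≥
obs})/(n_perm + 1)`, which is never smaller than `1/(n_perm+1)` and is
exact under exchangeability. k-mers are counted on the given strand
only: 3′UTRs are sense sequences. Records shorter than k are excluded
(error if none remain).

## PASS-read quantification

The PASS rule anchors the non-genomic A's to the genome/clip junction:
a read qualifies iff the mRNA-sense 3′ soft-clip *starts* with ≥
`min_a` A's (default 2). Non-A bases deeper in the clip (sequencing
error inside the A-tail) do not disqualify; a non-A immediately at the
junction does. This makes PASS monotone in `min_a`, which is
property-tested.

Orientation: the reader converts alignments to mRNA sense. Forward
alignments take the trailing soft-clip as-is; FLAG-16 alignments take
the leading soft-clip reverse-complemented, and their 3′ end is the
leftmost aligned base. The MAPQ ≥ 10 filter is inclusive.

Assignment sends a PASS read to the UTR containing its 3′-end
coordinate on the matching chromosome and strand. Overlapping UTRs are
resolved to the gene with the nearer annotated 3′ terminus; exact ties
break to the lexicographically smaller gene id and are counted so users
can audit ambiguity. No deduplication and no poly(A)-site clustering or
internal-priming filtering are performed: the read 3′ end is used
directly, which is the right granularity for gene-level RPM but not for
poly(A)-site discovery.

RPM divides by *total* PASS reads (assigned or not), so reads outside
annotated UTRs dilute all genes equally; the per-run conservation
identity `#input = #low-MAPQ + #non-PASS + #unassigned + #assigned` is
checked on every run. Condition contrasts use
`log2((rpm_a + ψ)/(rpm_b + ψ))` with a symmetric pseudocount ψ = 1 RPM
(configurable): genes absent from one condition stay finite, equal
expression maps to exactly 0, and the bias for genes above ~50 RPM is
below `log2(1 + 1/50) ≈ 0.03` bits.

## Differential-expression hits

Per-row Welch's t (unequal variances, Welch–Satterthwaite df) compares
the two replicate groups on the log2 scale. Moderated-variance
approaches shrink row variances across the matrix; with the ≥ 10-fold
effect size this pipeline targets, plain Welch's t loses little power
and keeps each row's test self-contained, so recovery of planted truth
— not any historical hit list — is the test surface. Degenerate rows
are defined, not errors: both groups constant with equal means gives
p = 1; constant with unequal means gives a vanishing p and a logged
flag.

The BH family is all rows with non-zero overall variance (a minimal
detection filter). A hit requires all three of: |Δmean| > log2(10),
BH-adjusted p < 0.05, and *consistency* — every treatment column on the
same side of the control mean as the overall fold change, a guard
against single-replicate artefacts. Hits are monotone in both
thresholds. Gene collapsing marks genes with both up- and down- probes
as discordant and excludes them from both sets.

## Tissue-specificity ranks

For a gene and focal tissue, the rank is `1 + #{tissues strictly
below} + #{tied tissues earlier in column order}` — the focal position
after a stable ascending sort. Stable-order tie-breaking (rather than
mid-ranks) keeps ranks integral in 1..T; it matters only when atlas
values tie exactly, which has probability zero under the continuous
synthetic atlas. Ranks are translation-invariant per row and form a
bijection onto 1..T across focal tissues when values are distinct.

Right-skew of a gene set's ranks uses D⁺ = sup(F_background − F_set)
with the one-sided asymptotic bound `p = exp(−2 D⁺² nm/(n+m))`, clipped
to (0, 1]. The bound is conservative and accurate at the set sizes this
pipeline sees (tens to thousands); exact small-sample KS is deliberately
not implemented. The default background is all atlas rows; when the
compared sample matrices are available, `expressed_genes` restricts the
background to atlas genes detected in ≥ 1 compared sample (above the
atlas 10th percentile by default). Genes absent from the atlas are
dropped with a logged count, never imputed. The per-tissue scan repeats
the test with each tissue as focal; neural-vs-non-neural comparison of
the scan's p-values uses the one-sided Wilcoxon rank-sum test.

## Shared statistics

* Two-sided KS: D over pooled breakpoints; p from the Kolmogorov
  survival function at `sqrt(nm/(n+m))·D` (no small-sample correction
  factor — symmetric in the two samples, accurate for n, m ≥ ~20 and
  conservative below).
* Wilcoxon rank-sum: exact null distribution by the standard counting
  recurrence when the pooled size is ≤ 20 and tie-free; otherwise the
  normal approximation with tie and continuity corrections. The two
  branches agree within 0.02 absolute at the crossover (tested).
* BH adjustment: step-up with cumulative minimum, capped at 1.
* Floating-point comparisons in tests use 1e−9 relative tolerance
  unless a test states otherwise.

## Synthetic-data generators

Each generator draws from its own seeded stream (`default_rng([stream,
seed])`), so datasets are independent and every output is a pure
function of the config — byte-identical FASTA/SAM/TSV across runs,
which the suite asserts.

* **UTRs** — background bases i.i.d. with configurable GC (default
  0.5), lengths uniform in 150–300 nt. Motifs are planted as literal
  blocks — an all-AU array `U(AUUU)ᶜAU` (padded to ≥ 12 nt) for
  clustered groups, G-capped `GAUUUAG` copies for isolated ones — and
  the whole sequence is rejection-sampled until annotation returns
  exactly the target count, so annotation tests have integer ground
  truth. Default plan: 150 genes in each of the four default bins with
  targets 0/2/4/7, the ≥ 6 bin clustered.
* **Fold changes** — bin effect `fc_effect · i/(n_bins−1)` (monotone in
  bin order) plus Normal(0, 0.5) noise; `fc_effect` defaults to 1
  log2-unit, a moderate regulatory shift that the 150-genes-per-bin KS
  comparisons detect with large margin.
* **3′-end alignments** — per gene, the planted number of PASS reads
  with 3′ ends uniform in the UTR, soft-clips of 2–6 A's, MAPQ 30;
  decoy classes labelled in read names: `nonpass` (0–1 junction A's),
  `lowmapq` (MAPQ uniform 0–9, removed exactly by the MAPQ filter) and
  `outside` (PASS-like, intergenic) at 10 % / 5 % / 5 % of the planted
  read count. Reverse-strand UTRs exercise the FLAG-16 path.
* **Atlas** — 81 tissues, 12 neural (first one named
  `cerebral_cortex`), matching the neural fraction of the public mouse
  tissue atlases this emulates; 5,000 background genes i.i.d.
  Normal(8, 1) per cell, plus 80 planted genes shifted +2 SD in every
  neural tissue. Gaussian noise (rather than resampling a real atlas)
  keeps the null rank distribution provably uniform, which the
  chi-square calibration test relies on.
* **KO/WT matrices** — 2,000 rows, 4 replicates per group, baselines
  Normal(8, 2), within-group noise SD 0.25, 50 rows planted at
  +log2(16) in all KO columns and 50 at −log2(16).

Because all noise is Gaussian and independent, passing tests establish
correctness of the computations and calibration under the stated model
— not robustness to heavy-tailed expression noise, probe saturation,
correlated genes, mapping artefacts or atlas batch structure.

## Pipeline and provenance

The `aretools run` orchestrator executes simulate → annotate → quantify
(two conditions) → compare → motif-group KS → hit selection →
tissue-rank scan, writing TSV at every stage boundary (greppable and
diffable; no binary intermediates) and a `manifest.json` with the
command line, config hash, seed, input checksums, version and
timestamp. A stage failure writes a `failed/STAGE` marker and returns a
non-zero status. Per-stage read/gene conservation counts go to stderr
at INFO level.

## Known limitations

* No ARE class taxonomy, RNA secondary structure, or conservation
  scoring.
* No poly(A)-site clustering: closely spaced alternative sites are not
  merged, and gene-level RPM is the finest supported resolution.
* The one-sided KS p-value is an upper bound; reported significances
  are conservative.
* The permutation enrichment test assumes exchangeable UTRs; strong
  length confounding between sets would require a stratified null that
  is not implemented.
* Real microarray preprocessing (normalisation from raw probe data) is
  out of scope; matrices are consumed as provided.
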