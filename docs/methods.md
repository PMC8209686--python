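# Methods

## Scope and data model

`juncnovo` analyzes pre-called exon–exon junction evidence; it never touches
reads or alignments. A junction is identified by
`(chromosome, start, end, strand)` with the intron's first and last bases in
0-based closed coordinates, and strand `?` (unknown) treated as a distinct
identity — collapsing unstranded evidence onto a strand would fabricate
information the antisense analysis depends on. Input dumps may be 1-based
closed (GTF/Snaptron raw), 0-based half-open (BED) or 0-based closed;
conversion happens once at ingestion and is idempotent. Chromosome names are
matched exactly (no `chr` aliasing): inputs are controlled, and silent
aliasing risks duplicate junctions.

The store is the analysis' relational backbone: three linked tables
(junction info, per-sample evidence, sample phenotypes) held as pandas
frames and persisted as a single SQLite file with indexes on the junction-ID
and sample-ID columns. Evidence merging is idempotent for exact duplicate
rows (re-loading a file changes nothing); distinct sources contributing
counts for the same (junction, sample) sum. Evidence naming a sample absent
from the phenotype table is a hard load error. GTEx "normals" derived from a
leukemia cell line are dropped at load. Cancer-subtype refinement re-labels
five cohorts (cervical, esophageal, lower-grade glioma, sarcoma,
pheochromocytoma/paraganglioma) from a clinical subtype field; unknown
subtype values keep the parent label with a logged warning so sample counts
are conserved.

## Novelty filter

Two filtering layers, in order:

1. **Global evidence floor** — a junction needs ≥ 2 reads summed over all
   samples of all cohorts. There is deliberately *no* per-sample minimum:
   high cohort prevalence at low per-sample coverage is treated as real
   signal.
2. **Hierarchical exclusion** — per cancer cohort, stage 0 < 1+ < 2+ < 3+
   (tissue-matched normals, all core normals, plus SRA non-cancer). A single
   read in a single sample of an exclusion set removes the junction; a
   configurable per-sample threshold exists (`normal_read_threshold`) but
   defaults to this strict behavior. All TCGA matched normals join the core
   normal set regardless of cancer type; recurrent/metastatic tumor samples
   count as tumor. Cohorts with no tissue-matched normal skip the stage-1+
   comparison (flagged `tm_evaluable=False`): their junctions are classed 0
   vs 2+ directly.

"Annotated" status is three-way: both sites match one annotated junction;
one site is an annotated splice site on the same chromosome+strand; neither.
The analysis does not filter on annotation status.

## Sharedness

Prevalence is positive-sample fraction per cohort; a junction in several
cancer cohorts contributes one data point per cohort. Shared panels keep the
≤ 200 most recurrent stage-2+ junctions at ≥ 1% prevalence (boundary
inclusive); the sort is by positive-sample count descending with a
lexicographic genomic tie-break (chromosome, start, end ascending) — the
tie-break is ours, chosen purely so panel construction is deterministic and
testable. Cross-cancer-type averages are unweighted means over cohorts.
Distribution comparisons use the Kruskal–Wallis H test with tie correction
(scipy), p from the χ² approximation; an exhaustive-permutation oracle in
the test suite bounds the approximation error at tiny n. All-tied inputs are
degenerate (H=0, p=1, flagged, never raised).

## SRA set assignment

Stage-2+ junctions are tested for presence in SRA non-cancer categories,
each mapped to a broad group (adult / developmental / stem) by an editable
YAML taxonomy. Placenta is its own flag outside the developmental set: a
placenta-only junction is "explained" but not "developmental". Placenta
evidence is excluded from the developmental flag under both membership
rules. Unexplained = none of the four flags. The default rule needs one
positive sample per category; the two-sample rule needs ≥ 2 positive samples
across a broad group, with developmental subsets needing only ≥ 1 of their
own once the group-wide criterion holds — provably more conservative, so the
unexplained set can only grow. Matched SRA cancer evidence never affects
unexplained status (it is cancer, not normal); it feeds only the
Kruskal–Wallis replication test of whether SRA-replicating junctions are
more shared in the tumor cohort.

## Gene context

Protein-coding gene boundaries are gene-level spans (introns included).
Boundary stabbing uses a sorted-start array with a running maximum of ends
(bisect + bounded scan, O(log n + k)); `intervaltree` is not a dependency.
A junction is protein-coding if either splice site stabs a same-strand
protein-coding gene (all overlapping sense genes attach), antisense if only
opposite-strand genes overlap — sense takes precedence when both exist.
Unknown-strand junctions overlapping a gene default to protein-coding
(conservative w.r.t. antisense claims; configurable). Cancer-relevant flags
require a *sense* overlap with a listed gene; lists are one-gene-per-line
files.

## Cohort statistics

- Burden: `n_stage2+ junctions / (mapped_reads / 10 000)` per tumor sample
  (per-Mb under the 100-bp-read assumption); OLS of burden on TMB
  (silent + non-silent per Mb). Constant-TMB inputs are flagged degenerate.
- Mutation stratification: two criteria — a user-supplied splicing gene set
  (e.g. a UniProt keyword export, resource-versioned so never hardcoded) and
  the fixed five-gene sQTL set {U2AF1, SF3B1, TADA1, PPP2R1A, IDH1}
  (hardcoded with an override). Only non-synonymous MAF variant classes
  count. The two-way ANOVA (cancer type × mutation status) is fit *with* an
  interaction term and reports it, flagged non-normative since either
  reading of the procedure is defensible; per-cohort Welch t-tests are
  BH-corrected within each criterion's family (the conservative reading of
  "BH correction" when the family is unstated).
- Fisher sharedness: per junction seen in ≥ 2 patients, a two-sided exact
  test of (junction-positive × mutated) patient counts; patients, not
  samples, are the unit. Zero-margin tables give p=1 with undefined OR,
  flagged.
- Survival: Kaplan–Meier (lifelines); death dates are events, patients
  without one are censored at last follow-up, patients with neither field
  are excluded with a warning.

## Synthetic worlds

The generator emits everything the pipeline reads — GTF, Snaptron-dialect
evidence (1-based closed, `sample:count` lists), phenotype/mutation/TMB/
survival TSVs, gene lists, taxonomy and match-map YAMLs, and a manifest with
config + checksums — with a mutually exclusive truth label per junction.
Defaults are the structure the analysis is known to face at reduced scale:
2000 junctions, 3 tumor cohorts × 50 samples, 90 core normals, ~60 SRA
non-cancer samples in 8 categories. The planted label partition is
tissue-matched 0.495 and other-core-normal 0.407 (so 90.2% of junctions are
in core normals and 80.6% of those escaping the tissue-matched comparison
are caught by other normals), with the stage-2+ remainder split adult 0.26 /
developmental 0.15 / stem 0.03 / unexplained 0.56. These SRA-group numbers
are exclusive truth labels, which is why the remainder is 0.56 rather than
the ~0.65 a non-exclusive set count would give. The sharedness spectrum puts
weight 0.53 on single-sample junctions and the rest on cohort prevalences
0.05/0.15/0.30; antisense fraction is 0.40 among unexplained junctions
(0.05 elsewhere) and 4.8% of unexplained junctions sit in planted
cancer-associated genes.

Mechanics and their rationale:

- Within-cohort inclusion is Bernoulli at the planted prevalence, but
  *conditioned on the junction's sharedness class*: singletons get exactly
  one positive tumor sample and non-singleton draws are resampled until ≥ 2
  positives. Unconditioned Bernoulli at p=0.05 in a 50-sample cohort yields
  an accidental singleton ~20% of the time, which would contradict the
  planted singleton fraction the generator must realize.
- Read counts per positive sample are zero-truncated Poisson(λ=3) —
  realistic low coverage with plenty of 1-read observations. A dedicated
  "filtered" class (extra junctions with exactly one read in total)
  exercises the global two-read floor; analysis junctions whose one
  singleton draw lands on a single read are bumped to two reads so the
  planted category fractions stay exact among filter-passing junctions.
- Category planting is deterministic in presence/absence (largest-remainder
  allocation of counts, forced ≥ 1 positive sample in the permitted normal/
  SRA pool), so downstream recovery is exact up to the read-level filter,
  and the recovery tests use 3·binomial-SE tolerances only for the
  genuinely stochastic pieces.
- One master seed; per-table substreams use fixed offsets, so regenerating a
  single table reproduces it. Identical configs are byte-identical.

What the generator does **not** emulate: read-level noise and mapping
artifacts, junction-calling errors, batch effects between archives,
correlated splicing programs across junctions, and realistic genome
geometry (a single synthetic chromosome with non-overlapping, evenly spaced
genes). A green recovery test therefore establishes that the cohort logic,
filters and statistics are implemented correctly — not that the pipeline is
robust to real-data pathologies.

## Numerical choices and degenerate inputs

Prevalence/threshold comparisons use a 1e-12 slack so "at least 1%" and "at
least 5%" boundaries are inclusive under floating-point division. Empty
cohorts raise; empty junction sets yield absent values (None) rather than
NaN arithmetic. Kruskal–Wallis with all-tied data, Fisher with a zero
margin, and regression with constant TMB all return flagged degenerate
results instead of raising, since they occur naturally in small cohorts.
Heatmap/dendrogram rendering for prevalence matrices is presentation-layer
only; no clustering choice is validated and none is part of the tested
surface.

## Known limitations

- The tissue-match map and SRA taxonomy ship as documented example
  configurations; fidelity to any particular study's supplementary pairing
  tables is not asserted.
- The strand-distinct junction identity for unknown-strand evidence is a
  design choice flagged for sensitivity testing, not a validated claim.
- The two-way ANOVA's interaction term and the BH family definition are
  package decisions where the underlying procedure is ambiguous; both are
  surfaced in the outputs rather than hidden.
- Full-scale (tens of thousands of samples) performance is out of scope; the
  store targets desk-scale and cluster-scale reproduction would need a
  sharded ingestion layer.
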