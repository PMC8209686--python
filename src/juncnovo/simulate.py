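"""Synthetic multi-cohort junction data with planted ground truth.

The generator emulates the statistical structure the junction-novelty
analysis assumes: tumor cohorts with a prevalence spectrum of recurrent and
private junctions, core-normal tissues (tissue-matched and otherwise), SRA
non-cancer categories partitioned into adult / developmental / stem broad
groups (developmental including placenta), matched SRA cancer cohorts, and
clinical side tables (mutations, TMB, survival). Every junction carries a
mutually exclusive truth label so downstream recovery is checkable exactly.

It does NOT simulate reads, alignment or junction calling — the analysis
consumes pre-called junction evidence, and so does the generator's output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneRegion
from .coords import JunctionCoord

CATEGORY_LABELS = (
    "tissue_matched_normal",
    "other_core_normal",
    "sra_adult",
    "sra_developmental",
    "sra_stem",
    "sra_placenta",
    "unexplained",
    "filtered",  # total evidence below the global two-read filter
)

# fixed per-table RNG substream offsets (master seed + offset)
_RS_ANNOT, _RS_COHORT, _RS_CLINICAL = 11, 23, 37


def _default_spectrum() -> list[tuple[object, float]]:
    # sharedness spectrum: 53% of junctions private to one tumor sample,
    # the rest recurrent at low/moderate cohort prevalence
    return [("singleton", 0.53), (0.05, 0.27), (0.15, 0.15), (0.30, 0.05)]


def _default_sra_sizes() -> dict[str, int]:
    return {
        "adult_epithelium": 10,
        "adult_blood": 10,
        "adult_brain": 10,
        "dev_embryonic": 8,
        "dev_fetal": 8,
        "placenta": 6,
        "stem_esc": 8,
        "stem_ipsc": 8,
    }


def _default_sra_groups() -> dict[str, str]:
    return {
        "adult_epithelium": "adult",
        "adult_blood": "adult",
        "adult_brain": "adult",
        "dev_embryonic": "developmental",
        "dev_fetal": "developmental",
        "placenta": "developmental",
        "stem_esc": "stem",
        "stem_ipsc": "stem",
    }


@dataclass
class SimConfig:
    """Stated world of one synthetic experiment.

    Fractions of the truth-label partition: ``frac_in_tissue_matched`` and
    ``frac_in_other_core_normal`` are absolute fractions of all junctions
    (their sum is the planted core-normal overlap); ``frac_in_sra_by_group``,
    ``frac_in_sra_placenta`` and ``frac_unexplained`` partition the
    *remaining* (stage-2+) junctions and must sum to 1.
    """

    seed: int = 0
    n_cancer_cohorts: int = 3
    samples_per_cancer_cohort: int = 50
    n_core_normal_samples: int = 90
    tissue_match_map: dict[str, tuple[str, ...]] | None = None
    sra_category_sizes: dict[str, int] = field(default_factory=_default_sra_sizes)
    sra_category_groups: dict[str, str] = field(default_factory=_default_sra_groups)
    n_junctions: int = 2000
    # core-normal overlap 0.902 split so that 80.6% of junctions passing the
    # tissue-matched comparison are caught by other core normals
    frac_in_tissue_matched: float = 0.495
    frac_in_other_core_normal: float = 0.407
    frac_in_sra_by_group: dict[str, float] = field(
        default_factory=lambda: {"adult": 0.26, "developmental": 0.15, "stem": 0.03}
    )
    frac_in_sra_placenta: float = 0.0
    frac_unexplained: float = 0.56
    prevalence_spectrum: list[tuple[object, float]] = field(default_factory=_default_spectrum)
    frac_antisense: float = 0.40  # among unexplained junctions
    frac_antisense_other: float = 0.05  # among all other categories
    frac_cancer_gene: float = 0.048  # among unexplained: sense junction in a cancer gene
    read_count_model: tuple[str, float] = ("ztpoisson", 3.0)
    frac_singleton_reads: float = 0.05
    n_cross_cohort_junctions: int = 0
    cross_cohort_prevalence: float = 0.10
    # matched SRA cancer overlay (stage-2+ junctions only): recurrent
    # junctions replicate in the matched SRA cancer cohort more often than
    # private ones, planting the sharedness association
    sra_cancer_match_map: dict[str, str] | None = None
    frac_sra_cancer_shared: float = 0.40
    frac_sra_cancer_singleton: float = 0.10
    # annotation fixture shape
    n_genes: int = 40
    transcripts_per_gene: int = 2
    exons_per_transcript: int = 8
    frac_cancer_genes: float = 0.15  # genes marked cancer-associated

    def __post_init__(self) -> None:
        self.validate()

    # -- derived structure ---------------------------------------------------
    def cancer_cohorts(self) -> list[str]:
        return [f"cancer_{i:02d}" for i in range(self.n_cancer_cohorts)]

    def match_map(self) -> dict[str, tuple[str, ...]]:
        if self.tissue_match_map is not None:
            return {c: tuple(v) for c, v in self.tissue_match_map.items()}
        return {c: (f"tissue_{i:02d}",) for i, c in enumerate(self.cancer_cohorts())}

    def normal_cohorts(self) -> list[str]:
        seen: list[str] = []
        for tissues in self.match_map().values():
            for t in tissues:
                if t not in seen:
                    seen.append(t)
        return seen

    def cancer_match_map(self) -> dict[str, str]:
        if self.sra_cancer_match_map is not None:
            return dict(self.sra_cancer_match_map)
        return {c: f"sra_{c}" for c in self.cancer_cohorts()}

    def validate(self) -> None:
        fracs = {
            "frac_in_tissue_matched": self.frac_in_tissue_matched,
            "frac_in_other_core_normal": self.frac_in_other_core_normal,
            "frac_in_sra_placenta": self.frac_in_sra_placenta,
            "frac_unexplained": self.frac_unexplained,
            "frac_antisense": self.frac_antisense,
            "frac_antisense_other": self.frac_antisense_other,
            "frac_cancer_gene": self.frac_cancer_gene,
            "frac_singleton_reads": self.frac_singleton_reads,
            **{f"frac_in_sra[{g}]": f for g, f in self.frac_in_sra_by_group.items()},
        }
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f} outside [0, 1]")
        if self.frac_in_tissue_matched + self.frac_in_other_core_normal > 1 + 1e-9:
            raise ValueError("core-normal fractions exceed 1")
        stage2_sum = (
            sum(self.frac_in_sra_by_group.values())
            + self.frac_in_sra_placenta
            + self.frac_unexplained
        )
        if abs(stage2_sum - 1.0) > 1e-9:
            raise ValueError(
                f"stage-2+ category fractions must sum to 1, got {stage2_sum}"
            )
        wsum = sum(w for _p, w in self.prevalence_spectrum)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"prevalence_spectrum weights must sum to 1, got {wsum}")
        mm = self.match_map()
        if set(mm) != set(self.cancer_cohorts()):
            raise ValueError(
                "tissue_match_map keys must be exactly the cancer cohorts "
                f"{self.cancer_cohorts()}, got {sorted(mm)}"
            )
        for cohort, tissues in mm.items():
            if not tissues:
                raise ValueError(
                    f"tissue_match_map[{cohort}] is empty: the generator needs a "
                    "tissue-matched normal cohort to plant against"
                )
        for cat in self.sra_category_sizes:
            if cat not in self.sra_category_groups:
                raise ValueError(f"SRA category {cat!r} has no broad-group assignment")


@dataclass
class AnnotationTruth:
    """What :func:`generate_annotation` planted."""

    junctions: list[JunctionCoord]
    genes: list[GeneRegion]
    chrom: str
    chrom_len: int


def generate_annotation(
    n_genes: int,
    transcripts_per_gene: int = 2,
    exons_per_transcript: int = 8,
    seed: int = 0,
    chrom: str = "chrS",
    frac_cancer_genes: float = 0.0,
) -> tuple[str, AnnotationTruth]:
    """Emit a GENCODE-dialect GTF for a synthetic chromosome.

    Genes are non-overlapping, alternate strand, all ``protein_coding``.
    Each gene's first transcript uses the full exon grid; later transcripts
    skip one internal exon, so some junctions are shared between transcripts
    and some are transcript-specific.
    """
    if n_genes < 0 or transcripts_per_gene < 1 or exons_per_transcript < 1:
        raise ValueError("gene/transcript/exon counts must be non-negative (>=1 for per-gene counts)")
    rng = np.random.default_rng((seed, _RS_ANNOT))
    exon_len, intron_len, gap = 150, 100, 2000
    gene_span = exons_per_transcript * exon_len + (exons_per_transcript - 1) * intron_len

    lines = ["##description: synthetic annotation (juncnovo simulator)"]
    genes: list[GeneRegion] = []
    junctions: set[JunctionCoord] = set()
    n_cancer = int(round(frac_cancer_genes * n_genes))
    cancer_idx = set(rng.choice(n_genes, size=n_cancer, replace=False)) if n_cancer else set()

    pos = 1001  # 1-based
    for gi in range(n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        name = f"GENE{gi:03d}"
        g_start, g_end = pos, pos + gene_span - 1
        genes.append(
            GeneRegion(name, chrom, strand, g_start - 1, g_end - 1, gi in cancer_idx)
        )
        attrs = f'gene_id "{name}.1"; gene_type "protein_coding"; gene_name "{name}";'
        lines.append(
            f"{chrom}\tsim\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\t{attrs}"
        )
        exon_grid = [
            (g_start + j * (exon_len + intron_len),
             g_start + j * (exon_len + intron_len) + exon_len - 1)
            for j in range(exons_per_transcript)
        ]
        for ti in range(transcripts_per_gene):
            tx = f"{name}.t{ti}"
            tx_exons = list(exon_grid)
            if ti > 0 and exons_per_transcript >= 3:
                skip = 1 + (ti - 1) % (exons_per_transcript - 2)
                tx_exons = tx_exons[:skip] + tx_exons[skip + 1:]
            tattrs = attrs + f' transcript_id "{tx}";'
            lines.append(
                f"{chrom}\tsim\ttranscript\t{tx_exons[0][0]}\t{tx_exons[-1][1]}\t.\t{strand}\t.\t{tattrs}"
            )
            for (es, ee) in tx_exons:
                lines.append(
                    f"{chrom}\tsim\texon\t{es}\t{ee}\t.\t{strand}\t.\t{tattrs}"
                )
            for (s1, e1), (s2, e2) in zip(tx_exons, tx_exons[1:]):
                junctions.add(JunctionCoord(chrom, e1, s2 - 2, strand))
        pos = g_end + gap + 1

    truth = AnnotationTruth(
        junctions=sorted(junctions), genes=genes, chrom=chrom, chrom_len=pos + gap
    )
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# cohort generation


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (per-positive-sample read counts)."""
    out = rng.poisson(lam, size=size)
    while True:
        zeros = out == 0
        if not zeros.any():
            return out
        out[zeros] = rng.poisson(lam, size=int(zeros.sum()))


def _draw_reads(rng: np.random.Generator, model: tuple[str, float], size: int) -> np.ndarray:
    family, param = model
    if family == "ztpoisson":
        return _zt_poisson(rng, float(param), size)
    raise ValueError(f"unknown read_count_model family {family!r}")


def _alloc_counts(n: int, fracs: list[float]) -> list[int]:
    """Largest-remainder allocation of n items to fractions (sums to n)."""
    raw = [f * n for f in fracs]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])
    for i in range(short):
        base[int(order[i])] += 1
    return base


def _sample_present(
    rng: np.random.Generator, samples: list[str], p: float, min_positive: int = 1
) -> list[str]:
    """Bernoulli(p) inclusion per sample, conditioned on >= min_positive hits."""
    if not samples:
        return []
    min_positive = min(min_positive, len(samples))
    while True:
        mask = rng.random(len(samples)) < p
        if int(mask.sum()) >= min_positive:
            return [s for s, m in zip(samples, mask) if m]


class _CoordFactory:
    """Draw unique junction coordinates with a requested gene context."""

    def __init__(self, truth: AnnotationTruth, rng: np.random.Generator):
        self.rng = rng
        self.chrom = truth.chrom
        self.chrom_len = truth.chrom_len
        self.genes = truth.genes
        self.cancer_genes = [g for g in truth.genes if g.cancer_associated]
        self.plain_genes = [g for g in truth.genes if not g.cancer_associated]
        self.used: set[JunctionCoord] = set(truth.junctions)
        self.annotated = list(truth.junctions)
        self.ann_sites: set[int] = set()
        for j in truth.junctions:
            self.ann_sites.update((j.start, j.end))
        self.unused_annotated = [j for j in self.annotated]
        self.rng.shuffle(self.unused_annotated)
        # intergenic gaps (0-based closed), away from any gene boundary
        bounds = sorted((g.start, g.end) for g in truth.genes)
        self.gaps: list[tuple[int, int]] = []
        prev = 10
        for s, e in bounds:
            if s - 1 - prev > 400:
                self.gaps.append((prev + 50, s - 51))
            prev = e + 1
        self.gaps.append((prev + 50, prev + 5000))

    def _fresh(self, chrom: str, a: int, b: int, strand: str) -> JunctionCoord | None:
        c = JunctionCoord(chrom, a, b, strand)
        if c in self.used or a in self.ann_sites or b in self.ann_sites or a >= b:
            return None
        self.used.add(c)
        return c

    def _in_gene(self, gene: GeneRegion, strand: str) -> JunctionCoord:
        for _ in range(200):
            a = int(self.rng.integers(gene.start + 5, gene.end - 60))
            b = int(self.rng.integers(a + 30, min(a + 800, gene.end - 4)))
            c = self._fresh(gene.chrom, a, b, strand)
            if c is not None:
                return c
        raise RuntimeError("coordinate space exhausted inside gene; increase gene count")

    def annotated_junction(self) -> JunctionCoord | None:
        """A real annotated junction (status 'both'), each used once."""
        while self.unused_annotated:
            j = self.unused_annotated.pop()
            gene = next(
                (g for g in self.genes if g.strand == j.strand and g.start <= j.start <= g.end),
                None,
            )
            if gene is not None and not gene.cancer_associated:
                return j
        return None

    def half_annotated(self) -> JunctionCoord:
        """Shares its left splice site with an annotated junction (status 'one')."""
        cancer_spans = [(g.start, g.end, g.strand) for g in self.cancer_genes]
        for _ in range(500):
            j = self.annotated[int(self.rng.integers(len(self.annotated)))]
            if any(s <= j.start <= e and st == j.strand for s, e, st in cancer_spans):
                continue  # keep planted cancer-gene fractions exact
            b = j.end + int(self.rng.integers(5, 60))
            c = JunctionCoord(j.chrom, j.start, b, j.strand)
            if c not in self.used and b not in self.ann_sites:
                self.used.add(c)
                return c
        raise RuntimeError("could not place half-annotated junction")

    def sense(self, cancer_gene: bool = False) -> JunctionCoord:
        pool = self.cancer_genes if cancer_gene else self.plain_genes
        gene = pool[int(self.rng.integers(len(pool)))]
        return self._in_gene(gene, gene.strand)

    def antisense(self) -> JunctionCoord:
        pool = self.plain_genes or self.genes
        gene = pool[int(self.rng.integers(len(pool)))]
        return self._in_gene(gene, "-" if gene.strand == "+" else "+")

    def intergenic(self) -> JunctionCoord:
        for _ in range(500):
            gs, ge = self.gaps[int(self.rng.integers(len(self.gaps)))]
            a = int(self.rng.integers(gs, ge - 40))
            b = int(self.rng.integers(a + 20, min(a + 300, ge)))
            strand = "+" if self.rng.random() < 0.5 else "-"
            c = self._fresh(self.chrom, a, b, strand)
            if c is not None:
                return c
        raise RuntimeError("could not place intergenic junction")


def _assign_contexts(
    rng: np.random.Generator,
    factory: _CoordFactory,
    categories: list[str],
    cfg: SimConfig,
) -> tuple[list[JunctionCoord], list[str], list[bool], list[str]]:
    """Choose coordinates + gene context per junction given its category.

    Unexplained junctions get the elevated antisense fraction and the planted
    cancer-gene fraction; every other category uses the baseline mix.
    """
    n = len(categories)
    coords: list[JunctionCoord | None] = [None] * n
    contexts = [""] * n
    cancer_flags = [False] * n
    ann_status = [""] * n

    unex = [i for i, c in enumerate(categories) if c == "unexplained"]
    other = [i for i, c in enumerate(categories) if c != "unexplained"]

    def place(indices: list[int], antisense_frac: float, cancer_frac: float) -> None:
        k = len(indices)
        if k == 0:
            return
        n_cg = int(round(cancer_frac * k))
        n_anti = int(round(antisense_frac * k))
        n_rest = k - n_cg - n_anti
        n_sense = int(round(0.70 * n_rest))
        n_inter = n_rest - n_sense
        roles = (
            ["cancer"] * n_cg + ["antisense"] * n_anti
            + ["sense"] * n_sense + ["intergenic"] * n_inter
        )
        rng.shuffle(roles)
        for i, role in zip(indices, roles):
            if role == "cancer":
                coords[i] = factory.sense(cancer_gene=True)
                contexts[i], cancer_flags[i] = "protein_coding", True
                ann_status[i] = "neither"
            elif role == "antisense":
                coords[i] = factory.antisense()
                contexts[i], ann_status[i] = "antisense", "neither"
            elif role == "intergenic":
                coords[i] = factory.intergenic()
                contexts[i], ann_status[i] = "neither", "neither"
            else:
                # sense junctions carry the annotated / half-annotated statuses
                u = rng.random()
                if u < 0.15:
                    j = factory.annotated_junction()
                    if j is not None:
                        coords[i], contexts[i], ann_status[i] = j, "protein_coding", "both"
                        continue
                    u = 0.5  # annotated pool exhausted; fall through
                if u < 0.25:
                    coords[i], contexts[i], ann_status[i] = (
                        factory.half_annotated(), "protein_coding", "one",
                    )
                else:
                    coords[i], contexts[i], ann_status[i] = (
                        factory.sense(), "protein_coding", "neither",
                    )

    place(unex, cfg.frac_antisense, cfg.frac_cancer_gene)
    place(other, cfg.frac_antisense_other, 0.0)
    return [c for c in coords], contexts, cancer_flags, ann_status  # type: ignore[misc]


def generate_cohorts(
    config: SimConfig, annotation_truth: AnnotationTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the junction evidence table, phenotype table and truth table.

    Returns
    -------
    evidence : DataFrame
        Long form: one row per (junction, sample) with a positive read
        count. Columns ``chrom start end strand sample_id reads``;
        coordinates canonical 0-based closed.
    phenotypes : DataFrame
        One row per sample: ``sample_id cohort cohort_class`` plus clinical
        fields for tumor samples.
    truth : DataFrame
        One row per junction with the planted category, context, statuses
        and per-cohort planted prevalence class.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng((cfg.seed, _RS_COHORT))
    if annotation_truth is None:
        _, annotation_truth = generate_annotation(
            cfg.n_genes,
            cfg.transcripts_per_gene,
            cfg.exons_per_transcript,
            seed=cfg.seed,
            frac_cancer_genes=cfg.frac_cancer_genes,
        )

    # ---- samples ----
    rows = []
    cancer_cohorts = cfg.cancer_cohorts()
    genders = ("female", "male")
    for cohort in cancer_cohorts:
        for i in range(cfg.samples_per_cancer_cohort):
            rows.append(
                dict(
                    sample_id=f"{cohort}_s{i:03d}",
                    cohort=cohort,
                    cohort_class="tumor",
                    sample_type="primary_tumor",
                    stage=f"stage_{1 + i % 4}",
                    gender=genders[i % 2],
                    vital_status="",
                    days_to_death="",
                    days_to_last_followup="",
                    mapped_read_count=int(rng.integers(30_000_000, 60_000_000)),
                )
            )
    normal_cohorts = cfg.normal_cohorts()
    if normal_cohorts:
        per_tissue = _alloc_counts(
            cfg.n_core_normal_samples, [1.0 / len(normal_cohorts)] * len(normal_cohorts)
        )
        for tissue, n_t in zip(normal_cohorts, per_tissue):
            for i in range(n_t):
                rows.append(
                    dict(
                        sample_id=f"{tissue}_n{i:03d}",
                        cohort=tissue,
                        cohort_class="gtex_normal",
                        sample_type="normal",
                        stage="", gender=genders[i % 2], vital_status="",
                        days_to_death="", days_to_last_followup="",
                        mapped_read_count=int(rng.integers(30_000_000, 60_000_000)),
                    )
                )
    for cat, size in cfg.sra_category_sizes.items():
        group = cfg.sra_category_groups[cat]
        klass = "sra_placenta" if cat == "placenta" else f"sra_{group}"
        for i in range(size):
            rows.append(
                dict(
                    sample_id=f"sra_{cat}_s{i:02d}",
                    cohort=cat, cohort_class=klass, sample_type="sra",
                    stage="", gender="", vital_status="",
                    days_to_death="", days_to_last_followup="",
                    mapped_read_count=int(rng.integers(20_000_000, 50_000_000)),
                )
            )
    cancer_match = cfg.cancer_match_map()
    for cohort, cat in cancer_match.items():
        for i in range(10):
            rows.append(
                dict(
                    sample_id=f"{cat}_s{i:02d}",
                    cohort=cat, cohort_class="sra_cancer", sample_type="sra",
                    stage="", gender="", vital_status="",
                    days_to_death="", days_to_last_followup="",
                    mapped_read_count=int(rng.integers(20_000_000, 50_000_000)),
                )
            )
    phenotypes = pd.DataFrame(rows)

    samples_by_cohort = {
        c: list(phenotypes.loc[phenotypes.cohort == c, "sample_id"])
        for c in phenotypes.cohort.unique()
    }
    match_map = cfg.match_map()

    # ---- junction truth labels ----
    n = cfg.n_junctions
    t, o = cfg.frac_in_tissue_matched, cfg.frac_in_other_core_normal
    stage2_frac = 1.0 - t - o
    group_fracs = cfg.frac_in_sra_by_group
    abs_fracs = [
        t, o,
        stage2_frac * group_fracs.get("adult", 0.0),
        stage2_frac * group_fracs.get("developmental", 0.0),
        stage2_frac * group_fracs.get("stem", 0.0),
        stage2_frac * cfg.frac_in_sra_placenta,
        stage2_frac * cfg.frac_unexplained,
    ]
    counts = _alloc_counts(n, abs_fracs)
    categories: list[str] = []
    for label, k in zip(CATEGORY_LABELS[:7], counts):
        categories.extend([label] * k)
    rng.shuffle(categories)
    # below-filter junctions are extra, on top of the n analysis junctions
    n_filtered = int(round(cfg.frac_singleton_reads * n / max(1e-12, 1 - cfg.frac_singleton_reads)))
    categories += ["filtered"] * n_filtered
    n_cross = cfg.n_cross_cohort_junctions
    categories += ["unexplained"] * n_cross  # cross-cohort extras

    factory = _CoordFactory(annotation_truth, rng)
    coords, contexts, cancer_flags, ann_status = _assign_contexts(
        rng, factory, categories, cfg
    )

    # ---- plant per-sample presence and read counts ----
    spectrum = cfg.prevalence_spectrum
    spec_p = np.array([w for _v, w in spectrum])
    ev_junc: list[int] = []
    ev_sample: list[str] = []
    truth_rows = []
    n_total = len(categories)
    cross_start = n_total - n_cross

    for ji in range(n_total):
        cat = categories[ji]
        coord = coords[ji]
        if cat == "filtered":
            cohort = cancer_cohorts[int(rng.integers(len(cancer_cohorts)))]
            s = samples_by_cohort[cohort][int(rng.integers(len(samples_by_cohort[cohort])))]
            positives = [s]
            home = [cohort]
            shared_class = "singleton"
        elif ji >= cross_start:
            # planted cross-cohort junction: recurrent in >=2 cancer cohorts
            k = min(2, len(cancer_cohorts))
            idx = rng.choice(len(cancer_cohorts), size=k, replace=False)
            home = [cancer_cohorts[int(i)] for i in idx]
            positives = []
            for cohort in home:
                positives += _sample_present(
                    rng, samples_by_cohort[cohort], cfg.cross_cohort_prevalence,
                    min_positive=max(2, int(np.ceil(0.05 * len(samples_by_cohort[cohort])))),
                )
            shared_class = "cross_cohort"
        else:
            cohort = cancer_cohorts[int(rng.integers(len(cancer_cohorts)))]
            home = [cohort]
            ci = int(rng.choice(len(spectrum), p=spec_p))
            val = spectrum[ci][0]
            if val == "singleton":
                s = samples_by_cohort[cohort][int(rng.integers(len(samples_by_cohort[cohort])))]
                positives = [s]
                shared_class = "singleton"
            else:
                positives = _sample_present(
                    rng, samples_by_cohort[cohort], float(val), min_positive=2
                )
                shared_class = f"p{val}"

        # evidence outside tumors, as the truth label permits
        if cat == "tissue_matched_normal":
            tissues = match_map.get(home[0], ())
            pool = [s for tt in tissues for s in samples_by_cohort.get(tt, [])]
            positives += _sample_present(rng, pool, 0.3, min_positive=1)
        elif cat == "other_core_normal":
            matched = set(match_map.get(home[0], ()))
            pool = [
                s
                for tissue in cfg.normal_cohorts()
                if tissue not in matched
                for s in samples_by_cohort.get(tissue, [])
            ]
            positives += _sample_present(rng, pool, 0.3, min_positive=1)
        elif cat in ("sra_adult", "sra_developmental", "sra_stem"):
            group = cat.removeprefix("sra_")
            cats = [
                c for c, g in cfg.sra_category_groups.items()
                if g == group and c != "placenta" and c in cfg.sra_category_sizes
            ]
            chosen = cats[int(rng.integers(len(cats)))]
            positives += _sample_present(
                rng, samples_by_cohort[chosen], 0.3, min_positive=1
            )
        elif cat == "sra_placenta":
            positives += _sample_present(
                rng, samples_by_cohort.get("placenta", []), 0.3, min_positive=1
            )

        # matched SRA cancer overlay for stage-2+ junctions
        in_sra_cancer = False
        if cat in ("sra_adult", "sra_developmental", "sra_stem", "sra_placenta", "unexplained"):
            p_rep = (
                cfg.frac_sra_cancer_singleton
                if shared_class == "singleton"
                else cfg.frac_sra_cancer_shared
            )
            for cohort in home:
                cat_name = cancer_match.get(cohort)
                if cat_name and rng.random() < p_rep:
                    positives += _sample_present(
                        rng, samples_by_cohort.get(cat_name, []), 0.3, min_positive=1
                    )
                    in_sra_cancer = True

        ev_junc.extend([ji] * len(positives))
        ev_sample.extend(positives)
        truth_rows.append(
            dict(
                chrom=coord.chrom, start=coord.start, end=coord.end, strand=coord.strand,
                category=cat, home_cohorts="|".join(home), shared_class=shared_class,
                gene_context=contexts[ji], cancer_gene=cancer_flags[ji],
                annotation_status=ann_status[ji], in_sra_cancer=in_sra_cancer,
            )
        )

    reads = _draw_reads(rng, cfg.read_count_model, len(ev_junc))
    filtered_mask = np.array([categories[j] == "filtered" for j in ev_junc], dtype=bool)
    reads[filtered_mask] = 1
    # analysis junctions must clear the two-read global evidence floor: a
    # singleton whose only sample drew 1 read is bumped to 2 so planted
    # category fractions stay exact among filter-passing junctions
    ev_junc_arr = np.array(ev_junc, dtype=int)
    if len(ev_junc_arr):
        totals = np.bincount(ev_junc_arr, weights=reads, minlength=n_total)
        low = np.isin(ev_junc_arr, np.nonzero(totals == 1)[0]) & ~filtered_mask
        reads[low] = 2

    truth = pd.DataFrame(truth_rows)
    evidence = pd.DataFrame(
        dict(
            chrom=[coords[j].chrom for j in ev_junc],
            start=[coords[j].start for j in ev_junc],
            end=[coords[j].end for j in ev_junc],
            strand=[coords[j].strand for j in ev_junc],
            sample_id=ev_sample,
            reads=reads,
        )
    )
    evidence = (
        evidence.groupby(["chrom", "start", "end", "strand", "sample_id"], as_index=False)
        .reads.sum()
        .sort_values(["chrom", "start", "end", "strand", "sample_id"])
        .reset_index(drop=True)
    )
    return evidence, phenotypes, truth


# ---------------------------------------------------------------------------
# clinical side tables


@dataclass
class MutationEffect:
    """Planted clinical effects for the cohort-statistics fixtures."""

    mutated_fraction: float = 0.5
    burden_shift: float = 0.0  # added stage-2+ junction count in mutated patients
    base_count_mean: float = 100.0
    base_count_sd: float = 10.0
    survival_hazard_ratio: float = 1.0  # junction-positive vs negative
    baseline_event_rate: float = 0.5
    splicing_gene: str = "SF3B1"


def generate_clinical_tables(
    config: SimConfig,
    effect: MutationEffect,
    phenotypes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Mutation-call, TMB and survival tables keyed to the tumor samples.

    One patient per tumor sample. Mutated patients carry one non-synonymous
    mutation in ``effect.splicing_gene``; everyone carries a synonymous
    decoy (which must not count) and a non-splicing missense decoy.
    """
    cfg = config
    rng = np.random.default_rng((cfg.seed, _RS_CLINICAL))
    if phenotypes is None:
        _, phenotypes, _ = generate_cohorts(cfg)
    tumor = phenotypes[phenotypes.cohort_class == "tumor"]
    if tumor.empty:
        raise ValueError("phenotype table contains no tumor samples")
    patients = list(tumor.sample_id)
    cohorts = list(tumor.cohort)
    n = len(patients)
    mutated = rng.random(n) < effect.mutated_fraction

    mut_rows = []
    for pid, is_mut in zip(patients, mutated):
        mut_rows.append(dict(patient_id=pid, gene="TP53", variant_class="Silent"))
        mut_rows.append(dict(patient_id=pid, gene="TTN", variant_class="Missense_Mutation"))
        if is_mut:
            mut_rows.append(
                dict(patient_id=pid, gene=effect.splicing_gene, variant_class="Missense_Mutation")
            )
    mutations = pd.DataFrame(mut_rows)

    tmb = pd.DataFrame(
        dict(
            patient_id=patients,
            silent_per_mb=np.round(rng.gamma(2.0, 1.0, n), 4),
            nonsilent_per_mb=np.round(rng.gamma(4.0, 1.5, n), 4),
        )
    )

    counts = rng.normal(effect.base_count_mean, effect.base_count_sd, n)
    counts = np.maximum(0, np.round(counts + effect.burden_shift * mutated)).astype(int)

    # survival: exponential event times, hazard scaled for junction-positive
    positive = rng.random(n) < 0.5
    lam = 1.0 / 1000.0 * np.where(positive, effect.survival_hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / lam)
    censor_time = rng.uniform(200, 2000, n)
    died = (event_time <= censor_time) & (rng.random(n) < effect.baseline_event_rate)
    surv = pd.DataFrame(
        dict(
            patient_id=patients,
            junction_positive=positive,
            vital_status=np.where(died, "dead", "alive"),
            days_to_death=np.where(died, np.round(event_time, 1), np.nan),
            days_to_last_followup=np.round(np.minimum(event_time, censor_time), 1),
        )
    )

    planted = dict(
        mutated_patients=[p for p, m in zip(patients, mutated) if m],
        planted_counts={p: int(c) for p, c in zip(patients, counts)},
        cohorts={p: c for p, c in zip(patients, cohorts)},
        burden_shift=effect.burden_shift,
        survival_hazard_ratio=effect.survival_hazard_ratio,
    )
    return mutations, tmb, surv, planted


def simulate_stratified_counts(
    n_per_group: int,
    n_cohorts: int,
    shift: float,
    base_mean: float = 100.0,
    sd: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient stage-2+ junction counts for ANOVA power/type-I studies.

    Counts are normal(base_mean, sd) with ``shift`` added for mutated
    patients; balanced ``n_per_group`` per (cohort, mutation status) cell.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ci in range(n_cohorts):
        for mutated in (False, True):
            mu = base_mean + (shift if mutated else 0.0)
            for v in rng.normal(mu, sd, n_per_group):
                rows.append(
                    dict(cohort=f"cohort_{ci}", mutated=mutated, count=float(v))
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file emission


def _evidence_to_snaptron(evidence: pd.DataFrame) -> pd.DataFrame:
    """Collapse long evidence to the Snaptron-like dump dialect.

    One row per junction, raw 1-based closed coordinates, samples as
    comma-separated ``sample_id:reads`` pairs.
    """
    def pack(g: pd.DataFrame) -> str:
        g = g.sort_values("sample_id")
        return ",".join(f"{s}:{r}" for s, r in zip(g.sample_id, g.reads))

    grouped = (
        evidence.groupby(["chrom", "start", "end", "strand"])
        .apply(pack, include_groups=False)
        .rename("samples")
        .reset_index()
    )
    grouped["start"] = grouped["start"] + 1  # 0-based closed -> 1-based closed
    grouped["end"] = grouped["end"] + 1
    return grouped.sort_values(["chrom", "start", "end", "strand"]).reset_index(drop=True)


def write_simulated_inputs(
    outdir: str | Path,
    config: SimConfig,
    effect: MutationEffect | None = None,
) -> dict[str, Path]:
    """Generate everything and write the on-disk input set for the pipeline.

    Emits GTF, Snaptron-dialect evidence TSV (1-based closed), phenotype
    TSV, truth TSV, clinical TSVs, cancer-gene list, SRA taxonomy YAML,
    tissue-match YAML and a manifest JSON recording config and checksums.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf_text, ann_truth = generate_annotation(
        config.n_genes, config.transcripts_per_gene, config.exons_per_transcript,
        seed=config.seed, frac_cancer_genes=config.frac_cancer_genes,
    )
    evidence, phenotypes, truth = generate_cohorts(config, ann_truth)
    effect = effect or MutationEffect()
    mutations, tmb, surv, _planted = generate_clinical_tables(config, effect, phenotypes)

    paths = {}
    paths["annotation"] = outdir / "annotation.gtf"
    paths["annotation"].write_text(gtf_text)
    paths["evidence"] = outdir / "evidence.tsv"
    _evidence_to_snaptron(evidence).to_csv(paths["evidence"], sep="\t", index=False)
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["mutations"] = outdir / "mutations.tsv"
    mutations.to_csv(paths["mutations"], sep="\t", index=False)
    paths["tmb"] = outdir / "tmb.tsv"
    tmb.to_csv(paths["tmb"], sep="\t", index=False)
    paths["survival"] = outdir / "survival.tsv"
    surv.to_csv(paths["survival"], sep="\t", index=False)
    paths["cancer_genes"] = outdir / "cancer_genes.txt"
    paths["cancer_genes"].write_text(
        "\n".join(sorted(g.name for g in ann_truth.genes if g.cancer_associated)) + "\n"
    )
    paths["taxonomy"] = outdir / "sra_taxonomy.yaml"
    paths["taxonomy"].write_text(
        yaml.safe_dump(
            dict(categories=config.sra_category_groups, placenta_category="placenta"),
            sort_keys=True,
        )
    )
    paths["tissue_match"] = outdir / "tissue_match.yaml"
    paths["tissue_match"].write_text(
        yaml.safe_dump({c: list(v) for c, v in config.match_map().items()}, sort_keys=True)
    )
    paths["sra_cancer_match"] = outdir / "sra_cancer_match.yaml"
    paths["sra_cancer_match"].write_text(
        yaml.safe_dump(dict(config.cancer_match_map()), sort_keys=True)
    )

    manifest = dict(
        config=asdict(config),
        coordinate_dialects={"evidence.tsv": "1-closed"},
        checksums={
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(paths.values())
        },
    )
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    paths["manifest"] = mpath
    return paths
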