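"""Gene-context classification: protein-coding sense, antisense, or neither.

A junction is *protein-coding* if at least one of its two splice sites falls
within the boundary interval of a protein-coding gene on the same strand,
and *antisense* if sites overlap protein-coding gene boundaries only on the
opposite strand. Sense overlap takes precedence when both exist. Junctions
touching no gene boundary are *neither*.

Unknown-strand junctions overlapping a gene are labeled protein-coding by
default (conservative with respect to antisense claims); this is
configurable.
"""

from __future__ import annotations

import logging

import pandas as pd

from .annotation import AnnotationIndex
from .coords import JunctionCoord
from .store import JunctionStore

logger = logging.getLogger(__name__)

CONTEXTS = ("protein_coding", "antisense", "neither")


def classify_gene_context(
    coord: JunctionCoord,
    index: AnnotationIndex,
    unknown_strand_label: str = "protein_coding",
) -> tuple[str, tuple[str, ...]]:
    """Label one junction and return the overlapping gene names.

    For protein-coding labels the genes returned are all same-strand
    overlapping genes (a junction spanning two same-strand genes attaches to
    both); for antisense, the opposite-strand genes.
    """
    hits = {g.name: g for g in index.genes_at(coord.chrom, coord.start)}
    hits.update({g.name: g for g in index.genes_at(coord.chrom, coord.end)})
    if not hits:
        return "neither", ()
    if coord.strand not in ("+", "-"):
        return unknown_strand_label, tuple(sorted(hits))
    sense = sorted(name for name, g in hits.items() if g.strand == coord.strand)
    if sense:
        return "protein_coding", tuple(sense)
    return "antisense", tuple(sorted(hits))


def classify_store(
    store: JunctionStore,
    index: AnnotationIndex,
    cancer_genes: set[str] | None = None,
    unknown_strand_label: str = "protein_coding",
) -> pd.DataFrame:
    """Classify every junction in the store; returns the context table.

    Fills ``gene_context``, ``genes`` and ``cancer_gene_flag`` on
    ``store.junctions`` in place and returns that frame.
    """
    if cancer_genes is not None and not cancer_genes:
        logger.warning("empty cancer gene list: all cancer flags will be False")
    contexts, genes_col, flags = [], [], []
    jt = store.junctions
    for chrom, start, end, strand in zip(jt.chrom, jt.start, jt.end, jt.strand):
        coord = JunctionCoord(chrom, int(start), int(end), strand)
        label, genes = classify_gene_context(coord, index, unknown_strand_label)
        contexts.append(label)
        genes_col.append("|".join(genes))
        flags.append(
            label == "protein_coding"
            and bool(cancer_genes)
            and any(g in cancer_genes for g in genes)
        )
    jt["gene_context"] = contexts
    jt["genes"] = genes_col
    jt["cancer_gene_flag"] = flags
    return jt


def flag_cancer_genes(contexts: pd.DataFrame, cancer_genes: set[str]) -> pd.Series:
    """Cancer-relevant-locus flag per junction from a context table.

    True iff the junction is sense protein-coding and any attached gene is
    in the cancer-associated list (union of the configured resources).
    """
    if not cancer_genes:
        logger.warning("empty cancer gene list: all cancer flags will be False")
    def hit(row) -> bool:
        if row.gene_context != "protein_coding" or not row.genes:
            return False
        return any(g in cancer_genes for g in str(row.genes).split("|"))
    return contexts.apply(hit, axis=1)


def antisense_fraction_by_category(labels: pd.DataFrame) -> pd.DataFrame:
    """Percent antisense junctions per (cohort, category).

    ``labels`` must carry one row per (cohort, junction) with columns
    ``cohort``, ``category`` and ``gene_context``. Empty categories are
    simply absent from the output.
    """
    grouped = labels.groupby(["cohort", "category"], sort=True)
    out = grouped.agg(
        n=("gene_context", "size"),
        n_antisense=("gene_context", lambda s: int((s == "antisense").sum())),
    ).reset_index()
    out["percent_antisense"] = 100.0 * out.n_antisense / out.n
    return out
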