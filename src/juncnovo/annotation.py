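"""GTF parsing and the searchable annotation index.

The annotation index answers three questions the downstream analysis needs:

* is a junction (or one of its two splice sites) annotated in any transcript?
* which protein-coding gene boundary intervals does a point fall inside
  (stabbing query, strand-aware)?
* what are the annotated left/right splice-site sets per chromosome+strand?

Gene "boundaries" are gene-level start/end spans (introns included), not exon
unions. Coordinates are converted from the GTF's 1-based closed convention to
the canonical 0-based closed intron system on load.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coords import JunctionCoord

_ATTR_RE = re.compile(r'(\S+) "([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


@dataclass(frozen=True)
class GeneRegion:
    """A protein-coding gene boundary span (0-based closed)."""

    name: str
    chrom: str
    strand: str
    start: int
    end: int
    cancer_associated: bool = False


class IntervalIndex:
    """Static interval set supporting point-stabbing queries.

    Intervals are 0-based closed. Built once from a list, queried many
    times; uses sorted starts plus a running maximum of ends so a stab is
    a bisect followed by a bounded leftward scan.
    """

    def __init__(self, intervals: list[tuple[int, int, object]]):
        ordered = sorted(intervals, key=lambda iv: (iv[0], iv[1]))
        self._starts = np.array([iv[0] for iv in ordered], dtype=np.int64)
        self._ends = np.array([iv[1] for iv in ordered], dtype=np.int64)
        self._payloads = [iv[2] for iv in ordered]
        self._max_end = (
            np.maximum.accumulate(self._ends)
            if len(ordered)
            else np.array([], dtype=np.int64)
        )

    def __len__(self) -> int:
        return len(self._payloads)

    def stab(self, point: int) -> list[object]:
        """Return payloads of all intervals containing ``point``."""
        hits: list[object] = []
        i = bisect_right(self._starts, point) - 1
        while i >= 0 and self._max_end[i] >= point:
            if self._ends[i] >= point:
                hits.append(self._payloads[i])
            i -= 1
        return hits


@dataclass
class AnnotationIndex:
    """Annotated junctions, splice-site sets and gene-boundary trees."""

    annotated_junctions: set[JunctionCoord] = field(default_factory=set)
    # splice-site sets keyed by (chrom, strand)
    left_sites: dict[tuple[str, str], set[int]] = field(default_factory=dict)
    right_sites: dict[tuple[str, str], set[int]] = field(default_factory=dict)
    genes: dict[str, GeneRegion] = field(default_factory=dict)
    _gene_index: dict[str, IntervalIndex] = field(default_factory=dict)

    def add_annotated_junction(self, coord: JunctionCoord) -> None:
        self.annotated_junctions.add(coord)
        key = (coord.chrom, coord.strand)
        self.left_sites.setdefault(key, set()).add(coord.start)
        self.right_sites.setdefault(key, set()).add(coord.end)

    def build_gene_index(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, GeneRegion]]] = {}
        for gene in self.genes.values():
            by_chrom.setdefault(gene.chrom, []).append((gene.start, gene.end, gene))
        self._gene_index = {c: IntervalIndex(ivs) for c, ivs in by_chrom.items()}

    def genes_at(self, chrom: str, point: int) -> list[GeneRegion]:
        """All protein-coding genes whose boundary interval contains ``point``."""
        index = self._gene_index.get(chrom)
        return list(index.stab(point)) if index is not None else []

    def annotation_status(self, coord: JunctionCoord) -> str:
        """Three-way GENCODE annotation status of a junction.

        ``"both"`` — the exact junction is annotated; ``"one"`` — at least
        one of its splice sites is an annotated site on the same
        chromosome+strand; ``"neither"`` otherwise.
        """
        if coord in self.annotated_junctions:
            return "both"
        key = (coord.chrom, coord.strand)
        left = coord.start in self.left_sites.get(key, ())
        right = coord.end in self.right_sites.get(key, ())
        return "one" if (left or right) else "neither"

    def set_cancer_genes(self, cancer_genes: set[str]) -> None:
        """Mark genes whose name appears in a cancer-associated gene list."""
        for name, gene in list(self.genes.items()):
            flag = name in cancer_genes
            if flag != gene.cancer_associated:
                self.genes[name] = GeneRegion(
                    gene.name, gene.chrom, gene.strand, gene.start, gene.end, flag
                )
        self.build_gene_index()


def parse_annotation(gtf: str | Path) -> AnnotationIndex:
    """Parse a GENCODE-dialect GTF into an :class:`AnnotationIndex`.

    ``gtf`` is a path, or the GTF text itself if it contains newlines.
    Junctions are derived from consecutive exons of each transcript
    (duplicates across transcripts collapse); gene boundaries come from
    gene-level lines of ``protein_coding`` genes.
    """
    if isinstance(gtf, Path) or "\n" not in str(gtf):
        text = Path(gtf).read_text()
    else:
        text = str(gtf)

    index = AnnotationIndex()
    # exons accumulated per transcript, as 1-based closed (start, end)
    exons: dict[str, list[tuple[int, int, str, str]]] = {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GTF line {lineno}: expected 9 fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
        if end < start:
            raise ValueError(f"GTF line {lineno}: end {end} < start {start}")

        if feature == "gene":
            attr = _parse_attributes(attrs)
            if attr.get("gene_type") == "protein_coding":
                name = attr.get("gene_name") or attr.get("gene_id", f"gene_line{lineno}")
                index.genes[name] = GeneRegion(name, chrom, strand, start - 1, end - 1)
        elif feature == "exon":
            attr = _parse_attributes(attrs)
            tx = attr.get("transcript_id")
            if tx is None:
                raise ValueError(f"GTF line {lineno}: exon lacks transcript_id")
            exons.setdefault(tx, []).append((start, end, chrom, strand))

    for tx_exons in exons.values():
        tx_exons.sort()
        for (s1, e1, chrom, strand), (s2, e2, _c, _s) in zip(tx_exons, tx_exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in one transcript: [{s1},{e1}] and [{s2},{e2}]")
            # intron is 1-based closed [e1+1, s2-1] -> 0-based closed (e1, s2-2)
            index.add_annotated_junction(JunctionCoord(chrom, e1, s2 - 2, strand).validate())

    index.build_gene_index()
    return index


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-gene-per-line text file (or CSV first column) of gene names."""
    names: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        names.add(line.split(",")[0].split("\t")[0].strip())
    return names
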