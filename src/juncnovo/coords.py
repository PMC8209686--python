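"""Junction coordinate handling.

A splice junction is represented by its intron: the first and last intronic
bases, in a 0-based closed coordinate system. All internal computation uses
this canonical form; input tables may arrive in any of three dialects
(1-based closed, 0-based half-open, 0-based closed) and are converted on
ingestion.
"""

from __future__ import annotations

from typing import NamedTuple

STRANDS = ("+", "-", "?")

#: Coordinate dialects accepted by :func:`convert_coordinates`.
DIALECTS = ("1-closed", "0-half-open", "0-closed")


class JunctionCoord(NamedTuple):
    """One exon-exon junction in canonical 0-based closed intron coordinates.

    ``start`` is the first base of the intron and ``end`` the last base,
    both 0-based. ``strand`` is '+', '-' or '?' (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str

    def canonical(self) -> str:
        """Unique textual form ``chrom:start-end(strand)``."""
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    def validate(self) -> "JunctionCoord":
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid junction interval {self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        return self


def convert_coordinates(
    chrom: str, a: int, b: int, strand: str, dialect: str = "1-closed"
) -> JunctionCoord:
    """Convert raw junction coordinates to the canonical 0-based closed form.

    Parameters
    ----------
    chrom, a, b, strand
        Raw junction record: ``a``/``b`` delimit the intron in the given
        dialect.
    dialect
        One of ``"1-closed"`` (GTF/Snaptron raw dumps), ``"0-half-open"``
        (BED) or ``"0-closed"`` (already canonical; identity).
    """
    if dialect == "1-closed":
        if a > b:
            raise ValueError(f"closed interval requires a <= b, got {a} > {b}")
        coord = JunctionCoord(chrom, a - 1, b - 1, strand)
    elif dialect == "0-half-open":
        if a >= b:
            raise ValueError(f"half-open interval requires a < b, got {a} >= {b}")
        coord = JunctionCoord(chrom, a, b - 1, strand)
    elif dialect == "0-closed":
        if a > b:
            raise ValueError(f"closed interval requires a <= b, got {a} > {b}")
        coord = JunctionCoord(chrom, a, b, strand)
    else:
        raise ValueError(f"unknown coordinate dialect {dialect!r}; expected one of {DIALECTS}")
    return coord.validate()


def to_bed_interval(coord: JunctionCoord) -> tuple[str, int, int, str]:
    """Export canonical coordinates as a BED (0-based half-open) interval."""
    return (coord.chrom, coord.start, coord.end + 1, coord.strand)
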