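"""The three-table junction store: junctions, evidence, samples.

Mirrors the relational design the analysis queries run against: (i) sample
IDs with associated junction IDs and read counts, (ii) sample phenotypes,
(iii) junction information (canonical 0-based closed coordinates, annotation
status, gene context). Persisted as a single SQLite file with indexes on the
junction-ID and sample-ID columns; held in memory as pandas frames.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import AnnotationIndex
from .coords import JunctionCoord, convert_coordinates

logger = logging.getLogger(__name__)

COORD_COLS = ["chrom", "start", "end", "strand"]

#: GTEx normals derived from a leukemia cell line are not normal tissue and
#: are dropped at load.
DEFAULT_EXCLUDED_COHORTS = frozenset({"Cells - Leukemia cell line (CML)"})

#: Cancer-subtype refinements of five TCGA designations, keyed by parent
#: cohort then clinical subtype value.
DEFAULT_SUBTYPE_MAP: dict[str, dict[str, str]] = {
    "cervical squamous cell carcinoma and endocervical adenocarcinoma": {
        "squamous": "cervical squamous cell carcinoma",
        "adenocarcinoma": "endocervical adenocarcinoma",
        "adenosquamous": "cervical adenosquamous",
    },
    "esophageal carcinoma": {
        "adenocarcinoma": "esophagus adenocarcinoma",
        "squamous": "esophagus squamous cell carcinoma",
    },
    "brain lower grade glioma": {
        "astrocytoma": "astrocytoma",
        "oligoastrocytoma": "oligoastrocytoma",
        "oligodendroglioma": "oligodendroglioma",
    },
    "sarcoma": {
        "leiomyosarcoma": "leiomyosarcoma",
        "myxofibrosarcoma": "myxofibrosarcoma",
        "malignant peripheral nerve sheath tumors": "malignant peripheral nerve sheath tumors",
        "desmoid tumors": "desmoid tumors",
        "dedifferentiated liposarcoma": "dedifferentiated liposarcoma",
        "synovial sarcoma": "synovial sarcoma",
        "undifferentiated pleomorphic sarcoma": "undifferentiated pleomorphic sarcoma",
    },
    "pheochromocytoma and paraganglioma": {
        "pheochromocytoma": "pheochromocytoma",
        "paraganglioma": "paraganglioma",
    },
}

CORE_NORMAL_CLASSES = ("gtex_normal", "matched_normal")
SRA_NONCANCER_CLASSES = ("sra_adult", "sra_developmental", "sra_stem", "sra_placenta")


def parse_snaptron_table(
    table: pd.DataFrame | str | Path, dialect: str = "1-closed"
) -> pd.DataFrame:
    """Explode a Snaptron-like dump into long evidence with canonical coords.

    Input columns: ``chrom start end strand samples`` where ``samples`` is a
    comma-separated list of ``sample_id:read_count`` pairs and the raw
    coordinates are in ``dialect``. Output columns:
    ``chrom start end strand sample_id reads`` (0-based closed).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype={"chrom": str})
    rows = []
    for chrom, a, b, strand, samples in zip(
        table.chrom, table.start, table.end, table.strand, table.samples
    ):
        coord = convert_coordinates(str(chrom), int(a), int(b), str(strand), dialect)
        for pair in str(samples).split(","):
            sid, _, cnt = pair.partition(":")
            rows.append((coord.chrom, coord.start, coord.end, coord.strand, sid, int(cnt)))
    return pd.DataFrame(rows, columns=COORD_COLS + ["sample_id", "reads"])


def load_phenotypes(
    table: pd.DataFrame | str | Path,
    excluded_cohorts: frozenset[str] = DEFAULT_EXCLUDED_COHORTS,
) -> pd.DataFrame:
    """Load a phenotype TSV, dropping excluded cohorts at load time."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype={"sample_id": str})
    n0 = len(table)
    table = table[~table.cohort.isin(excluded_cohorts)].reset_index(drop=True)
    if len(table) < n0:
        logger.info("dropped %d samples from excluded cohorts", n0 - len(table))
    return table


def refine_subtypes(
    phenotypes: pd.DataFrame,
    subtype_map: dict[str, dict[str, str]] = DEFAULT_SUBTYPE_MAP,
    subtype_col: str = "subtype",
) -> pd.DataFrame:
    """Re-label listed cancer cohorts by their clinical subtype field.

    Only cohorts present as keys of ``subtype_map`` are modified; a sample
    whose subtype value is absent from the map keeps the parent label (with
    a logged warning). Sample counts are conserved.
    """
    out = phenotypes.copy()
    if subtype_col not in out.columns:
        return out
    for i in out.index:
        cohort = out.at[i, "cohort"]
        if cohort not in subtype_map:
            continue
        sub = out.at[i, subtype_col]
        refined = subtype_map[cohort].get(str(sub))
        if refined is None:
            logger.warning(
                "sample %s: subtype %r not in map for cohort %r; keeping parent label",
                out.at[i, "sample_id"], sub, cohort,
            )
        else:
            out.at[i, "cohort"] = refined
    return out


@dataclass
class JunctionStore:
    """In-memory three-table store with SQLite persistence."""

    junctions: pd.DataFrame  # junction_id + coords + annotation_status, gene_context, cancer_gene_flag
    evidence: pd.DataFrame  # junction_id, sample_id, reads
    samples: pd.DataFrame  # sample_id, cohort, cohort_class, clinical fields
    _samples_by_junction: dict | None = field(default=None, repr=False)

    # -- construction --------------------------------------------------------
    @classmethod
    def build(
        cls,
        evidence_tables: list[pd.DataFrame],
        phenotypes: pd.DataFrame,
        annotation: AnnotationIndex | None = None,
    ) -> "JunctionStore":
        """Build the store from long-form evidence tables and phenotypes.

        Evidence must already be canonical (see :func:`parse_snaptron_table`).
        Exact duplicate (junction, sample, reads) rows merge idempotently;
        remaining duplicate (junction, sample) pairs from different sources
        sum their counts. Evidence naming a sample absent from the phenotype
        table is a load error listing the offenders (evidence for samples in
        excluded cohorts is silently dropped only if the caller already
        dropped them from the phenotype table *and* flagged them: here,
        unknown means unknown).
        """
        ev = pd.concat(evidence_tables, ignore_index=True)
        ev = ev.drop_duplicates()  # idempotent re-load of identical rows
        ev = ev.groupby(COORD_COLS + ["sample_id"], as_index=False).reads.sum()
        if (ev.reads < 1).any():
            raise ValueError("evidence read counts must be >= 1 (absence is omission)")

        known = set(phenotypes.sample_id)
        offenders = sorted(set(ev.sample_id) - known)
        if offenders:
            raise ValueError(
                f"evidence names {len(offenders)} samples absent from phenotypes: "
                f"{offenders[:10]}"
            )

        junctions = (
            ev[COORD_COLS]
            .drop_duplicates()
            .sort_values(COORD_COLS)
            .reset_index(drop=True)
        )
        junctions.insert(0, "junction_id", range(len(junctions)))
        if annotation is not None:
            junctions["annotation_status"] = [
                annotation.annotation_status(JunctionCoord(c, s, e, t))
                for c, s, e, t in zip(
                    junctions.chrom, junctions.start, junctions.end, junctions.strand
                )
            ]
        else:
            junctions["annotation_status"] = "unknown"
        junctions["gene_context"] = ""  # set by annotation_classify
        junctions["cancer_gene_flag"] = False

        ev = ev.merge(junctions[["junction_id"] + COORD_COLS], on=COORD_COLS)
        evidence = ev[["junction_id", "sample_id", "reads"]].sort_values(
            ["junction_id", "sample_id"]
        ).reset_index(drop=True)
        return cls(junctions=junctions, evidence=evidence, samples=phenotypes.reset_index(drop=True))

    # -- queries -------------------------------------------------------------
    def coord_of(self, junction_id: int) -> JunctionCoord:
        row = self.junctions.loc[self.junctions.junction_id == junction_id].iloc[0]
        return JunctionCoord(row.chrom, int(row.start), int(row.end), row.strand)

    def samples_in_cohorts(self, cohorts: set[str] | list[str]) -> set[str]:
        unknown = set(cohorts) - set(self.samples.cohort)
        if unknown:
            raise ValueError(f"unknown cohorts: {sorted(unknown)}")
        return set(self.samples.loc[self.samples.cohort.isin(set(cohorts)), "sample_id"])

    def samples_in_classes(self, classes: set[str] | list[str]) -> set[str]:
        return set(
            self.samples.loc[self.samples.cohort_class.isin(set(classes)), "sample_id"]
        )

    def junctions_of_sample(self, sample_id: str) -> set[int]:
        return set(self.evidence.loc[self.evidence.sample_id == sample_id, "junction_id"])

    def samples_of_junction(self, junction_id: int) -> set[str]:
        return set(self.evidence.loc[self.evidence.junction_id == junction_id, "sample_id"])

    def evidence_with_classes(self) -> pd.DataFrame:
        """Evidence joined to cohort and cohort_class (the analysis workhorse)."""
        return self.evidence.merge(
            self.samples[["sample_id", "cohort", "cohort_class"]], on="sample_id"
        )

    def tumor_cohorts(self) -> list[str]:
        return sorted(
            self.samples.loc[self.samples.cohort_class == "tumor", "cohort"].unique()
        )

    def cohort_sizes(self) -> pd.Series:
        return self.samples.groupby("cohort").sample_id.nunique()

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the single-file SQLite database with the standard indexes."""
        path = Path(path)
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as con:
            self.junctions.to_sql("junctions", con, index=False)
            self.evidence.to_sql("evidence", con, index=False)
            self.samples.to_sql("samples", con, index=False)
            con.execute("CREATE INDEX idx_evidence_junction ON evidence (junction_id)")
            con.execute("CREATE INDEX idx_evidence_sample ON evidence (sample_id)")
            con.execute("CREATE INDEX idx_junctions_id ON junctions (junction_id)")
            con.execute("CREATE INDEX idx_samples_id ON samples (sample_id)")

    @classmethod
    def load(cls, path: str | Path) -> "JunctionStore":
        with sqlite3.connect(Path(path)) as con:
            junctions = pd.read_sql("SELECT * FROM junctions", con)
            evidence = pd.read_sql("SELECT * FROM evidence", con)
            samples = pd.read_sql("SELECT * FROM samples", con)
        samples = samples.fillna("")
        junctions["cancer_gene_flag"] = junctions["cancer_gene_flag"].astype(bool)
        return cls(junctions=junctions, evidence=evidence, samples=samples)

    def export_junctions_tsv(self, path: str | Path) -> None:
        """Canonical 0-based closed junction table export."""
        self.junctions.to_csv(path, sep="\t", index=False)
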