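"""Shared fixtures: tiny hand-built stores and a small synthetic world."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from juncnovo.annotation import parse_annotation
from juncnovo.simulate import SimConfig, generate_annotation, generate_cohorts
from juncnovo.store import JunctionStore


def make_store(
    evidence_rows: list[tuple],
    sample_rows: list[tuple],
    annotation=None,
) -> JunctionStore:
    """Build a store from literal rows.

    evidence_rows: (chrom, start, end, strand, sample_id, reads) canonical.
    sample_rows: (sample_id, cohort, cohort_class).
    """
    ev = pd.DataFrame(
        evidence_rows, columns=["chrom", "start", "end", "strand", "sample_id", "reads"]
    )
    ph = pd.DataFrame(sample_rows, columns=["sample_id", "cohort", "cohort_class"])
    ph["mapped_read_count"] = 1_000_000
    return JunctionStore.build([ev], ph, annotation=annotation)


def random_small_store(rng: np.random.Generator, max_junctions=50, max_samples=50):
    """A randomized small store with tumor / normal / SRA cohorts, for
    brute-force oracle equivalence tests. Returns (store, match_map)."""
    n_j = int(rng.integers(1, max_junctions + 1))
    cohorts = [
        ("tum_a", "tumor"), ("tum_b", "tumor"),
        ("tis_a", "gtex_normal"), ("tis_x", "gtex_normal"),
        ("mn_b", "matched_normal"),
        ("sra_adult1", "sra_adult"), ("sra_dev1", "sra_developmental"),
        ("placenta", "sra_placenta"), ("sra_stem1", "sra_stem"),
        ("sra_can_a", "sra_cancer"),
    ]
    samples = []
    for cohort, klass in cohorts:
        for i in range(int(rng.integers(1, max(2, max_samples // len(cohorts))))):
            samples.append((f"{cohort}_s{i}", cohort, klass))
    ev_rows = []
    for j in range(n_j):
        start = 100 + 10 * j
        k = int(rng.integers(1, 6))
        chosen = rng.choice(len(samples), size=min(k, len(samples)), replace=False)
        for si in chosen:
            ev_rows.append(
                ("chrS", start, start + 5, "+", samples[int(si)][0], int(rng.integers(1, 5)))
            )
    match_map = {"tum_a": ("tis_a",), "tum_b": ("mn_b",)}
    return make_store(ev_rows, samples), match_map


@pytest.fixture(scope="session")
def small_world():
    """One modest synthetic world shared by read-only tests."""
    cfg = SimConfig(seed=42, n_junctions=400, n_genes=25)
    gtf, ann_truth = generate_annotation(
        cfg.n_genes, cfg.transcripts_per_gene, cfg.exons_per_transcript,
        seed=cfg.seed, frac_cancer_genes=cfg.frac_cancer_genes,
    )
    evidence, phenotypes, truth = generate_cohorts(cfg, ann_truth)
    ann = parse_annotation(gtf)
    store = JunctionStore.build([evidence], phenotypes, annotation=ann)
    return dict(
        cfg=cfg, gtf=gtf, ann_truth=ann_truth, ann=ann,
        evidence=evidence, phenotypes=phenotypes, truth=truth, store=store,
    )
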