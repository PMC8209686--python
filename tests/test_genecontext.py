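"""Gene-context classification (protein-coding / antisense / neither)."""

import numpy as np
import pandas as pd
import pytest

from juncnovo.annotation import AnnotationIndex, GeneRegion
from juncnovo.coords import JunctionCoord
from juncnovo.genecontext import (
    antisense_fraction_by_category,
    classify_gene_context,
    classify_store,
    flag_cancer_genes,
)


def index_with(*genes):
    idx = AnnotationIndex()
    for g in genes:
        idx.genes[g.name] = g
    idx.build_gene_index()
    return idx


PLUS_GENE = GeneRegion("G1", "chrS", "+", 100, 500)
MINUS_GENE = GeneRegion("G2", "chrS", "-", 400, 900)


@pytest.mark.parametrize(
    "coord, expected_label, expected_genes",
    [
        (JunctionCoord("chrS", 150, 300, "+"), "protein_coding", ("G1",)),
        (JunctionCoord("chrS", 150, 300, "-"), "antisense", ("G1",)),
        # one site inside a '+' gene, no '-' gene overlap -> antisense
        (JunctionCoord("chrS", 450, 2000, "-"), "protein_coding", ("G2",)),
        (JunctionCoord("chrS", 150, 2000, "-"), "antisense", ("G1",)),
        (JunctionCoord("chrS", 2000, 3000, "+"), "neither", ()),
    ],
)
def test_context_examples(coord, expected_label, expected_genes):
    idx = index_with(PLUS_GENE, MINUS_GENE)
    label, genes = classify_gene_context(coord, idx)
    assert (label, genes) == (expected_label, expected_genes)


def test_sense_precedence_over_antisense():
    """With overlapping genes on both strands, the same-strand assignment
    wins and only sense genes attach."""
    idx = index_with(PLUS_GENE, MINUS_GENE)
    label, genes = classify_gene_context(JunctionCoord("chrS", 450, 480, "+"), idx)
    assert label == "protein_coding" and genes == ("G1",)


def test_junction_spanning_two_same_strand_genes_attaches_both():
    g3 = GeneRegion("G3", "chrS", "+", 600, 800)
    idx = index_with(PLUS_GENE, g3)
    label, genes = classify_gene_context(JunctionCoord("chrS", 200, 700, "+"), idx)
    assert label == "protein_coding" and genes == ("G1", "G3")


def test_unknown_strand_defaults_to_protein_coding_but_is_configurable():
    idx = index_with(PLUS_GENE)
    coord = JunctionCoord("chrS", 150, 300, "?")
    assert classify_gene_context(coord, idx)[0] == "protein_coding"
    assert classify_gene_context(coord, idx, unknown_strand_label="antisense")[0] == "antisense"


def test_matches_naive_overlap_scan_randomized():
    rng = np.random.default_rng(3)
    genes = [
        GeneRegion(f"g{i}", "chrS", "+" if i % 2 else "-", int(s), int(s + rng.integers(50, 300)))
        for i, s in enumerate(rng.integers(0, 3000, size=30))
    ]
    idx = index_with(*genes)
    for _ in range(300):
        a = int(rng.integers(0, 3300))
        b = a + int(rng.integers(1, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        coord = JunctionCoord("chrS", a, b, strand)
        hits = {g.name: g for g in genes if g.start <= a <= g.end or g.start <= b <= g.end}
        sense = tuple(sorted(n for n, g in hits.items() if g.strand == strand))
        if sense:
            expected = ("protein_coding", sense)
        elif hits:
            expected = ("antisense", tuple(sorted(hits)))
        else:
            expected = ("neither", ())
        assert classify_gene_context(coord, idx) == expected


def test_planted_contexts_recovered(small_world):
    """classify_store reproduces the generator's planted gene contexts and
    cancer-gene flags exactly."""
    store, ann, truth = small_world["store"], small_world["ann"], small_world["truth"]
    cancer_genes = {g.name for g in small_world["ann_truth"].genes if g.cancer_associated}
    contexts = classify_store(store, ann, cancer_genes)
    key = ["chrom", "start", "end", "strand"]
    merged = truth.merge(
        contexts[key + ["gene_context", "cancer_gene_flag"]],
        on=key, suffixes=("_planted", ""),
    )
    assert (merged.gene_context == merged.gene_context_planted).all()
    assert (merged.cancer_gene_flag == merged.cancer_gene).all()


def test_flag_cancer_genes_and_empty_list_warns(caplog):
    contexts = pd.DataFrame(
        dict(
            junction_id=[0, 1, 2],
            gene_context=["protein_coding", "protein_coding", "antisense"],
            genes=["ONC1", "OTHER", "ONC1"],
        )
    )
    flags = flag_cancer_genes(contexts, {"ONC1"})
    assert flags.tolist() == [True, False, False]  # antisense never flags
    with caplog.at_level("WARNING"):
        none = flag_cancer_genes(contexts, set())
    assert not none.any() and "empty cancer gene list" in caplog.text


def test_antisense_fractions_order_invariant():
    labels = pd.DataFrame(
        dict(
            cohort=["c1"] * 4 + ["c2"] * 2,
            category=["unexplained"] * 4 + ["adult"] * 2,
            gene_context=["antisense", "protein_coding", "antisense", "neither",
                          "protein_coding", "protein_coding"],
        )
    )
    out = antisense_fraction_by_category(labels)
    shuffled = antisense_fraction_by_category(labels.sample(frac=1, random_state=1))
    pd.testing.assert_frame_equal(out, shuffled)
    row = out[(out.cohort == "c1") & (out.category == "unexplained")].iloc[0]
    assert row.percent_antisense == pytest.approx(50.0)
    adult = out[(out.cohort == "c2") & (out.category == "adult")].iloc[0]
    assert adult.percent_antisense == 0.0
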