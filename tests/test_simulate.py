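"""Generator contracts: determinism, consistency and label faithfulness."""

import numpy as np
import pandas as pd
import pytest

from juncnovo.simulate import (
    MutationEffect,
    SimConfig,
    generate_annotation,
    generate_clinical_tables,
    generate_cohorts,
)

# which cohort classes may carry reads for each planted truth label
PERMITTED = {
    "tissue_matched_normal": {"tumor", "gtex_normal", "matched_normal"},
    "other_core_normal": {"tumor", "gtex_normal", "matched_normal"},
    "sra_adult": {"tumor", "sra_adult", "sra_cancer"},
    "sra_developmental": {"tumor", "sra_developmental", "sra_cancer"},
    "sra_stem": {"tumor", "sra_stem", "sra_cancer"},
    "sra_placenta": {"tumor", "sra_placenta", "sra_cancer"},
    "unexplained": {"tumor", "sra_cancer"},
    "filtered": {"tumor"},
}


def test_generation_is_deterministic():
    cfg = SimConfig(seed=5, n_junctions=200, n_genes=15)
    out1 = generate_cohorts(cfg)
    out2 = generate_cohorts(SimConfig(seed=5, n_junctions=200, n_genes=15))
    for a, b in zip(out1, out2):
        pd.testing.assert_frame_equal(a, b)


def test_different_seed_changes_output():
    a, _, _ = generate_cohorts(SimConfig(seed=1, n_junctions=100, n_genes=15))
    b, _, _ = generate_cohorts(SimConfig(seed=2, n_junctions=100, n_genes=15))
    assert not a.equals(b)


def test_evidence_samples_all_in_phenotypes(small_world):
    ev, ph = small_world["evidence"], small_world["phenotypes"]
    assert set(ev.sample_id) <= set(ph.sample_id)
    assert (ev.reads >= 1).all()


def test_label_faithfulness(small_world):
    """Reads appear only in cohort classes the planted category permits."""
    ev, ph, truth = small_world["evidence"], small_world["phenotypes"], small_world["truth"]
    klass = ph.set_index("sample_id").cohort_class
    ev = ev.assign(klass=ev.sample_id.map(klass))
    key = ["chrom", "start", "end", "strand"]
    merged = ev.merge(truth[key + ["category"]], on=key)
    for cat, sub in merged.groupby("category"):
        assert set(sub.klass) <= PERMITTED[cat], cat


def test_every_junction_appears_exactly_once_in_truth(small_world):
    truth = small_world["truth"]
    key = truth[["chrom", "start", "end", "strand"]]
    assert not key.duplicated().any()


def test_filtered_junctions_have_exactly_one_read(small_world):
    ev, truth = small_world["evidence"], small_world["truth"]
    key = ["chrom", "start", "end", "strand"]
    totals = ev.groupby(key).reads.sum().reset_index(name="total")
    merged = truth.merge(totals, on=key, how="left")
    assert (merged.loc[merged.category == "filtered", "total"] == 1).all()
    assert (merged.loc[merged.category != "filtered", "total"] >= 2).all()


def test_empty_annotation_and_empty_cohort_edges():
    gtf, truth = generate_annotation(0, seed=0)
    assert truth.junctions == [] and truth.genes == []
    assert all(line.startswith("#") for line in gtf.strip().splitlines())

    _, truth_single = generate_annotation(1, 1, exons_per_transcript=1, seed=0)
    assert truth_single.junctions == []  # single exon implies no intron

    cfg = SimConfig(seed=0, n_junctions=0, samples_per_cancer_cohort=0, n_genes=5)
    ev, ph, truth = generate_cohorts(cfg)
    assert len(ev) == 0 and len(truth) == 0
    assert (ph.cohort_class != "tumor").all()


def test_negative_annotation_counts_raise():
    with pytest.raises(ValueError):
        generate_annotation(-1)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(frac_in_tissue_matched=1.2),
        dict(frac_unexplained=0.9),  # stage-2+ fractions no longer sum to 1
        dict(prevalence_spectrum=[(0.1, 0.5)]),  # weights sum to 0.5
        dict(tissue_match_map={"cancer_00": ("nonexistent_tissue",), "x": ()}),
        dict(sra_category_sizes={"mystery": 3}),  # no broad-group assignment
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        SimConfig(seed=0, **kwargs)


def test_planted_prevalence_recovered_within_binomial_bound():
    """Prevalence 0.30 planted in a 200-sample cohort lands within
    3*sqrt(0.3*0.7/200) ~ 0.097 of the target."""
    cfg = SimConfig(
        seed=3, n_cancer_cohorts=1, samples_per_cancer_cohort=200,
        n_junctions=60, n_genes=20,
        prevalence_spectrum=[(0.30, 1.0)], frac_singleton_reads=0.0,
    )
    ev, ph, truth = generate_cohorts(cfg)
    tumor = set(ph.loc[ph.cohort_class == "tumor", "sample_id"])
    key = ["chrom", "start", "end", "strand"]
    n_pos = ev[ev.sample_id.isin(tumor)].groupby(key).sample_id.nunique()
    prev = n_pos / 200
    assert abs(prev.mean() - 0.30) < 3 * np.sqrt(0.3 * 0.7 / 200)


def test_clinical_tables_keyed_to_tumor_samples():
    cfg = SimConfig(seed=9, n_junctions=50, n_genes=10)
    _, ph, _ = generate_cohorts(cfg)
    muts, tmb, surv, planted = generate_clinical_tables(
        cfg, MutationEffect(burden_shift=50.0), ph
    )
    tumor = set(ph.loc[ph.cohort_class == "tumor", "sample_id"])
    assert set(muts.patient_id) <= tumor
    assert set(tmb.patient_id) == tumor == set(surv.patient_id)
    assert set(planted["mutated_patients"]) <= tumor
    # mutated patients carry a non-synonymous splicing-gene call
    mutated = set(
        muts.loc[
            (muts.gene == "SF3B1") & (muts.variant_class == "Missense_Mutation"),
            "patient_id",
        ]
    )
    assert mutated == set(planted["mutated_patients"])
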