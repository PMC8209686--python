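"""Prevalence, shared panels, cross-cohort sharing and the KW comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from juncnovo.novelty import assign_novelty_stages
from juncnovo.sharedness import (
    all_cohort_prevalences,
    build_prevalence_matrix,
    cohort_prevalence,
    compare_prevalence_distributions,
    cross_cohort_sharing,
    select_shared_panel,
    singleton_fraction,
)
from conftest import make_store


def prevalence_fixture(n_samples=10, positives=(("j0", 3), ("j1", 1))):
    samples = [(f"s{i}", "tum", "tumor") for i in range(n_samples)]
    rows = []
    for start_name, n_pos in positives:
        start = 100 + 10 * int(start_name[1:])
        for i in range(n_pos):
            rows.append(("chrS", start, start + 5, "+", f"s{i}", 2))
    return make_store(rows, samples)


def test_prevalence_counts_positive_samples():
    store = prevalence_fixture()
    prev = cohort_prevalence(store, "tum").set_index("junction_id")
    vals = sorted(prev.prevalence)
    assert vals == [0.1, 0.3]
    assert (prev.cohort_size == 10).all()
    # 350 of 430 reproduces the highest-prevalence ovarian figure of merit
    assert round(350 / 430, 3) == 0.814


def test_prevalence_boundaries_and_empty_cohort():
    store = prevalence_fixture(positives=(("j0", 10), ("j1", 0)))
    prev = cohort_prevalence(
        store, "tum", set(store.junctions.junction_id) | {999}
    ).set_index("junction_id")
    assert prev.prevalence.max() == 1.0
    assert prev.loc[999].prevalence == 0.0
    with pytest.raises(ValueError):
        cohort_prevalence(store, "not_a_cohort")


def _staged_world(small_world):
    store, cfg = small_world["store"], small_world["cfg"]
    return store, assign_novelty_stages(store, cfg.match_map())


def test_panel_respects_admission_rule_and_sort_oracle(small_world):
    """Panel members are stage>=2+, prevalence>=1%; ordering equals a
    brute-force sort by (count desc, chrom, start, end)."""
    store, stages = _staged_world(small_world)
    cohort = store.tumor_cohorts()[0]
    panel = select_shared_panel(store, stages, cohort, cap=5)
    assert len(panel) <= 5
    assert (panel.prevalence >= 0.01).all()
    stage2 = set(
        stages[(stages.cohort == cohort) & stages.stage.isin(["2+", "3+"])].junction_id
    )
    assert set(panel.junction_id) <= stage2

    full = select_shared_panel(store, stages, cohort, cap=10**9)
    rows = list(
        full[["n_positive", "chrom", "start", "end", "junction_id"]].itertuples(
            index=False, name=None
        )
    )
    expected = sorted(rows, key=lambda r: (-r[0], r[1], r[2], r[3]))
    assert rows == expected
    # deterministic: recomputation is identical
    pd.testing.assert_frame_equal(
        full, select_shared_panel(store, stages, cohort, cap=10**9)
    )


def test_panel_boundary_exactly_one_percent():
    store = prevalence_fixture(n_samples=100, positives=(("j0", 1), ("j1", 2)))
    stages = pd.DataFrame(
        dict(cohort="tum", junction_id=store.junctions.junction_id, stage="2+")
    )
    panel = select_shared_panel(store, stages, "tum")
    # 1/100 = exactly 1% -> included ("at least 1%")
    assert len(panel) == 2


def test_cross_cohort_sharing_boundaries():
    samples = [(f"a{i}", "tum_a", "tumor") for i in range(20)] + [
        (f"b{i}", "tum_b", "tumor") for i in range(20)
    ]
    rows = []
    for s in ("a0", "b0"):  # exactly 5% in both cohorts
        rows.append(("chrS", 100, 105, "+", s, 2))
    for s in ("a0", "a1", "a2", "a3"):  # 20% in one cohort only
        rows.append(("chrS", 200, 205, "+", s, 2))
    store = make_store(rows, samples)
    prev = all_cohort_prevalences(store)
    n, table = cross_cohort_sharing(store, prev, threshold=0.05, min_cohorts=2)
    assert n == 1
    assert table.cohorts.iloc[0] == ["tum_a", "tum_b"]
    with pytest.raises(ValueError):
        cross_cohort_sharing(store, prev, threshold=1.5)


def test_singleton_fraction_edges_and_undefined():
    store = prevalence_fixture(positives=(("j0", 1), ("j1", 1)))
    ids = set(store.junctions.junction_id)
    assert singleton_fraction(store, ids) == 1.0
    store2 = prevalence_fixture(positives=(("j0", 2), ("j1", 3)))
    assert singleton_fraction(store2, set(store2.junctions.junction_id)) == 0.0
    assert singleton_fraction(store, set()) is None


def test_prevalence_matrix_shape_and_zeros(small_world):
    store, stages = _staged_world(small_world)
    cohorts = store.tumor_cohorts()
    panels = [select_shared_panel(store, stages, c, cap=20) for c in cohorts]
    panels = [p for p in panels if len(p)]
    matrix = build_prevalence_matrix(store, panels, cohorts)
    assert list(matrix.columns) == cohorts
    assert matrix.index.is_unique
    assert (matrix.max(axis=1) >= 0.01 - 1e-12).all()  # panel admission rule
    assert ((matrix >= 0) & (matrix <= 1)).all().all()


def test_kruskal_wallis_hand_value_and_degenerate():
    res = compare_prevalence_distributions([1, 2, 3], [4, 5, 6])
    # H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 3.857...
    assert res.H == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-9)
    same = compare_prevalence_distributions([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
    assert same.H == pytest.approx(0.0, abs=1e-9)
    assert same.p > 0.9
    flat = compare_prevalence_distributions([1.0, 1.0], [1.0])
    assert flat.degenerate and flat.H == 0.0 and flat.p == 1.0
    with pytest.raises(ValueError):
        compare_prevalence_distributions([], [1.0])


def test_kruskal_p_close_to_exact_permutation_small_n():
    """The chi-squared approximation tracks the exhaustive permutation
    distribution for tiny samples (documented approximation error)."""
    from oracles import exact_kw_permutation_p

    for a, b in [([1, 2, 3], [4, 5, 6]), ([1, 5, 2], [4, 3, 6]), ([1, 2], [3, 4, 5, 6])]:
        approx = compare_prevalence_distributions(a, b).p
        exact = exact_kw_permutation_p(a, b)
        assert abs(approx - exact) < 0.15


def test_prevalence_conservation(small_world):
    """Sum of positive-sample counts equals the number of (sample, junction)
    presence pairs in the cohort."""
    store = small_world["store"]
    cohort = store.tumor_cohorts()[0]
    samples = store.samples_in_cohorts([cohort])
    prev = cohort_prevalence(store, cohort)
    pairs = store.evidence[store.evidence.sample_id.isin(samples)]
    assert prev.n_positive.sum() == len(pairs.drop_duplicates(["junction_id", "sample_id"]))
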