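"""SRA set assignment, the two-sample rule and upset summaries."""

import numpy as np
import pandas as pd
import pytest

from juncnovo.novelty import assign_novelty_stages, stage_at_least
from juncnovo.sets import (
    SraTaxonomy,
    apply_two_sample_rule,
    assign_sets,
    figure_categories,
    matched_cancer_sharedness_test,
    upset_summary,
)
from conftest import make_store, random_small_store

TAX = SraTaxonomy(
    groups={
        "sra_adult1": "adult",
        "sra_dev1": "developmental",
        "placenta": "developmental",
        "sra_stem1": "stem",
    },
    placenta_category="placenta",
)

SAMPLES = [
    ("t1", "tum_a", "tumor"),
    ("t2", "tum_a", "tumor"),
    ("a1", "sra_adult1", "sra_adult"),
    ("a2", "sra_adult1", "sra_adult"),
    ("d1", "sra_dev1", "sra_developmental"),
    ("p1", "placenta", "sra_placenta"),
    ("st1", "sra_stem1", "sra_stem"),
    ("st2", "sra_stem1", "sra_stem"),
    ("c1", "sra_can_a", "sra_cancer"),
]
MATCH = {"tum_a": ()}


def _assign(rows, rule="default"):
    store = make_store(rows, SAMPLES)
    stages = assign_novelty_stages(store, MATCH)
    return store, assign_sets(
        store, stages, TAX, rule=rule, sra_cancer_match_map={"tum_a": "sra_can_a"}
    )


def base(start):
    return [("chrS", start, start + 5, "+", "t1", 1), ("chrS", start, start + 5, "+", "t2", 1)]


def test_tumor_only_junction_is_unexplained():
    _, asg = _assign(base(10))
    row = asg.iloc[0]
    assert row.unexplained and row.combination == "unexplained"


def test_single_adult_read_explains_under_default_rule():
    """One read in one SRA adult sample is enough by default (the EGFRvIII
    'adult non-cancer' behavior)."""
    _, asg = _assign(base(10) + [("chrS", 10, 15, "+", "a1", 1)])
    row = asg.iloc[0]
    assert row.in_sra_adult and not row.unexplained


def test_placenta_only_is_not_developmental():
    _, asg = _assign(base(10) + [("chrS", 10, 15, "+", "p1", 1)])
    row = asg.iloc[0]
    assert row.in_sra_placenta and not row.in_sra_developmental
    assert not row.unexplained  # placenta evidence still explains


def test_two_sample_rule_examples():
    # one adult sample: flagged by default, not under the two-sample rule
    _, strict = _assign(base(10) + [("chrS", 10, 15, "+", "a1", 1)], rule="two_sample")
    assert not strict.iloc[0].in_sra_adult and strict.iloc[0].unexplained

    # 1 fetal-like + 1 placenta sample: two across the developmental group,
    # so both the developmental subset and placenta flags hold
    _, dev = _assign(
        base(20) + [("chrS", 20, 25, "+", "d1", 1), ("chrS", 20, 25, "+", "p1", 1)],
        rule="two_sample",
    )
    assert dev.iloc[0].in_sra_developmental and dev.iloc[0].in_sra_placenta

    # 2 samples of one stem category meet the threshold within one category
    _, stem = _assign(
        base(30) + [("chrS", 30, 35, "+", "st1", 1), ("chrS", 30, 35, "+", "st2", 1)],
        rule="two_sample",
    )
    assert stem.iloc[0].in_sra_stem


def test_two_sample_rule_is_strictly_more_conservative(small_world):
    """Flags under the two-sample rule are subsets of the default rule's,
    so the unexplained set can only grow."""
    store, cfg = small_world["store"], small_world["cfg"]
    tax = SraTaxonomy(cfg.sra_category_groups)
    stages = assign_novelty_stages(store, cfg.match_map())
    default = assign_sets(store, stages, tax).set_index(["cohort", "junction_id"])
    strict = apply_two_sample_rule(store, stages, tax).set_index(["cohort", "junction_id"])
    for col in ("in_sra_adult", "in_sra_developmental", "in_sra_placenta", "in_sra_stem"):
        assert not (strict[col] & ~default[col]).any()
    assert (default.unexplained <= strict.unexplained).all() or (
        set(default.index[default.unexplained]) <= set(strict.index[strict.unexplained])
    )


def test_upset_summary_partition_and_empty_cohort():
    _, asg = _assign(base(10) + base(20))
    summary = upset_summary(asg, "tum_a")
    combos = summary[summary.kind == "combination"]
    assert combos.percent.sum() == pytest.approx(100.0)
    assert combos.label.tolist() == ["unexplained"] and combos.percent.iloc[0] == 100.0
    empty = upset_summary(asg, "tum_ghost")
    assert empty.empty


def test_exclusive_combination_totals_conserve(small_world):
    store, cfg = small_world["store"], small_world["cfg"]
    tax = SraTaxonomy(cfg.sra_category_groups)
    stages = assign_novelty_stages(store, cfg.match_map())
    asg = assign_sets(store, stages, tax)
    for cohort in store.tumor_cohorts():
        sub = asg[asg.cohort == cohort]
        if sub.empty:
            continue
        summary = upset_summary(asg, cohort)
        combos = summary[summary.kind == "combination"]
        assert combos["count"].sum() == len(sub)
        assert combos.percent.sum() == pytest.approx(100.0)


def test_brute_force_set_oracle_randomized():
    from oracles import brute_force_sets

    taxonomy = SraTaxonomy(
        groups={
            "sra_adult1": "adult",
            "sra_dev1": "developmental",
            "placenta": "developmental",
            "sra_stem1": "stem",
        }
    )
    rng = np.random.default_rng(7)
    for _ in range(10):
        store, match_map = random_small_store(rng)
        stages = assign_novelty_stages(store, match_map)
        pairs = list(
            stage_at_least(stages, "2+")[["cohort", "junction_id"]].itertuples(
                index=False, name=None
            )
        )
        for rule in ("default", "two_sample"):
            expected = brute_force_sets(store, pairs, taxonomy, rule)
            got = assign_sets(store, stages, taxonomy, rule=rule)
            for _, r in got.iterrows():
                assert expected[(r.cohort, r.junction_id)] == (
                    r.in_sra_adult, r.in_sra_developmental, r.in_sra_placenta,
                    r.in_sra_stem, r.unexplained,
                )


def test_matched_cancer_sharedness_test_paths():
    # planted: SRA-cancer-present junctions recur more in the tumor cohort
    rows = []
    for j, (n_tumor, in_sra_cancer) in enumerate(
        [(2, True), (2, True), (1, False), (1, False)]
    ):
        start = 10 * (j + 1)
        for i in range(n_tumor):
            rows.append(("chrS", start, start + 5, "+", f"t{i+1}", 2))
        if in_sra_cancer:
            rows.append(("chrS", start, start + 5, "+", "c1", 1))
    store = make_store(rows, SAMPLES)
    stages = assign_novelty_stages(store, MATCH)
    asg = assign_sets(store, stages, TAX, sra_cancer_match_map={"tum_a": "sra_can_a"})
    res = matched_cancer_sharedness_test(store, stages, asg, "tum_a")
    assert res is not None and res.H > 0

    # no declared match -> skipped with notice, not an error
    asg_nomatch = assign_sets(store, stages, TAX, sra_cancer_match_map=None)
    assert matched_cancer_sharedness_test(store, stages, asg_nomatch, "tum_a") is None


def test_figure_categories_precedence():
    rows = base(10) + [
        ("chrS", 10, 15, "+", "a1", 1),
        ("chrS", 10, 15, "+", "d1", 1),  # adult takes precedence over dev
    ]
    store, asg = _assign(rows)
    stages = assign_novelty_stages(store, MATCH)
    cats = figure_categories(stages, asg)
    assert cats.category.iloc[0] == "adult"
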