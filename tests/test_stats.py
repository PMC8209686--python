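"""Burden, regression, stratified ANOVA, Fisher and Kaplan-Meier checks."""

import numpy as np
import pandas as pd
import pytest

from juncnovo.simulate import MutationEffect, SimConfig, generate_clinical_tables
from juncnovo.stats import (
    SQTL_FIVE_GENES,
    bh_adjust,
    classify_mutation_strata,
    cohort_fisher_tests,
    fisher_sharedness_test,
    junction_burden,
    km_survival,
    regress_burden_vs_tmb,
    stratify_and_test_counts,
)


@pytest.mark.parametrize(
    "n, reads, expected",
    [(100, 1_000_000, 1.0), (0, 5_000_000, 0.0), (37, 2_500_000, 0.148)],
)
def test_junction_burden_formula(n, reads, expected):
    assert junction_burden(n, reads) == pytest.approx(expected)


def test_burden_scaling_and_errors():
    assert junction_burden(80, 2_000_000) == junction_burden(80, 1_000_000) / 2
    with pytest.raises(ValueError):
        junction_burden(10, 0)


def test_regression_exact_line_and_degenerate():
    df = pd.DataFrame(dict(tmb=[1.0, 2.0, 3.0, 4.0]))
    df["burden"] = 2 * df.tmb + 1
    fit = regress_burden_vs_tmb(df)
    assert (fit.slope, fit.intercept, fit.r) == pytest.approx((2.0, 1.0, 1.0))
    flat = regress_burden_vs_tmb(pd.DataFrame(dict(tmb=[1.0] * 5, burden=[1, 2, 3, 4, 5])))
    assert flat.degenerate
    with pytest.raises(ValueError):
        regress_burden_vs_tmb(df.head(2))


def test_fisher_examples_and_symmetry():
    assert fisher_sharedness_test(5, 10, 10, 20).p == pytest.approx(1.0)
    res = fisher_sharedness_test(2, 2, 2, 4)  # table [[2,0],[0,2]]
    assert res.p == pytest.approx(1 / 3)
    # transposing the 2x2 leaves p unchanged: swap roles of the margins
    res_t = fisher_sharedness_test(2, 2, 2, 4)
    assert res.p == res_t.p
    degen = fisher_sharedness_test(0, 0, 0, 10)  # zero margin
    assert degen.degenerate and degen.p == 1.0


def test_fisher_matches_enumeration_sampled_tables():
    """Implementation equals the hypergeometric enumeration oracle on a
    random sample of small tables (the full <=40 sweep runs in the
    acceptance suite)."""
    from oracles import fisher_exact_enumeration_p

    rng = np.random.default_rng(11)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        got = fisher_sharedness_test(a, a + b, a + c, a + b + c + d).p
        assert got == pytest.approx(fisher_exact_enumeration_p([[a, b], [c, d]]), rel=1e-6)


def test_bh_monotone_and_capped():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=50)
    adj = bh_adjust(p)
    assert (adj <= 1.0 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_classify_strata_nonsynonymous_only():
    muts = pd.DataFrame(
        [
            ("p1", "SF3B1", "Missense_Mutation"),
            ("p2", "SF3B1", "Silent"),  # synonymous: must not count
            ("p3", "TTN", "Missense_Mutation"),  # not in the five-gene set
        ],
        columns=["patient_id", "gene", "variant_class"],
    )
    strata = classify_mutation_strata(muts, "sqtl_five_gene", patients=["p1", "p2", "p3"])
    assert dict(zip(strata.patient_id, strata.mutated)) == {
        "p1": True, "p2": False, "p3": False,
    }
    assert SQTL_FIVE_GENES == {"U2AF1", "SF3B1", "TADA1", "PPP2R1A", "IDH1"}
    with pytest.raises(ValueError):
        classify_mutation_strata(muts, "uniprot_splicing")  # needs a gene set


def test_anova_detects_planted_shift_and_identical_groups():
    from juncnovo.simulate import simulate_stratified_counts

    shifted = simulate_stratified_counts(50, 3, shift=50.0, seed=1)
    res = stratify_and_test_counts(shifted)
    assert res.anova.loc["C(mutated)", "PR(>F)"] < 1e-6
    assert res.per_cohort.significant.all()

    flat = simulate_stratified_counts(20, 2, shift=0.0, seed=2)
    flat["count"] = 100.0  # identical groups
    res_flat = stratify_and_test_counts(flat)
    assert (res_flat.per_cohort.p_adj <= 1.0).all()
    assert (res_flat.per_cohort.p_adj == 1.0).all()


def test_cohort_fisher_requires_two_patients():
    occ = pd.DataFrame(
        dict(junction_id=[1, 1, 2], patient_id=["p1", "p2", "p1"])
    )
    strata = pd.DataFrame(
        dict(patient_id=["p1", "p2", "p3", "p4"], mutated=[True, False, False, True])
    )
    out = cohort_fisher_tests(occ, strata)
    assert set(out.junction_id) == {1}  # junction 2 seen in a single patient


def test_km_hand_fixture():
    """death t=1; censored t=2; death t=3; alive past 3 ->
    S(1)=3/4, S(3)=3/4 * 1/2 = 0.375."""
    surv = pd.DataFrame(
        dict(
            patient_id=["a", "b", "c", "d"],
            days_to_death=[1.0, np.nan, 3.0, np.nan],
            days_to_last_followup=[1.0, 2.0, 3.0, 4.0],
        )
    )
    curve = km_survival(surv)["all"]["curve"].set_index("t").S
    assert curve.loc[1.0] == pytest.approx(0.75)
    assert curve.loc[3.0] == pytest.approx(0.375)
    assert (curve.diff().dropna() <= 1e-12).all()  # monotone non-increasing


def test_km_matches_hand_product_limit_on_random_fixture():
    from oracles import hand_km

    rng = np.random.default_rng(5)
    t = rng.integers(1, 20, size=10).astype(float)
    dead = rng.random(10) < 0.6
    surv = pd.DataFrame(
        dict(
            patient_id=[f"p{i}" for i in range(10)],
            days_to_death=np.where(dead, t, np.nan),
            days_to_last_followup=t,
        )
    )
    curve = km_survival(surv)["all"]["curve"].set_index("t").S
    for tt, s in hand_km(t, dead).items():
        assert curve.loc[tt] == pytest.approx(s)


def test_km_no_events_and_exclusions(caplog):
    surv = pd.DataFrame(
        dict(
            patient_id=["a", "b", "c"],
            days_to_death=[np.nan, np.nan, np.nan],
            days_to_last_followup=[5.0, 10.0, np.nan],  # c has no data at all
        )
    )
    with caplog.at_level("WARNING"):
        out = km_survival(surv)
    assert "excluding 1 patients" in caplog.text
    assert (out["all"]["curve"].S == 1.0).all()  # no deaths: flat at 1


def test_simulated_no_event_survival_is_flat():
    cfg = SimConfig(seed=4, n_junctions=20, n_genes=10)
    _, _, surv, _ = generate_clinical_tables(
        cfg, MutationEffect(baseline_event_rate=0.0)
    )
    curve = km_survival(surv)["all"]["curve"]
    assert (curve.S == 1.0).all()
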