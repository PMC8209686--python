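"""Cohort-level statistics: junction burden vs TMB, splicing-factor
mutation stratification, Fisher sharedness tests and Kaplan-Meier survival.

Junction burden for a patient is the count of their stage-2+ junctions
(junctions not found in any core normal) divided by (mapped reads / 10 000)
— a per-Mb scaling under the 100-bp-read assumption. TMB is silent plus
non-silent mutations per Mb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Genes previously identified as sQTL-associated, used for the five-gene
#: stratification criterion.
SQTL_FIVE_GENES = frozenset({"U2AF1", "SF3B1", "TADA1", "PPP2R1A", "IDH1"})

#: Variant classes counted as non-synonymous (MAF-style labels).
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
        "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
        "Splice_Site", "Translation_Start_Site",
    }
)


def junction_burden(n_junctions: int, mapped_reads: int) -> float:
    """Stage-2+ junction count scaled by mapped reads / 10 000."""
    if mapped_reads <= 0:
        raise ValueError(f"mapped_reads must be positive, got {mapped_reads}")
    if n_junctions < 0:
        raise ValueError("n_junctions must be >= 0")
    return n_junctions / (mapped_reads / 10_000)


def total_tmb(tmb: pd.DataFrame) -> pd.Series:
    """Silent plus non-silent mutations per Mb, indexed by patient."""
    return (tmb.silent_per_mb + tmb.nonsilent_per_mb).set_axis(tmb.patient_id)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    degenerate: bool = False


def regress_burden_vs_tmb(records: pd.DataFrame) -> RegressionResult:
    """OLS of junction burden on TMB across tumor samples.

    ``records`` needs columns ``burden`` and ``tmb``. A constant-TMB input
    is degenerate and flagged rather than raised.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for the regression")
    x, y = records.tmb.to_numpy(float), records.burden.to_numpy(float)
    if np.all(x == x[0]):
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, degenerate=True)
    fit = sps.linregress(x, y)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue)
    )


def classify_mutation_strata(
    mutations: pd.DataFrame,
    criterion: str,
    patients: list[str] | None = None,
    splicing_genes: set[str] | None = None,
    sqtl_genes: frozenset[str] = SQTL_FIVE_GENES,
) -> pd.DataFrame:
    """Per-patient mutated flag under one stratification criterion.

    ``criterion`` is ``"sqtl_five_gene"`` (the fixed five-gene set, override
    via ``sqtl_genes``) or ``"uniprot_splicing"`` (requires
    ``splicing_genes``, e.g. a UniProt keyword export). Only non-synonymous
    variant classes count.
    """
    if criterion == "sqtl_five_gene":
        gene_set = set(sqtl_genes)
    elif criterion == "uniprot_splicing":
        if splicing_genes is None:
            raise ValueError("uniprot_splicing criterion requires a splicing gene set")
        gene_set = set(splicing_genes)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    hits = mutations[
        mutations.gene.isin(gene_set)
        & mutations.variant_class.isin(NONSYNONYMOUS_CLASSES)
    ]
    mutated = set(hits.patient_id)
    if patients is None:
        patients = sorted(set(mutations.patient_id))
    return pd.DataFrame(
        dict(patient_id=patients, criterion=criterion, mutated=[p in mutated for p in patients])
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(list(pvals), float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


@dataclass
class StratifiedTestResult:
    anova: pd.DataFrame  # two-way ANOVA table (cohort, mutation status, interaction)
    per_cohort: pd.DataFrame  # cohort, n_mutated, n_wild, p_raw, p_adj


def stratify_and_test_counts(
    counts: pd.DataFrame, alpha: float = 0.05
) -> StratifiedTestResult:
    """Two-way ANOVA of per-patient stage-2+ junction counts.

    ``counts`` needs columns ``cohort`` (cancer type), ``mutated`` (bool)
    and ``count``. Factors are cancer type and mutation status plus their
    interaction (the interaction is reported but non-normative). Per-cohort
    mutated-vs-wild comparisons (Welch t-tests) are BH-corrected within the
    criterion's family. Factor levels with zero patients are dropped with a
    warning.
    """
    counts = counts.copy()
    sizes = counts.groupby("cohort").mutated.agg(["sum", "count"])
    drop = sizes.index[(sizes["sum"] == 0) | (sizes["sum"] == sizes["count"])]
    if len(drop):
        logger.warning("dropping cohorts with an empty stratum: %s", list(drop))
        counts = counts[~counts.cohort.isin(drop)]
    if counts.cohort.nunique() < 2 or counts.mutated.nunique() < 2:
        raise ValueError("need >= 2 cohorts and both mutation strata")

    model = ols("count ~ C(cohort) * C(mutated)", data=counts).fit()
    table = anova_lm(model, typ=2)

    rows = []
    for cohort, sub in counts.groupby("cohort"):
        mut = sub.loc[sub.mutated, "count"].to_numpy(float)
        wild = sub.loc[~sub.mutated, "count"].to_numpy(float)
        if np.all(np.concatenate([mut, wild]) == mut[0]):
            p = 1.0  # identical groups: no evidence of a difference
        else:
            p = float(sps.ttest_ind(mut, wild, equal_var=False).pvalue)
        rows.append((cohort, len(mut), len(wild), p))
    per_cohort = pd.DataFrame(rows, columns=["cohort", "n_mutated", "n_wild", "p_raw"])
    per_cohort["p_adj"] = bh_adjust(per_cohort.p_raw)
    per_cohort["significant"] = per_cohort.p_adj < alpha
    return StratifiedTestResult(anova=table, per_cohort=per_cohort)


@dataclass
class FisherResult:
    odds_ratio: float
    p: float
    degenerate: bool = False


def fisher_sharedness_test(
    in_mutated: int, mutated_size: int, total: int, cohort_size: int
) -> FisherResult:
    """Two-sided Fisher's exact test of junction occurrence vs mutation status.

    The 2x2 table is (junction-positive / negative) x (mutated /
    non-mutated) patients. A zero margin yields p = 1 with an undefined
    odds ratio, flagged rather than raised.
    """
    in_wild = total - in_mutated
    wild_size = cohort_size - mutated_size
    if min(in_mutated, in_wild) < 0 or in_mutated > mutated_size or in_wild > wild_size:
        raise ValueError("inconsistent 2x2 counts")
    table = np.array(
        [[in_mutated, mutated_size - in_mutated], [in_wild, wild_size - in_wild]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return FisherResult(np.nan, 1.0, degenerate=True)
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return FisherResult(float(odds), float(p))


def cohort_fisher_tests(
    occurrence: pd.DataFrame, strata: pd.DataFrame, min_patients: int = 2
) -> pd.DataFrame:
    """Fisher sharedness tests for every junction seen in >= 2 patients.

    ``occurrence`` has one row per (junction_id, patient_id) presence pair
    within one cohort; ``strata`` maps patient_id -> mutated. Multi-sample
    patients must already be collapsed to one patient row. BH correction is
    applied across the cohort's junctions.
    """
    mutated = set(strata.loc[strata.mutated, "patient_id"])
    cohort_patients = set(strata.patient_id)
    cohort_size, mutated_size = len(cohort_patients), len(mutated)
    rows = []
    for jid, sub in occurrence.groupby("junction_id"):
        pats = set(sub.patient_id) & cohort_patients
        if len(pats) < min_patients:
            continue
        res = fisher_sharedness_test(
            len(pats & mutated), mutated_size, len(pats), cohort_size
        )
        rows.append((jid, len(pats), len(pats & mutated), res.odds_ratio, res.p, res.degenerate))
    out = pd.DataFrame(
        rows, columns=["junction_id", "n_patients", "n_mutated", "odds_ratio", "p", "degenerate"]
    )
    if len(out):
        out["p_adj"] = bh_adjust(out.p)
    return out


def patient_burden_table(
    store, retained: set[int], core_present: set[int], tmb: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-tumor-sample stage-2+ junction counts, burden, and optional TMB.

    Counts junctions that pass the global read filter, occur in the sample,
    and are absent from all core normals; burden scales by the sample's
    mapped read count / 10 000.
    """
    tumor = store.samples[store.samples.cohort_class == "tumor"]
    ev = store.evidence[
        store.evidence.junction_id.isin(retained - core_present)
        & store.evidence.sample_id.isin(set(tumor.sample_id))
    ]
    n_junc = ev.groupby("sample_id").junction_id.nunique()
    out = tumor[["sample_id", "cohort", "mapped_read_count"]].copy()
    out["n_stage2_junctions"] = out.sample_id.map(n_junc).fillna(0).astype(int)
    out["burden"] = [
        junction_burden(n, int(r))
        for n, r in zip(out.n_stage2_junctions, out.mapped_read_count)
    ]
    if tmb is not None:
        out["tmb"] = out.sample_id.map(total_tmb(tmb))
    return out.reset_index(drop=True)


def km_survival(
    survival: pd.DataFrame, group_col: str | None = None
) -> dict[str, dict[str, pd.DataFrame]]:
    """Kaplan-Meier product-limit curves, optionally per group.

    Each patient needs ``days_to_death`` (event) or
    ``days_to_last_followup`` (right-censoring time for dropouts with no
    death date); patients with neither are excluded with a warning. Returns
    ``{group: {"curve": ..., "events": ...}}``; the curve frame has columns
    ``t`` and ``S`` (monotone non-increasing from 1.0).
    """
    df = survival.copy()
    death = pd.to_numeric(df.get("days_to_death"), errors="coerce")
    follow = pd.to_numeric(df.get("days_to_last_followup"), errors="coerce")
    has_any = death.notna() | follow.notna()
    if (~has_any).any():
        logger.warning(
            "excluding %d patients with neither days-to-death nor follow-up",
            int((~has_any).sum()),
        )
        df, death, follow = df[has_any], death[has_any], follow[has_any]
    event = death.notna()
    duration = death.where(event, follow)

    out: dict[str, dict[str, pd.DataFrame]] = {}
    groups = (
        {str(g): df.index[df[group_col] == g] for g in df[group_col].unique()}
        if group_col
        else {"all": df.index}
    )
    for label, idx in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(duration.loc[idx], event_observed=event.loc[idx].astype(int))
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["t", "S"]
        out[label] = {"curve": curve, "events": kmf.event_table.reset_index()}
    return out
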