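"""Junction prevalence and sharedness within and across cancer cohorts.

"Prevalence" of a junction in a cohort is the fraction of the cohort's
samples with at least one supporting read; "sharedness" is the positive
sample count itself. A junction found in multiple cancer types contributes
one data point per cohort. Cross-cancer-type summaries are unweighted means
over cohorts (macro averaging).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .novelty import stage_at_least
from .store import JunctionStore


def cohort_prevalence(
    store: JunctionStore,
    cohort: str,
    junction_ids: set[int] | None = None,
) -> pd.DataFrame:
    """Per-junction positive-sample counts and prevalence within one cohort.

    Returns columns ``junction_id cohort n_positive cohort_size prevalence``
    for every junction with evidence in the cohort (restricted to
    ``junction_ids`` when given).
    """
    samples = store.samples_in_cohorts([cohort])
    if not samples:
        raise ValueError(f"cohort {cohort!r} is empty")
    ev = store.evidence[store.evidence.sample_id.isin(samples)]
    if junction_ids is not None:
        ev = ev[ev.junction_id.isin(junction_ids)]
    n_pos = ev.groupby("junction_id").sample_id.nunique()
    if junction_ids is not None:
        n_pos = n_pos.reindex(sorted(junction_ids), fill_value=0)
    out = n_pos.rename("n_positive").reset_index()
    out.insert(1, "cohort", cohort)
    out["cohort_size"] = len(samples)
    out["prevalence"] = out.n_positive / out.cohort_size
    return out


def all_cohort_prevalences(
    store: JunctionStore, cohorts: Sequence[str] | None = None
) -> pd.DataFrame:
    cohorts = list(cohorts) if cohorts is not None else store.tumor_cohorts()
    return pd.concat(
        [cohort_prevalence(store, c) for c in cohorts], ignore_index=True
    )


def select_shared_panel(
    store: JunctionStore,
    stages: pd.DataFrame,
    cohort: str,
    min_prevalence: float = 0.01,
    cap: int = 200,
) -> pd.DataFrame:
    """The cohort's shared-junction panel.

    Up to ``cap`` most highly recurring junctions with prevalence >=
    ``min_prevalence`` (boundary inclusive) and novelty stage >= 2+ in this
    cohort. Ordering (and the truncation tie-break) is by descending
    positive-sample count, then ascending chromosome, start, end.
    """
    stage2 = stage_at_least(stages[stages.cohort == cohort], "2+")
    prev = cohort_prevalence(store, cohort, set(stage2.junction_id))
    prev = prev[prev.prevalence >= min_prevalence - 1e-12]
    prev = prev.merge(store.junctions[["junction_id", "chrom", "start", "end", "strand"]])
    prev = prev.sort_values(
        ["n_positive", "chrom", "start", "end"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)
    return prev.head(cap)


def cross_cohort_sharing(
    store: JunctionStore,
    prevalences: pd.DataFrame,
    threshold: float = 0.05,
    min_cohorts: int = 2,
) -> tuple[int, pd.DataFrame]:
    """Junctions at >= ``threshold`` prevalence in >= ``min_cohorts`` cohorts.

    Both comparisons are inclusive. Returns the count and a per-junction
    table of the qualifying cohorts.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    hits = prevalences[prevalences.prevalence >= threshold - 1e-12]
    per_junction = (
        hits.groupby("junction_id")
        .cohort.agg(lambda c: sorted(c))
        .rename("cohorts")
        .reset_index()
    )
    per_junction["n_cohorts"] = per_junction.cohorts.str.len()
    qualifying = per_junction[per_junction.n_cohorts >= min_cohorts].reset_index(drop=True)
    return len(qualifying), qualifying


def singleton_fraction(store: JunctionStore, stage2_junctions: set[int]) -> float | None:
    """Fraction of stage-2+ junctions confined to a single tumor sample.

    The positive-sample count is over ALL tumor samples of all cohorts.
    Returns None for an empty input set (undefined).
    """
    if not stage2_junctions:
        return None
    tumor_samples = store.samples_in_classes(["tumor"])
    ev = store.evidence[
        store.evidence.junction_id.isin(stage2_junctions)
        & store.evidence.sample_id.isin(tumor_samples)
    ]
    n_pos = ev.groupby("junction_id").sample_id.nunique()
    n_pos = n_pos.reindex(sorted(stage2_junctions), fill_value=0)
    return float((n_pos == 1).mean())


def build_prevalence_matrix(
    store: JunctionStore,
    panels: Sequence[pd.DataFrame],
    cohorts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Junction x cohort prevalence matrix over the union of panel members.

    Rows are the deduplicated union of panel junctions (sorted by genomic
    coordinates), columns the cohorts; a junction absent from a cohort gets
    prevalence 0.0.
    """
    members = sorted(set().union(*[set(p.junction_id) for p in panels])) if panels else []
    if not members:
        raise ValueError("union of panel junctions is empty")
    cohorts = list(cohorts) if cohorts is not None else store.tumor_cohorts()
    cols = {}
    for cohort in cohorts:
        prev = cohort_prevalence(store, cohort, set(members)).set_index("junction_id")
        cols[cohort] = prev.prevalence.reindex(members, fill_value=0.0)
    coords = store.junctions.set_index("junction_id").loc[members]
    order = coords.sort_values(["chrom", "start", "end", "strand"]).index
    return pd.DataFrame(cols, index=members).loc[order]


class KruskalResult(NamedTuple):
    H: float
    p: float
    degenerate: bool = False


def compare_prevalence_distributions(
    group_a: Sequence[float], group_b: Sequence[float]
) -> KruskalResult:
    """Kruskal-Wallis H-test between two sharedness/prevalence samples.

    Rank-based H with tie correction; p from the chi-squared approximation
    (1 df for two groups). If every value in both groups is identical the
    test is degenerate: H = 0, p = 1, flagged.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0, degenerate=True)
    h, p = stats.kruskal(a, b)
    return KruskalResult(float(h), float(p), degenerate=False)
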