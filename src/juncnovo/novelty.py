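"""The hierarchical cancer-specificity (novelty) filter.

Stages, from most to least permissive:

* ``0``  — all junctions of a cancer cohort;
* ``1+`` — not found in that cohort's tissue-matched GTEx/TCGA normals;
* ``2+`` — not found in ANY core normal (all GTEx + all TCGA matched
  normals, across every cancer type);
* ``3+`` — additionally not found in any selected SRA non-cancer sample.

Exclusion is strict by default: a single read in a single sample of the
exclusion set removes the junction from the stage. A global evidence filter
(total reads >= 2 across all cohorts) is applied first to drop one-read
artifacts; there is no per-sample minimum.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .store import (
    CORE_NORMAL_CLASSES,
    SRA_NONCANCER_CLASSES,
    JunctionStore,
)

STAGES = ("0", "1+", "2+", "3+")
STAGE_RANK = {s: i for i, s in enumerate(STAGES)}


def load_tissue_match_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a cancer-cohort -> tissue-matched-normal-cohorts YAML map."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    return {str(c): tuple(v or ()) for c, v in raw.items()}


def validate_match_map(
    match_map: dict[str, tuple[str, ...]], store: JunctionStore
) -> None:
    declared = set(store.samples.cohort)
    for cohort, tissues in match_map.items():
        missing = set(tissues) - declared
        if missing:
            raise ValueError(f"match map for {cohort!r} references unknown cohorts {sorted(missing)}")


def apply_global_read_filter(store: JunctionStore, min_total_reads: int = 2) -> set[int]:
    """Junction IDs whose total read count over ALL samples meets the floor."""
    if min_total_reads < 1:
        raise ValueError("min_total_reads must be >= 1")
    totals = store.evidence.groupby("junction_id").reads.sum()
    return set(totals.index[totals >= min_total_reads])


def cohort_presence(store: JunctionStore, junction_id: int, cohorts: set[str] | list[str]) -> bool:
    """True iff the junction has >= 1 read in >= 1 sample of the cohort set."""
    if not cohorts:
        raise ValueError("cohort set must be nonempty")
    samples = store.samples_in_cohorts(cohorts)
    ev = store.evidence
    return bool(
        ((ev.junction_id == junction_id) & (ev.sample_id.isin(samples))).any()
    )


def _present_junctions(ev: pd.DataFrame, samples: set[str], min_reads: int = 1) -> set[int]:
    sub = ev[ev.sample_id.isin(samples)]
    if min_reads > 1:
        sub = sub[sub.reads >= min_reads]
    return set(sub.junction_id)


def core_normal_present(
    store: JunctionStore,
    retained: set[int] | None = None,
    normal_read_threshold: int = 1,
) -> set[int]:
    """Junction IDs with evidence in any core-normal sample (all GTEx plus
    all TCGA matched normals, across every cancer type)."""
    ev = store.evidence
    if retained is not None:
        ev = ev[ev.junction_id.isin(retained)]
    return _present_junctions(
        ev, store.samples_in_classes(CORE_NORMAL_CLASSES), normal_read_threshold
    )


def assign_novelty_stages(
    store: JunctionStore,
    match_map: dict[str, tuple[str, ...]],
    retained: set[int] | None = None,
    min_total_reads: int = 2,
    normal_read_threshold: int = 1,
) -> pd.DataFrame:
    """Stage every (cancer cohort, junction) pair through the hierarchy.

    Parameters
    ----------
    match_map
        Cancer cohort -> tuple of tissue-matched normal cohorts. Cohorts
        with an empty tuple have no tissue-matched normals: their stage-1+
        comparison is not evaluable and junctions are classed 0 vs 2+
        directly (``tm_evaluable`` False in the output).
    retained
        Junction IDs passing the global read filter; computed from
        ``min_total_reads`` when omitted.
    normal_read_threshold
        Per-sample read count for a junction to count as "in" an exclusion
        set. Default 1 = the strict single-read exclusion.

    Returns
    -------
    DataFrame with one row per (cohort, junction present in that cohort):
    ``cohort junction_id stage in_tissue_matched in_core_normal
    in_sra_noncancer tm_evaluable``.
    """
    validate_match_map(match_map, store)
    if retained is None:
        retained = apply_global_read_filter(store, min_total_reads)
    ev = store.evidence[store.evidence.junction_id.isin(retained)]

    core_samples = store.samples_in_classes(CORE_NORMAL_CLASSES)
    sra_samples = store.samples_in_classes(SRA_NONCANCER_CLASSES)
    in_core = _present_junctions(ev, core_samples, normal_read_threshold)
    in_sra = _present_junctions(ev, sra_samples, normal_read_threshold)

    frames = []
    for cohort in store.tumor_cohorts():
        tumor_samples = store.samples_in_cohorts([cohort])
        cohort_junctions = sorted(_present_junctions(ev, tumor_samples))
        if not cohort_junctions:
            continue
        tissues = match_map.get(cohort, ())
        evaluable = len(tissues) > 0
        in_tm = (
            _present_junctions(
                ev, store.samples_in_cohorts(list(tissues)), normal_read_threshold
            )
            if evaluable
            else set()
        )
        rows = []
        for j in cohort_junctions:
            tm, core, sra = j in in_tm, j in in_core, j in in_sra
            if evaluable and tm:
                stage = "0"
            elif core:
                stage = "0" if not evaluable else "1+"
            elif sra:
                stage = "2+"
            else:
                stage = "3+"
            rows.append((cohort, j, stage, tm, core, sra, evaluable))
        frames.append(
            pd.DataFrame(
                rows,
                columns=[
                    "cohort", "junction_id", "stage", "in_tissue_matched",
                    "in_core_normal", "in_sra_noncancer", "tm_evaluable",
                ],
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "cohort", "junction_id", "stage", "in_tissue_matched",
                "in_core_normal", "in_sra_noncancer", "tm_evaluable",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def assign_novelty_stage(
    store: JunctionStore,
    junction_id: int,
    cohort: str,
    match_map: dict[str, tuple[str, ...]],
) -> str:
    """Stage of a single junction within one cancer cohort."""
    table = assign_novelty_stages(store, match_map)
    hit = table[(table.cohort == cohort) & (table.junction_id == junction_id)]
    if hit.empty:
        raise ValueError(
            f"junction {junction_id} not present in cohort {cohort!r} "
            "(or removed by the global read filter)"
        )
    return str(hit.iloc[0].stage)


def stage_at_least(stages: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Rows at or above a stage in the hierarchy (nested decreasing sets)."""
    rank = STAGE_RANK[stage]
    return stages[stages.stage.map(STAGE_RANK) >= rank]
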