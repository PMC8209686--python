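"""SRA set assignment of stage-2+ junctions and the unexplained class.

Every junction absent from all core normals is tested for presence in SRA
non-cancer categories, grouped into adult / developmental / stem, with
placenta tracked as its own flag outside the developmental set (a junction
seen only in placenta is "explained" but not "developmental"). A junction in
none of the four sets is *unexplained*. Matched SRA cancer evidence never
affects unexplained status — it is cancer, not normal — and feeds only the
sharedness replication test.

Two membership rules:

* default — one read in one sample of a category suffices;
* two-sample — at least two positive samples across the broad group, with a
  one-sample exception for developmental subset categories once the
  group-wide criterion is met.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .novelty import stage_at_least
from .sharedness import KruskalResult, cohort_prevalence, compare_prevalence_distributions
from .store import SRA_NONCANCER_CLASSES, JunctionStore

logger = logging.getLogger(__name__)

BROAD_GROUPS = ("adult", "developmental", "stem")
FLAG_COLS = ["in_sra_adult", "in_sra_developmental", "in_sra_placenta", "in_sra_stem"]


@dataclass
class SraTaxonomy:
    """Category -> broad group map, with the placenta category singled out."""

    groups: dict[str, str]
    placenta_category: str = "placenta"

    def __post_init__(self) -> None:
        bad = {c: g for c, g in self.groups.items() if g not in BROAD_GROUPS}
        if bad:
            raise ValueError(f"unknown broad groups: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SraTaxonomy":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            groups=dict(raw["categories"]),
            placenta_category=raw.get("placenta_category", "placenta"),
        )


def _category_sample_counts(store: JunctionStore, junction_ids: set[int]) -> pd.DataFrame:
    """Positive-sample counts per (junction, SRA non-cancer category)."""
    sra_samples = store.samples[store.samples.cohort_class.isin(SRA_NONCANCER_CLASSES)]
    missing = sra_samples.cohort.isna() | (sra_samples.cohort == "")
    if missing.any():
        raise ValueError(
            f"{int(missing.sum())} SRA samples lack a category label"
        )
    ev = store.evidence[store.evidence.junction_id.isin(junction_ids)]
    ev = ev.merge(sra_samples[["sample_id", "cohort"]], on="sample_id")
    return (
        ev.groupby(["junction_id", "cohort"]).sample_id.nunique().rename("n_samples").reset_index()
    )


def assign_sets(
    store: JunctionStore,
    stages: pd.DataFrame,
    taxonomy: SraTaxonomy,
    rule: str = "default",
    sra_cancer_match_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Set membership for every (cohort, stage-2+ junction) pair.

    Returns one row per pair with per-group positive-sample counts, the
    four set flags under the chosen ``rule`` ("default" or "two_sample"),
    the matched-SRA-cancer flag/count where a match is declared, the derived
    ``unexplained`` flag and the exclusive ``combination`` label.
    """
    if rule not in ("default", "two_sample"):
        raise ValueError(f"unknown rule {rule!r}")
    stage2 = stage_at_least(stages, "2+")[["cohort", "junction_id"]].copy()
    if stage2.empty:
        return pd.DataFrame(
            columns=["cohort", "junction_id", *FLAG_COLS, "unexplained", "combination"]
        )
    counts = _category_sample_counts(store, set(stage2.junction_id))
    cat_group = taxonomy.groups
    placenta = taxonomy.placenta_category

    def agg_counts(jid: int) -> dict[str, int]:
        sub = counts[counts.junction_id == jid]
        out = dict(n_adult=0, n_dev=0, n_placenta=0, n_stem=0, n_dev_group=0)
        for cat, n in zip(sub.cohort, sub.n_samples):
            group = cat_group.get(cat)
            if group is None:
                continue
            if cat == placenta:
                out["n_placenta"] += n
                out["n_dev_group"] += n
            elif group == "developmental":
                out["n_dev"] += n
                out["n_dev_group"] += n
            elif group == "adult":
                out["n_adult"] += n
            elif group == "stem":
                out["n_stem"] += n
        return out

    count_cache = {jid: agg_counts(jid) for jid in stage2.junction_id.unique()}

    # matched SRA cancer positive-sample counts per (cohort, junction)
    cancer_counts: dict[tuple[str, int], int] = {}
    if sra_cancer_match_map:
        for cohort, cat in sra_cancer_match_map.items():
            cat_samples = set(
                store.samples.loc[
                    (store.samples.cohort == cat)
                    & (store.samples.cohort_class == "sra_cancer"),
                    "sample_id",
                ]
            )
            if not cat_samples:
                continue
            ev = store.evidence[store.evidence.sample_id.isin(cat_samples)]
            for jid, n in ev.groupby("junction_id").sample_id.nunique().items():
                cancer_counts[(cohort, int(jid))] = int(n)

    rows = []
    for cohort, jid in zip(stage2.cohort, stage2.junction_id):
        c = count_cache[jid]
        if rule == "default":
            adult = c["n_adult"] >= 1
            dev = c["n_dev"] >= 1
            plac = c["n_placenta"] >= 1
            stem = c["n_stem"] >= 1
        else:
            adult = c["n_adult"] >= 2
            stem = c["n_stem"] >= 2
            dev = c["n_dev"] >= 1 and c["n_dev_group"] >= 2
            plac = c["n_placenta"] >= 1 and c["n_dev_group"] >= 2
        unexplained = not (adult or dev or plac or stem)
        combo = (
            "unexplained"
            if unexplained
            else "+".join(
                name
                for name, flag in zip(
                    ("adult", "developmental", "placenta", "stem"),
                    (adult, dev, plac, stem),
                )
                if flag
            )
        )
        n_cancer = cancer_counts.get((cohort, int(jid)), 0)
        rows.append(
            (
                cohort, jid, adult, dev, plac, stem,
                c["n_adult"], c["n_dev"], c["n_placenta"], c["n_stem"],
                n_cancer, n_cancer >= 1, unexplained, combo,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cohort", "junction_id", *FLAG_COLS,
            "n_adult", "n_developmental", "n_placenta", "n_stem",
            "n_sra_cancer_matched", "in_sra_cancer_matched",
            "unexplained", "combination",
        ],
    )


def apply_two_sample_rule(
    store: JunctionStore,
    stages: pd.DataFrame,
    taxonomy: SraTaxonomy,
    sra_cancer_match_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Set assignment under the conservative two-sample membership rule."""
    return assign_sets(
        store, stages, taxonomy, rule="two_sample",
        sra_cancer_match_map=sra_cancer_match_map,
    )


def upset_summary(assignments: pd.DataFrame, cohort: str) -> pd.DataFrame:
    """Per-set and per-exclusive-combination counts for one cohort.

    Percents are of the cohort's stage-2+ junctions; exclusive combinations
    partition to 100%. Rows with ``kind == "set"`` are (overlapping)
    per-set marginals; ``kind == "combination"`` rows are exclusive.
    """
    sub = assignments[assignments.cohort == cohort]
    if sub.empty:
        logger.warning("cohort %r has no stage-2+ junctions: empty upset summary", cohort)
        return pd.DataFrame(columns=["cohort", "kind", "label", "count", "percent"])
    total = len(sub)
    rows = []
    for name, col in zip(
        ("adult", "developmental", "placenta", "stem", "unexplained"),
        (*FLAG_COLS, "unexplained"),
    ):
        n = int(sub[col].sum())
        rows.append((cohort, "set", name, n, 100.0 * n / total))
    combos = sub.combination.value_counts().sort_index()
    for label, n in combos.items():
        rows.append((cohort, "combination", label, int(n), 100.0 * n / total))
    return pd.DataFrame(rows, columns=["cohort", "kind", "label", "count", "percent"])


def figure_categories(stages: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Exclusive five-way category per (cohort, junction) for reporting.

    Core-normal (stage 0/1+), then adult > developmental > stem > placenta
    precedence among SRA sets, else unexplained. Used for the antisense-
    fraction-by-category summary.
    """
    base = stages[["cohort", "junction_id", "stage"]].copy()
    base = base.merge(
        assignments[["cohort", "junction_id", *FLAG_COLS, "unexplained"]],
        on=["cohort", "junction_id"], how="left",
    )
    def label(row) -> str:
        if row.stage in ("0", "1+"):
            return "core_normal"
        if row.get("in_sra_adult"):
            return "adult"
        if row.get("in_sra_developmental"):
            return "developmental"
        if row.get("in_sra_stem"):
            return "stem"
        if row.get("in_sra_placenta"):
            return "placenta"
        return "unexplained"
    base["category"] = base.apply(label, axis=1)
    return base[["cohort", "junction_id", "category"]]


def matched_cancer_sharedness_test(
    store: JunctionStore,
    stages: pd.DataFrame,
    assignments: pd.DataFrame,
    cohort: str,
) -> KruskalResult | None:
    """Kruskal-Wallis on tumor sharedness: SRA-cancer-present vs absent.

    Compares the TCGA positive-sample counts of the cohort's stage-2+
    junctions that are vs are not present in the matched SRA cancer
    category. Returns None (with a notice) when the cohort has no declared
    match or one of the groups is empty; a degenerate (all-tied) comparison
    is flagged on the result, not an error.
    """
    sub = assignments[assignments.cohort == cohort]
    if sub.empty or "in_sra_cancer_matched" not in sub.columns:
        logger.info("cohort %r: no matched SRA cancer category; test skipped", cohort)
        return None
    prev = cohort_prevalence(store, cohort, set(sub.junction_id)).set_index("junction_id")
    counts = prev.n_positive
    present = sub[sub.in_sra_cancer_matched].junction_id
    absent = sub[~sub.in_sra_cancer_matched].junction_id
    if len(present) == 0 or len(absent) == 0:
        logger.info("cohort %r: one sharedness group is empty; test skipped", cohort)
        return None
    return compare_prevalence_distributions(
        counts.loc[present].to_numpy(), counts.loc[absent].to_numpy()
    )
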