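"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as a naive scan over (junction, sample) pairs or
an exhaustive enumeration, deliberately ignoring the package's own vectorized
paths.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import hypergeom, rankdata

CORE_CLASSES = {"gtex_normal", "matched_normal"}
SRA_CLASSES = {"sra_adult", "sra_developmental", "sra_placenta", "sra_stem"}


def _pairs(store) -> list[tuple[int, str, int]]:
    """All (junction_id, sample_id, reads) evidence triples, one pass."""
    return list(
        zip(store.evidence.junction_id, store.evidence.sample_id, store.evidence.reads)
    )


def _sample_info(store) -> dict[str, tuple[str, str]]:
    """sample_id -> (cohort, cohort_class)."""
    return {
        s: (c, k)
        for s, c, k in zip(
            store.samples.sample_id, store.samples.cohort, store.samples.cohort_class
        )
    }


def brute_force_stages(store, match_map, min_total_reads=2):
    """Naive novelty staging: scan every (junction, sample) pair directly."""
    pairs = _pairs(store)
    info = _sample_info(store)
    totals: dict[int, int] = {}
    j2s: dict[int, set[str]] = {}
    for j, s, r in pairs:
        totals[j] = totals.get(j, 0) + r
        j2s.setdefault(j, set()).add(s)
    retained = {j for j, t in totals.items() if t >= min_total_reads}

    def present(j, sample_set):
        return any(s in sample_set for s in j2s.get(j, ()))

    core = {s for s, (_, k) in info.items() if k in CORE_CLASSES}
    sra = {s for s, (_, k) in info.items() if k in SRA_CLASSES}
    tumor_cohorts = sorted({c for c, k in info.values() if k == "tumor"})
    out = {}
    for cohort in tumor_cohorts:
        tumor = {s for s, (c, _) in info.items() if c == cohort}
        tissues = match_map.get(cohort, ())
        tm = (
            {s for s, (c, _) in info.items() if c in set(tissues)} if tissues else None
        )
        for j in sorted(retained):
            if not present(j, tumor):
                continue
            if tm is not None and present(j, tm):
                stage = "0"
            elif present(j, core):
                stage = "0" if tm is None else "1+"
            elif present(j, sra):
                stage = "2+"
            else:
                stage = "3+"
            out[(cohort, j)] = stage
    return out


def brute_force_prevalence(store, cohort) -> dict[int, tuple[int, int]]:
    """junction -> (n_positive, cohort_size) by direct scan."""
    info = _sample_info(store)
    samples = {s for s, (c, _) in info.items() if c == cohort}
    pos: dict[int, set[str]] = {}
    for j, s, _r in _pairs(store):
        if s in samples:
            pos.setdefault(j, set()).add(s)
    return {j: (len(s), len(samples)) for j, s in pos.items()}


def brute_force_sets(store, stage2_pairs, taxonomy, rule="default"):
    """Naive SRA set assignment for (cohort, junction) stage-2+ pairs."""
    info = _sample_info(store)
    cat_of = {s: c for s, (c, k) in info.items() if k in SRA_CLASSES}
    j_cat: dict[int, dict[str, set[str]]] = {}
    for j, s, _r in _pairs(store):
        if s in cat_of:
            j_cat.setdefault(j, {}).setdefault(cat_of[s], set()).add(s)
    out = {}
    for cohort, j in stage2_pairs:
        per_cat = j_cat.get(j, {})
        n_adult = n_dev = n_plac = n_stem = 0
        for cat, ss in per_cat.items():
            group = taxonomy.groups.get(cat)
            if cat == taxonomy.placenta_category:
                n_plac += len(ss)
            elif group == "developmental":
                n_dev += len(ss)
            elif group == "adult":
                n_adult += len(ss)
            elif group == "stem":
                n_stem += len(ss)
        n_dev_group = n_dev + n_plac
        if rule == "default":
            flags = (n_adult >= 1, n_dev >= 1, n_plac >= 1, n_stem >= 1)
        else:
            flags = (
                n_adult >= 2,
                n_dev >= 1 and n_dev_group >= 2,
                n_plac >= 1 and n_dev_group >= 2,
                n_stem >= 2,
            )
        out[(cohort, j)] = flags + (not any(flags),)
    return out


def kruskal_h(a, b) -> float:
    """Hand Kruskal-Wallis H with tie correction."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = rankdata(pooled)
    ra, rb = ranks[: len(a)].sum(), ranks[len(a):].sum()
    h = 12.0 / (n * (n + 1)) * (ra**2 / len(a) + rb**2 / len(b)) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / tie


def exact_kw_permutation_p(a, b) -> float:
    """Exact permutation p-value of the KW H statistic (tiny n only)."""
    a, b = list(a), list(b)
    pooled = a + b
    n, na = len(pooled), len(a)
    h_obs = kruskal_h(a, b)
    count = total = 0
    for idx in combinations(range(n), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        if kruskal_h(ga, gb) >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def fisher_exact_enumeration_p(table) -> float:
    """Two-sided Fisher p by summing hypergeometric pmfs <= observed.

    Uses the conventional relative-tolerance comparison so results match
    the standard conditional-exact definition.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = hypergeom.pmf(np.arange(lo, hi + 1), n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def hand_km(durations, events):
    """Product-limit estimator computed directly from the definition.

    Returns dict t -> S(t) at each distinct event time.
    """
    order = np.argsort(durations)
    durations = np.asarray(durations, float)[order]
    events = np.asarray(events, bool)[order]
    s = 1.0
    curve = {}
    for t in sorted(set(durations[events])):
        at_risk = int((durations >= t).sum())
        d = int(((durations == t) & events).sum())
        s *= 1 - d / at_risk
        curve[float(t)] = s
    return curve
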