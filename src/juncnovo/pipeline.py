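"""End-to-end orchestration of the junction-novelty analysis.

Stages mirror the analysis order — ``simulate`` (optional, synthetic inputs),
``index``, ``filter``, ``prevalence``, ``sets``, ``classify``, ``stats`` —
each a plain function over a :class:`RunConfig` that writes its module's TSV
outputs plus a JSON manifest (inputs, parameters, checksums, version) into
the run's output directory. ``run_all`` chains them. Reruns on unchanged
inputs are byte-identical.

Filter-parameter defaults are the analysis' published operating point: a
two-read global evidence floor, 1% panel prevalence, 200-junction panel cap
and 5% cross-cohort threshold. Every deviation is echoed into the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import parse_annotation, read_gene_list
from .genecontext import antisense_fraction_by_category, classify_store
from .novelty import (
    apply_global_read_filter,
    assign_novelty_stages,
    core_normal_present,
    load_tissue_match_map,
    stage_at_least,
)
from .sets import (
    SraTaxonomy,
    assign_sets,
    figure_categories,
    matched_cancer_sharedness_test,
    upset_summary,
)
from .sharedness import (
    all_cohort_prevalences,
    build_prevalence_matrix,
    cross_cohort_sharing,
    select_shared_panel,
    singleton_fraction,
)
from .simulate import MutationEffect, SimConfig, write_simulated_inputs
from .stats import (
    classify_mutation_strata,
    cohort_fisher_tests,
    km_survival,
    patient_burden_table,
    regress_burden_vs_tmb,
    stratify_and_test_counts,
)
from .store import JunctionStore, load_phenotypes, parse_snaptron_table

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "index", "filter", "prevalence", "sets", "classify", "stats"]


@dataclass
class RunConfig:
    """Paths and filter parameters for one analysis run."""

    input_dir: str | Path
    output_dir: str | Path
    annotation: str = "annotation.gtf"
    evidence: list[str] = field(default_factory=lambda: ["evidence.tsv"])
    evidence_dialect: str = "1-closed"
    phenotypes: str = "phenotypes.tsv"
    tissue_match: str = "tissue_match.yaml"
    taxonomy: str = "sra_taxonomy.yaml"
    sra_cancer_match: str = "sra_cancer_match.yaml"
    cancer_genes: str = "cancer_genes.txt"
    mutations: str = "mutations.tsv"
    tmb: str = "tmb.tsv"
    survival: str = "survival.tsv"
    splicing_genes: str | None = None  # UniProt keyword export; optional
    min_total_reads: int = 2
    min_prevalence: float = 0.01
    panel_cap: int = 200
    cross_cohort_threshold: float = 0.05
    two_sample_rule: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))

    def inpath(self, name: str) -> Path:
        p = Path(self.input_dir) / name
        if not p.exists():
            raise FileNotFoundError(
                f"input {p} missing: run the 'simulate' stage first or point "
                "input_dir at real data"
            )
        return p

    def outpath(self, name: str) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name


def _require(cfg: RunConfig, name: str, producer: str) -> Path:
    p = Path(cfg.output_dir) / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {p.name}: run the {producer!r} stage first"
        )
    return p


def _manifest(cfg: RunConfig, stage: str, params: dict, outputs: list[Path]) -> Path:
    manifest = dict(
        stage=stage,
        version=__version__,
        parameters=params,
        config=asdict(cfg),
        checksums={
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(outputs)
        },
    )
    path = cfg.outpath(f"manifest_{stage}.json")
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def simulate(
    cfg: RunConfig, sim: SimConfig | None = None, effect: MutationEffect | None = None
) -> dict[str, Path]:
    """Generate synthetic inputs under ``cfg.input_dir``."""
    sim = sim or SimConfig(seed=cfg.seed)
    return write_simulated_inputs(cfg.input_dir, sim, effect)


def index(cfg: RunConfig) -> JunctionStore:
    """Parse annotation and evidence, build and persist the junction store."""
    ann = parse_annotation(cfg.inpath(cfg.annotation))
    evidence = [
        parse_snaptron_table(cfg.inpath(name), cfg.evidence_dialect)
        for name in cfg.evidence
    ]
    phenotypes = load_phenotypes(cfg.inpath(cfg.phenotypes))
    store = JunctionStore.build(evidence, phenotypes, annotation=ann)
    logger.info(
        "indexed %d junctions, %d evidence pairs, %d samples",
        len(store.junctions), len(store.evidence), len(store.samples),
    )
    db = cfg.outpath("junctions.sqlite")
    store.save(db)
    jtsv = cfg.outpath("junctions.tsv")
    store.export_junctions_tsv(jtsv)
    _manifest(cfg, "index", dict(evidence_dialect=cfg.evidence_dialect), [db, jtsv])
    return store


def _load_store(cfg: RunConfig) -> JunctionStore:
    return JunctionStore.load(_require(cfg, "junctions.sqlite", "index"))


def filter_stage(cfg: RunConfig) -> pd.DataFrame:
    """Global read filter + novelty staging; writes novelty.tsv."""
    store = _load_store(cfg)
    match_map = load_tissue_match_map(cfg.inpath(cfg.tissue_match))
    retained = apply_global_read_filter(store, cfg.min_total_reads)
    logger.info(
        "global %d-read filter: %d of %d junctions retained",
        cfg.min_total_reads, len(retained), len(store.junctions),
    )
    stages = assign_novelty_stages(store, match_map, retained=retained)
    out = cfg.outpath("novelty.tsv")
    stages.merge(store.junctions[["junction_id", "chrom", "start", "end", "strand"]]).to_csv(
        out, sep="\t", index=False
    )
    _manifest(cfg, "filter", dict(min_total_reads=cfg.min_total_reads), [out])
    return stages


def prevalence(cfg: RunConfig) -> dict:
    """Prevalences, shared panels, prevalence matrix, cross-cohort counts."""
    store = _load_store(cfg)
    stages = pd.read_csv(_require(cfg, "novelty.tsv", "filter"), sep="\t")
    prev = all_cohort_prevalences(store)
    outputs = []
    p1 = cfg.outpath("prevalence.tsv")
    prev.to_csv(p1, sep="\t", index=False)
    outputs.append(p1)

    panels = {}
    for cohort in store.tumor_cohorts():
        panels[cohort] = select_shared_panel(
            store, stages, cohort, cfg.min_prevalence, cfg.panel_cap
        )
    panel_df = pd.concat(panels.values(), ignore_index=True)
    p2 = cfg.outpath("shared_panels.tsv")
    panel_df.to_csv(p2, sep="\t", index=False)
    outputs.append(p2)

    nonempty = [p for p in panels.values() if len(p)]
    summary: dict = {}
    if nonempty:
        matrix = build_prevalence_matrix(store, nonempty)
        p3 = cfg.outpath("prevalence_matrix.tsv")
        matrix.to_csv(p3, sep="\t")
        outputs.append(p3)

    stage2_prev = prev.merge(
        stage_at_least(stages, "2+")[["cohort", "junction_id"]],
        on=["cohort", "junction_id"],
    )
    n_cross, _ = cross_cohort_sharing(store, stage2_prev, cfg.cross_cohort_threshold)
    stage2_ids = set(stage_at_least(stages, "2+").junction_id)
    summary.update(
        n_cross_cohort=n_cross,
        singleton_fraction=singleton_fraction(store, stage2_ids),
        n_stage2_junctions=len(stage2_ids),
    )
    p4 = cfg.outpath("sharedness_summary.json")
    p4.write_text(json.dumps(summary, indent=2) + "\n")
    outputs.append(p4)
    _manifest(
        cfg, "prevalence",
        dict(
            min_prevalence=cfg.min_prevalence, panel_cap=cfg.panel_cap,
            cross_cohort_threshold=cfg.cross_cohort_threshold,
        ),
        outputs,
    )
    return summary


def sets(cfg: RunConfig) -> pd.DataFrame:
    """SRA set assignment, upset summaries, matched-cancer sharedness tests."""
    store = _load_store(cfg)
    stages = pd.read_csv(_require(cfg, "novelty.tsv", "filter"), sep="\t")
    taxonomy = SraTaxonomy.from_yaml(cfg.inpath(cfg.taxonomy))
    import yaml

    cancer_match = yaml.safe_load(cfg.inpath(cfg.sra_cancer_match).read_text()) or {}
    rule = "two_sample" if cfg.two_sample_rule else "default"
    assignments = assign_sets(
        store, stages, taxonomy, rule=rule, sra_cancer_match_map=cancer_match
    )
    outputs = []
    p1 = cfg.outpath("set_assignments.tsv")
    assignments.to_csv(p1, sep="\t", index=False)
    outputs.append(p1)

    upsets = [upset_summary(assignments, c) for c in store.tumor_cohorts()]
    p2 = cfg.outpath("upset_summary.tsv")
    pd.concat(upsets, ignore_index=True).to_csv(p2, sep="\t", index=False)
    outputs.append(p2)

    tests = {}
    for cohort in store.tumor_cohorts():
        res = matched_cancer_sharedness_test(store, stages, assignments, cohort)
        if res is not None:
            tests[cohort] = dict(H=res.H, p=res.p, degenerate=res.degenerate)
    p3 = cfg.outpath("matched_cancer_tests.json")
    p3.write_text(json.dumps(tests, indent=2) + "\n")
    outputs.append(p3)
    _manifest(cfg, "sets", dict(rule=rule), outputs)
    return assignments


def classify(cfg: RunConfig) -> pd.DataFrame:
    """Gene context, cancer-gene flags and antisense fractions by category."""
    store = _load_store(cfg)
    ann = parse_annotation(cfg.inpath(cfg.annotation))
    cancer_genes = read_gene_list(cfg.inpath(cfg.cancer_genes))
    contexts = classify_store(store, ann, cancer_genes)
    outputs = []
    p1 = cfg.outpath("gene_context.tsv")
    contexts.to_csv(p1, sep="\t", index=False)
    outputs.append(p1)

    stages = pd.read_csv(_require(cfg, "novelty.tsv", "filter"), sep="\t")
    assignments = pd.read_csv(_require(cfg, "set_assignments.tsv", "sets"), sep="\t")
    cats = figure_categories(stages, assignments)
    labeled = cats.merge(contexts[["junction_id", "gene_context"]], on="junction_id")
    fractions = antisense_fraction_by_category(labeled)
    p2 = cfg.outpath("antisense_by_category.tsv")
    fractions.to_csv(p2, sep="\t", index=False)
    outputs.append(p2)
    store.save(cfg.outpath("junctions.sqlite"))  # persist contexts
    _manifest(cfg, "classify", {}, outputs)
    return fractions


def stats(cfg: RunConfig) -> dict:
    """Burden-vs-TMB regression, mutation stratification, Fisher tests, KM."""
    store = _load_store(cfg)
    retained = apply_global_read_filter(store, cfg.min_total_reads)
    core = core_normal_present(store, retained)
    tmb = pd.read_csv(cfg.inpath(cfg.tmb), sep="\t")
    burdens = patient_burden_table(store, retained, core, tmb)
    outputs = []
    p1 = cfg.outpath("burden.tsv")
    burdens.to_csv(p1, sep="\t", index=False)
    outputs.append(p1)
    reg = regress_burden_vs_tmb(burdens.dropna(subset=["tmb"]))

    mutations = pd.read_csv(cfg.inpath(cfg.mutations), sep="\t")
    patients = list(burdens.sample_id)
    splicing = (
        read_gene_list(cfg.inpath(cfg.splicing_genes)) if cfg.splicing_genes else None
    )
    results: dict = dict(
        regression=dict(slope=reg.slope, intercept=reg.intercept, r=reg.r, p=reg.p)
    )
    for criterion in ("sqtl_five_gene",) + (("uniprot_splicing",) if splicing else ()):
        strata = classify_mutation_strata(
            mutations, criterion, patients=patients, splicing_genes=splicing
        )
        counts = burdens.merge(
            strata.rename(columns={"patient_id": "sample_id"}), on="sample_id"
        ).rename(columns={"n_stage2_junctions": "count"})
        try:
            res = stratify_and_test_counts(counts[["cohort", "mutated", "count"]])
        except ValueError as exc:
            logger.warning("%s ANOVA skipped: %s", criterion, exc)
            continue
        pa = cfg.outpath(f"anova_{criterion}.tsv")
        res.anova.to_csv(pa, sep="\t")
        pc = cfg.outpath(f"per_cohort_{criterion}.tsv")
        res.per_cohort.to_csv(pc, sep="\t", index=False)
        outputs += [pa, pc]
        results[criterion] = dict(
            anova_mutation_p=float(res.anova.loc["C(mutated)", "PR(>F)"]),
            n_significant_cohorts=int(res.per_cohort.significant.sum()),
        )

        # per-junction Fisher sharedness tests, per cohort
        fisher_frames = []
        tumor_ev = store.evidence[store.evidence.sample_id.isin(set(patients))]
        occ = tumor_ev[tumor_ev.junction_id.isin(retained - core)].rename(
            columns={"sample_id": "patient_id"}
        )
        occ = occ.merge(
            store.samples[["sample_id", "cohort"]].rename(
                columns={"sample_id": "patient_id"}
            ),
            on="patient_id",
        )
        for cohort, sub in occ.groupby("cohort"):
            cstrata = strata[strata.patient_id.isin(
                set(store.samples.loc[store.samples.cohort == cohort, "sample_id"])
            )]
            ft = cohort_fisher_tests(sub[["junction_id", "patient_id"]], cstrata)
            if len(ft):
                ft.insert(0, "cohort", cohort)
                fisher_frames.append(ft)
        if fisher_frames:
            pf = cfg.outpath(f"fisher_{criterion}.tsv")
            pd.concat(fisher_frames, ignore_index=True).to_csv(pf, sep="\t", index=False)
            outputs.append(pf)

    surv = pd.read_csv(cfg.inpath(cfg.survival), sep="\t")
    group_col = "junction_positive" if "junction_positive" in surv.columns else None
    km = km_survival(surv, group_col)
    curves = []
    for label, parts in km.items():
        c = parts["curve"].copy()
        c.insert(0, "group", label)
        curves.append(c)
    pk = cfg.outpath("km_curves.tsv")
    pd.concat(curves, ignore_index=True).to_csv(pk, sep="\t", index=False)
    outputs.append(pk)

    ps = cfg.outpath("stats_summary.json")
    ps.write_text(json.dumps(results, indent=2) + "\n")
    outputs.append(ps)
    _manifest(cfg, "stats", dict(min_total_reads=cfg.min_total_reads), outputs)
    return results


def run_all(
    cfg: RunConfig,
    sim: SimConfig | None = None,
    effect: MutationEffect | None = None,
    with_simulate: bool = True,
) -> dict:
    """Chain every stage; returns the prevalence and stats summaries."""
    if with_simulate:
        simulate(cfg, sim, effect)
    index(cfg)
    filter_stage(cfg)
    shared = prevalence(cfg)
    sets(cfg)
    classify(cfg)
    stat = stats(cfg)
    return dict(sharedness=shared, stats=stat)
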