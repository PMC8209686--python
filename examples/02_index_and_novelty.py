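"""Index junction evidence and stage it through the novelty hierarchy.

Stage 0 junctions occur in tissue-matched normals; 1+ only in other core
normals; 2+ escape all core normals; 3+ additionally escape every selected
SRA non-cancer sample.
"""

from juncnovo.annotation import parse_annotation
from juncnovo.novelty import apply_global_read_filter, assign_novelty_stages
from juncnovo.simulate import SimConfig, generate_annotation, generate_cohorts
from juncnovo.store import JunctionStore

cfg = SimConfig(seed=1)
gtf, ann_truth = generate_annotation(
    cfg.n_genes, cfg.transcripts_per_gene, cfg.exons_per_transcript,
    seed=cfg.seed, frac_cancer_genes=cfg.frac_cancer_genes,
)
evidence, phenotypes, _truth = generate_cohorts(cfg, ann_truth)
store = JunctionStore.build([evidence], phenotypes, annotation=parse_annotation(gtf))

retained = apply_global_read_filter(store, min_total_reads=2)
print(f"{len(store.junctions)} junctions indexed; {len(retained)} pass the 2-read floor")

stages = assign_novelty_stages(store, cfg.match_map(), retained=retained)
for cohort, sub in stages.groupby("cohort"):
    counts = sub.stage.value_counts().reindex(["0", "1+", "2+", "3+"], fill_value=0)
    frac_core = (counts["0"] + counts["1+"]) / counts.sum()
    print(
        f"{cohort}: {dict(counts)}  -> {100*frac_core:.1f}% of junctions are "
        "found in core normals (real-data cohort surveys report ~90%)"
    )
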