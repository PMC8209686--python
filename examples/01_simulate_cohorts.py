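"""Generate a synthetic multi-cohort junction dataset with planted truth.

The generator emulates the inputs of a cancer-vs-normal junction survey:
tumor cohorts, tissue-matched and other core normals, SRA non-cancer
categories (adult / developmental / stem, incl. placenta) and matched SRA
cancer cohorts. Every junction carries a mutually exclusive truth label.
"""

from juncnovo.simulate import SimConfig, generate_cohorts

cfg = SimConfig(seed=1, n_junctions=1000, n_genes=30)
evidence, phenotypes, truth = generate_cohorts(cfg)

print("samples per cohort class:")
print(phenotypes.cohort_class.value_counts().to_string())
print("\nplanted truth labels (mutually exclusive):")
print(truth.category.value_counts().to_string())
print(f"\nevidence pairs: {len(evidence)} (junction x sample with >=1 read)")
print(
    "\nThe 'filtered' junctions carry exactly one read in total and exist to "
    "exercise the global two-read evidence floor; all other labels state in "
    "which non-tumor cohorts (if any) the junction was planted."
)
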