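"""Generate a synthetic infant cohort with known ground truth.

Draws 101 subjects with correlated antigen titers, threshold-defined
low vaccine responders (LVR), zero-inflated oral antibiotic exposure
and Dirichlet-multinomial microbiome tables, then writes everything as
TSV. The printed counts are the planted ground truth that downstream
examples try to recover.
"""

from vaxbiome import CohortConfig, generate_cohort, write_cohort

config = CohortConfig(seed=3)
cohort = generate_cohort(config)

labels = list(cohort.ground_truth.responder_1yr.values())
print(f"subjects: {config.n_subjects}; assessed at year 1: {len(labels)}")
print(f"planted LVR at year 1: {labels.count('LVR')} "
      f"({100 * labels.count('LVR') / len(labels):.1f}%)")
print(f"titer rows: {len(cohort.titers)}; antibiotic courses: {len(cohort.exposures)}")
print(f"planted KO module: {cohort.ground_truth.planted_module} "
      f"({len(cohort.ground_truth.planted_kos)} KOs, "
      f"Spearman-scale effect {cohort.ground_truth.planted_ko_effect})")

manifest = write_cohort(cohort, "scratch/example_cohort")
print("\nfiles written:")
print(manifest.to_string(index=False))
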