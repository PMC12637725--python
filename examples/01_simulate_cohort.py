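"""Generate the default synthetic AIN/ATN cohort and look at its anatomy.

Builds 8 ground-truthed samples (4 AIN, 4 ATN) and prints the cohort's
dimensions plus how many cells fall in each anatomical domain — the
structure every later analysis tries to rediscover.
"""
from nephroniche import default_config, generate_cohort

cohort = generate_cohort(default_config(seed=1))
print(f"{cohort.n_cells} cells, {len(cohort.genes)} genes, "
      f"{len(cohort.transcripts)} transcript spots")
print(cohort.samples.to_string(index=False))
print("\ncells per true anatomical domain:")
print(cohort.ground_truth.cells["domain"].value_counts().to_string())
# Every domain is a niche archetype the pipeline should later recover.
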