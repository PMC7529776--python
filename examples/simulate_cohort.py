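"""Generate a seeded synthetic cohort with an injected persistent outlier.

Builds a small longitudinal plasma-proteomics cohort (cases with negative
pre-diagnosis draw days, controls anchored at enrollment), injects one
persistent elevation, and writes the three CSVs the rest of the pipeline
consumes.
"""

from madtrack import Injection, SimulationConfig, generate_cohort, write_cohort

config = SimulationConfig(
    n_cases=3,
    n_controls=12,
    n_proteins=50,
    seed=11,
    injections=(
        # an 8-MAD persistent elevation over the first 3 draws of case_01
        Injection("case_01", "P0010", "persistent", magnitude=8.0, onset_draw=0, duration_draws=3),
    ),
)
cohort, truth = generate_cohort(config)
write_cohort(cohort, "measurements.csv", "metadata.csv")
truth.to_csv("truth.csv")

n_draws = cohort.schedule().groupby("individual_id").size()
print(f"subjects: {len(cohort.subjects)} ({(cohort.subjects.status == 'case').sum()} cases)")
print(f"measurements: {len(cohort.measurements)} rows, {len(cohort.protein_ids)} proteins")
print(f"draws per individual: min {n_draws.min()}, max {n_draws.max()}")
print("injected ground truth:")
print(truth.events[["individual_id", "protein_id", "archetype", "magnitude"]].to_string(index=False))
# Each individual has 3-6 draws spaced 120-240 days apart; the injected
# (individual, protein) pair should surface later as a persistent outlier.
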