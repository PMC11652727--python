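"""Generate a synthetic dense-mammogram cohort and simulated readers.

Builds a small case set (normal and cancer cases, CC + MLO views) with
planted suspicious areas of known difficulty, then simulates a reader
cohort with two planted high-false-positive outliers and prints the
resulting annotation counts.
"""

from mammoread.synthetic import (SyntheticConfig, generate_case_set,
                                 simulate_readers)

config = SyntheticConfig(n_normal_cases=10, n_cancer_cases=5,
                         n_readers=12, n_outlier_readers=2, seed=7)
case_set = generate_case_set(config)
sim = simulate_readers(case_set, config)

print(f"cases: {config.n_normal_cases} normal + {config.n_cancer_cases} "
      f"cancer, {len(case_set.images)} view images")
print(f"lesion truths: {len(case_set.lesion_truths)} "
      f"(subtypes: {case_set.lesion_truths['subtype'].value_counts().to_dict()})")
print(f"planted areas: {len(case_set.planted_area_truths)} "
      f"({(case_set.planted_area_truths['difficulty'] == 'difficult').sum()}"
      " difficult)")
print(f"annotations: {len(sim.annotations)} "
      f"({(sim.annotations['rating'] >= 3).sum()} positive marks)")
print("per-reader positive-mark counts "
      "(planted outliers should stand out):")
positives = sim.annotations[sim.annotations["rating"] >= 3]
counts = positives.groupby("reader_id").size()
truth = sim.reader_truth.set_index("reader_id")["is_outlier"]
for reader, n in counts.items():
    tag = "  <- planted outlier" if truth[reader] else ""
    print(f"  {reader}: {n}{tag}")
# The printed counts are raw positive marks; the analysis pipeline
# identifies the outliers from the clustered false-response matrix.
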