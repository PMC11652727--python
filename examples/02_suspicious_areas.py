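"""From raw annotations to labelled suspicious areas.

Pools positive marks (rating >= 3), clusters them with the bounded-
diameter rule, boxes each cluster with a 10 px margin, hit-tests
against lesion truths (12.5 mm radius) and labels each area easy or
difficult by the median split of its false-response count.
"""

from mammoread.annotations import (PipelineThresholds, areas_to_frame,
                                   assign_difficulty, build_response_matrix,
                                   build_suspicious_areas)
from mammoread.synthetic import (SyntheticConfig, generate_case_set,
                                 reader_ids, simulate_readers)

config = SyntheticConfig(n_normal_cases=8, n_cancer_cases=4, seed=3)
case_set = generate_case_set(config)
sim = simulate_readers(case_set, config)

# 60 px clustering suits the synthetic image scale; the study-scale
# default is 250 px on full-resolution mammograms
thresholds = PipelineThresholds(cluster_max_distance=60.0)
areas = build_suspicious_areas(sim.annotations, case_set.lesion_truths,
                               case_set.pixel_spacing, thresholds,
                               config.image_size)
matrix = build_response_matrix(areas, reader_ids(config.n_readers),
                               sim.annotations)
assign_difficulty(areas, matrix)

table = areas_to_frame(areas)
print(table.head(12).to_string(index=False))
print(f"\n{len(table)} areas: "
      f"{(table['kind'] == 'normal').sum()} normal (false-positive sites), "
      f"{(table['kind'] == 'cancer').sum()} cancer-containing")
print("difficulty split per kind "
      "(count > median false responses -> difficult):")
print(table.groupby(["kind", "difficulty"]).size())
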