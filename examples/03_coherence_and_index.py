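"""Coherence maps and the intelligibility index on a small simulated cohort.

Six subjects watch 'natural' and 'reversed' stimuli; every occipital voxel
couples to the feature tracks, more strongly for natural stimuli.  The
intelligibility index (natural minus reversed coherence, averaged over
1-7 Hz) should therefore be positive in occipital cortex and near zero
elsewhere.
"""

import numpy as np

from silenttrack.config import PipelineConfig
from silenttrack.coherence import COMBINED_BAND
from silenttrack.pipeline import cohort_coherence, cohort_index_maps
from silenttrack import synth

grid = synth.build_grid((4, 4, 4))
cohort = synth.simulate_cohort(
    n_subjects=6, coupling=synth.CouplingModel.headline(), grid=grid,
    n_trials_per_condition=24, seed=3,
)
cfg = PipelineConfig(grid_shape=(4, 4, 4), n_trials_per_condition=24)

maps = cohort_coherence(cohort, cfg)
index = cohort_index_maps(maps, cohort.subject_ids, ("lip", "envelope", "formant", "pitch"),
                          COMBINED_BAND)

occ = grid.region_mask("occipital")
other = grid.region_mask("other")
print("mean intelligibility index (natural - reversed coherence), 1-7 Hz:")
print(f"{'feature':>10} {'occipital':>10} {'other':>10}")
for name, stack in index.items():
    print(f"{name:>10} {stack[:, occ].mean():>10.4f} {stack[:, other].mean():>10.4f}")
print("\nPositive occipital values show the planted preference for natural")
print("stimuli; 'other' voxels carry no coupling and sit near zero.")
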