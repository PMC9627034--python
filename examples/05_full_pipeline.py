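"""Run the whole analysis end to end and list the artifacts it writes.

Simulate -> coherence -> intelligibility index -> feature x naturalness
model -> contrasts -> cluster permutation per band -> data-driven ROI
regressions.  Scaled down (8 subjects, 4x4x4 grid) so it finishes in
seconds; every output lands in scratch/full_run with a provenance-stamped
manifest, and rerunning with the same config + seed reproduces all numbers
bit-identically.
"""

from silenttrack.config import PipelineConfig
from silenttrack.pipeline import run_full_analysis

cfg = PipelineConfig(
    n_subjects=8, grid_shape=(4, 4, 4), n_trials_per_condition=20,
    n_permutations=200, seed=5, out_dir="scratch/full_run",
)
bundle = run_full_analysis(cfg, force=True)

print("fixed-effect F tests (occipital ROI, 1-7 Hz coherence):")
print(bundle.anova.to_string(index=False))
print("\nnatural-vs-reversed contrasts per feature (BH-adjusted):")
print(bundle.contrasts["naturalness"][["contrast", "estimate", "p_fdr"]].to_string(index=False))
print("\ncluster p values (band x feature):")
for (band, feat), res in bundle.cluster_results.items():
    print(f"  {band:>8} {feat:>8}: min p = {res.min_p:.4f}")
print("\nROI regressions of the index on age:")
if bundle.roi_fits.empty:
    print("  (no significant formant cluster at this scale)")
else:
    print(bundle.roi_fits.to_string(index=False))
print(f"\nartifacts in {cfg.out_dir}: manifest.json, maps.h5, *.tsv, config.yaml")
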