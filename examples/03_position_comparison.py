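"""Prone vs supine rSNR comparison on small digital subjects.

Runs the end-to-end two-position pipeline at a reduced problem size: two
digital subjects, each simulated prone (16-channel lateral paddles) and
supine (conformal surface array), rSNR against the body-coil reference,
and region-wise bootstrapped percentile tests.  Prints the supine:prone
median-rSNR ratios and distances to the nearest coil element.
"""

from rsnr import ComparisonConfig, run_position_comparison

cfg = ComparisonConfig(
    subject_volumes_ml=(800.0, 1200.0),
    grid_shape=(48, 40, 32),
    voxel_size_mm=6.0,
    supine_channels=24,
    prone_channels=8,
    calib_region=(16, 16, 8),
    accels=((1, 1), (2, 4)),
    n_boot=1000,
    max_voxels_per_region=3000,
)
report = run_position_comparison(cfg, seed=2)

for i, subj in enumerate(report["subjects"]):
    vols = subj["breast_volume_ml"]
    print(f"subject {i}: breast volume prone {vols['prone']:.0f} mL, "
          f"supine {vols['supine']:.0f} mL")
    for region in ("breast", "chest_wall", "axilla"):
        stats = subj["regions"][region]["1x1"]
        test = stats["tests"][50]
        print(f"  {region:<11} supine/prone median ratio "
              f"{stats['median_ratio_supine_prone']:5.2f}   "
              f"p = {test['p_value']:.4f} ({test['direction']})")
    d = subj["distance"]
    print(f"  median breast distance-to-coil: prone "
          f"{d['prone']['breast']['median_distance_mm']:.0f} mm, supine "
          f"{d['supine']['breast']['median_distance_mm']:.0f} mm")

print()
print("Ratios above 1 with small p-values: the conformal supine array wins")
print("wherever the tissue sits closer to its elements.")
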