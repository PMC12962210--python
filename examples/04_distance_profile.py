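"""Distance-from-coil analysis: median rSNR versus element distance.

Places the two coil geometries on matching digital subjects, computes the
exact per-voxel distance to the nearest coil element, and bins a surrogate
rSNR map (the array's root-sum-of-squares sensitivity, normalised) into
2 mm distance chunks, mirroring how coil proximity drives SNR.
"""

import numpy as np

from rsnr import (
    distance_to_coil_map,
    make_coil_array,
    make_digital_subject,
    prone_coil_geometry,
    rsnr_vs_distance,
    supine_coil_geometry,
)
from rsnr.coils import evaluate_sensitivities
from rsnr.relative import RSNRVolume

for position in ("prone", "supine"):
    subject = make_digital_subject(position, 1000.0, seed=9)
    if position == "supine":
        geom = supine_coil_geometry(subject, element_count=60, element_diameter_mm=70.0)
        coil = make_coil_array("surface_conformal", subject, 60, 70.0)
    else:
        geom = prone_coil_geometry(subject.labels)
        coil = make_coil_array("side_paddles", subject, 16)
    dist = distance_to_coil_map(subject.signal, geom)
    rss = np.sqrt((np.abs(evaluate_sensitivities(coil, subject.signal)) ** 2).sum(0))
    surrogate = RSNRVolume(
        rss / rss.max(), subject.body_mask, voxel_size_mm=subject.signal.voxel_size_mm
    )
    profiles = rsnr_vs_distance(surrogate, dist, subject.labels, bin_mm=2.0)
    breast = profiles["breast"]
    print(f"{position}: breast distance percentiles (mm): "
          + ", ".join(f"p{p}={v:.0f}" for p, v in breast.distance_percentiles_mm.items()))
    filled = np.nonzero(breast.voxel_count > 50)[0]
    show = filled[:: max(1, len(filled) // 5)][:5]
    for b in show:
        print(f"    bin [{breast.bin_edges_mm[b]:.0f}, {breast.bin_edges_mm[b+1]:.0f}) mm: "
              f"median {breast.median_rsnr[b]:.3f}  (n={breast.voxel_count[b]})")

print()
print("Supine distances are systematically shorter and the profile decays")
print("with distance from the elements, as surface-coil physics dictates.")
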