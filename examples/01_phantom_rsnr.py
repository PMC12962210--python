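"""Two-contrast phantom rSNR: tissue independence and its noise limit.

Simulates the same phantom geometry with two different contrast profiles,
each acquired with an 8-channel surface array and a uniform body coil,
computes the two rSNR maps and the symmetric percent-difference map between
them, and prints the histogram FWHM.  A small FWHM means the rSNR maps are
nearly contrast-independent; its size is set by the measurement noise of
the two acquisitions.
"""

import numpy as np

from rsnr import PhantomConfig, phantom_rsnr_pair
from rsnr.relative import histogram_fwhm, percent_difference_map

cfg = PhantomConfig()  # 64^3 grid, calibrated baseline noise
rsnr_a, rsnr_b, sim = phantom_rsnr_pair(cfg, seed=7)

on = rsnr_a.valid_mask & rsnr_b.valid_mask
diff = percent_difference_map(rsnr_a, rsnr_b)
fwhm = histogram_fwhm(diff.values(), bin_width=0.5)

print(f"valid voxels:            {on.sum()}")
print(f"median rSNR (contrast A): {np.median(rsnr_a.rsnr[on]):.3f}")
print(f"median rSNR (contrast B): {np.median(rsnr_b.rsnr[on]):.3f}")
print(f"percent-difference median: {np.median(diff.values()):+.2f} %")
print(f"percent-difference FWHM:   {fwhm:.1f} %")
print()
print("The two medians agree although the phantom intensities differ by")
print("design; the near-zero-centred difference histogram shows the maps")
print("deviate only through acquisition noise.")
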