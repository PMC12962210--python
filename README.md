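# rsnr — relative-SNR analysis for parallel MRI

`rsnr` is a tested Python pipeline for comparing receive-coil performance
when the imaged tissue deforms between setups — the situation in prone vs.
supine breast MRI, where the same anatomy takes radically different shapes
and a voxelwise SNR comparison between positions is meaningless.

The central quantity is the **relative SNR**,

```
rSNR = SNR_ext / SNR_ref ,
```

the voxelwise ratio between the SNR map of the external array coil under
study and the SNR map of the scanner's transmit/receive body coil acquired
in the same position. Both maps share the object's signal `m(x)`, so tissue
contrast cancels in the ratio: rSNR depends only on coil sensitivity,
noise, and geometry, and distributions of rSNR can be compared across
positions even though individual voxels cannot be matched.

SNR maps come from SENSE reconstruction with analytic noise propagation.
With channel sensitivities `S` (stacked per aliased voxel set), channel
noise covariance `Ψ` estimated from a 2048-sample prescan noise block, and
aliased data `a`, the unfolded image, per-voxel noise and geometry factor
are

```
v        = (S^H Ψ⁻¹ S)⁻¹ S^H Ψ⁻¹ a
noise(ρ) = sqrt( R · [(S^H Ψ⁻¹ S)⁻¹]_ρρ )          (unitary DFT convention)
g(ρ)     = sqrt( [(S^H Ψ⁻¹ S)⁻¹]_ρρ · [S^H Ψ⁻¹ S]_ρρ )  ≥ 1,  ≡ 1 at R = 1
SNR      = |v| / noise .
```

Because no raw scanner data accompany this problem, the package ships a
first-class synthetic-data layer: a labelled multi-contrast Shepp–Logan
phantom, parameterised prone/supine digital subjects with
breast / chest-wall / axilla label masks, loop-element coil models with
smooth falloff fields, and a correlated-Gaussian k-space noise model with
prescan noise blocks. Every downstream stage is exercised against these
generators, against closed-form oracles, and against brute-force
re-implementations.

## What's inside

| module | contents |
| --- | --- |
| `rsnr.phantom`, `rsnr.subjects`, `rsnr.coils`, `rsnr.acquisition` | synthetic objects, coils, multichannel k-space + noise |
| `rsnr.recon` | noise-covariance and sensitivity-map estimation, retrospective subsampling, SENSE unfolding, SNR / g-factor maps |
| `rsnr.relative` | rSNR maps, symmetric percent-difference maps, histogram FWHM |
| `rsnr.regions` | label masks, slicewise erosion, percentile summaries, two-tailed bootstrapped percentile tests, volume trends |
| `rsnr.geometry` | coil-element point sets, exact distance-to-coil maps, 2 mm distance profiles |
| `rsnr.experiments` | the two orchestrated studies: tissue-independence FWHM and the prone-vs-supine comparison |
| `rsnr.io`, `rsnr.cli` | HDF5 k-space containers, NIfTI maps/masks, CSV/JSON reports; a thin `rsnr` command-line wrapper |

## Worked example

`examples/01_phantom_rsnr.py` simulates one phantom geometry with two
contrast profiles, each scanned with an 8-channel surface array and the
body-coil reference, and measures how contrast-independent the rSNR maps
are:

```
valid voxels:            78496
median rSNR (contrast A): 1.502
median rSNR (contrast B): 1.499
percent-difference median: -0.02 %
percent-difference FWHM:   12.4 %
```

The two contrasts give the same median rSNR to 0.2% although their
intensities differ by up to 3×; the width of the percent-difference
histogram (FWHM ≈ 12 percentage points at the calibrated baseline noise)
is pure measurement noise and shrinks as `1/sqrt(10)` when both noise
variances are cut tenfold.

`examples/03_position_comparison.py` runs the two-position pipeline on
small digital subjects:

```
subject 0: breast volume prone 799 mL, supine 798 mL
  breast      supine/prone median ratio  1.39   p = 0.0020 (supine)
  chest_wall  supine/prone median ratio  3.47   p = 0.0020 (supine)
  ...
  median breast distance-to-coil: prone 30 mm, supine 27 mm
```

A conformal on-skin array in the supine position sits closer to breast and
chest wall than lateral prone paddles, and the rSNR medians follow. The
other examples show accelerated SENSE g-factor maps and distance-binned
rSNR profiles.

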