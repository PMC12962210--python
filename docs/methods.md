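# Methods

## The metric

A receive coil's SNR map depends on the object's signal, the coil's
sensitivity field, and receiver noise. Dividing two SNR maps of the *same
object in the same position* — external array over body-coil reference —
cancels the signal term voxelwise:

    rSNR(x) = SNR_ext(x) / SNR_ref(x)
            = |s_ext-combined(x)| · σ_ref-effective / σ_ext-effective(x)

so rSNR is a property of the coils and the geometry, not of tissue
contrast. This is what makes distributional comparisons across body
positions meaningful despite tissue deformation: the maps cannot be
registered voxel-to-voxel, but their region-wise distributions can be
compared because neither depends on what the tissue is, only on where it
is relative to the coil.

At finite noise the two SNR maps carry independent measurement error, so
two rSNR maps of the same setup differ; the width (FWHM) of the histogram
of their symmetric percent difference,

    d(x) = 100 · (rSNR_A − rSNR_B) / ((rSNR_A + rSNR_B)/2) ,

quantifies that noise floor. To first order, a voxel's d-spread is
`100·√2·sqrt(SNR_ext⁻² + SNR_ref⁻²)`, so the FWHM scales linearly with
noise amplitude and is dominated by whichever coil is noisier.

## SNR machinery

* **Noise covariance.** `Ψ = (1/n) Σ x xᴴ` over a noise-only prescan block
  (default n = 2048), Hermitian-symmetrised; degenerate channels flagged
  through the eigenvalue spectrum.
* **Sensitivity maps.** Central calibration region of k-space (default
  24×24×12), separable Tukey window (α = 0.5) against ringing, zero-pad,
  unitary inverse DFT, RSS normalisation with the phase referenced to the
  principal-component virtual channel. Support = RSS above 5% of its 99th
  percentile (robust to isolated bright voxels).
* **SENSE unfolding.** Regular Cartesian lattices only; acceleration
  (R_si, R_rl) keeps every R-th phase-encode line from stored index 0.
  Per aliased set, the generalised-least-squares solution and its noise
  covariance (see README formulas). The centred-array sampling lattice
  contributes a per-replica phase `exp(2πi·t·(N/2)/R)` which is absorbed
  into the columns of S. `SᴴΨ⁻¹S` is inverted by pseudo-inverse with
  relative tolerance 1e-8; voxels at the tolerance are flagged invalid,
  never filled.
* **DFT convention.** Unitary transforms throughout, so k-space and image
  noise variances coincide and the aliased data vector `a = R · (zero-
  filled inverse DFT)` carries covariance `R·Ψ`. All SNR statements are
  internal-consistency statements under this fixed convention; pseudo-
  replica simulations (complex-image std over noise realisations) agree
  with the analytic maps to ~2% RMS at 500 replicas for R = 1 and 2×4.
* **rSNR validity.** Ratio taken where both supports hold and
  SNR_ref ≥ 2 (the body-coil map is near zero in air and would blow up
  the ratio; the floor is a package default, adjustable per call).
* **FWHM.** Histogram with 0.5-unit bins, one bin centred at 0; peak bin
  located, half-maximum crossings by linear interpolation between bin
  centres. Degenerate samples (spread below bin resolution) and edge
  peaks raise errors instead of returning numbers.

## Synthetic data: what it emulates, what it does not

* **Phantom.** The classical ten-ellipse head layout painted as labelled
  regions and extruded along S/I with per-slice axis scaling (the outer
  ellipse sweeps an ellipsoid). A contrast profile maps ellipse labels to
  intensities; two profiles on one grid share identical support by
  construction. The default T1-like/T2-like profiles keep the dominant
  tissue compartment at comparable brightness while interior compartments
  swap contrast by up to 3×.
* **Digital subjects.** Elliptic torso slab, two breast ellipsoids
  (prone: elongated 1.6:1:1 along A/P, pendant; supine: flattened
  0.55:1.3:1.2, spread laterally), chest-wall slab at the anterior torso
  face, two ~34 mm axilla spheres lateral to it. The breast scale is
  solved numerically so the rasterised label hits the volume target
  (within 2% typically, 10% guaranteed) even when large supine breasts
  merge medially. A seeded smooth multiplicative field (±15%) emulates
  tissue heterogeneity. The two positions are independent geometries — no
  biomechanical deformation is modelled, so cross-position comparisons are
  distributional only, exactly as the pipeline requires.
* **Coils.** Elements are points with an isotropic loop-like falloff
  `|s|(d) = a³/(a²+d²)^{3/2}` (radius a, |s| = 1 at the centre) and a
  smooth per-element linear phase. Conformal arrays use greedy
  farthest-point placement on the anterior skin surface (insulation
  thickness 0); prone paddles are bars one voxel lateral of each breast's
  bounding box; the body coil is a single uniform channel. No element
  coupling, no Biot–Savart line integrals, no load-dependent noise.
* **Noise.** Circular complex Gaussian, i.i.d. across k-space samples,
  channel covariance `σ²·0.15^|i−j|` for arrays (nearest-neighbour
  correlation 0.15), real/imaginary parts independent with half the
  variance each. Prescan blocks are drawn from the same covariance.

Consequently, passing tests demonstrate the *pipeline's* correctness and
the *qualitative* physics (proximity → SNR, acceleration → g ≥ 1, noise →
percent-difference width); they do not validate against scanner data,
B1 physics, or real coil coupling.

## Noise calibration of the tissue-independence simulation

The simulation's free parameters are the two noise levels. The
external:body split is fixed so the interior per-voxel SNR of the
dominant-tissue compartment is ≈ 50 for the array combination and ≈ 30
for the body coil; a single global scale was then calibrated once so the
baseline percent-difference FWHM lands at its reference width (≈ 12.8),
and frozen as `sigma_ext = 0.004348`, `sigma_body = 0.039853` (per-channel
noise std in the phantom's signal units). The reduced-noise conditions are
run with those frozen values scaled by the stated variance factors —
they are predictions, not separately tuned.

The experiment reconstructs with the generator's sensitivities and true
noise covariance (`use_model_sensitivities` / `use_model_covariance`,
both default True for this experiment only). Estimating either from the
simulated data adds a noise-scale-*independent* broadening — contrast-
dependent calibration ringing, and the ~1.5% relative error of a
2048-sample covariance estimate — which would put a floor under the
percent-difference width and break the noiseless limit (zero noise must
give an identically zero difference map). The position-comparison
pipeline, which emulates the measured-data workflow, uses the estimated
covariance and estimated sensitivity maps throughout.

In the noiseless limit the acquisition itself is noise-free but noise
*propagation* falls back to the unscaled baseline covariance, keeping SNR
maps finite while the rSNR ratio and its contrast-independence are exact.

## Statistics

* **Percentiles** by linear interpolation of closest ranks (NumPy
  `linear`), fixed for reproducibility.
* **Bootstrap percentile test.** Both groups resampled independently B
  times; `d* = q_p(a*) − q_p(b*)`;
  `p = 2·min(#{d*≤0}+1, #{d*≥0}+1)/(B+1)` capped at 1, significance at
  p < α = 0.01, direction from the observed sign. Defaults: B = 10,000
  for the standalone test. Voxels are treated as independent draws;
  spatial correlation is acknowledged but not modelled, matching how the
  region distributions are interpreted.
* **Erosion analysis.** Slicewise (in-plane) binary erosion per region
  with a disk of 1 or 2 px, mirroring how segmentations are drawn and
  perturbed. Stability of region medians under erosion is asserted at
  2 mm voxels, the scale at which 1–2 px corresponds to realistic
  reader-boundary error; at the 4 mm simulation grid a 2-px disk removes
  the majority of a thin chest-wall slab and the property is not
  expected.
* **Trends.** Ordinary least squares of (breast volume, supine:prone
  median-rSNR ratio) per region, with the count of points above the y = 1
  reference.

## Problem sizes

The orchestrated runs are sized for a single CPU: the phantom experiment
uses a 64³ grid with an 8-channel array, five seeds per condition
(~3 s per seed-condition); the position comparison uses three subjects in
[750, 3000] mL on a 72×60×48 grid at 4 mm with 60 supine / 16 prone
channels, B = 2,000 bootstrap resamples over at most 6,000 voxels per
region (the standalone test keeps B = 10,000; full-population runs are a
config change). Larger presets mainly need a larger lateral FOV for the
flattened supine geometry.

## Known limitations

* Percent-difference FWHM under strong noise reduction scales exactly as
  the noise amplitude (`1/√10` for variance/10); mechanisms that would
  break that scaling (very low reference SNR, Rician floors) are outside
  the calibrated regime.
* Prone paddles are modelled as bars flanking each breast; whether bars
  should flank each breast individually or the whole chest is
  configuration, with per-breast flanking the default.
* The axilla region is small; at coarse voxel sizes its valid-voxel count
  limits percentile precision, and heavy acceleration with few channels
  can push parts of any region outside the reconstructible support.
* g-factor and SNR claims are tied to the unitary-DFT convention; absolute
  scales are not comparable across conventions, ratios are.
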