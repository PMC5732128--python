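# Methods

## The reconstruction problem

Multi-pinhole SPECT cameras acquire all projections simultaneously through
a static ring of pinhole-detector units.  Classical ML-EM reconstruction
updates an activity estimate `f` by

    f_new_j = f_old_j / Σ_i a_ij · Σ_i a_ij · p_i / Σ_k a_ik f_old_k ,

where `a_ij` is the probability that a decay in voxel `j` produces a count
in pixel `i` and `p` are the measured projections.  Any mismatch between
`a` and the true projection physics propagates into the image, which is
why quantitative SPECT normally needs attenuation/scatter corrections plus
a measured calibration factor.

`pinrecon` instead uses a *dual-matrix* update: the denominator projection
`q = Σ_k a_ik f_old_k` is computed by a Monte Carlo simulation that carries
the full photon physics, while the outer sums use an approximate
analytical ray-tracing back-projector `b_ij`:

    f_new_j = f_old_j / Σ_i b_ij · Σ_i b_ij · p_i / q_i .

Because the Monte Carlo forward model ties simulated counts to absolute
activity (each history carries the weight
`A_total · 1e6 · t · photons_per_decay / n_histories`), the reconstructed
voxel values are in MBq with no external calibration: if `q` falls short
of `p`, the multiplicative update raises the estimate until the absolute
count rates match.

The estimate is stored as two coupled datasets: the float activity volume
(MBq) and an integer history map, re-apportioned each iteration by
largest-remainder allocation so its entries sum exactly to the
per-iteration history budget.  The forward simulation emits exactly those
histories.

Dual-matrix updates forfeit the ML-EM monotone-likelihood guarantee; a
Poisson log-likelihood proxy is logged per iteration but never asserted.

## Monte Carlo forward model

Photons start uniformly inside their source voxel at 140.5 keV (single
photon per decay; the 0.885 branching fraction is a weight factor).
Transport through the voxelized density/material map samples free paths
against the local linear attenuation by marching across voxel boundaries;
interactions split into photoelectric absorption and Compton scattering
with Klein-Nishina angular sampling and the Compton energy shift, up to a
configurable scatter order (default 8).  Cross sections: photoelectric
from a compact embedded table (log-log interpolated); incoherent from the
closed-form Klein-Nishina cross-section times electron density, so the
attenuation channel and the sampled angular distribution come from the
same cross-section (free-electron approximation; coherent scatter,
binding and Doppler broadening neglected).  Materials are air and water.

Detection is ideal absorption with an optional Gaussian energy blur
(default 6% FWHM at the photopeak) and an energy window (default
140.5 keV ± 10%); the window enters as the analytic Gaussian window
probability, a small variance reduction over sampling the deposited
energy.  The CZT charge-transport physics of real cadmium-zinc-telluride
detectors is deliberately out of scope.

Per history and pinhole unit the estimator splits into two exactly
unbiased parts:

* **analytic primary** — a point is sampled uniformly on the aperture
  disc; the unscattered flux weight `cos θ_A · (π a²) / (4π s²)` times the
  deterministic attenuation `exp(-τ)` along the line of sight is binned at
  the ray's detector intercept.  No pass/fail or survival sampling, so the
  primary component of the projections is essentially noise-free — the
  property the calibration-free update relies on at desk-scale history
  budgets.
* **forced scatter** — the emission direction is drawn uniformly over the
  cone subtending a disc of diameter four times the aperture diameter
  centred on the pinhole (weight Ω/4π), and the photon is traced through
  the object.  It is scored only if it scattered at least once (the
  unscattered through-aperture path is already covered), or, with
  knife-edge penetration enabled, if it missed the opening.

A forced photon is scored only on the unit it was forced toward: the
forcing captures small-angle scatter near each line of sight but
under-samples large-angle and cross-unit scatter.  This is inherent to
the technique; since reconstruction uses the identical estimator that
generated the study data, the self-consistency experiments are unaffected,
but absolute scatter fractions in the recorded spectra are lower bounds.

Randomness is counter-based: each history seeds an xorshift64* stream by
splitmix64-hashing (master seed, history index), so results are bit-for-bit
reproducible and independent of voxel traversal order.  Decay during
acquisition is ignored (acquisition times are minutes against a 6-h
half-life).

## Ray-tracing back-projector

The backward model deliberately assumes (a) no attenuation or scatter,
(b) an infinitesimal aperture, (c) angle-independent efficiency.  For
voxel `j` and unit `k` the voxel centre is rotated into the pinhole frame
(`z'` along the axis), projected to the detector intercept
`(-M x', -M y')` with magnification `M = H/(R - z')`, and spread over an
`n × n` cell-centred lattice of width `m·M` (the voxel footprint), with

    n = floor(2 + 60 / (1 + (R - z')^0.8) + 0.5),   (R - z') in cm,

bounded by [2, 62] and decreasing with distance to mimic pinhole
sensitivity at bounded cost.  `b_ij` is the number of lattice points in
pixel `i` divided by `Σ_k n²_{j,k}` over the units the voxel lies in front
of.  Lattice points falling off the active detector area stay in the
denominator but contribute nothing; an alternative normalization that
counts only on-detector points is selectable (`denominator="on_detector"`)
because the two readings of the normalization are both defensible.  Voxels
at or behind a pinhole plane skip that unit entirely; voxels with no
contributions anywhere have zero sensitivity and are excluded from
updates.

The operator is iteration-independent and is materialized once per
(geometry, grid) as a sparse matrix; the sensitivity map `Σ_i b_ij` is its
product with unit projections.  The distance unit of the lattice heuristic
is a configurable scale (default cm, the convention of the formula above).
Pixel binning uses half-open floor-convention bins centred on the
pinhole-axis intercept, identically in the forward and backward models.

## Camera geometry

The default camera is a synthetic 19-unit arc: pinhole axes at equally
spaced polar angles spanning 180° in the transaxial plane, all with
R = 180 mm, H = 120 mm, 5-mm apertures, and 32 × 32 detectors of
78.7/32 mm pitch.  (The commercial camera this emulates has a proprietary
per-unit geometry with tilted lateral detectors; every parameter here is
loadable from a flat-text config so nothing is hard-coded.)  With these
distances the detector width limits the fully sampled transaxial field of
view to ≈ 118 mm, less than the nominal 190-mm FOV sphere; reconstruction
therefore initializes on the intersection of the FOV sphere with the voxel
grid, and edge voxels simply have reduced sensitivity.  Detector tilt is
supported in the forward model through general plane intersection; the
back-projector always assumes a perpendicular detector, consistent with
its other approximations.

## Phantoms

All phantoms are voxel-centre-inclusion masks on a cubic grid (default
4-mm voxels, matching the clinical reconstruction voxel size):

* **sphere** — uniform activity, radius from the volume; totals are exact
  by construction.
* **NEMA spheres in torso** — six spheres (0.5, 1, 2, 4, 8, 16 mL) at one
  activity concentration on a 50-mm ring in a plane tilted 45° about the
  x-axis (emulating the short-axis mounting disk; ring radius and tilt are
  conventions, not measured values), inside an elliptical water-or-air
  torso of 150 × 100 mm semi-axes.  Sphere interiors are always
  water-equivalent.
* **point-source grid** — single-voxel sources on an n³ cubic grid
  (default 20-mm spacing) centred on the origin.  With 4-mm voxels the
  true positions are voxel-aligned, so a perfect reconstruction localizes
  each peak exactly; residual plane-distance errors measure reconstruction
  artefacts only, without the sub-voxel quantization a physical
  translation stage would add.
* **cardiac phantom** — a half-ellipsoid myocardial shell (wall 10.3 mm)
  around a 38-mm water-filled ventricular cavity; the outer long semi-axis
  is solved so the voxelized shell volume matches 120 mL (within 5%),
  starting from the closed-form continuous solution and refining by a
  deterministic scan.  At 21.1 MBq the shell concentration is
  ≈ 0.18 MBq/mL.
* **density from attenuation** — a linear rescale of a μ-map by the water
  coefficient at the reference energy, labelling voxels above 5% of water
  density as water.

What the generators do *not* emulate: measurement noise in the reference
activities, phantom walls and mounting hardware, detector gaps and
per-unit geometry differences, CZT spectral tailing, patient motion.
Passing the simulation studies therefore demonstrates the internal
consistency and normalization of the reconstruction chain, not agreement
with any physical camera.

## Quantification analyses

* **ARC/TARC** — estimated over reference activity in a spherical VOI of
  the physical diameter (ARC) or the physical diameter + 8 mm — two voxel
  lengths — (TARC), by Eq. ARC = A_E / A_R.
* **plane-distance analysis** — volumes are filtered with a fixed 7³
  Gaussian kernel (σ = 1 voxel, renormalized to unit sum), the maximum
  voxel located, positions grouped into planes by the known true grid,
  per-plane mean coordinates differenced between adjacent planes, and the
  standard deviation of the per-point differences reported (points paired
  by lateral position; population standard deviation).  Grouping uses the
  known true positions — simulation makes the manual plane identification
  a physical measurement needs unnecessary.
* **post-filters** — the same fixed-kernel Gaussian, and a radially
  symmetric 3-D Butterworth low-pass with gain `1/√(1 + (f/f_c)^{2n})`,
  `f` in cycles/cm and `f_c` the −3 dB cutoff (stated explicitly because
  Butterworth conventions vary); DC gain 1 preserves the mean.
* **display helpers** — maximum-intensity projections and cubic-kernel
  binary dilation (for myocardial VOIs, the known shell mask plus one 3³
  dilation stands in for the manual delineation used on measured data).

## Numerical choices

* Pixel ratios are guarded: `q` is floored at `ratio_epsilon` (default
  1e-3) times the mean nonzero simulated pixel value, so empty simulated
  pixels cap rather than explode the ratio.
* Voxels with positive activity but zero allocated histories are still
  updated through the back-projection — the float map is authoritative,
  preventing premature zero-locking.
* Iteration `i` seeds its forward simulation with `seed + i`; studies
  derive generation and reconstruction seeds from one master seed.
* The initial estimate is a uniform 1 MBq over the in-FOV voxels; the
  multiplicative update rescales the magnitude within a few iterations.
* Half-open floor-convention bins everywhere (pixels, voxels); boundary
  points belong to the bin whose lower edge they sit on.
* Low-energy transport cutoff 10 keV; scattered photons below it are
  absorbed.

## Study conditions and problem sizes

The bundled studies run at desk scale on one CPU: sphere
self-consistency on a 35³ grid with 10⁵ histories/iteration and 20
iterations (generation 10⁶ histories, no Poisson noise, recovered in a
VOI of twice the sphere diameter — errors come out at 1.5–1.6%,
reflecting the remaining convergence residual at 20 iterations); the
six-sphere torso study on a 44³ grid, 4 × 10⁵ generation histories,
10⁵ histories/iteration, 40 iterations (TARCs within 8% of unity, worst
for the 0.5-mL sphere); the point-grid study with a 3³ grid of sources,
10⁵ generation histories and 2.5 × 10⁴ histories/iteration over 20
iterations.  Larger grids and budgets only sharpen the same quantities.

## Known limitations

* Scatter reaching a detector from initial directions outside its forcing
  cone is under-sampled; recorded scatter fractions are lower bounds.
* The knife-edge penetration model is a simple wedge-chord attenuation
  with a configurable opening angle; no edge scatter.
* Air and water are the only materials; bone or contrast media would need
  additional photoelectric table rows.
* The back-projector models no finite-aperture blur, so resolution
  recovery rests entirely on the forward model; ARC for small spheres
  converges slowly with iterations, as expected for EM-type resolution
  compensation.
* OS-EM acceleration and regularization are deliberately not implemented.
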