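# pinrecon

Calibration-free Monte Carlo pinhole SPECT reconstruction.

`pinrecon` is for physicists and imaging researchers who want absolute
activity quantification (MBq, not arbitrary units) from multi-pinhole
emission tomography — the camera class used for dedicated myocardial
perfusion SPECT — without a measured calibration factor, and who want to
study that reconstruction chain end to end on purely simulated data.

## The method

The package implements a **dual-matrix ML-EM** loop.  Classical ML-EM
updates the activity estimate `f` with one system matrix `a`:

    f_j^new = f_j^old / Σ_i a_ij · Σ_i a_ij · p_i / Σ_k a_ik f_k^old .

Here the two roles are split:

* the **forward projection** `q_i = Σ_k a_ik f_k^old` is a Monte Carlo
  simulation with the full photon physics — non-homogeneous attenuation,
  Klein–Nishina Compton scatter in the object, finite pinhole apertures,
  energy windowing — realized per iteration from an integer history map,
  never as a stored matrix;
* the **back-projection** uses an approximate analytical ray-tracing model
  `b_ij` (no attenuation, infinitesimal aperture, angle-independent
  efficiency): each voxel's detector intercept `(-Mx', -My')`, with
  magnification `M = H/(R − z')`, is spread over an `n×n` lattice of width
  `mM`, `n = ⌊2 + 60/(1 + (R−z')^0.8) + 0.5⌋ ∈ [2, 62]`, and
  `b_ij = n_ij / Σ_k n²_{j,k}`.

Because every simulated history carries the absolute weight
`A_total · 10⁶ decays/s/MBq · t · photons-per-decay / n_histories`, the
simulated counts and the activity estimate stay in a fixed relationship,
and the multiplicative update drives the estimate to the activity that
reproduces the measured count rate — no calibration input anywhere.

The package also ships the phantom generators (spheres, NEMA sphere set
in an elliptical torso, point-source grids, a cardiac shell phantom), the
quantification analyses (activity recovery coefficients ARC/TARC,
plane-distance spatial-integrity analysis, line profiles, Gaussian and
Butterworth post-filters, MIPs), and an Interfile-style projection format.

## Worked example

Simulate a 9-mL, 1-MBq sphere with the 19-unit pinhole arc, reconstruct
it with the matched forward model, and read off the absolute activity:

```python
from pinrecon import (VoxelGrid, default_arc_geometry, PhysicsTables,
                      ReconstructionConfig, reconstruct, allocate_histories,
                      SimulationConfig, forward_project)
from pinrecon.phantoms import make_sphere, uniform_air_density
from pinrecon.analysis import spherical_voi_mask, recovery_coefficient

grid = VoxelGrid(35, 4.0)                    # 35^3 voxels, 4 mm
geometry = default_arc_geometry(K=19)        # 19-unit pinhole arc
tables = PhysicsTables.default()
density = uniform_air_density(grid)

truth = make_sphere(grid, center=(0, 0, 0), volume_ml=9.0, activity_mbq=1.0)
measured = forward_project(
    allocate_histories(truth, 500_000), truth.total, 60.0,
    geometry, density, tables, SimulationConfig(n_histories=500_000, seed=7),
)
print(f"simulated projections: {measured.counts.sum():.0f} expected counts")

config = ReconstructionConfig(n_iterations=20, histories_per_iteration=100_000, seed=1)
result = reconstruct(measured, geometry, density, tables, config)
voi = spherical_voi_mask(grid, (0, 0, 0), diameter=51.6)   # twice the sphere diameter
rec = recovery_coefficient(result.state.activity, voi, reference_mbq=1.0)
print(f"recovered activity: {rec.A_E:.3f} MBq (truth 1.000, TARC-style VOI)")
print(f"relative error: {100 * (rec.coefficient - 1):+.1f} %")
```

Output:

```
simulated projections: 48578 expected counts
recovered activity: 1.017 MBq (truth 1.000, TARC-style VOI)
relative error: +1.7 %
```

The +1.7% is the convergence residual of 20 EM iterations — the recovered
activity was obtained with no calibration factor.  The same pipeline is
available from the shell:

```sh
pinrecon phantom sphere --grid-n 35 --out ph
pinrecon simulate --activity ph_activity.hdr --histories 500000 --seed 7 --out proj.hdr
pinrecon reconstruct --projections proj.hdr --grid-n 35 --iterations 20 --out recon.hdr
pinrecon analyze --volume recon.hdr --truth ph_activity.hdr --voi 0,0,0,25.8 --report report.json
```

Every command writes a reproducibility manifest beside its output.

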