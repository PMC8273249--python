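# spfdloc

EEG source localization on voxelized volume-conductor head models:
a scalar-potential finite-difference (SPFD) forward solver, lead-field
matrices built by the reciprocity principle, and a matching-pursuit
sparse inverse localizer, with synthetic layered-sphere phantoms and a
Monte-Carlo evaluation harness.

## The problem

An EEG electrode array measures scalp potentials produced by a small
cortical current dipole. Recovering the dipole's position — the inverse
problem — requires (1) an accurate forward model of how currents in the
head produce scalp potentials, which depends strongly on the tissue
conductivity distribution (the thin, highly conductive CSF layer in
particular), and (2) an inverse solver that scales to millions of
candidate source voxels.

`spfdloc` implements the full stack for voxel head models:

- **Forward (SPFD)**: the quasi-static equation ∇·(σ∇φ) = −∇·J is
  discretized on the voxel grid's node lattice. Each lattice edge gets a
  conductance S = σ̄·h (σ̄ the mean conductivity of the up-to-4 voxels
  sharing the edge), and Kirchhoff's current law at every node gives a
  sparse symmetric system Σₙ Sₙ(φ₀ − φₙ) = I₀. It is solved by SOR, by a
  geometric multigrid V-cycle, or by V-cycle-preconditioned conjugate
  gradients, to a relative residual below 10⁻⁶. Current density follows
  as j = −σ∇φ.
- **Lead field by reciprocity**: the M × 3N matrix L maps gray-matter
  current components to ground-referenced electrode potentials, Lj = φ.
  Instead of 3N dipole solves, one forward solve per non-ground
  electrode (74 for the 75-electrode 10-10 montage) injects current
  between that electrode and the ground; row m of L is the induced
  electric field at every gray voxel divided by the injection current.
- **Inverse (matching pursuit)**: the estimated source is the column of
  L most correlated with the observation,
  corrcoef(i) = φ·Lᵢ/(‖φ‖‖Lᵢ‖), i = 1…3N, with O(N) time and memory;
  greedy iteration on the least-squares residual handles multiple
  sources, and a final forward solve turns the estimate into a
  Kirchhoff-consistent current-density map.
- **Phantoms and evaluation**: five-shell spheres (scalp, skull, CSF,
  gray, white) in four conductivity variants — segmented, homogeneous,
  CSF-insert, and segmentation-free (smoothed conductivity) — plus
  10-20/10-10 montage placement, SNR-controlled Gaussian noise,
  Monte-Carlo error statistics, cumulative distributions, depth-error
  correlations and pairwise t-tests between head models.

## Worked example

```python
import numpy as np
import spfdloc as sl
from spfdloc.forward import DipoleSource, dipole_source_term

labels  = sl.make_layered_sphere(spacing_mm=4.0, radii_mm=(44, 38, 32, 28, 18))
sigma   = sl.assign_conductivity(labels)          # Table of tissue conductivities
gm      = sl.gray_matter_index(labels)
montage = sl.place_montage(labels, "10-10")       # 75 electrodes

solver = sl.SPFDSolver(sigma, pin_node=tuple(montage.node_index[montage.ground]))
lfm    = sl.build_lfm(sigma, montage, gm, solver=solver)

vox    = gm.voxel_list[gm.n // 2]
dipole = DipoleSource.at_voxel(sigma.grid, vox, axis=1, sign=-1)
phi    = sl.reference_potentials(
    solver.solve(dipole_source_term(dipole, sigma.grid)), montage)
est    = sl.mp_localize(lfm, phi)
print(tuple(int(v) for v in est.est_voxel), abs(est.corr))
```

prints

```
(12, 12, 17) 0.9999999949560286
```

— the exact source voxel (`gm.voxel_list[gm.n // 2]`) with correlation 1
up to solver tolerance: noise-free potentials from a matched model are
literally a scaled lead-field column, so the localization error is 0 mm. The scripts in `examples/` walk through each
capability (phantom variants, forward solve, lead field + localization,
noise Monte-Carlo, lead-field mismatch, current-density reconstruction);
`examples/04_noise_monte_carlo.py` prints the mean ± SD error table over
SNR ∞ → 0 dB and the fraction of errors below 10 mm.

A thin CLI mirrors the pipeline for shell use:

```bash
spfdloc phantom --model anatomical --spacing 2 --out sigma.nii.gz --labels-out labels.nii.gz
spfdloc leadfield --model sigma.nii.gz --labels labels.nii.gz --system 10-10 --out lfm.h5
spfdloc localize --lfm lfm.h5 --potentials phi.csv --out result.json
spfdloc evaluate --config exp.yaml --out report/
```

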