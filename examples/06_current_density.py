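"""Reconstruct the current-density distribution of an estimated source.

The matching-pursuit coefficient alone does not satisfy Kirchhoff's
current law, so the package re-solves the forward problem with a dipole
at the estimated location and derives j = -sigma grad(phi) per voxel —
a physically consistent current pattern whose peak marks the source.
"""

import numpy as np

import spfdloc as sl
from spfdloc.forward import DipoleSource, dipole_source_term

labels = sl.make_layered_sphere(spacing_mm=4.0, radii_mm=(44, 38, 32, 28, 18))
sigma = sl.assign_conductivity(labels)
gm = sl.gray_matter_index(labels)
montage = sl.place_montage(labels, "10-10")
solver = sl.SPFDSolver(sigma, pin_node=tuple(montage.node_index[montage.ground]))
lfm = sl.build_lfm(sigma, montage, gm, solver=solver)

vox = gm.voxel_list[gm.n // 3]
dipole = DipoleSource.at_voxel(sigma.grid, vox, axis=0, sign=1)
phi0 = sl.reference_potentials(
    solver.solve(dipole_source_term(dipole, sigma.grid)), montage
)
phi = sl.add_noise(phi0, 10.0, np.random.default_rng(2))

est = sl.mp_localize(lfm, phi)
j = sl.reconstruct_distribution(est, sigma, solver=solver)
mag = j.magnitude()
peak = np.unravel_index(np.argmax(mag), sigma.grid.shape)
print(f"true dipole voxel      {tuple(int(v) for v in vox)}")
print(f"estimated source voxel {tuple(int(v) for v in est.est_voxel)} (SNR 10 dB)")
print(f"peak |j| voxel         {tuple(int(v) for v in peak)}  "
      f"|j| = {mag[peak]:.3e} A/m^2")
err = np.linalg.norm(sigma.grid.voxel_centers_mm(np.array(peak))
                     - sigma.grid.voxel_centers_mm(vox))
print(f"distance peak-to-true: {err:.1f} mm")
# The reconstructed current concentrates at the estimated source; its
# distance to the true dipole grows as the SNR falls.
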