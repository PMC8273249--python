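"""Reciprocity-based lead-field matrix (LFM) construction.

The LFM ``L`` maps gray-matter current sources to ground-referenced
electrode potentials, ``L j = phi``.  Building it column-by-column would
take one forward solve per gray voxel and component (3N solves); the
reciprocity principle reduces this to one solve per non-ground electrode
(M - 1 solves): inject a current I between electrode m and the ground,
solve the forward problem once, and read off the induced electric field
at every gray voxel.  Row m of L is that field divided by I.

Each gray voxel's field component is sampled on the voxel's base lattice
edge — the same edge a one-edge test dipole at that voxel occupies — so
the discrete reciprocity identity between L and direct dipole solves is
exact up to solver tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward import (
    SPFDSolver,
    SolverConfig,
    electrode_pair_source,
)
from .montage import ElectrodeMontage, ScalpPotentials
from .phantom import ConductivityVolume, GrayMatterIndex

__all__ = ["LeadFieldMatrix", "build_lfm", "lfm_predict"]

logger = logging.getLogger(__name__)

_MM = 1.0e-3


@dataclass
class LeadFieldMatrix:
    """M x 3N lead-field matrix.

    Rows follow montage order (the ground row is identically zero);
    columns are voxel-major with x, y, z interleaved: column ``3n + c``
    is component c of gray voxel n in the gray-matter index ordering.
    Entries are E/I in (V/m)/A.
    """

    values: np.ndarray  # (M, 3N)
    injection_current: float
    montage: ElectrodeMontage
    gm: GrayMatterIndex

    def __post_init__(self) -> None:
        m = self.montage.n_electrodes
        if self.values.shape != (m, 3 * self.gm.n):
            raise ValueError(
                f"lead field shape {self.values.shape} does not match "
                f"M={m}, N={self.gm.n}"
            )

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gm.n

    def column_norms(self) -> np.ndarray:
        """Euclidean norms of the 3N columns (cached)."""
        if not hasattr(self, "_col_norms"):
            self._col_norms = np.linalg.norm(self.values, axis=0)
        return self._col_norms

    def column_to_source(self, col: int) -> tuple[np.ndarray, int]:
        """Column index -> (gray voxel (i,j,k), component axis)."""
        n, axis = divmod(int(col), 3)
        return self.gm.voxel_list[n], axis

    def column_location_mm(self, col: int) -> np.ndarray:
        """World location (mm) of the gray voxel a column belongs to."""
        vox, _ = self.column_to_source(col)
        return self.gm.grid.voxel_centers_mm(vox)


def build_lfm(
    sigma: ConductivityVolume,
    montage: ElectrodeMontage,
    gm: GrayMatterIndex,
    config: SolverConfig | None = None,
    injection_current: float = 1e-3,
    method: str = "mgcg",
    solver: SPFDSolver | None = None,
) -> LeadFieldMatrix:
    """Build the LFM with one forward solve per non-ground electrode.

    The solver is pinned at the ground electrode's node, so every solved
    potential field is already ground-referenced.  A pre-built solver for
    the same volume may be passed to reuse its hierarchy.
    """
    ground_node = tuple(int(v) for v in montage.node_index[montage.ground])
    if solver is None:
        solver = SPFDSolver(sigma, config, pin_node=ground_node)
    elif solver.pin_node != ground_node:
        raise ValueError("reused solver must be pinned at the montage ground node")

    M, N = montage.n_electrodes, gm.n
    h_m = sigma.grid.spacing * _MM
    idx = gm.voxel_list
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]

    L = np.zeros((M, 3 * N))
    n_solved = 0
    for m in range(M):
        if m == montage.ground:
            continue
        src = electrode_pair_source(montage, m, injection_current, sigma.grid)
        fld = solver.solve(src, method=method)
        n_solved += 1
        logger.info(
            "lead field: electrode %s (%d/%d), %d iterations, residual %.2e",
            montage.names[m], n_solved, M - 1, fld.n_iter, fld.rel_residual,
        )
        p = fld.phi
        # E = -grad(phi) sampled on each voxel's base edge per component
        L[m, 0::3] = (p[i, j, k] - p[i + 1, j, k]) / h_m
        L[m, 1::3] = (p[i, j, k] - p[i, j + 1, k]) / h_m
        L[m, 2::3] = (p[i, j, k] - p[i, j, k + 1]) / h_m
    L /= injection_current
    logger.info("lead field complete: %d forward solves for %d electrodes", n_solved, M)
    return LeadFieldMatrix(
        values=L, injection_current=injection_current, montage=montage, gm=gm
    )


def lfm_predict(L: LeadFieldMatrix, j: np.ndarray) -> ScalpPotentials:
    """Predict referenced scalp potentials, phi = L j.

    ``j`` is a length-3N vector in the LFM's column ordering (dense or
    scipy sparse); the ground entry of the result is exactly 0 because
    the ground row of L is zero.
    """
    j = np.asarray(j if not hasattr(j, "toarray") else j.toarray()).ravel()
    if j.size != L.values.shape[1]:
        raise ValueError(
            f"source vector length {j.size} != 3N = {L.values.shape[1]}"
        )
    phi = L.values @ j
    return ScalpPotentials(phi=phi, ground=L.montage.ground)
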