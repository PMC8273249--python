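"""Scalar-potential finite-difference (SPFD) forward solver.

The quasi-static volume-conduction equation ``div(sigma grad phi) = -div J``
is discretized on the node lattice of a voxel grid.  Each lattice edge gets
a conductance derived from the (up to four) voxels sharing it, and
Kirchhoff's current law at every node yields a symmetric system

    sum_n S_n (phi_0 - phi_n) = I_0

with ``I_0`` the current injected at the node (a current dipole is a +/-I
pair one edge apart; a lead-field injection is a +/-I electrode pair).  Air
is a pure Neumann boundary realized by zero-conductance edges, and the
constant nullspace is removed by pinning one reference node to 0 V.

Systems are solved by SOR sweeps, by a geometric multigrid V-cycle with
SOR smoothing (factor-2 coarsening, coarse operators rediscretized from
block-averaged conductivities, direct solve at the coarsest level), or by
sparse direct factorization for small grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import ndimage
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from . import _kernels
from .phantom import ConductivityVolume, TissueLabelVolume, VoxelGrid

__all__ = [
    "SolverConfig",
    "EdgeConductances",
    "SourceTerm",
    "DipoleSource",
    "PotentialField",
    "CurrentDensityField",
    "AssembledSystem",
    "edge_conductances",
    "assemble_system",
    "dipole_source_term",
    "electrode_pair_source",
    "SPFDSolver",
    "solve_sor",
    "solve_multigrid",
    "current_density",
]

_MM = 1.0e-3  # mm -> m


@dataclass(frozen=True)
class SolverConfig:
    """Iterative-solver parameters.

    ``tol`` is the relative residual ||b - A x|| / ||b|| at which a solve
    is declared converged.  ``sor_omega`` drives plain SOR; the multigrid
    smoother uses the milder ``mg_smooth_omega`` (over-relaxation close to
    2 accelerates standalone SOR but is a poor smoother).  ``mg_levels``
    of None coarsens by 2 until the coarsest grid has fewer than
    ``min_coarse_voxels`` voxels along some axis.
    """

    tol: float = 1e-6
    max_iter: int = 50_000
    sor_omega: float = 1.9
    mg_levels: int | None = None
    mg_pre_sweeps: int = 2
    mg_post_sweeps: int = 2
    mg_smooth_omega: float = 1.2
    mg_max_cycles: int = 200
    min_coarse_voxels: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.tol < 1):
            raise ValueError("tol must be in (0, 1)")
        if not (1 <= self.sor_omega < 2):
            raise ValueError("sor_omega must be in [1, 2)")
        if self.mg_levels is not None and self.mg_levels < 1:
            raise ValueError("mg_levels must be >= 1")


@dataclass
class EdgeConductances:
    """Per-edge conductances (siemens) on the node lattice of ``grid``."""

    grid: VoxelGrid
    Sx: np.ndarray  # (nx, ny+1, nz+1)
    Sy: np.ndarray  # (nx+1, ny, nz+1)
    Sz: np.ndarray  # (nx+1, ny+1, nz)

    def node_diagonal(self) -> np.ndarray:
        """Sum of incident edge conductances at every lattice node."""
        n0, n1, n2 = self.grid.node_shape
        d = np.zeros((n0, n1, n2))
        d[:-1] += self.Sx
        d[1:] += self.Sx
        d[:, :-1] += self.Sy
        d[:, 1:] += self.Sy
        d[:, :, :-1] += self.Sz
        d[:, :, 1:] += self.Sz
        return d


@dataclass
class SourceTerm:
    """Injected nodal currents (amperes) on the node lattice."""

    rhs: np.ndarray  # node_shape, float64
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DipoleSource:
    """One-edge current dipole: -I at ``node_minus``, +I at ``node_plus``.

    The two pole nodes are one lattice edge apart along a signed
    coordinate axis; the dipole moment is ``current * length`` (A m)
    pointing from the negative to the positive pole.
    """

    node_minus: tuple[int, int, int]
    axis: int  # 0, 1, 2
    sign: int  # +1 or -1
    length_mm: float
    current: float = 1e-3

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    @property
    def node_plus(self) -> tuple[int, int, int]:
        step = [0, 0, 0]
        step[self.axis] = self.sign
        return tuple(a + s for a, s in zip(self.node_minus, step))

    @property
    def axis_vector(self) -> np.ndarray:
        v = np.zeros(3)
        v[self.axis] = float(self.sign)
        return v

    @property
    def moment_am(self) -> np.ndarray:
        """Dipole moment in A m."""
        return self.axis_vector * self.current * self.length_mm * _MM

    @classmethod
    def at_voxel(
        cls,
        grid: VoxelGrid,
        voxel_ijk,
        axis: int,
        sign: int = 1,
        current: float = 1e-3,
    ) -> "DipoleSource":
        """Dipole on the base edge of a voxel along ``axis``.

        The dipole occupies the lattice edge from the voxel's base node
        (its corner nearest the grid origin) to the next node along
        ``axis``; this is the same edge the lead-field matrix samples for
        that voxel/component, so matched forward and inverse models use
        identical discrete sources.
        """
        i, j, k = (int(v) for v in voxel_ijk)
        base = (i, j, k)
        if sign >= 0:
            return cls(base, axis, 1, grid.spacing, current)
        step = [0, 0, 0]
        step[axis] = 1
        minus = tuple(a + s for a, s in zip(base, step))
        return cls(minus, axis, -1, grid.spacing, current)


@dataclass
class PotentialField:
    """Node potentials (volts) with solver diagnostics."""

    phi: np.ndarray  # node_shape
    grid: VoxelGrid
    method: str = ""
    n_iter: int = 0
    rel_residual: float = 0.0
    residual_history: np.ndarray | None = None

    def at_node(self, node) -> float:
        return float(self.phi[tuple(int(v) for v in node)])


@dataclass
class CurrentDensityField:
    """Per-voxel current density vectors (A/m^2)."""

    j: np.ndarray  # grid.shape + (3,)
    grid: VoxelGrid

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.j, axis=-1)


def _edge_conductances_raw(sigma: np.ndarray, spacing_mm: float):
    """Edge conductances from a raw conductivity array.

    Each edge is bordered by up to four voxels; its conductance is the
    arithmetic mean of their conductivities (missing/air voxels count as
    zero in the mean) times the edge length, i.e. sigma_bar * h for cubic
    voxels whose cross-section h^2 cancels one power of the length h.
    """
    h_m = spacing_mm * _MM

    def mean4(edge_axis):
        pad = [(1, 1)] * 3
        pad[edge_axis] = (0, 0)
        p = np.pad(sigma, pad)
        # the four voxels sharing an edge differ in the two transverse axes
        t1, t2 = [ax for ax in range(3) if ax != edge_axis]
        lo1 = [slice(None)] * 3
        hi1 = [slice(None)] * 3
        lo1[t1], hi1[t1] = slice(None, -1), slice(1, None)
        lo2 = [slice(None)] * 3
        hi2 = [slice(None)] * 3
        lo2[t2], hi2[t2] = slice(None, -1), slice(1, None)

        def sl(s1, s2):
            out = [slice(None)] * 3
            out[t1] = s1[t1]
            out[t2] = s2[t2]
            return tuple(out)

        s = (
            p[sl(lo1, lo2)] + p[sl(lo1, hi2)] + p[sl(hi1, lo2)] + p[sl(hi1, hi2)]
        )
        return 0.25 * s * h_m

    return mean4(0), mean4(1), mean4(2)


def edge_conductances(sigma: ConductivityVolume) -> EdgeConductances:
    """Edge conductances S = sigma_bar * h for every lattice edge."""
    Sx, Sy, Sz = _edge_conductances_raw(sigma.sigma, sigma.grid.spacing)
    return EdgeConductances(grid=sigma.grid, Sx=Sx, Sy=Sy, Sz=Sz)


@dataclass
class AssembledSystem:
    """Sparse symmetric Kirchhoff operator restricted to head nodes.

    ``A`` is the (singular) edge-conductance graph Laplacian: row sums are
    zero and the constant vector spans its nullspace.  ``head_flat`` maps
    reduced indices back to flat node-lattice indices.
    """

    A: sp.csr_matrix
    head_flat: np.ndarray
    node_shape: tuple[int, int, int]

    def reduced_index(self) -> np.ndarray:
        """Flat lattice index -> reduced index (-1 off the head)."""
        idx = np.full(int(np.prod(self.node_shape)), -1, dtype=np.int64)
        idx[self.head_flat] = np.arange(self.head_flat.size)
        return idx


def assemble_system(S: EdgeConductances, check_connected: bool = True) -> AssembledSystem:
    """Assemble the sparse node-lattice Laplacian over head nodes."""
    node_shape = S.grid.node_shape
    diag = S.node_diagonal()
    head = diag > 0
    if not head.any():
        raise ValueError("no head nodes: conductivity volume is all air")
    flat_head = np.flatnonzero(head.ravel())
    red = np.full(int(np.prod(node_shape)), -1, dtype=np.int64)
    red[flat_head] = np.arange(flat_head.size)

    rows, cols, vals = [], [], []
    strides = np.array(
        [node_shape[1] * node_shape[2], node_shape[2], 1], dtype=np.int64
    )
    for axis, E in enumerate((S.Sx, S.Sy, S.Sz)):
        ii, jj, kk = np.nonzero(E)
        w = E[ii, jj, kk]
        a = ii * strides[0] + jj * strides[1] + kk * strides[2]
        b = a + strides[axis]
        rows.append(red[a])
        cols.append(red[b])
        vals.append(w)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    n = flat_head.size
    W = sp.coo_matrix((v, (r, c)), shape=(n, n))
    W = W + W.T
    A = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W
    A = A.tocsr()
    if check_connected:
        ncomp, _ = csgraph.connected_components(W, directed=False)
        if ncomp > 1:
            raise ValueError(
                f"head region has {ncomp} disconnected components; the "
                "potential is undefined between them"
            )
    return AssembledSystem(A=A, head_flat=flat_head, node_shape=node_shape)


def _node_in_tissue(labels: TissueLabelVolume, node, tissue_mask: np.ndarray) -> bool:
    """True if any of the <= 8 voxels touching the node is in the mask."""
    a, b, c = (int(v) for v in node)
    sl = tuple(
        slice(max(v - 1, 0), min(v + 1, n))
        for v, n in zip((a, b, c), labels.grid.shape)
    )
    return bool(tissue_mask[sl].any())


def dipole_source_term(
    d: DipoleSource,
    grid: VoxelGrid,
    labels: TissueLabelVolume | None = None,
    gray_tissue: str = "gray matter",
) -> SourceTerm:
    """Equivalent nodal-current source of a one-edge dipole.

    If ``labels`` is given, both pole nodes must touch gray matter.
    """
    rhs = np.zeros(grid.node_shape)
    minus, plus = d.node_minus, d.node_plus
    for node in (minus, plus):
        if any(v < 0 or v >= n for v, n in zip(node, grid.node_shape)):
            raise ValueError(f"dipole pole node {node} outside the grid")
    if labels is not None:
        gm = labels.mask_of(gray_tissue)
        for node in (minus, plus):
            if not _node_in_tissue(labels, node, gm):
                raise ValueError(f"dipole pole node {node} is not in gray matter")
    rhs[plus] += d.current
    rhs[minus] -= d.current
    return SourceTerm(rhs=rhs, meta={"kind": "dipole", "dipole": d})


def electrode_pair_source(montage, active_idx: int, current: float, grid: VoxelGrid) -> SourceTerm:
    """+I at the active electrode node, -I at the ground node."""
    if active_idx == montage.ground:
        raise ValueError("active electrode must differ from the ground electrode")
    rhs = np.zeros(grid.node_shape)
    a = tuple(int(v) for v in montage.node_index[active_idx])
    g = tuple(int(v) for v in montage.node_index[montage.ground])
    rhs[a] += current
    rhs[g] -= current
    return SourceTerm(
        rhs=rhs,
        meta={"kind": "electrode_pair", "active": active_idx, "ground": montage.ground},
    )


# ---------------------------------------------------------------------------
# grid-transfer helpers (trilinear prolongation and its adjoint)


def _prolong_axis(c: np.ndarray, n_fine: int, axis: int) -> np.ndarray:
    c = np.moveaxis(c, axis, 0)
    m = c.shape[0] - 1
    f = np.zeros((2 * m + 1,) + c.shape[1:])
    f[0::2] = c
    f[1::2] = 0.5 * (c[:-1] + c[1:])
    return np.moveaxis(f[:n_fine], 0, axis)


def _restrict_axis(f: np.ndarray, axis: int) -> np.ndarray:
    f = np.moveaxis(f, axis, 0)
    n = f.shape[0]
    m = math.ceil((n - 1) / 2)
    if n < 2 * m + 1:
        pad = np.zeros((2 * m + 1 - n,) + f.shape[1:])
        f = np.concatenate([f, pad], axis=0)
    c = f[0::2].copy()
    odd = f[1::2]
    c[:-1] += 0.5 * odd
    c[1:] += 0.5 * odd
    return np.moveaxis(c, 0, axis)


def _prolong(c: np.ndarray, fine_shape) -> np.ndarray:
    out = c
    for ax in range(3):
        out = _prolong_axis(out, fine_shape[ax], ax)
    return out


def _restrict(f: np.ndarray) -> np.ndarray:
    out = f
    for ax in range(3):
        out = _restrict_axis(out, ax)
    return out


def _coarsen_sigma(sigma: np.ndarray) -> np.ndarray:
    """2x2x2 block-average of voxel conductivity (air-padded to even dims)."""
    shape = sigma.shape
    pad = [(0, s % 2) for s in shape]
    if any(p[1] for p in pad):
        sigma = np.pad(sigma, pad)
    m = tuple(s // 2 for s in sigma.shape)
    return sigma.reshape(m[0], 2, m[1], 2, m[2], 2).mean(axis=(1, 3, 5))


@dataclass
class _Level:
    spacing_mm: float
    Sx: np.ndarray
    Sy: np.ndarray
    Sz: np.ndarray
    diag: np.ndarray
    free: np.ndarray  # bool: head nodes minus the pinned node
    node_shape: tuple[int, int, int]
    pin: tuple[int, int, int]
    _lu: object = None  # cached coarsest-level factorization
    _lu_flat: np.ndarray | None = None


def _safe_diag(diag: np.ndarray, free: np.ndarray) -> np.ndarray:
    out = diag.copy()
    out[~free] = 1.0  # never divided by on skipped nodes, keep finite
    return out


class SPFDSolver:
    """SPFD system for one conductivity volume, reusable across sources.

    Building the solver assembles the edge conductances and (for
    multigrid) the coarse hierarchy once; every subsequent
    :meth:`solve` reuses them, which is what makes the one-solve-per-
    electrode lead-field construction cheap.
    """

    def __init__(
        self,
        sigma: ConductivityVolume,
        config: SolverConfig | None = None,
        pin_node: tuple[int, int, int] | None = None,
        check_connected: bool = True,
    ):
        self.sigma = sigma
        self.grid = sigma.grid
        self.config = config or SolverConfig()
        self.n_solves = 0

        if check_connected:
            lab, ncomp = ndimage.label(sigma.head_mask)
            del lab
            if ncomp > 1:
                raise ValueError(
                    f"head region has {ncomp} disconnected components"
                )

        level0 = self._make_level(sigma.sigma, self.grid.spacing, pin_node)
        self.levels = [level0]
        n_levels = self.config.mg_levels
        s = sigma.sigma
        pin = level0.pin
        while True:
            if n_levels is not None and len(self.levels) >= n_levels:
                break
            if min(s.shape) < self.config.min_coarse_voxels:
                break
            s = _coarsen_sigma(s)
            pin = tuple(p // 2 for p in pin)
            lvl = self._make_level(
                s, self.levels[-1].spacing_mm * 2, pin, allow_move_pin=True
            )
            self.levels.append(lvl)

    # -- construction ------------------------------------------------------

    def _make_level(self, sigma_arr, spacing_mm, pin_node, allow_move_pin=False):
        Sx, Sy, Sz = _edge_conductances_raw(sigma_arr, spacing_mm)
        node_shape = tuple(s + 1 for s in sigma_arr.shape)
        diag = np.zeros(node_shape)
        diag[:-1] += Sx
        diag[1:] += Sx
        diag[:, :-1] += Sy
        diag[:, 1:] += Sy
        diag[:, :, :-1] += Sz
        diag[:, :, 1:] += Sz
        head = diag > 0
        if not head.any():
            raise ValueError("conductivity volume is all air")
        if pin_node is None:
            pin_node = tuple(int(v) for v in np.argwhere(head)[0])
        pin_node = tuple(int(v) for v in pin_node)
        if not head[pin_node]:
            if not allow_move_pin:
                raise ValueError(f"pin node {pin_node} is not a head node")
            cand = np.argwhere(head)
            d2 = ((cand - np.asarray(pin_node)) ** 2).sum(axis=1)
            pin_node = tuple(int(v) for v in cand[int(np.argmin(d2))])
        free = head.copy()
        free[pin_node] = False
        return _Level(
            spacing_mm=spacing_mm,
            Sx=Sx,
            Sy=Sy,
            Sz=Sz,
            diag=_safe_diag(diag, head),
            free=free,
            node_shape=node_shape,
            pin=pin_node,
        )

    @property
    def pin_node(self) -> tuple[int, int, int]:
        return self.levels[0].pin

    # -- smoothing / residual ---------------------------------------------

    @staticmethod
    def _sweep(level: _Level, x, b, omega, forward=True):
        _kernels.sor_sweep(
            x, b, level.Sx, level.Sy, level.Sz, level.diag, level.free, omega, forward
        )

    @staticmethod
    def _residual(level: _Level, x, b):
        return _kernels.residual(
            x, b, level.Sx, level.Sy, level.Sz, level.diag, level.free
        )

    # -- coarsest-level direct solve --------------------------------------

    def _level_sparse(self, level: _Level):
        n0, n1, n2 = level.node_shape
        strides = np.array([n1 * n2, n2, 1], dtype=np.int64)
        free_flat = np.flatnonzero(level.free.ravel())
        red = np.full(n0 * n1 * n2, -1, dtype=np.int64)
        red[free_flat] = np.arange(free_flat.size)
        rows, cols, vals = [], [], []
        for axis, E in enumerate((level.Sx, level.Sy, level.Sz)):
            ii, jj, kk = np.nonzero(E)
            w = E[ii, jj, kk]
            a = ii * strides[0] + jj * strides[1] + kk * strides[2]
            b = a + strides[axis]
            ra, rb = red[a], red[b]
            keep = (ra >= 0) & (rb >= 0)
            rows.append(ra[keep])
            cols.append(rb[keep])
            vals.append(w[keep])
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        v = np.concatenate(vals)
        n = free_flat.size
        W = sp.coo_matrix((v, (r, c)), shape=(n, n))
        W = W + W.T
        diag_red = level.diag.ravel()[free_flat]
        A = sp.diags(diag_red) - W
        return A.tocsc(), free_flat

    def _coarse_solve(self, level: _Level, b):
        if level._lu is None:
            A, free_flat = self._level_sparse(level)
            level._lu = splu(A)
            level._lu_flat = free_flat
        x = np.zeros(int(np.prod(level.node_shape)))
        x[level._lu_flat] = level._lu.solve(b.ravel()[level._lu_flat])
        return x.reshape(level.node_shape)

    # -- V-cycle -----------------------------------------------------------

    def _vcycle(self, li: int, b, x):
        cfg = self.config
        level = self.levels[li]
        if li == len(self.levels) - 1:
            if len(self.levels) == 1:
                # degenerate 1-level hierarchy: pure smoothing
                for _ in range(cfg.mg_pre_sweeps + cfg.mg_post_sweeps):
                    self._sweep(level, x, b, cfg.mg_smooth_omega, forward=True)
            else:
                x += self._coarse_solve(level, b)
            return
        for _ in range(cfg.mg_pre_sweeps):
            self._sweep(level, x, b, cfg.mg_smooth_omega, forward=True)
        r = self._residual(level, x, b)
        rc = _restrict(r)
        coarse = self.levels[li + 1]
        rc[~coarse.free] = 0.0
        ec = np.zeros(coarse.node_shape)
        self._vcycle(li + 1, rc, ec)
        e = _prolong(ec, level.node_shape)
        e[~level.free] = 0.0
        x += e
        for _ in range(cfg.mg_post_sweeps):
            self._sweep(level, x, b, cfg.mg_smooth_omega, forward=False)

    # -- public solve ------------------------------------------------------

    def solve(
        self,
        source: SourceTerm | np.ndarray,
        method: str = "mgcg",
        x0: np.ndarray | None = None,
        tol: float | None = None,
    ) -> PotentialField:
        """Solve for node potentials; method is 'mg', 'sor' or 'direct'."""
        cfg = self.config
        tol = cfg.tol if tol is None else tol
        b = source.rhs if isinstance(source, SourceTerm) else np.asarray(source)
        if b.shape != self.levels[0].node_shape:
            raise ValueError("source term shape does not match the node lattice")
        level = self.levels[0]
        self.n_solves += 1

        bnorm = float(np.linalg.norm(b[level.free]))
        if bnorm == 0.0:
            return PotentialField(
                phi=np.zeros(level.node_shape),
                grid=self.grid,
                method=method,
                n_iter=0,
                rel_residual=0.0,
                residual_history=np.zeros(0),
            )

        if method == "direct":
            x = self._coarse_solve(level, b)
            r = self._residual(level, x, b)
            rel = float(np.linalg.norm(r[level.free])) / bnorm
            return PotentialField(
                phi=x, grid=self.grid, method="direct", n_iter=1,
                rel_residual=rel, residual_history=np.array([rel]),
            )

        x = np.zeros(level.node_shape) if x0 is None else x0.copy()
        history = []
        if method == "sor":
            check_every = 2
            for it in range(1, cfg.max_iter + 1):
                self._sweep(level, x, b, cfg.sor_omega, forward=True)
                if it % check_every == 0 or it == cfg.max_iter:
                    r = self._residual(level, x, b)
                    rel = float(np.linalg.norm(r[level.free])) / bnorm
                    history.append(rel)
                    if rel < tol:
                        return PotentialField(
                            phi=x, grid=self.grid, method="sor", n_iter=it,
                            rel_residual=rel,
                            residual_history=np.asarray(history),
                        )
            raise RuntimeError(
                f"SOR did not reach tol={tol:g} in {cfg.max_iter} sweeps "
                f"(residual {history[-1]:.3e}); history attached",
            )
        if method == "mg":
            for it in range(1, cfg.mg_max_cycles + 1):
                self._vcycle(0, b, x)
                r = self._residual(level, x, b)
                rel = float(np.linalg.norm(r[level.free])) / bnorm
                history.append(rel)
                if rel < tol:
                    return PotentialField(
                        phi=x, grid=self.grid, method="mg", n_iter=it,
                        rel_residual=rel, residual_history=np.asarray(history),
                    )
            raise RuntimeError(
                f"multigrid did not reach tol={tol:g} in {cfg.mg_max_cycles} "
                f"V-cycles (residual {history[-1]:.3e})"
            )
        if method == "mgcg":
            # conjugate gradients preconditioned by one symmetric V-cycle
            # (forward pre-smoothing, backward post-smoothing); robust to
            # the strong conductivity contrasts of segmented head models
            r = b.copy()
            r[~level.free] = 0.0
            z = np.zeros(level.node_shape)
            self._vcycle(0, r, z)
            z[~level.free] = 0.0
            p = z.copy()
            rz = float(np.dot(r.ravel(), z.ravel()))
            for it in range(1, cfg.mg_max_cycles + 1):
                Ap = -self._residual(level, p, np.zeros_like(p))
                alpha = rz / float(np.dot(p.ravel(), Ap.ravel()))
                x += alpha * p
                r -= alpha * Ap
                rel = float(np.linalg.norm(r[level.free])) / bnorm
                history.append(rel)
                if rel < tol:
                    return PotentialField(
                        phi=x, grid=self.grid, method="mgcg", n_iter=it,
                        rel_residual=rel, residual_history=np.asarray(history),
                    )
                z = np.zeros(level.node_shape)
                self._vcycle(0, r, z)
                z[~level.free] = 0.0
                rz_new = float(np.dot(r.ravel(), z.ravel()))
                p = z + (rz_new / rz) * p
                rz = rz_new
            raise RuntimeError(
                f"preconditioned CG did not reach tol={tol:g} in "
                f"{cfg.mg_max_cycles} iterations (residual {history[-1]:.3e})"
            )
        raise ValueError(f"unknown method {method!r}")


def solve_sor(
    sigma: ConductivityVolume,
    source: SourceTerm,
    config: SolverConfig | None = None,
    pin_node=None,
) -> PotentialField:
    """One-shot SOR solve (builds a single-level solver)."""
    solver = SPFDSolver(sigma, config, pin_node=pin_node)
    return solver.solve(source, method="sor")


def solve_multigrid(
    sigma: ConductivityVolume,
    source: SourceTerm,
    config: SolverConfig | None = None,
    pin_node=None,
) -> PotentialField:
    """One-shot geometric-multigrid solve."""
    solver = SPFDSolver(sigma, config, pin_node=pin_node)
    return solver.solve(source, method="mg")


def current_density(
    phi: PotentialField | np.ndarray, sigma: ConductivityVolume
) -> CurrentDensityField:
    """j = -sigma grad(phi) at voxel centers (A/m^2); zero on air.

    The gradient along each axis is the difference of the mean node
    potential on the voxel's opposing faces, i.e. the average of the four
    parallel edge differences.
    """
    p = phi.phi if isinstance(phi, PotentialField) else np.asarray(phi)
    grid = sigma.grid
    if p.shape != grid.node_shape:
        raise ValueError("potential field does not match the grid's node lattice")
    h_m = grid.spacing * _MM
    j = np.empty(grid.shape + (3,))

    fx = 0.25 * (p[:, :-1, :-1] + p[:, 1:, :-1] + p[:, :-1, 1:] + p[:, 1:, 1:])
    j[..., 0] = -(fx[1:] - fx[:-1]) / h_m
    fy = 0.25 * (p[:-1, :, :-1] + p[1:, :, :-1] + p[:-1, :, 1:] + p[1:, :, 1:])
    j[..., 1] = -(fy[:, 1:] - fy[:, :-1]) / h_m
    fz = 0.25 * (p[:-1, :-1, :] + p[1:, :-1, :] + p[:-1, 1:, :] + p[1:, 1:, :])
    j[..., 2] = -(fz[:, :, 1:] - fz[:, :, :-1]) / h_m

    j *= sigma.sigma[..., None]
    return CurrentDensityField(j=j, grid=grid)
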