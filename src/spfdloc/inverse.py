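"""Matching-pursuit source localization.

Brain activity measured by EEG is spatially sparse, so the inverse
problem is posed as sparse reconstruction over the lead-field dictionary:
the estimated source is the gray-matter voxel/component whose LFM column
is most correlated with the observed scalp potential vector,

    corrcoef(i) = phi . L_i / (||phi|| ||L_i||),    i = 1 .. 3N,

and its location is the voxel center of the winning column.  Memory and
time are O(N): only the M x 3N matrix and length-3N vectors are ever
formed.  For multiple sources the greedy pursuit iterates on the residual
after least-squares projection onto the columns selected so far.

By default the argmax is taken over |corrcoef| rather than the signed
value: a dipole of reversed polarity produces the negated potential
pattern, which the signed argmax would miss while carrying no extra
information about location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forward import (
    CurrentDensityField,
    DipoleSource,
    SPFDSolver,
    SolverConfig,
    current_density,
    dipole_source_term,
)
from .leadfield import LeadFieldMatrix
from .montage import ScalpPotentials
from .phantom import ConductivityVolume

__all__ = [
    "LocalizationResult",
    "correlate_columns",
    "mp_localize",
    "mp_iterative",
    "reconstruct_distribution",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass
class LocalizationResult:
    """One selected source: column, voxel, axis, location and correlation."""

    est_column: int
    est_voxel: np.ndarray  # (3,) int
    est_axis: int  # 0, 1, 2
    est_location_mm: np.ndarray  # (3,)
    corr: float
    sign: int = 1  # sign of the winning correlation
    all_corr: np.ndarray | None = None


def correlate_columns(L: LeadFieldMatrix, phi: ScalpPotentials | np.ndarray) -> np.ndarray:
    """Normalized inner product of phi with every LFM column.

    Zero-norm columns (gray voxels electrically shielded at coarse
    resolution) get correlation 0 by convention.
    """
    v = phi.phi if isinstance(phi, ScalpPotentials) else np.asarray(phi, dtype=float)
    if v.shape != (L.n_electrodes,):
        raise ValueError(f"potential vector has shape {v.shape}, expected ({L.n_electrodes},)")
    vnorm = np.linalg.norm(v)
    if vnorm == 0:
        raise ValueError("scalp potential vector is identically zero (no signal)")
    col_norms = L.column_norms()
    c = (v @ L.values) / vnorm
    out = np.zeros_like(c)
    np.divide(c, col_norms, out=out, where=col_norms > 0)
    return out


def _select(corr: np.ndarray, mode: str) -> int:
    if mode == "abs":
        score = np.abs(corr)
    elif mode == "signed":
        score = corr
    else:
        raise ValueError(f"mode must be 'abs' or 'signed', got {mode!r}")
    best = int(np.argmax(score))  # argmax takes the lowest index on ties
    ties = np.flatnonzero(score >= score[best] - _TIE_TOL)
    if ties.size > 1:
        logger.info(
            "correlation tie among %d columns; selecting lowest index %d",
            ties.size, best,
        )
    return best


def mp_localize(
    L: LeadFieldMatrix,
    phi: ScalpPotentials | np.ndarray,
    mode: str = "abs",
    keep_corr: bool = False,
) -> LocalizationResult:
    """Single-source matching-pursuit localization."""
    corr = correlate_columns(L, phi)
    best = _select(corr, mode)
    vox, axis = L.column_to_source(best)
    return LocalizationResult(
        est_column=best,
        est_voxel=np.asarray(vox),
        est_axis=axis,
        est_location_mm=L.column_location_mm(best),
        corr=float(corr[best]),
        sign=1 if corr[best] >= 0 else -1,
        all_corr=corr if keep_corr else None,
    )


def mp_iterative(
    L: LeadFieldMatrix,
    phi: ScalpPotentials | np.ndarray,
    k_sources: int = 1,
    mode: str = "abs",
) -> tuple[list[LocalizationResult], np.ndarray]:
    """Greedy matching pursuit for up to ``k_sources`` sources.

    After each selection the residual is the observation minus its
    least-squares projection onto all columns selected so far, so the
    residual norm is nonincreasing.  Returns the selections and the
    residual-norm history (entry 0 is ||phi||).  Stops early if the
    residual is numerically zero.
    """
    if k_sources < 1:
        raise ValueError("k_sources must be >= 1")
    v = phi.phi if isinstance(phi, ScalpPotentials) else np.asarray(phi, dtype=float)
    v = v.astype(np.float64)
    results: list[LocalizationResult] = []
    chosen: list[int] = []
    resid = v.copy()
    history = [float(np.linalg.norm(v))]
    eps = max(history[0], 1.0) * 1e-13
    for _ in range(k_sources):
        if np.linalg.norm(resid) <= eps:
            logger.info("residual at machine tolerance after %d sources", len(results))
            break
        corr = correlate_columns(L, resid)
        best = _select(corr, mode)
        chosen.append(best)
        vox, axis = L.column_to_source(best)
        results.append(
            LocalizationResult(
                est_column=best,
                est_voxel=np.asarray(vox),
                est_axis=axis,
                est_location_mm=L.column_location_mm(best),
                corr=float(corr[best]),
                sign=1 if corr[best] >= 0 else -1,
            )
        )
        basis = L.values[:, chosen]
        coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
        resid = v - basis @ coef
        history.append(float(np.linalg.norm(resid)))
    return results, np.asarray(history)


def reconstruct_distribution(
    est: LocalizationResult,
    sigma: ConductivityVolume,
    config: SolverConfig | None = None,
    current: float = 1e-3,
    solver: SPFDSolver | None = None,
    method: str = "mgcg",
) -> CurrentDensityField:
    """Current-density distribution of the estimated source.

    The matching-pursuit coefficient itself does not satisfy Kirchhoff's
    current law, so the distribution is obtained physically: place a
    one-edge dipole at the estimated voxel along the estimated axis and
    re-solve the forward problem, then take j = -sigma grad(phi).
    """
    d = DipoleSource.at_voxel(
        sigma.grid, est.est_voxel, est.est_axis, sign=est.sign, current=current
    )
    src = dipole_source_term(d, sigma.grid)
    if solver is None:
        solver = SPFDSolver(sigma, config)
    fld = solver.solve(src, method=method)
    return current_density(fld, sigma)
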