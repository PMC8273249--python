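"""Synthetic voxelized head phantoms.

Volume-conductor models for EEG forward/inverse experiments are built here
as concentric-shell spheres on a regular voxel grid.  Four variants mirror
the head-model families commonly compared in source-localization studies:

* ``anatomical`` — a multi-compartment segmented model (scalp, skull, CSF,
  gray matter, white matter), each tissue at its literature conductivity;
* ``homogeneous`` — every head voxel at the gray-matter conductivity;
* ``csf-insert`` — homogeneous brain/skull/scalp with the CSF shell kept at
  its own (highest-in-head) conductivity;
* ``segmentation-free`` — the segmented conductivity field smoothed inside
  the head mask, emulating models whose tissue transitions are gradual
  rather than abrupt.

All variants share one grid and one head mask, so lead fields built from
them are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "TissueLabelVolume",
    "ConductivityTable",
    "ConductivityVolume",
    "GrayMatterIndex",
    "TISSUE_CONDUCTIVITY_S_PER_M",
    "default_conductivity_table",
    "make_layered_sphere",
    "assign_conductivity",
    "make_homogeneous",
    "make_csf_insert",
    "make_segmentation_free",
    "gray_matter_index",
    "DEFAULT_RADII_MM",
    "DEFAULT_SHELL_TISSUES",
]

#: Low-frequency tissue conductivities in S/m (4-Cole-Cole model snapshot;
#: skin set to 0.1 S/m as the practical whole-skin value rather than the
#: stratum-corneum figure).
TISSUE_CONDUCTIVITY_S_PER_M: dict[str, float] = {
    "skin": 0.1000,
    "muscle": 0.2020,
    "fat": 0.0377,
    "bone (cort.)": 0.0200,
    "bone (canc.)": 0.0756,
    "cartilage": 0.1611,
    "gray matter": 0.0275,
    "white matter": 0.0277,
    "cerebellum": 0.0475,
    "csf": 2.0000,
    "humor": 1.5000,
    "blood": 0.6999,
    "mucous membrane": 0.0004,
    "dura": 0.5003,
}

#: Default 5-shell sphere: outer radius of each shell in mm, outermost first.
DEFAULT_RADII_MM = (85.0, 78.0, 72.0, 70.0, 55.0)
DEFAULT_SHELL_TISSUES = ("skin", "bone (cort.)", "csf", "gray matter", "white matter")


@dataclass(frozen=True)
class VoxelGrid:
    """Regular isotropic voxel grid.

    ``origin`` is the world (mm) coordinate of the *center* of voxel
    (0, 0, 0); the center of voxel (i, j, k) is ``origin + spacing*(i,j,k)``.
    Potentials live on the node lattice at voxel corners, shape + 1 per
    axis; node (a, b, c) sits at ``origin - spacing/2 + spacing*(a,b,c)``.
    """

    shape: tuple[int, int, int]
    spacing: float  # mm per voxel edge, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if len(self.shape) != 3 or any(int(s) < 3 for s in self.shape):
            raise ValueError(f"shape must be three components >= 3, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def node_shape(self) -> tuple[int, int, int]:
        return tuple(s + 1 for s in self.shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_shape))

    def voxel_centers_mm(self, ijk: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers, ijk of shape (..., 3)."""
        return np.asarray(self.origin) + self.spacing * np.asarray(ijk, dtype=float)

    def node_coords_mm(self, abc: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of lattice nodes, abc of shape (..., 3)."""
        half = self.spacing / 2.0
        return np.asarray(self.origin) - half + self.spacing * np.asarray(abc, dtype=float)

    def axis_coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates."""
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.shape[a]) for a in range(3)
        )


@dataclass
class TissueLabelVolume:
    """Integer tissue labels on a voxel grid; 0 is air/outside."""

    grid: VoxelGrid
    labels: np.ndarray  # int, grid.shape
    label_names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid shape")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def head_mask(self) -> np.ndarray:
        return self.labels != 0

    def mask_of(self, tissue: str) -> np.ndarray:
        ids = [k for k, v in self.label_names.items() if v.lower() == tissue.lower()]
        if not ids:
            raise KeyError(f"tissue {tissue!r} not present in label map")
        return np.isin(self.labels, ids)


@dataclass(frozen=True)
class ConductivityTable:
    """Tissue name -> conductivity (S/m)."""

    entries: dict[str, float] = field(
        default_factory=lambda: dict(TISSUE_CONDUCTIVITY_S_PER_M)
    )

    def __post_init__(self) -> None:
        for name, sig in self.entries.items():
            if sig < 0 or not np.isfinite(sig):
                raise ValueError(f"conductivity of {name!r} must be finite and >= 0")

    def __getitem__(self, tissue: str) -> float:
        key = tissue.lower()
        if key not in self.entries:
            raise KeyError(f"no conductivity for tissue {tissue!r}")
        return self.entries[key]


def default_conductivity_table() -> ConductivityTable:
    return ConductivityTable()


@dataclass
class ConductivityVolume:
    """Per-voxel electrical conductivity (S/m); exactly 0 on air voxels."""

    grid: VoxelGrid
    sigma: np.ndarray  # float, grid.shape

    def __post_init__(self) -> None:
        self.sigma = np.ascontiguousarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != self.grid.shape:
            raise ValueError("sigma shape does not match grid shape")
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError("sigma contains non-finite values")
        if np.any(self.sigma < 0):
            raise ValueError("sigma contains negative values")

    @property
    def head_mask(self) -> np.ndarray:
        return self.sigma > 0


@dataclass
class GrayMatterIndex:
    """Deterministic enumeration of the N gray-matter voxels.

    ``voxel_list[n]`` is the (i, j, k) of the n-th gray voxel in
    lexicographic (i, j, k) order; ``reverse`` maps flat voxel index back
    to n (-1 elsewhere).
    """

    mask: np.ndarray  # bool, grid shape
    voxel_list: np.ndarray  # (N, 3) int
    reverse: np.ndarray  # flat, int64, -1 outside gray matter
    grid: VoxelGrid

    @property
    def n(self) -> int:
        return int(self.voxel_list.shape[0])

    def locations_mm(self) -> np.ndarray:
        """(N, 3) gray-voxel centers in mm."""
        return self.grid.voxel_centers_mm(self.voxel_list)


def make_layered_sphere(
    spacing_mm: float = 2.0,
    radii_mm: tuple[float, ...] = DEFAULT_RADII_MM,
    tissue_order: tuple[str, ...] = DEFAULT_SHELL_TISSUES,
    pad_voxels: int = 1,
) -> TissueLabelVolume:
    """Concentric-shell sphere phantom centered on the grid center.

    ``radii_mm`` are shell outer radii, strictly decreasing (outermost
    first), paired with ``tissue_order``.  A voxel is labeled by the
    innermost shell whose outer radius exceeds its center distance from
    the sphere center; centers beyond the outermost radius are air (0).
    """
    radii = tuple(float(r) for r in radii_mm)
    if len(radii) != len(tissue_order):
        raise ValueError("radii_mm and tissue_order must have equal length")
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ValueError(f"radii must be strictly decreasing, got {radii}")
    # every shell must be at least one voxel thick to survive discretization
    thickness = [a - b for a, b in zip(radii, radii[1:])] + [radii[-1]]
    for tiss, th in zip(tissue_order, thickness):
        if th < spacing_mm:
            raise ValueError(
                f"shell {tiss!r} is {th:g} mm thick, thinner than one "
                f"{spacing_mm:g} mm voxel"
            )

    half = int(np.ceil(radii[0] / spacing_mm)) + int(pad_voxels)
    n = 2 * half + 1
    grid = VoxelGrid(
        shape=(n, n, n),
        spacing=spacing_mm,
        origin=(-half * spacing_mm,) * 3,
    )
    ax = np.arange(n) - half
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    r = spacing_mm * np.sqrt(ii**2 + jj**2 + kk**2)

    labels = np.zeros(grid.shape, dtype=np.int16)
    # assign outermost-in so inner shells overwrite
    for lab, (rad, _tiss) in enumerate(zip(radii, tissue_order), start=1):
        labels[r < rad] = lab
    label_names = {i + 1: t for i, t in enumerate(tissue_order)}
    return TissueLabelVolume(grid=grid, labels=labels, label_names=label_names)


def assign_conductivity(
    labels: TissueLabelVolume, table: ConductivityTable | None = None
) -> ConductivityVolume:
    """Map tissue labels to conductivities; air stays exactly 0."""
    table = table or default_conductivity_table()
    present = [int(v) for v in np.unique(labels.labels) if v != 0]
    lut = np.zeros(max(present, default=0) + 1, dtype=np.float64)
    for lab in present:
        name = labels.label_names[lab]
        try:
            lut[lab] = table[name]
        except KeyError as exc:
            raise KeyError(
                f"label {lab} ({name!r}) has no conductivity in the table"
            ) from exc
    return ConductivityVolume(grid=labels.grid, sigma=lut[labels.labels])


def make_homogeneous(
    labels: TissueLabelVolume,
    sigma_value: float = TISSUE_CONDUCTIVITY_S_PER_M["gray matter"],
) -> ConductivityVolume:
    """Single-conductivity head: every head voxel at ``sigma_value``."""
    if sigma_value <= 0:
        raise ValueError("sigma_value must be positive")
    sigma = np.where(labels.head_mask, float(sigma_value), 0.0)
    return ConductivityVolume(grid=labels.grid, sigma=sigma)


def make_csf_insert(
    labels: TissueLabelVolume, table: ConductivityTable | None = None
) -> ConductivityVolume:
    """Homogeneous head except the CSF shell, which keeps its own value."""
    table = table or default_conductivity_table()
    sigma = np.where(labels.head_mask, table["gray matter"], 0.0)
    try:
        csf = labels.mask_of("csf")
    except KeyError:
        csf = np.zeros(labels.grid.shape, dtype=bool)
    if not csf.any():
        warnings.warn(
            "no CSF voxels present; csf-insert model degenerates to homogeneous",
            stacklevel=2,
        )
    sigma[csf] = table["csf"]
    return ConductivityVolume(grid=labels.grid, sigma=sigma)


def make_segmentation_free(
    sigma: ConductivityVolume, smooth_fwhm_mm: float = 2.0
) -> ConductivityVolume:
    """Smooth the conductivity field inside the head mask.

    Emulates volume conductors whose conductivity varies gradually across
    tissue boundaries instead of jumping at segmentation edges.  The
    smoothing is a normalized masked Gaussian convolution, so air never
    bleeds into the head, the head mask is unchanged, and total
    conductivity mass over head voxels is conserved up to the mask
    normalization; values are clipped to the input head range.
    """
    if smooth_fwhm_mm < 0:
        raise ValueError("smooth_fwhm_mm must be >= 0")
    if smooth_fwhm_mm == 0:
        return ConductivityVolume(grid=sigma.grid, sigma=sigma.sigma.copy())
    mask = sigma.head_mask
    sd_vox = smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / sigma.grid.spacing
    num = ndimage.gaussian_filter(sigma.sigma, sd_vox, mode="constant")
    den = ndimage.gaussian_filter(mask.astype(np.float64), sd_vox, mode="constant")
    out = np.zeros_like(sigma.sigma)
    np.divide(num, den, out=out, where=mask & (den > 0))
    head_vals = sigma.sigma[mask]
    np.clip(out, head_vals.min(), head_vals.max(), out=out)
    out[~mask] = 0.0
    return ConductivityVolume(grid=sigma.grid, sigma=out)


def gray_matter_index(
    labels: TissueLabelVolume, tissue: str = "gray matter"
) -> GrayMatterIndex:
    """Enumerate gray-matter voxels in lexicographic (i, j, k) order."""
    try:
        mask = labels.mask_of(tissue)
    except KeyError as exc:
        raise ValueError(f"no {tissue!r} voxels in the label volume") from exc
    if not mask.any():
        raise ValueError(f"no {tissue!r} voxels in the label volume")
    voxel_list = np.argwhere(mask)  # argwhere is C-order, i.e. lexicographic
    reverse = np.full(labels.grid.n_voxels, -1, dtype=np.int64)
    flat = np.ravel_multi_index(voxel_list.T, labels.grid.shape)
    reverse[flat] = np.arange(voxel_list.shape[0])
    return GrayMatterIndex(
        mask=mask, voxel_list=voxel_list, reverse=reverse, grid=labels.grid
    )
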