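"""File formats: NIfTI volumes, HDF5 lead fields, CSV tables, run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .leadfield import LeadFieldMatrix
from .montage import ElectrodeMontage, ScalpPotentials
from .phantom import (
    ConductivityVolume,
    GrayMatterIndex,
    TissueLabelVolume,
    VoxelGrid,
)

__all__ = [
    "write_volume",
    "write_scalar_volume",
    "read_volume",
    "save_lfm",
    "load_lfm",
    "write_montage_csv",
    "read_montage_csv",
    "write_potentials_csv",
    "read_potentials_csv",
    "RunManifest",
]

_LABEL_EXT_CODE = 6  # NIfTI 'comment' extension, used for the label-name map


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag([grid.spacing] * 3 + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> VoxelGrid:
    lin = aff[:3, :3]
    off = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off)) > 1e-6:
        raise ValueError("sheared affine: only axis-aligned volumes are supported")
    d = np.diag(lin)
    if np.any(d <= 0):
        raise ValueError("affine must have positive diagonal spacing")
    if np.max(np.abs(d - d[0])) > 1e-6 * d[0]:
        raise ValueError(f"non-isotropic spacing {tuple(d)} is not supported")
    return VoxelGrid(shape=tuple(shape), spacing=float(d[0]), origin=tuple(aff[:3, 3]))


def write_volume(path, vol: TissueLabelVolume | ConductivityVolume) -> None:
    """Write labels (integer) or conductivity (float) as NIfTI-1."""
    if isinstance(vol, TissueLabelVolume):
        data = vol.labels.astype(np.int16)
        img = nib.Nifti1Image(data, _affine(vol.grid))
        payload = json.dumps({str(k): v for k, v in vol.label_names.items()})
        img.header.extensions.append(
            nib.nifti1.Nifti1Extension(_LABEL_EXT_CODE, payload.encode())
        )
    else:
        img = nib.Nifti1Image(vol.sigma.astype(np.float64), _affine(vol.grid))
    nib.save(img, str(path))


def write_scalar_volume(path, grid: VoxelGrid, data: np.ndarray) -> None:
    """Write an arbitrary per-voxel scalar field (e.g. potentials) as NIfTI-1."""
    if data.shape != grid.shape:
        raise ValueError("data shape does not match grid shape")
    nib.save(nib.Nifti1Image(data.astype(np.float64), _affine(grid)), str(path))


def read_volume(path) -> TissueLabelVolume | ConductivityVolume:
    """Read a NIfTI-1 volume; integer data -> labels, float -> conductivity."""
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating) and np.isnan(data).any():
        raise ValueError(f"{path}: volume contains NaN voxels")
    if np.issubdtype(data.dtype, np.integer):
        names: dict[int, str] = {}
        for ext in img.header.extensions:
            if ext.get_code() == _LABEL_EXT_CODE:
                try:
                    raw = ext.get_content()
                    raw = raw.decode() if isinstance(raw, bytes) else raw
                    names = {int(k): v for k, v in json.loads(raw).items()}
                except (ValueError, json.JSONDecodeError):
                    continue
        if not names:
            names = {int(v): f"tissue_{int(v)}" for v in np.unique(data) if v != 0}
        return TissueLabelVolume(grid=grid, labels=data.astype(np.int32), label_names=names)
    return ConductivityVolume(grid=grid, sigma=data.astype(np.float64))


def save_lfm(path, L: LeadFieldMatrix) -> None:
    """Write a lead field with montage, gray index and grid metadata (HDF5)."""
    g = L.gm.grid
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=L.values, compression="gzip")
        f.attrs["injection_current"] = L.injection_current
        f.attrs["column_order"] = "voxel-major, xyz interleaved"
        mg = f.create_group("montage")
        mg.create_dataset("names", data=np.array(L.montage.names, dtype="S16"))
        mg.create_dataset("positions_mm", data=L.montage.positions)
        mg.create_dataset("node_index", data=L.montage.node_index)
        mg.attrs["ground"] = L.montage.ground
        mg.attrs["system"] = L.montage.system
        gg = f.create_group("gray")
        gg.create_dataset("voxel_list", data=L.gm.voxel_list)
        fg = f.create_group("grid")
        fg.attrs["shape"] = g.shape
        fg.attrs["spacing_mm"] = g.spacing
        fg.attrs["origin_mm"] = g.origin


def load_lfm(path) -> LeadFieldMatrix:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        injection_current = float(f.attrs["injection_current"])
        fg = f["grid"]
        grid = VoxelGrid(
            shape=tuple(int(v) for v in fg.attrs["shape"]),
            spacing=float(fg.attrs["spacing_mm"]),
            origin=tuple(float(v) for v in fg.attrs["origin_mm"]),
        )
        mg = f["montage"]
        montage = ElectrodeMontage(
            names=[n.decode() for n in mg["names"][()]],
            positions=mg["positions_mm"][()],
            node_index=mg["node_index"][()],
            ground=int(mg.attrs["ground"]),
            system=str(mg.attrs["system"]),
        )
        voxel_list = f["gray"]["voxel_list"][()]
    mask = np.zeros(grid.shape, dtype=bool)
    mask[voxel_list[:, 0], voxel_list[:, 1], voxel_list[:, 2]] = True
    reverse = np.full(grid.n_voxels, -1, dtype=np.int64)
    reverse[np.ravel_multi_index(voxel_list.T, grid.shape)] = np.arange(len(voxel_list))
    gm = GrayMatterIndex(mask=mask, voxel_list=voxel_list, reverse=reverse, grid=grid)
    return LeadFieldMatrix(
        values=values,
        injection_current=injection_current,
        montage=montage,
        gm=gm,
    )


def write_montage_csv(path, montage: ElectrodeMontage) -> None:
    df = pd.DataFrame(
        {
            "name": montage.names,
            "x_mm": montage.positions[:, 0],
            "y_mm": montage.positions[:, 1],
            "z_mm": montage.positions[:, 2],
            "node_i": montage.node_index[:, 0],
            "node_j": montage.node_index[:, 1],
            "node_k": montage.node_index[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_montage_csv(path, system: str = "custom", ground: int = 0) -> ElectrodeMontage:
    df = pd.read_csv(path)
    required = {"name", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage CSV needs columns {sorted(required)}")
    if not {"node_i", "node_j", "node_k"}.issubset(df.columns):
        raise ValueError(
            "montage CSV lacks node indices; re-snap positions with place_montage"
        )
    return ElectrodeMontage(
        names=df["name"].astype(str).tolist(),
        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        node_index=df[["node_i", "node_j", "node_k"]].to_numpy(np.int64),
        ground=ground,
        system=system,
    )


def write_potentials_csv(path, phi: ScalpPotentials, names=None) -> None:
    df = pd.DataFrame(
        {
            "electrode": names if names is not None else np.arange(phi.n_electrodes),
            "phi_volts": phi.phi,
        }
    )
    df.to_csv(path, index=False)


def read_potentials_csv(path, ground: int = 0) -> ScalpPotentials:
    df = pd.read_csv(path)
    if "phi_volts" not in df.columns:
        raise ValueError("potentials CSV needs a 'phi_volts' column")
    return ScalpPotentials(phi=df["phi_volts"].to_numpy(float), ground=ground)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one CLI run: config, seeds, file digests."""

    stage: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _digest(Path(path))

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _digest(Path(path))

    def write(self, path) -> None:
        from . import __version__

        payload = {
            "stage": self.stage,
            "package_version": __version__,
            "seed": self.seed,
            "config": self.config,
            "config_digest": hashlib.sha256(
                json.dumps(self.config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "inputs": self.inputs,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))
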