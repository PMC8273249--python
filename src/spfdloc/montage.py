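"""Proportional scalp electrode montages on voxel phantoms.

Electrode sites of the international 10-20 (21 electrodes) and 10-10
(75 electrodes) systems are generated from the standard proportional
angular scheme: the vertex Cz sits on the up axis, the nasion-inion and
preauricular arcs define the reference plane, ring electrodes sit at
fixed azimuth fractions on the 10%-circle, and interior rows are placed
by spherical interpolation between the ring and the midline.  Each ideal
direction is then snapped to the nearest outer-surface lattice node of
the phantom.

Head frame convention: +x to the subject's right, +y anterior (nasion),
+z superior (vertex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import TissueLabelVolume

__all__ = [
    "ElectrodeMontage",
    "ScalpPotentials",
    "place_montage",
    "mean_interelectrode_distance",
    "reference_potentials",
    "montage_labels",
    "scalp_surface_nodes",
]


def _unit(theta_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector: theta measured from the vertex (+z), azimuth from +y
    (anterior) positive toward +x (right)."""
    t = np.deg2rad(theta_deg)
    a = np.deg2rad(azim_deg)
    return np.array([np.sin(t) * np.sin(a), np.sin(t) * np.cos(a), np.cos(t)])


def _slerp(u: np.ndarray, v: np.ndarray, f: float) -> np.ndarray:
    """Point at arc fraction f on the great circle from u to v."""
    w = float(np.clip(np.dot(u, v), -1.0, 1.0))
    ang = np.arccos(w)
    if ang < 1e-12:
        return u.copy()
    return (np.sin((1 - f) * ang) * u + np.sin(f * ang) * v) / np.sin(ang)


def _mirror(u: np.ndarray) -> np.ndarray:
    """Left-right mirror (negate x)."""
    return np.array([-u[0], u[1], u[2]])


def _build_10_20() -> dict[str, np.ndarray]:
    """Classic 21-electrode 10-20 set (with A1/A2 earlobe sites)."""
    pos: dict[str, np.ndarray] = {}
    ring = {  # 10%-circle, theta = 72 deg from vertex
        "Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T7": -90, "T8": 90,
        "P7": -126, "P8": 126, "O1": -162, "O2": 162,
    }
    for name, az in ring.items():
        pos[name] = _unit(72, az)
    pos["Fz"] = _unit(36, 0)
    pos["Cz"] = _unit(0, 0)
    pos["Pz"] = _unit(36, 180)
    pos["C3"] = _unit(36, -90)
    pos["C4"] = _unit(36, 90)
    pos["F3"] = _slerp(pos["F7"], pos["Fz"], 0.5)
    pos["F4"] = _mirror(pos["F3"])
    pos["P3"] = _slerp(pos["P7"], pos["Pz"], 0.5)
    pos["P4"] = _mirror(pos["P3"])
    pos["A1"] = _unit(100, -90)
    pos["A2"] = _unit(100, 90)
    order = [
        "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4",
        "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2", "A1", "A2",
    ]
    return {k: pos[k] for k in order}


def _build_10_10() -> dict[str, np.ndarray]:
    """75-electrode 10-10 extension (5% ring steps, quarter-arc rows)."""
    pos: dict[str, np.ndarray] = {}
    # midline, 10% (18 deg) steps along the nasion-inion arc
    mid = {
        "Fpz": (72, 0), "AFz": (54, 0), "Fz": (36, 0), "FCz": (18, 0),
        "Cz": (0, 0), "CPz": (18, 180), "Pz": (36, 180), "POz": (54, 180),
        "Oz": (72, 180),
    }
    for name, (t, a) in mid.items():
        pos[name] = _unit(t, a)
    # 10%-circle at theta = 72, 5% (18 deg) azimuth steps
    ring_left = {
        "Fp1": -18, "AF7": -36, "F7": -54, "FT7": -72, "T7": -90,
        "TP7": -108, "P7": -126, "PO7": -144, "O1": -162,
    }
    right_of = {
        "Fp1": "Fp2", "AF7": "AF8", "F7": "F8", "FT7": "FT8", "T7": "T8",
        "TP7": "TP8", "P7": "P8", "PO7": "PO8", "O1": "O2",
    }
    for name, az in ring_left.items():
        pos[name] = _unit(72, az)
        pos[right_of[name]] = _unit(72, -az)
    # interior rows: quarter-arc fractions from ring site to midline site
    rows = {
        ("AF7", "AFz"): {"AF3": 0.5},
        ("F7", "Fz"): {"F5": 0.25, "F3": 0.5, "F1": 0.75},
        ("FT7", "FCz"): {"FC5": 0.25, "FC3": 0.5, "FC1": 0.75},
        ("T7", "Cz"): {"C5": 0.25, "C3": 0.5, "C1": 0.75},
        ("TP7", "CPz"): {"CP5": 0.25, "CP3": 0.5, "CP1": 0.75},
        ("P7", "Pz"): {"P5": 0.25, "P3": 0.5, "P1": 0.75},
        ("PO7", "POz"): {"PO3": 0.5},
    }
    mirror_name = str.maketrans({"1": "2", "3": "4", "5": "6", "7": "8"})
    for (ring_name, mid_name), sites in rows.items():
        for name, f in sites.items():
            pos[name] = _slerp(pos[ring_name], pos[mid_name], f)
            pos[name.translate(mirror_name)] = _mirror(pos[name])
    # reference-plane ring (theta = 90): Nz, Iz and the 9/10 temporal chain
    pos["Nz"] = _unit(90, 0)
    pos["Iz"] = _unit(90, 180)
    for name, az in {"F9": -54, "FT9": -72, "T9": -90, "TP9": -108, "P9": -126}.items():
        pos[name] = _unit(90, az)
        pos[name[:-1] + "10"] = _unit(90, -az)
    pos["A1"] = _unit(100, -90)
    pos["A2"] = _unit(100, 90)
    order = sorted(pos)  # deterministic canonical order
    return {k: pos[k] for k in order}


_BUILDERS = {"10-20": _build_10_20, "10-10": _build_10_10}


def montage_labels(system: str) -> list[str]:
    """Electrode labels of a system in canonical order."""
    return list(_positions(system))


def _positions(system: str) -> dict[str, np.ndarray]:
    if system not in _BUILDERS:
        raise ValueError(f"unknown montage system {system!r}; use '10-20' or '10-10'")
    return _BUILDERS[system]()


@dataclass
class ElectrodeMontage:
    """Named scalp electrodes snapped to lattice nodes.

    ``node_index[m]`` is the (a, b, c) node-lattice index of electrode m;
    ``positions[m]`` its world coordinate in mm.  ``ground`` indexes the
    reference electrode whose potential defines 0 V.
    """

    names: list[str]
    positions: np.ndarray  # (M, 3) mm
    node_index: np.ndarray  # (M, 3) int
    ground: int
    system: str

    def __post_init__(self) -> None:
        m = len(self.names)
        if self.positions.shape != (m, 3) or self.node_index.shape != (m, 3):
            raise ValueError("positions/node_index shape mismatch with names")
        if not (0 <= self.ground < m):
            raise ValueError("ground index out of range")

    @property
    def n_electrodes(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class ScalpPotentials:
    """Ground-referenced electrode potentials (volts); ground entry is 0."""

    phi: np.ndarray  # (M,)
    ground: int

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if not np.isfinite(self.phi).all():
            raise ValueError("scalp potentials contain non-finite values")

    @property
    def n_electrodes(self) -> int:
        return self.phi.size


def scalp_surface_nodes(labels: TissueLabelVolume) -> np.ndarray:
    """(K, 3) lattice nodes on the outer head surface.

    A surface node touches at least one head voxel and at least one
    air voxel (or the grid boundary) among its up-to-8 adjacent voxels.
    """
    head = labels.head_mask
    pad = np.pad(head, 1)  # grid boundary counts as air
    # node (a,b,c) touches voxels (a-1..a, b-1..b, c-1..c); in padded
    # coordinates those are (a..a+1, ...) minus the +1 shift of the pad
    n0, n1, n2 = labels.grid.node_shape
    touch_head = np.zeros((n0, n1, n2), dtype=bool)
    touch_air = np.zeros((n0, n1, n2), dtype=bool)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                block = pad[di : di + n0, dj : dj + n1, dk : dk + n2]
                touch_head |= block
                touch_air |= ~block
    return np.argwhere(touch_head & touch_air)


def place_montage(
    labels: TissueLabelVolume,
    system: str = "10-10",
    ground: int | str = 0,
    center_mm: np.ndarray | None = None,
) -> ElectrodeMontage:
    """Place a proportional montage on the phantom scalp.

    Ideal directions from the head center are snapped to the
    outer-surface lattice node of maximum angular agreement (ties broken
    by radial proximity).  ``ground`` may be an electrode name or index;
    the default is the first electrode in canonical order.
    """
    ideal = _positions(system)
    surf = scalp_surface_nodes(labels)
    if surf.shape[0] == 0:
        raise ValueError("phantom has no scalp surface nodes")
    surf_mm = labels.grid.node_coords_mm(surf)
    if center_mm is None:
        head_vox = np.argwhere(labels.head_mask)
        center_mm = labels.grid.voxel_centers_mm(head_vox).mean(axis=0)
    center_mm = np.asarray(center_mm, dtype=float)
    rel = surf_mm - center_mm
    rad = np.linalg.norm(rel, axis=1)
    if np.any(rad == 0):
        raise ValueError("head center coincides with a surface node")
    dirs = rel / rad[:, None]

    names = list(ideal)
    node_index = np.empty((len(names), 3), dtype=np.int64)
    positions = np.empty((len(names), 3))
    for m, name in enumerate(names):
        u = ideal[name]
        cosang = dirs @ u
        best = cosang >= cosang.max() - 1e-12
        cand = np.flatnonzero(best)
        pick = cand[int(np.argmax(rad[cand]))]  # outermost among ties
        node_index[m] = surf[pick]
        positions[m] = surf_mm[pick]

    # distinctness: coarse grids can collapse neighboring sites
    uniq = {tuple(n) for n in node_index}
    if len(uniq) < len(names):
        seen: dict[tuple, str] = {}
        for name, n in zip(names, node_index):
            t = tuple(n)
            if t in seen:
                raise ValueError(
                    f"electrodes {seen[t]} and {name} snap to the same scalp "
                    f"node at {labels.grid.spacing:g} mm spacing; use a finer grid"
                )
            seen[t] = name

    if isinstance(ground, str):
        ground = names.index(ground)
    return ElectrodeMontage(
        names=names,
        positions=positions,
        node_index=node_index,
        ground=int(ground),
        system=system,
    )


def mean_interelectrode_distance(montage: ElectrodeMontage) -> float:
    """Mean over electrodes of the nearest-neighbor Euclidean distance (mm)."""
    p = montage.positions
    if p.shape[0] < 2:
        raise ValueError("need at least two electrodes")
    d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def reference_potentials(phi_nodes, montage: ElectrodeMontage) -> ScalpPotentials:
    """Electrode potentials referenced to the ground electrode.

    ``phi_nodes`` is a node-lattice array or a PotentialField; the ground
    entry of the result is exactly 0.
    """
    p = getattr(phi_nodes, "phi", phi_nodes)
    p = np.asarray(p)
    idx = montage.node_index
    vals = p[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.float64)
    vals = vals - vals[montage.ground]
    vals[montage.ground] = 0.0
    return ScalpPotentials(phi=vals, ground=montage.ground)
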