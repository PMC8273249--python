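"""Shared fixtures: a small 4 mm five-shell sphere phantom.

The mini phantom keeps every structural feature of the full study phantom
(five tissues, thin high-conductivity CSF shell between resistive skull
and brain) at desk-test scale: 44 mm outer radius, 4 mm voxels, ~1000
gray voxels, so lead fields build in seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

import spfdloc as sl

MINI_RADII = (44.0, 38.0, 32.0, 28.0, 18.0)
MINI_SPACING = 4.0


@pytest.fixture(scope="session")
def mini_labels() -> sl.TissueLabelVolume:
    return sl.make_layered_sphere(MINI_SPACING, MINI_RADII)


@pytest.fixture(scope="session")
def mini_sigma(mini_labels) -> sl.ConductivityVolume:
    return sl.assign_conductivity(mini_labels)


@pytest.fixture(scope="session")
def mini_gm(mini_labels) -> sl.GrayMatterIndex:
    return sl.gray_matter_index(mini_labels)


@pytest.fixture(scope="session")
def mini_1010(mini_labels) -> sl.ElectrodeMontage:
    return sl.place_montage(mini_labels, "10-10")


@pytest.fixture(scope="session")
def mini_1020(mini_labels) -> sl.ElectrodeMontage:
    return sl.place_montage(mini_labels, "10-20")


@pytest.fixture(scope="session")
def mini_solver(mini_sigma, mini_1010) -> sl.SPFDSolver:
    pin = tuple(int(v) for v in mini_1010.node_index[mini_1010.ground])
    return sl.SPFDSolver(mini_sigma, sl.SolverConfig(), pin_node=pin)


@pytest.fixture(scope="session")
def mini_lfm(mini_sigma, mini_1010, mini_gm, mini_solver) -> sl.LeadFieldMatrix:
    return sl.build_lfm(mini_sigma, mini_1010, mini_gm, solver=mini_solver)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
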