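"""Shared fixtures: small synthetic structures and density maps."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from proligand import FixtureSpec, make_predicted, make_reference


@pytest.fixture
def helix_spec() -> FixtureSpec:
    return FixtureSpec(
        n_chains=2,
        residues_per_chain=30,
        noise_sd=0.1,
        rigid_rotation_axis=(1.0, -2.0, 0.5),
        rigid_rotation_deg=40.0,
        rigid_translation=(5.0, -3.0, 8.0),
        fraction_displaced=0.2,
        ligand_codes=("PTQ",),
        seed=42,
    )


@pytest.fixture
def helix_pair(helix_spec):
    ref = make_reference(helix_spec)
    pred, truth = make_predicted(ref, helix_spec)
    return ref, pred, truth


def polymer_keys(structure) -> set[tuple[str, int, str]]:
    return {
        (c.id, r.number, r.insertion_code)
        for c in structure.chains
        for r in c.polymer_residues()
    }


def write_raw_mrc(path, grid: np.ndarray, voxel: float, origin, axis_order=(1, 2, 3)) -> None:
    """Minimal MRC2014 writer used as an independent oracle for read_mrc.

    ``grid`` is indexed [x, y, z]; ``axis_order`` gives (MAPC, MAPR, MAPS),
    i.e. which physical axis runs along file columns/rows/sections.
    """
    mapc, mapr, maps = axis_order
    # data loops sections (slowest) / rows / columns (fastest)
    data = np.transpose(grid, (maps - 1, mapr - 1, mapc - 1))
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, data.shape[2], data.shape[1], data.shape[0])
    struct.pack_into("<i", header, 12, 2)  # mode 2: float32
    struct.pack_into("<3i", header, 28, *grid.shape)  # MX, MY, MZ
    struct.pack_into("<3f", header, 40, *(n * voxel for n in grid.shape))
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, mapc, mapr, maps)
    struct.pack_into("<i", header, 88, 1)  # ISPG
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    struct.pack_into("<3f", header, 196, *origin)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(data, dtype="<f4").tobytes())
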