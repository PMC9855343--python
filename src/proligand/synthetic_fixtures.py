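"""Synthetic test structures and density maps with known ground truth.

The reference structure is an ideal alpha-helical poly-alanine backbone
(rise 1.5 A per residue, 100 degree turn, 2.3 A helix radius; N, C, O placed
at fixed offsets from CA in the local helix frame), optionally decorated with
small hetero ligand residues.  The "predicted" structure is a backbone-only
copy with seeded Gaussian coordinate noise, a chosen fraction of residues
displaced 3 A along the outward radial direction of the helix (guaranteed
beyond the default 1 A merge threshold, and at least ~3 A from every other
residue's CA), and a known rigid transform applied to the whole model.
Density maps are sums of isotropic atom-centred Gaussians on a regular grid.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .map_qscore import DensityMap
from .structure_io import Atom, Chain, Residue, Structure

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "make_reference",
    "make_predicted",
    "simulate_map",
]

HELIX_RISE = 1.5        # A per residue along the axis
HELIX_TURN = 100.0      # degrees per residue
HELIX_RADIUS = 2.3      # A, CA distance from the axis
CHAIN_SPACING = 16.0    # A between parallel helix axes
DISPLACEMENT = 3.0      # A, push for "wrong" residues; >> 1 A threshold

# backbone offsets from CA in the local frame (radial, tangential, axial)
_BACKBONE_OFFSETS = {
    "N": np.array([-0.40, -1.10, -0.80]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([-0.30, 1.20, 0.70]),
    "O": np.array([-0.90, 2.10, 0.40]),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}

# a small rigid 5-atom cluster standing in for a bound small molecule
_LIGAND_OFFSETS = [
    ("C1", "C", np.array([0.0, 0.0, 0.0])),
    ("C2", "C", np.array([1.5, 0.0, 0.0])),
    ("O1", "O", np.array([-0.7, 1.2, 0.0])),
    ("C3", "C", np.array([0.7, -1.2, 0.7])),
    ("N1", "N", np.array([2.2, 1.2, 0.5])),
]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic reference/predicted pair."""

    n_chains: int = 1
    residues_per_chain: int = 50
    noise_sd: float = 0.1
    rigid_rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rigid_rotation_deg: float = 0.0
    rigid_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fraction_displaced: float = 0.0
    ligand_codes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.fraction_displaced <= 1.0):
            raise ValueError("fraction_displaced must lie in [0, 1]")
        self.ligand_codes = tuple(self.ligand_codes)

    def rotation_matrix(self) -> np.ndarray:
        axis = np.asarray(self.rigid_rotation_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0 or self.rigid_rotation_deg == 0.0:
            return np.eye(3)
        return Rotation.from_rotvec(
            np.deg2rad(self.rigid_rotation_deg) * axis / norm
        ).as_matrix()

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        data = json.loads(Path(path).read_text())
        for key in ("rigid_rotation_axis", "rigid_translation", "ligand_codes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """What make_predicted actually did: which residues were pushed out of
    register and the rigid transform applied afterwards."""

    displaced: frozenset[tuple[str, int, str]]
    rotation: np.ndarray
    translation: np.ndarray


def _chain_ids(n: int) -> list[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if n > len(alphabet):
        raise ValueError("at most 26 chains supported")
    return list(alphabet[:n])


def _local_frame(angle_rad: float) -> np.ndarray:
    """Columns: radial, tangential, axial unit vectors at helix angle."""
    radial = np.array([np.cos(angle_rad), np.sin(angle_rad), 0.0])
    tangential = np.array([-np.sin(angle_rad), np.cos(angle_rad), 0.0])
    axial = np.array([0.0, 0.0, 1.0])
    return np.column_stack([radial, tangential, axial])


def make_reference(spec: FixtureSpec) -> Structure:
    """Ideal poly-alanine helical reference, plus one hetero ligand residue
    per entry of ``spec.ligand_codes``.

    Ligand i is attached to chain i mod n_chains, numbered after the polymer,
    5 A radially out from that chain's last CA.
    """
    chains: list[Chain] = []
    for ci, cid in enumerate(_chain_ids(spec.n_chains)):
        axis_offset = np.array([CHAIN_SPACING * ci, 0.0, 0.0])
        chain = Chain(id=cid)
        for i in range(spec.residues_per_chain):
            angle = np.deg2rad(HELIX_TURN * i)
            frame = _local_frame(angle)
            ca = axis_offset + HELIX_RADIUS * frame[:, 0] + np.array([0, 0, HELIX_RISE * i])
            atoms = [
                Atom(name=name, element=_ELEMENTS[name], position=ca + frame @ off)
                for name, off in _BACKBONE_OFFSETS.items()
            ]
            chain.residues.append(Residue(name="ALA", number=i + 1, atoms=atoms))
        chains.append(chain)

    for li, code in enumerate(spec.ligand_codes):
        chain = chains[li % spec.n_chains]
        last_ca = chain.residues[spec.residues_per_chain - 1].atom("CA").position
        axis_offset = np.array([CHAIN_SPACING * (li % spec.n_chains), 0.0, 0.0])
        radial = last_ca - axis_offset
        radial[2] = 0.0
        radial /= np.linalg.norm(radial)
        anchor = last_ca + 5.0 * radial
        atoms = [
            Atom(name=name, element=elem, position=anchor + off, is_hetero=True)
            for name, elem, off in _LIGAND_OFFSETS
        ]
        chain.residues.append(
            Residue(name=code, number=spec.residues_per_chain + 1 + li // spec.n_chains,
                    atoms=atoms)
        )
    return Structure(chains=chains, title="synthetic helical fixture")


def make_predicted(ref: Structure, spec: FixtureSpec) -> tuple[Structure, GroundTruth]:
    """Backbone-only perturbed copy of ``ref`` with recorded ground truth.

    Ligands and non-backbone atoms are stripped; Gaussian noise of sd
    ``spec.noise_sd`` is added to every atom; round(fraction_displaced x
    n_residues) residues, chosen at random, are displaced 3 A radially
    outward; finally the spec's rigid rotation and translation are applied to
    every atom.
    """
    rng = np.random.default_rng(spec.seed)
    rotation = spec.rotation_matrix()
    translation = np.asarray(spec.rigid_translation, dtype=float)

    polymer: list[tuple[Chain, Residue]] = [
        (c, r) for c in ref.chains for r in c.polymer_residues()
    ]
    n_displaced = int(round(spec.fraction_displaced * len(polymer)))
    displaced_idx = set(
        rng.choice(len(polymer), size=n_displaced, replace=False).tolist()
    ) if n_displaced else set()

    chain_axis = {
        cid: np.array([CHAIN_SPACING * i, 0.0, 0.0])
        for i, cid in enumerate(_chain_ids(len(ref.chains)))
    }

    out_chains: dict[str, Chain] = {}
    displaced_keys: set[tuple[str, int, str]] = set()
    for idx, (src_chain, src_res) in enumerate(polymer):
        chain = out_chains.setdefault(src_chain.id, Chain(id=src_chain.id))
        atoms = []
        shift = np.zeros(3)
        if idx in displaced_idx:
            ca = src_res.atom("CA").position
            radial = ca - chain_axis.get(src_chain.id, np.zeros(3))
            radial[2] = 0.0
            norm = np.linalg.norm(radial)
            direction = radial / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            shift = DISPLACEMENT * direction
            displaced_keys.add((src_chain.id, src_res.number, src_res.insertion_code))
        for name in ("N", "CA", "C", "O"):
            src_atom = src_res.atom(name)
            if src_atom is None:
                continue
            noisy = src_atom.position + shift + rng.normal(0.0, spec.noise_sd, size=3)
            atoms.append(Atom(name=name, element=src_atom.element,
                              position=rotation @ noisy + translation))
        chain.residues.append(
            Residue(name=src_res.name, number=src_res.number,
                    insertion_code=src_res.insertion_code, atoms=atoms)
        )
    pred = Structure(
        chains=[out_chains[c.id] for c in ref.chains if c.id in out_chains],
        title="synthetic predicted backbone",
    )
    truth = GroundTruth(
        displaced=frozenset(displaced_keys),
        rotation=rotation,
        translation=translation,
    )
    return pred, truth


def simulate_map(
    s: Structure,
    voxel: float = 0.5,
    sigma_atom: float = 0.6,
    amplitude: float = 1.0,
    offset: float = 0.0,
    pad: float = 3.0,
) -> DensityMap:
    """Density map as a sum of isotropic Gaussians centred on the atoms:

        rho(x) = offset + amplitude * sum_a exp(-0.5 (|x - x_a| / sigma_atom)^2)

    The grid covers the structure's bounding box plus ``pad`` A on each side.
    Each atom contributes within a 5 sigma cutoff (the tail beyond that is
    below 4e-6 of the amplitude).
    """
    if voxel <= 0 or sigma_atom <= 0:
        raise ValueError("voxel and sigma_atom must be positive")
    coords = np.array([a.position for a in s.atoms()])
    if coords.size == 0:
        raise ValueError("structure has no atoms")
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    grid = np.full(tuple(shape), float(offset), dtype=np.float64)
    axes = [lo[k] + voxel * np.arange(shape[k]) for k in range(3)]
    cutoff = 5.0 * sigma_atom
    for pos in coords:
        i_lo = np.maximum(np.floor((pos - cutoff - lo) / voxel).astype(int), 0)
        i_hi = np.minimum(np.ceil((pos + cutoff - lo) / voxel).astype(int) + 1, shape)
        dx = axes[0][i_lo[0]:i_hi[0]] - pos[0]
        dy = axes[1][i_lo[1]:i_hi[1]] - pos[1]
        dz = axes[2][i_lo[2]:i_hi[2]] - pos[2]
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
        grid[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]] += (
            amplitude * np.exp(-0.5 * d2 / sigma_atom**2)
        )
    return DensityMap(grid=grid, voxel_size=np.full(3, voxel), origin=lo)
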