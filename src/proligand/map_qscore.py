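"""Cryo-EM density map handling and map-model fit scoring.

The Q-score of an atom measures how closely the density around it resembles
the Gaussian profile expected for a well-resolved atom.  Map values are
sampled on concentric spherical shells around the atom (radius 0 to
``max_radius`` in steps of ``radial_step``; points per shell on a seeded,
randomly rotated Fibonacci lattice), averaged per shell into a vector u, and
compared by Pearson correlation against the vector v of reference-Gaussian
values at the same radii:

    g(d) = low + (high - low) * exp(-0.5 (d / sigma)^2)

with defaults sigma = 0.6 A, high = map mean + 10 sd, low = map mean - 1 sd.
Being a correlation, q lies in [-1, 1] and is invariant under positive affine
rescaling of the map intensities.

Per-target Q-scores of competing models are standardized to Z-scores
(sample standard deviation, ddof = 1) and summed across targets into the
cumulative leaderboard score.

Maps are read and written in MRC/CCP4 2014 format through gemmi, with axis
order normalized to (x, y, z) on read.
"""

from __future__ import annotations

import logging
import os
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.transform import Rotation

from .structure_io import Atom

__all__ = [
    "DensityMap",
    "QScoreParams",
    "QScoreResult",
    "MapFormatError",
    "OutOfBoundsError",
    "UnscorableAtomError",
    "read_mrc",
    "write_mrc",
    "interpolate",
    "reference_gaussian",
    "sample_shells",
    "qscore_atom",
    "qscore_selection",
    "zscores",
    "cumulative_z",
]

logger = logging.getLogger(__name__)


class MapFormatError(ValueError):
    pass


class OutOfBoundsError(ValueError):
    pass


class UnscorableAtomError(RuntimeError):
    pass


@dataclass(eq=False)
class DensityMap:
    """A 3D scalar density grid.

    ``grid`` is indexed [ix, iy, iz]; voxel centre i sits at
    ``origin + i * voxel_size`` (orthogonal cells only).
    """

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        # float64 in memory so affine intensity transforms are exact;
        # MRC mode 2 narrows to float32 only on write
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size components must be positive")
        self._interp: RegularGridInterpolator | None = None

    @property
    def mean(self) -> float:
        return float(self.grid.mean())

    @property
    def sd(self) -> float:
        return float(self.grid.std())

    def _interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            axes = [
                self.origin[k] + self.voxel_size[k] * np.arange(self.grid.shape[k])
                for k in range(3)
            ]
            self._interp = RegularGridInterpolator(
                axes, self.grid, method="linear",
                bounds_error=False, fill_value=np.nan,
            )
        return self._interp

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """Trilinear map values at Cartesian points; NaN where out of bounds."""
        return self._interpolator()(np.asarray(points, dtype=float))


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O
# ---------------------------------------------------------------------------

def _read_ccp4(path: str) -> DensityMap:
    try:
        ccp4 = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"not a readable MRC/CCP4 map: {exc}") from exc
    # header words before axis normalization: MAPC/MAPR/MAPS say which of
    # x,y,z runs along columns/rows/sections; NXSTART.. follow that order
    axis_map = [ccp4.header_i32(i) for i in (17, 18, 19)]
    nstart_crs = [ccp4.header_i32(i) for i in (5, 6, 7)]
    if sorted(axis_map) != [1, 2, 3]:
        raise MapFormatError(f"invalid axis mapping {axis_map}")
    nstart_xyz = [0, 0, 0]
    for crs_idx, xyz_axis in enumerate(axis_map):
        nstart_xyz[xyz_axis - 1] = nstart_crs[crs_idx]
    origin_words = np.array([ccp4.header_float(i) for i in (50, 51, 52)])
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(ccp4.grid, copy=True)
    voxel = np.array(ccp4.grid.spacing)
    if np.any(origin_words != 0.0):
        origin = origin_words
    else:
        origin = np.array(nstart_xyz, dtype=float) * voxel
    return DensityMap(grid=grid, voxel_size=voxel, origin=origin)


def read_mrc(source) -> DensityMap:
    """Read an MRC2014/CCP4 map from a path or a binary file-like object.

    The grid axis order is normalized to (x, y, z) using the header's axis
    mapping; the origin comes from the ORIGIN header words, falling back to
    NXSTART/NYSTART/NZSTART times the voxel size.
    """
    if isinstance(source, (str, Path)):
        return _read_ccp4(str(source))
    data = source.read()
    with tempfile.NamedTemporaryFile(suffix=".mrc", delete=False) as fh:
        fh.write(data)
        tmp = fh.name
    try:
        return _read_ccp4(tmp)
    finally:
        os.unlink(tmp)


def write_mrc(m: DensityMap, dest) -> None:
    """Write a map as MRC2014 mode 2 (32-bit float) to a path or binary
    file-like object, with voxel size, origin and grid statistics in the
    header."""
    nx, ny, nz = m.grid.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(gemmi.UnitCell(
        nx * m.voxel_size[0], ny * m.voxel_size[1], nz * m.voxel_size[2],
        90.0, 90.0, 90.0,
    ))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    np.array(grid, copy=False)[...] = m.grid.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), m.origin):
        ccp4.set_header_float(word, float(value))
    if isinstance(dest, (str, Path)):
        ccp4.write_ccp4_map(str(dest))
        return
    with tempfile.NamedTemporaryFile(suffix=".mrc", delete=False) as fh:
        tmp = fh.name
    try:
        ccp4.write_ccp4_map(tmp)
        with open(tmp, "rb") as fh:
            dest.write(fh.read())
    finally:
        os.unlink(tmp)


def interpolate(m: DensityMap, point: np.ndarray) -> float:
    """Trilinear interpolation at a single Cartesian point (A).

    Raises :class:`OutOfBoundsError` if the point lies outside the grid's
    bounding box.
    """
    value = float(m.values_at(np.asarray(point, dtype=float)[None, :])[0])
    if np.isnan(value):
        raise OutOfBoundsError(f"point {np.asarray(point)} outside map bounds")
    return value


# ---------------------------------------------------------------------------
# Q-score
# ---------------------------------------------------------------------------

@dataclass
class QScoreParams:
    """Sampling and reference-Gaussian parameters for Q-score computation.

    ``reference_high``/``reference_low`` default to map mean + 10 sd and
    map mean - 1 sd when left as None.
    """

    sigma: float = 0.6
    max_radius: float = 2.0
    radial_step: float = 0.1
    points_per_shell: int = 8
    reference_high: float | None = None
    reference_low: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.radial_step <= self.max_radius):
            raise ValueError("require 0 < radial_step <= max_radius")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.points_per_shell < 4:
            raise ValueError("points_per_shell must be at least 4")

    def resolve_reference(self, m: DensityMap) -> tuple[float, float]:
        high = self.reference_high if self.reference_high is not None else m.mean + 10.0 * m.sd
        low = self.reference_low if self.reference_low is not None else m.mean - 1.0 * m.sd
        return high, low

    def radii(self) -> np.ndarray:
        n = int(round(self.max_radius / self.radial_step))
        return np.arange(n + 1) * self.radial_step


@dataclass
class QScoreResult:
    """Per-atom Q-scores with residue- and selection-level means."""

    per_atom: list[float]
    n_unscorable: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_atom))


def reference_gaussian(d, p: QScoreParams, high: float, low: float):
    """Ideal-atom density profile at distance ``d`` (A) from the atom centre."""
    d = np.asarray(d, dtype=float)
    return low + (high - low) * np.exp(-0.5 * (d / p.sigma) ** 2)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sample_shells(
    center: np.ndarray, p: QScoreParams, seed: int
) -> list[tuple[float, np.ndarray]]:
    """Sample points on concentric shells around ``center``.

    Radius 0 contributes the centre itself; every other radius contributes
    ``points_per_shell`` points on a Fibonacci lattice given an independent
    random rotation (seeded, so point sets are reproducible).
    """
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    base = _fibonacci_sphere(p.points_per_shell)
    shells: list[tuple[float, np.ndarray]] = []
    for radius in p.radii():
        if radius == 0.0:
            shells.append((0.0, center[None, :]))
            continue
        rot = Rotation.random(rng=rng).as_matrix()
        shells.append((float(radius), center + radius * (base @ rot.T)))
    return shells


def qscore_atom(m: DensityMap, atom: Atom, p: QScoreParams | None = None, seed: int = 0) -> float:
    """Q-score of one atom: Pearson correlation between shell-averaged map
    values and the reference Gaussian evaluated at the shell radii.

    Sample points falling outside the map are dropped; a radius with no
    in-bounds points is dropped from both vectors.  Fewer than 3 usable radii
    raises :class:`UnscorableAtomError`.
    """
    if p is None:
        p = QScoreParams()
    high, low = p.resolve_reference(m)
    radii_used: list[float] = []
    u: list[float] = []
    for radius, points in sample_shells(atom.position, p, seed):
        values = m.values_at(points)
        values = values[~np.isnan(values)]
        if values.size == 0:
            continue
        radii_used.append(radius)
        u.append(float(values.mean()))
    if len(u) < 3:
        raise UnscorableAtomError(
            f"atom {atom.name} at {atom.position}: only {len(u)} usable radii"
        )
    u_arr = np.array(u)
    v_arr = reference_gaussian(np.array(radii_used), p, high, low)
    su, sv = u_arr.std(), v_arr.std()
    if su == 0.0 or sv == 0.0:
        logger.warning("flat sample vector for atom %s; q set to 0", atom.name)
        return 0.0
    q = float(np.corrcoef(u_arr, v_arr)[0, 1])
    return float(np.clip(q, -1.0, 1.0))


def qscore_selection(
    m: DensityMap,
    atoms: list[Atom],
    p: QScoreParams | None = None,
    seed: int = 0,
) -> QScoreResult:
    """Unweighted mean Q-score over the scorable atoms of a selection
    (e.g. one ligand).  Unscorable atoms are counted and logged; zero
    scorable atoms is an error."""
    scores: list[float] = []
    unscorable = 0
    for i, atom in enumerate(atoms):
        try:
            scores.append(qscore_atom(m, atom, p, seed=seed + i))
        except UnscorableAtomError:
            unscorable += 1
    if not scores:
        raise UnscorableAtomError("no scorable atoms in selection")
    if unscorable:
        logger.info("%d of %d atoms unscorable (outside map)", unscorable, len(atoms))
    return QScoreResult(per_atom=scores, n_unscorable=unscorable)


# ---------------------------------------------------------------------------
# Z-scores across groups
# ---------------------------------------------------------------------------

def zscores(q_by_group: dict[str, float]) -> dict[str, float]:
    """Standardize per-group Q-scores for one target: z = (q - mean)/sd with
    sample sd (ddof=1).  A zero spread yields all-zero z with a warning."""
    if len(q_by_group) < 2:
        raise ValueError("z-scores require at least 2 groups")
    values = np.array(list(q_by_group.values()), dtype=float)
    sd = values.std(ddof=1)
    if sd == 0.0:
        warnings.warn("all Q-scores identical; z-scores set to 0", stacklevel=2)
        return {g: 0.0 for g in q_by_group}
    mean = values.mean()
    return {g: float((q - mean) / sd) for g, q in q_by_group.items()}


def cumulative_z(per_target_z: list[dict[str, float]]) -> dict[str, float]:
    """Sum each group's z-scores over targets; a group missing from a target
    contributes 0 for that target (logged)."""
    totals: dict[str, float] = {}
    groups: set[str] = set()
    for table in per_target_z:
        groups.update(table)
    for group in sorted(groups):
        missing = sum(1 for table in per_target_z if group not in table)
        if missing:
            logger.info("group %s missing from %d target(s); contributes 0 there",
                        group, missing)
        totals[group] = float(sum(table.get(group, 0.0) for table in per_target_z))
    return totals
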