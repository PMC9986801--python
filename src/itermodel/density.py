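"""Real-space density maps and map-model correlation scoring.

Maps are plain 3-D grids on an orthogonal cell.  Model-derived density uses
a single Gaussian per atom whose integrated weight is proportional to the
element electron count and whose width combines the atomic B factor with a
resolution-dependent blur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import mrcfile

from .model_io import (AtomicModel, BACKBONE_ATOMS, ELECTRON_COUNT,
                       EmptyModelError)

#: Default mask radius (A) for per-residue correlations: midpoint of the
#: optimization grid used by global_cc.
DEFAULT_MASK_RADIUS = 2.5

#: Minimum number of masked grid points for a per-residue correlation to be
#: considered defined.
MIN_MASK_POINTS = 10

#: CA-CA distance (A) beyond which consecutive residues count as a chain break.
CHAIN_BREAK_DISTANCE = 4.2

_RADIUS_GRID = (1.5, 2.0, 2.5, 3.0)
_INCREMENT_GRID = (0.0, 10.0, 20.0, 40.0)


class MapCoverageError(Exception):
    """The map does not cover enough of the model for scoring."""


@dataclass
class DensityMap:
    """A 3-D density grid with Cartesian metadata.

    ``values`` is indexed ``[ix, iy, iz]``; the Cartesian position of grid
    point (i, j, k) is ``origin + (i, j, k) * spacing``.
    """

    values: np.ndarray
    spacing: np.ndarray  # A per grid step, shape (3,)
    origin: np.ndarray  # A, shape (3,)
    cell: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3-D with at least 2 points per axis")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.cell is None:
            extent = (np.array(self.values.shape)) * self.spacing
            self.cell = (float(extent[0]), float(extent[1]), float(extent[2]),
                         90.0, 90.0, 90.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.spacing.copy(),
                          self.origin.copy(), self.cell)

    def grid_coordinates(self, positions: np.ndarray) -> np.ndarray:
        """Cartesian positions -> fractional grid indices."""
        return (np.asarray(positions, dtype=float) - self.origin) / self.spacing

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of positions lying inside the grid."""
        idx = self.grid_coordinates(positions)
        shape = np.array(self.shape)
        return np.all((idx >= 0) & (idx <= shape - 1), axis=-1)


# ---------------------------------------------------------------------------
# CCP4/MRC I/O
# ---------------------------------------------------------------------------


def read_map(path: str) -> DensityMap:
    """Read a CCP4/MRC map, normalizing axis order to X, Y, Z."""
    with mrcfile.open(path, permissive=True) as mrc:
        data = np.asarray(mrc.data, dtype=np.float64)
        # mrcfile data is [z, y, x] for default axis order; honor mapc/r/s
        axis_order = (int(mrc.header.mapc), int(mrc.header.mapr), int(mrc.header.maps))
        # data axes are (slow, medium, fast) = (maps, mapr, mapc)
        data_axes_xyz = [axis_order[2] - 1, axis_order[1] - 1, axis_order[0] - 1]
        # transpose so values[x, y, z]
        perm = [data_axes_xyz.index(axis) for axis in range(3)]
        values = np.transpose(data, perm)
        voxel = mrc.voxel_size
        spacing = np.array([voxel.x, voxel.y, voxel.z], dtype=float)
        origin = np.array([mrc.header.origin.x, mrc.header.origin.y,
                           mrc.header.origin.z], dtype=float)
        if not np.any(origin):
            start = np.array([mrc.header.nxstart, mrc.header.nystart,
                              mrc.header.nzstart], dtype=float)
            # nxstart etc. are in the data (fast/medium/slow) frame
            start_xyz = np.empty(3)
            start_xyz[axis_order[0] - 1] = start[0]
            start_xyz[axis_order[1] - 1] = start[1]
            start_xyz[axis_order[2] - 1] = start[2]
            origin = start_xyz * spacing
        cell = (float(mrc.header.cella.x), float(mrc.header.cella.y),
                float(mrc.header.cella.z), float(mrc.header.cellb.alpha),
                float(mrc.header.cellb.beta), float(mrc.header.cellb.gamma))
    return DensityMap(values, spacing, origin, cell)


def write_map(density: DensityMap, path: str) -> None:
    """Write a map as MRC2014 (mode 2, X fastest)."""
    with mrcfile.new(path, overwrite=True) as mrc:
        mrc.set_data(np.ascontiguousarray(
            np.transpose(density.values, (2, 1, 0)).astype(np.float32)))
        mrc.voxel_size = tuple(float(s) for s in density.spacing)
        mrc.header.origin.x = float(density.origin[0])
        mrc.header.origin.y = float(density.origin[1])
        mrc.header.origin.z = float(density.origin[2])
        mrc.update_header_stats()


# ---------------------------------------------------------------------------
# Model-derived density
# ---------------------------------------------------------------------------


def resolution_blur(resolution: float) -> float:
    """Resolution-dependent B-factor blur added to every atom (A^2)."""
    return 79.0 * (resolution / 3.0) ** 2


def _atom_arrays(model: AtomicModel, side_chain_b_increment: float = 0.0
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    positions, weights, b_values = [], [], []
    for residue in model.iter_residues():
        for atom in residue.atoms:
            positions.append(atom.position)
            weights.append(ELECTRON_COUNT.get(atom.element, 6) * atom.occupancy)
            b = atom.b_iso
            if side_chain_b_increment and atom.name not in BACKBONE_ATOMS:
                b = b + side_chain_b_increment
            b_values.append(b)
    if not positions:
        raise EmptyModelError("model has no atoms")
    return np.array(positions), np.array(weights), np.array(b_values)


def model_to_map(model: AtomicModel, spacing: float = 1.0, resolution: float = 3.0,
                 pad: float = 5.0, grid_like: DensityMap | None = None,
                 side_chain_b_increment: float = 0.0) -> DensityMap:
    """Compute a model-based density map with one Gaussian per atom.

    Each atom contributes integrated weight proportional to its electron
    count, with variance sigma^2 = (b_iso + B_res) / (8 pi^2) where
    B_res = 79 (resolution / 3)^2.  When ``grid_like`` is given, density is
    sampled on that map's grid instead of a fresh grid covering the model
    extent plus ``pad`` angstroms.
    """
    if grid_like is None and spacing >= resolution / 2.0:
        raise ValueError(f"grid spacing {spacing} A undersamples resolution "
                         f"{resolution} A (need spacing < resolution/2)")
    positions, weights, b_values = _atom_arrays(model, side_chain_b_increment)

    if grid_like is not None:
        shape = grid_like.shape
        origin = grid_like.origin
        step = grid_like.spacing
    else:
        lo = positions.min(axis=0) - pad
        hi = positions.max(axis=0) + pad
        step = np.full(3, float(spacing))
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / step[a])) + 1 for a in range(3))
        shape = tuple(max(s, 2) for s in shape)
        origin = lo

    values = np.zeros(shape)
    sigma2 = (b_values + resolution_blur(resolution)) / (8.0 * np.pi**2)
    cutoff_sigmas = 4.5
    axes = [origin[a] + step[a] * np.arange(shape[a]) for a in range(3)]

    for pos, weight, s2 in zip(positions, weights, sigma2):
        radius = cutoff_sigmas * np.sqrt(s2)
        sub = []
        ok = True
        for a in range(3):
            i0 = int(np.floor((pos[a] - radius - origin[a]) / step[a]))
            i1 = int(np.ceil((pos[a] + radius - origin[a]) / step[a])) + 1
            i0, i1 = max(i0, 0), min(i1, shape[a])
            if i0 >= i1:
                ok = False
                break
            sub.append((i0, i1))
        if not ok:
            continue
        (x0, x1), (y0, y1), (z0, z1) = sub
        dx2 = (axes[0][x0:x1] - pos[0]) ** 2
        dy2 = (axes[1][y0:y1] - pos[1]) ** 2
        dz2 = (axes[2][z0:z1] - pos[2]) ** 2
        r2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        norm = weight / (2.0 * np.pi * s2) ** 1.5
        values[x0:x1, y0:y1, z0:z1] += norm * np.exp(-r2 / (2.0 * s2))

    return DensityMap(values, step.copy(), np.asarray(origin, dtype=float).copy())


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


@dataclass
class ResidueProfile:
    """Per-residue scalar tracks aligned 1:1 with a model's residues."""

    keys: list[tuple[str, int]]
    local_cc: np.ndarray
    plddt: np.ndarray | None = None
    smoothed_cc: np.ndarray | None = None
    smoothed_plddt: np.ndarray | None = None
    window: int = 10
    low_point_flags: np.ndarray | None = None
    segment_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.keys)


def _check_coverage(density: DensityMap, positions: np.ndarray,
                    min_fraction: float = 0.8) -> None:
    inside = density.contains(positions)
    fraction = inside.mean() if len(inside) else 0.0
    if fraction == 0.0:
        raise MapCoverageError("model lies entirely outside the map grid")
    if fraction < min_fraction:
        raise MapCoverageError(
            f"only {100 * fraction:.0f}% of atoms inside the map grid "
            f"(need >= {100 * min_fraction:.0f}%)")


def _mask_indices(density: DensityMap, positions: np.ndarray, radius: float
                  ) -> np.ndarray:
    """Flat indices of grid points within ``radius`` of any given position."""
    shape = np.array(density.shape)
    hits: set[int] = set()
    for pos in positions:
        lo = np.maximum(np.floor((pos - radius - density.origin) / density.spacing), 0
                        ).astype(int)
        hi = np.minimum(np.ceil((pos + radius - density.origin) / density.spacing),
                        shape - 1).astype(int)
        if np.any(lo > hi):
            continue
        ranges = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
        dists2 = [(density.origin[a] + ranges[a] * density.spacing[a] - pos[a]) ** 2
                  for a in range(3)]
        r2 = (dists2[0][:, None, None] + dists2[1][None, :, None]
              + dists2[2][None, None, :])
        sel = r2 <= radius * radius
        if not np.any(sel):
            continue
        gx, gy, gz = np.meshgrid(ranges[0], ranges[1], ranges[2], indexing="ij")
        flat = np.ravel_multi_index((gx[sel], gy[sel], gz[sel]), density.shape)
        hits.update(flat.tolist())
    return np.fromiter(hits, dtype=np.int64, count=len(hits))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def chain_breaks(model: AtomicModel) -> np.ndarray:
    """Segment id per residue; a new segment starts at each chain break.

    Breaks occur between different chains, at residue-number gaps > 1 and
    where consecutive CA atoms are more than 4.2 A apart.
    """
    ids = []
    seg = 0
    prev = None  # (chain_id, number, ca_position)
    for cid, residue in model.iter_chain_residues():
        ca = residue.ca
        pos = ca.position if ca is not None else None
        if prev is not None:
            broken = (cid != prev[0] or residue.number - prev[1] > 1)
            if not broken and pos is not None and prev[2] is not None:
                broken = np.linalg.norm(pos - prev[2]) > CHAIN_BREAK_DISTANCE
            if broken:
                seg += 1
        ids.append(seg)
        prev = (cid, residue.number, pos)
    return np.asarray(ids, dtype=int)


def smooth_track(values: np.ndarray, window: int,
                 segment_ids: np.ndarray | None = None) -> np.ndarray:
    """Centred moving average within contiguous segments.

    The window shrinks symmetrically near segment ends so that output length
    equals input length and smoothing never crosses a chain break.  Window 1
    is the identity.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if segment_ids is None:
        segment_ids = np.zeros(len(values), dtype=int)
    out = np.empty_like(values)
    half = window // 2
    for seg in np.unique(segment_ids):
        idx = np.where(segment_ids == seg)[0]
        track = values[idx]
        n = len(track)
        for j in range(n):
            h = min(half, j, n - 1 - j)
            out[idx[j]] = track[j - h: j + h + 1].mean()
    return out


def local_cc(model: AtomicModel, density: DensityMap,
             mask_radius: float = DEFAULT_MASK_RADIUS,
             resolution: float = 3.0) -> ResidueProfile:
    """Per-residue Pearson correlation between a map and the model's own map.

    For each residue the correlation is computed over grid points within
    ``mask_radius`` of any of its atoms.  Residues with fewer than
    ``MIN_MASK_POINTS`` masked points get cc = 0 and a flag.
    """
    positions, _, _ = _atom_arrays(model)
    _check_coverage(density, positions)
    model_map = model_to_map(model, resolution=resolution, grid_like=density)

    exp_flat = density.values.ravel()
    calc_flat = model_map.values.ravel()

    keys = []
    ccs = []
    flags = []
    for cid, residue in model.iter_chain_residues():
        keys.append((cid, residue.number))
        atom_pos = np.array([a.position for a in residue.atoms])
        idx = _mask_indices(density, atom_pos, mask_radius)
        if idx.size < MIN_MASK_POINTS:
            ccs.append(0.0)
            flags.append(True)
        else:
            ccs.append(_pearson(exp_flat[idx], calc_flat[idx]))
            flags.append(False)
    return ResidueProfile(keys=keys, local_cc=np.array(ccs),
                          low_point_flags=np.array(flags, dtype=bool),
                          segment_ids=chain_breaks(model))


def global_cc(model: AtomicModel, density: DensityMap, optimize: bool = False,
              resolution: float = 3.0) -> tuple[float, float, float]:
    """Whole-model masked map correlation.

    With ``optimize`` the mask radius is searched over {1.5, 2.0, 2.5, 3.0} A
    and a per-atom-beyond-CA B increment over {0, 10, 20, 40} A^2, returning
    the maximized correlation and the argmax; without, the defaults
    (radius 2.5 A, increment 0) are used.  The correlation is global over the
    union-of-spheres mask, mean-subtracted inside the mask.
    """
    positions, _, _ = _atom_arrays(model)
    _check_coverage(density, positions)
    exp_flat = density.values.ravel()

    def evaluate(radius: float, increment: float) -> float:
        calc = model_to_map(model, resolution=resolution, grid_like=density,
                            side_chain_b_increment=increment)
        idx = _mask_indices(density, positions, radius)
        if idx.size < MIN_MASK_POINTS:
            return 0.0
        return _pearson(exp_flat[idx], calc.values.ravel()[idx])

    if not optimize:
        return evaluate(DEFAULT_MASK_RADIUS, 0.0), DEFAULT_MASK_RADIUS, 0.0

    best = (-np.inf, DEFAULT_MASK_RADIUS, 0.0)
    for increment in _INCREMENT_GRID:
        calc = model_to_map(model, resolution=resolution, grid_like=density,
                            side_chain_b_increment=increment)
        calc_flat = calc.values.ravel()
        for radius in _RADIUS_GRID:
            idx = _mask_indices(density, positions, radius)
            if idx.size < MIN_MASK_POINTS:
                continue
            cc = _pearson(exp_flat[idx], calc_flat[idx])
            if cc > best[0]:
                best = (cc, radius, increment)
    return best
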