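"""Model-model comparison: superposition, r.m.s.d., completeness within 2 A,
coverage, symmetry-aware mapping and prediction assessment."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .confidence import residue_plddt
from .density import smooth_track
from .model_io import AtomicModel, SymmetryOperator, extract_ca

#: CA-CA distance threshold (A) for counting a reference CA as "matched".
COMPLETENESS_DISTANCE = 2.0

#: Maximum CA-CA distance (A) for nearest-atom residue pairing.
NEAREST_PAIRING_DISTANCE = 5.0


class ComparisonError(Exception):
    """No residue pairs could be established between the models."""


@dataclass
class RigidTransform:
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray  # 3-vector

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass
class ComparisonResult:
    rmsd: float
    n_matched: int
    completeness: float  # percent of reference CAs within 2 A of a mobile CA
    coverage: float  # percent of reference residues paired with a mobile residue
    per_residue_distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    pair_keys: list[tuple[str, int]] = field(default_factory=list)
    operator_index: int | None = None
    origin_shift: tuple[float, float, float] | None = None
    transform: RigidTransform | None = None


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray
           ) -> tuple[RigidTransform, float]:
    """Least-squares superposition of B onto A.

    Returns the proper rigid transform T minimizing ||A - T(B)|| and the
    residual r.m.s.d.  Requires at least 3 non-collinear pairs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    if len(a) < 3:
        raise ComparisonError("need at least 3 coordinate pairs to superpose")
    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    a0 = a - centroid_a
    b0 = b - centroid_b
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise ComparisonError("degenerate (collinear) geometry")
    rot, _ = Rotation.align_vectors(a0, b0)
    rotation = rot.as_matrix()
    translation = centroid_a - rotation @ centroid_b
    transform = RigidTransform(rotation, translation)
    moved = transform.apply(b)
    rmsd = float(np.sqrt(np.mean(np.sum((a - moved) ** 2, axis=1))))
    return transform, rmsd


def _paired_cas(reference: AtomicModel, mobile: AtomicModel, pairing: str
                ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    ref_entries, _ = extract_ca(reference)
    mob_entries, _ = extract_ca(mobile)
    if pairing == "number":
        mob_index = {(cid, num): pos for cid, num, pos in mob_entries}
        keys, ref_pos, mob_pos = [], [], []
        for cid, num, pos in ref_entries:
            partner = mob_index.get((cid, num))
            if partner is not None:
                keys.append((cid, num))
                ref_pos.append(pos)
                mob_pos.append(partner)
    elif pairing == "nearest":
        mob_coords = np.array([pos for _, _, pos in mob_entries])
        tree = cKDTree(mob_coords)
        keys, ref_pos, mob_pos = [], [], []
        for cid, num, pos in ref_entries:
            dist, j = tree.query(pos, distance_upper_bound=NEAREST_PAIRING_DISTANCE)
            if np.isfinite(dist):
                keys.append((cid, num))
                ref_pos.append(pos)
                mob_pos.append(mob_coords[j])
    else:
        raise ValueError(f"unknown pairing rule {pairing!r}")
    if not keys:
        raise ComparisonError("no residue pairs between the models")
    return np.array(ref_pos), np.array(mob_pos), keys


def compare_models(reference: AtomicModel, mobile: AtomicModel,
                   superpose: bool = False, pairing: str = "number"
                   ) -> ComparisonResult:
    """Compare two models on paired CA atoms.

    Completeness is the percentage of the reference's CA atoms lying within
    2 A of any CA of the mobile model; coverage is the percentage of
    reference residues that found a pairing partner.
    """
    ref_entries, _ = extract_ca(reference)
    n_ref = len(ref_entries)
    if n_ref == 0:
        raise ComparisonError("reference model has no CA atoms")
    ref_pos, mob_pos, keys = _paired_cas(reference, mobile, pairing)

    transform = None
    if superpose:
        transform, _ = kabsch(ref_pos, mob_pos)
        mob_all = np.array([pos for _, _, pos in extract_ca(mobile)[0]])
        mob_all = transform.apply(mob_all)
        mob_pos = transform.apply(mob_pos)
    else:
        mob_all = np.array([pos for _, _, pos in extract_ca(mobile)[0]])

    distances = np.linalg.norm(ref_pos - mob_pos, axis=1)
    rmsd = float(np.sqrt(np.mean(distances**2)))

    tree = cKDTree(mob_all)
    ref_all = np.array([pos for _, _, pos in ref_entries])
    nearest, _ = tree.query(ref_all)
    completeness = 100.0 * float(np.mean(nearest <= COMPLETENESS_DISTANCE))
    coverage = 100.0 * len(keys) / n_ref

    return ComparisonResult(rmsd=rmsd, n_matched=len(keys),
                            completeness=completeness, coverage=coverage,
                            per_residue_distances=distances, pair_keys=keys,
                            transform=transform)


def _apply_operator(model: AtomicModel, op: SymmetryOperator,
                    cell: tuple[float, float, float] | None,
                    extra_shift: np.ndarray) -> AtomicModel:
    """Transform a model by a symmetry operator plus a fractional origin shift."""
    out = model.copy()
    coords = out.coordinates()
    if op.fractional:
        if cell is None:
            raise ValueError("fractional symmetry operators require cell lengths")
        cell_arr = np.asarray(cell, dtype=float)
        frac = coords / cell_arr
        frac = frac @ op.rotation.T + op.translation + extra_shift
        coords = frac * cell_arr
    else:
        coords = coords @ op.rotation.T + op.translation + extra_shift
    out.set_coordinates(coords)
    return out


def symmetry_expand_best(reference: AtomicModel, mobile: AtomicModel,
                         operators: list[SymmetryOperator] | None,
                         cell: tuple[float, float, float] | None = None,
                         pairing: str = "nearest") -> ComparisonResult:
    """Best comparison over all operator images of the mobile model.

    Each operator image (with every allowed origin shift on a half-step
    grid per axis) is scored with :func:`compare_models`; the best result
    maximizes completeness, ties broken by minimum r.m.s.d.  Without
    operators the identity is used (with a warning).
    """
    if not operators:
        import warnings
        warnings.warn("no symmetry operators supplied; comparing identity only")
        operators = [SymmetryOperator(np.eye(3), np.zeros(3), fractional=False)]

    best: ComparisonResult | None = None
    for op_index, op in enumerate(operators):
        shift_options = []
        for axis in range(3):
            allowed = op.allowed_origin_shift[axis]
            shift_options.append((0.0, 0.5) if allowed != 0 else (0.0,))
        for shift in product(*shift_options):
            image = _apply_operator(mobile, op, cell, np.asarray(shift))
            try:
                result = compare_models(reference, image, superpose=False,
                                        pairing=pairing)
            except ComparisonError:
                continue
            result.operator_index = op_index
            result.origin_shift = shift
            if best is None or (result.completeness, -result.rmsd) > \
                    (best.completeness, -best.rmsd):
                best = result
    if best is None:
        raise ComparisonError("no operator image produced any residue pairing")
    return best


def assess_prediction(predicted: AtomicModel, deposited: AtomicModel,
                      plddt_cutoff: float = 70.0, rmsd_window: int = 10,
                      rmsd_cap: float = 3.0) -> tuple[float | None, float]:
    """Filtered accuracy of a prediction against a deposited structure.

    After pairing and least-squares superposition, residues with confidence
    below ``plddt_cutoff`` are removed, then residues whose per-residue CA
    deviation smoothed over ``rmsd_window`` residues exceeds ``rmsd_cap``.
    Returns (rmsd over survivors re-superposed, coverage as percent of
    deposited residues matched); rmsd is None when everything is filtered.
    """
    ref_entries, _ = extract_ca(deposited)
    n_ref = len(ref_entries)
    ref_pos, mob_pos, keys = _paired_cas(deposited, predicted, "number")
    transform, _ = kabsch(ref_pos, mob_pos)
    mob_pos = transform.apply(mob_pos)

    plddt_by_key = dict(zip(predicted.residue_keys(), residue_plddt(predicted)))
    confident = np.array([plddt_by_key.get(k, 0.0) >= plddt_cutoff for k in keys])

    ref_pos = ref_pos[confident]
    mob_pos = mob_pos[confident]
    keys = [k for k, ok in zip(keys, confident) if ok]
    if not keys:
        return None, 0.0

    distances = np.linalg.norm(ref_pos - mob_pos, axis=1)
    smoothed = smooth_track(distances, rmsd_window)
    keep = smoothed <= rmsd_cap
    ref_pos = ref_pos[keep]
    mob_pos = mob_pos[keep]
    if ref_pos.shape[0] == 0:
        return None, 0.0
    coverage = 100.0 * ref_pos.shape[0] / n_ref
    if ref_pos.shape[0] >= 3:
        _, rmsd = kabsch(ref_pos, mob_pos)
    else:
        rmsd = float(np.sqrt(np.mean(np.sum((ref_pos - mob_pos) ** 2, axis=1))))
    return rmsd, coverage
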