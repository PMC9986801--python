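"""Deterministic synthetic fixtures: toy folds, perturbed "predictions" with
simulated confidence tracks, and model-derived maps with optional noise.

Every generator is a pure function of its spec and seed, so fixtures are
rebuilt at test time rather than shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .density import DensityMap, model_to_map, smooth_track
from .model_io import Atom, AtomicModel, Chain, Residue

#: Ideal alpha-helix geometry for the CA trace.
HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.28  # A; gives consecutive CA-CA distances of ~3.8 A

#: Simulated-confidence model: plddt = 90 - ERROR_TO_PLDDT * smoothed error.
ERROR_TO_PLDDT = 10.0
PLDDT_FLOOR, PLDDT_CEIL = 20.0, 98.0


@dataclass
class RegionPerturbation:
    """Perturbation applied to one contiguous region of a prediction."""

    rmsd: float = 0.0  # target CA rmsd from random displacement (A)
    rotation_deg: float = 0.0  # rigid rotation about the region centroid
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class FixtureSpec:
    fold: str = "two_domain"  # helix | two_domain | three_domain
    n_res: int = 40  # residues per unit
    perturbations: list[RegionPerturbation] = field(default_factory=list)
    map_resolution: float = 3.0
    map_spacing: float = 1.0
    map_noise_sd: float = 0.0  # fraction of peak density
    seed: int = 0

    @property
    def n_domains(self) -> int:
        return {"helix": 1, "two_domain": 2, "three_domain": 3}[self.fold]


def _helix_ca(n_res: int, start_index: int = 0) -> np.ndarray:
    i = np.arange(start_index, start_index + n_res)
    theta = np.deg2rad(HELIX_TWIST) * i
    return np.stack([HELIX_RADIUS * np.cos(theta),
                     HELIX_RADIUS * np.sin(theta),
                     HELIX_RISE * i], axis=1)


def _backbone_atoms(ca_trace: np.ndarray, index: int, b_iso: float) -> list[Atom]:
    """Poly-alanine N, CA, C, O, CB around one CA, oriented by the trace."""
    ca = ca_trace[index]
    nxt = ca_trace[min(index + 1, len(ca_trace) - 1)]
    prv = ca_trace[max(index - 1, 0)]
    tangent = nxt - prv
    norm = np.linalg.norm(tangent)
    tangent = tangent / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, tangent)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    normal = np.cross(tangent, ref)
    normal /= np.linalg.norm(normal)
    binormal = np.cross(tangent, normal)
    return [
        Atom("N", "N", ca - 1.46 * tangent + 0.3 * normal, b_iso),
        Atom("CA", "C", ca.copy(), b_iso),
        Atom("C", "C", ca + 1.52 * tangent + 0.3 * normal, b_iso),
        Atom("O", "O", ca + 1.8 * tangent + 1.2 * normal, b_iso),
        Atom("CB", "C", ca + 1.53 * binormal, b_iso),
    ]


def _model_from_ca_trace(ca_trace: np.ndarray, chain_id: str = "A",
                         first_number: int = 1, b_iso: float = 20.0,
                         provenance: str = "deposited") -> AtomicModel:
    chain = Chain(chain_id)
    for i in range(len(ca_trace)):
        residue = Residue(first_number + i, "ALA",
                          atoms=_backbone_atoms(ca_trace, i, b_iso))
        chain.residues.append(residue)
    return AtomicModel([chain], provenance)  # type: ignore[arg-type]


def make_true_model(spec: FixtureSpec) -> AtomicModel:
    """Ideal poly-alanine toy fold: one helix, or several offset/rotated ones.

    Domain placement scales with the helix length so that randomly rotated
    domains can never come within contact distance of each other; the layout
    is deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    offset_step = spec.n_res * HELIX_RISE + 16.0
    traces = []
    for d in range(spec.n_domains):
        trace = _helix_ca(spec.n_res)
        trace -= trace.mean(axis=0)
        if d > 0:
            rot = Rotation.from_euler("xyz", rng.uniform(0, 360, 3), degrees=True)
            trace = trace @ rot.as_matrix().T
            trace = trace + np.array([offset_step * d, 5.0 * d, 0.0])
        traces.append(trace)
    full = np.concatenate(traces, axis=0)
    return _model_from_ca_trace(full, b_iso=20.0)


def _domain_slices(spec: FixtureSpec) -> list[slice]:
    return [slice(d * spec.n_res, (d + 1) * spec.n_res)
            for d in range(spec.n_domains)]


def make_prediction(true_model: AtomicModel, spec: FixtureSpec) -> AtomicModel:
    """Inaccurate "prediction": per-region noise/rotation plus simulated pLDDT.

    Region ``k`` (a domain of the fold) receives ``spec.perturbations[k]``
    (missing entries mean unperturbed).  Random displacements are rescaled
    so the realized region CA rmsd equals the requested value exactly.
    Confidence is written into b_iso as 90 - 10 * (smoothed local error, A),
    clipped to [20, 98].
    """
    rng = np.random.default_rng(spec.seed + 1)
    prediction = true_model.copy()
    prediction.provenance = "predicted"

    residues = list(prediction.iter_residues())
    n = len(residues)
    true_ca = np.array([r.ca.position for r in true_model.iter_residues()])

    for k, region in enumerate(_domain_slices(spec)):
        pert = (spec.perturbations[k] if k < len(spec.perturbations)
                else RegionPerturbation())
        members = residues[region]
        if not members:
            continue
        coords = np.array([a.position for r in members for a in r.atoms])
        centroid = np.array([r.ca.position for r in members]).mean(axis=0)
        if pert.rotation_deg:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            rot = Rotation.from_rotvec(np.deg2rad(pert.rotation_deg) * axis)
            coords = (coords - centroid) @ rot.as_matrix().T + centroid
        coords = coords + np.asarray(pert.translation, dtype=float)
        if pert.rmsd > 0:
            # one displacement per residue, smoothed along the chain so the
            # backbone stays continuous (prediction error is locally coherent)
            disp = rng.normal(size=(len(members), 3))
            disp = np.stack([smooth_track(disp[:, a], 9) for a in range(3)], axis=1)
            realized = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
            disp *= pert.rmsd / realized
            per_atom = np.repeat(disp, [len(r.atoms) for r in members], axis=0)
            coords = coords + per_atom
        i = 0
        for residue in members:
            for atom in residue.atoms:
                atom.position = coords[i]
                i += 1

    # simulated confidence anti-correlated with the realized local error
    pred_ca = np.array([r.ca.position for r in residues])
    error = np.linalg.norm(pred_ca - true_ca, axis=1)
    smoothed_error = smooth_track(error, 5)
    plddt = np.clip(90.0 - ERROR_TO_PLDDT * smoothed_error,
                    PLDDT_FLOOR, PLDDT_CEIL)
    for value, residue in zip(plddt, residues):
        for atom in residue.atoms:
            atom.b_iso = float(value)
    return prediction


def make_map(model: AtomicModel, resolution: float = 3.0, noise_sd: float = 0.0,
             seed: int = 0, spacing: float = 1.0) -> DensityMap:
    """Model-derived map plus seeded Gaussian grid noise (sd as peak fraction)."""
    density = model_to_map(model, spacing=spacing, resolution=resolution)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        peak = float(density.values.max())
        density.values = density.values + rng.normal(
            scale=noise_sd * peak, size=density.shape)
    return density


def make_fixture(spec: FixtureSpec) -> tuple[AtomicModel, AtomicModel, DensityMap]:
    """(truth, prediction, map) triple for a spec — the standard entry point."""
    truth = make_true_model(spec)
    prediction = make_prediction(truth, spec)
    density = make_map(truth, resolution=spec.map_resolution,
                       noise_sd=spec.map_noise_sd, seed=spec.seed,
                       spacing=spec.map_spacing)
    return truth, prediction, density
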