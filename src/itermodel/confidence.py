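"""Processing of predicted models: confidence trimming, pLDDT-to-ADP
conversion and splitting into compact domains.

Predicted models carry per-residue confidence (pLDDT, 0-100 or 0-1) in the
B-factor field; the residue-level confidence is taken from the CA atom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model_io import AtomicModel, EmptyModelError, ca_coords


@dataclass
class ConfidenceParams:
    """Parameters for predicted-model processing.

    ``plddt_cutoff`` is on the percent scale; models on the fractional scale
    are normalized before comparison.
    """

    plddt_cutoff: float = 70.0
    plddt_scale: str = "auto"  # percent | fraction | auto
    min_domain_residues: int = 10
    contact_distance: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.plddt_cutoff <= 100):
            raise ValueError(f"plddt_cutoff must be in (0, 100], got {self.plddt_cutoff}")
        if self.min_domain_residues < 1:
            raise ValueError("min_domain_residues must be >= 1")


class AllTrimmedError(Exception):
    """Every residue fell below the confidence cutoff."""


def detect_plddt_scale(model: AtomicModel) -> str:
    """``fraction`` if all confidence values are <= 1.0, else ``percent``."""
    values = residue_plddt(model, scale="raw")
    return "fraction" if values.size and values.max() <= 1.0 else "percent"


def residue_plddt(model: AtomicModel, scale: str = "auto") -> np.ndarray:
    """Per-residue confidence (CA b_iso), optionally normalized to percent.

    Residues without a CA fall back to the mean b_iso of their atoms.
    """
    values = []
    for residue in model.iter_residues():
        ca = residue.ca
        if ca is not None:
            values.append(ca.b_iso)
        elif residue.atoms:
            values.append(float(np.mean([a.b_iso for a in residue.atoms])))
        else:
            values.append(0.0)
    arr = np.asarray(values, dtype=float)
    if scale == "raw":
        return arr
    if scale == "auto":
        scale = "fraction" if (arr.size and arr.max() <= 1.0) else "percent"
    if scale == "fraction":
        arr = arr * 100.0
    return arr


def trim_low_confidence(model: AtomicModel, params: ConfidenceParams | None = None) -> AtomicModel:
    """Remove residues with confidence strictly below the cutoff."""
    params = params or ConfidenceParams()
    scale = params.plddt_scale if params.plddt_scale != "auto" else "auto"
    plddt = residue_plddt(model, scale=scale)
    keys = model.residue_keys()
    kept = [key for key, p in zip(keys, plddt) if p >= params.plddt_cutoff]
    if not kept:
        raise AllTrimmedError(
            f"all {len(keys)} residues fall below pLDDT cutoff {params.plddt_cutoff}")
    return model.select_residues(kept)


def plddt_to_adp(plddt: float | np.ndarray) -> float | np.ndarray:
    """Convert a percent-scale pLDDT to an estimated isotropic ADP (A^2).

    Uses the error-vs-confidence fit d = 1.5 * exp(4 * (0.7 - lddt)) with
    lddt fractional, mapped to B via B = (8 pi^2 / 3) d^2.  Strictly
    decreasing in pLDDT; pLDDT 70 corresponds to d = 1.5 A (B ~ 59.2 A^2).
    """
    arr = np.asarray(plddt, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("pLDDT values must be within [0, 100]")
    d = 1.5 * np.exp(4.0 * (0.7 - arr / 100.0))
    b = (8.0 * np.pi**2 / 3.0) * d**2
    return float(b) if np.isscalar(plddt) else b


def convert_plddt_to_adp(model: AtomicModel) -> AtomicModel:
    """Return a copy whose b_iso fields hold ADPs derived from the pLDDTs.

    All atoms of a residue receive the ADP of the residue's confidence.
    The result is flagged ``rebuilt``-style provenance-wise it no longer
    carries confidence, so the predicted flag is cleared.
    """
    scale = detect_plddt_scale(model)
    out = model.copy()
    plddt = residue_plddt(model, scale=scale)
    for value, residue in zip(plddt, out.iter_residues()):
        adp = plddt_to_adp(float(np.clip(value, 0.0, 100.0)))
        for atom in residue.atoms:
            atom.b_iso = adp
    out.provenance = "rebuilt"
    return out


def split_into_domains(model: AtomicModel, params: ConfidenceParams | None = None
                       ) -> list[AtomicModel]:
    """Partition residues into spatially compact groups.

    Connected components of the non-local CA contact graph: CA pairs closer
    than ``contact_distance`` whose sequence separation is at least 3 (bonded
    neighbours alone cannot hold a domain together, which lets extended
    linkers fall out as their own fragments).  Components smaller than
    ``min_domain_residues`` are merged into the spatially nearest larger
    group.  Groups are sequence-sorted internally and ordered by first
    residue.
    """
    params = params or ConfidenceParams()
    keys = []
    coords = []
    for cid, residue in model.iter_chain_residues():
        ca = residue.ca
        if ca is not None:
            keys.append((cid, residue.number))
            coords.append(ca.position)
    if not keys:
        raise EmptyModelError("no CA atoms to cluster")
    coords = np.array(coords)
    n = len(keys)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(params.contact_distance, output_type="ndarray")
    edges = []
    for i, j in pairs:
        same_chain = keys[i][0] == keys[j][0]
        if not same_chain or abs(keys[i][1] - keys[j][1]) >= 3:
            edges.append((i, j))
    if edges:
        arr = np.asarray(edges)
        rows = np.concatenate([arr[:, 0], arr[:, 1]])
        cols = np.concatenate([arr[:, 1], arr[:, 0]])
        graph = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    else:
        graph = csr_matrix((n, n))
    _, labels = connected_components(graph, directed=False)

    # merge undersized components into the nearest sufficiently large one
    sizes = np.bincount(labels)
    big = [l for l in range(sizes.size) if sizes[l] >= params.min_domain_residues]
    if big:
        for label in range(sizes.size):
            if sizes[label] >= params.min_domain_residues:
                continue
            members = labels == label
            centroid = coords[members].mean(axis=0)
            nearest = min(big, key=lambda l: np.linalg.norm(
                coords[labels == l] - centroid, axis=1).min())
            labels[members] = nearest
    else:
        labels[:] = labels[0]  # everything merges into a single group

    domains = []
    for label in sorted(set(labels), key=lambda l: int(np.argmax(labels == l))):
        member_keys = [keys[i] for i in range(n) if labels[i] == label]
        domains.append(model.select_residues(member_keys))
    return domains
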