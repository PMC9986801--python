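"""Superpose-and-morph: deform a full-length model onto a target model.

Rigid anchors are maximal runs of consecutive residues that match the target
under a run-local least-squares fit; residues outside anchors move by an
exponential-in-sequence-distance blend of the anchor transforms, so the
deformation is continuous along the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import ComparisonError, RigidTransform, kabsch
from .model_io import AtomicModel, extract_ca

#: Sequence-distance decay length (residues) of the anchor blend weights.
BLEND_TAU = 10.0


class NoAnchorsError(Exception):
    """No matching run of residues could be found between the models."""


@dataclass
class Anchor:
    chain_id: str
    moving_range: tuple[int, int]  # residue numbers, inclusive
    target_range: tuple[int, int]
    transform: RigidTransform
    indices: list[int] = field(default_factory=list)  # positions in pair list


@dataclass
class AnchorSet:
    anchors: list[Anchor]

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)


@dataclass
class MorphResult:
    model: AtomicModel
    anchors: AnchorSet
    max_local_distortion: float  # largest shift difference between neighbours (A)


@dataclass
class MorphParams:
    min_anchor: int = 5
    match_distance: float = 3.0


def _paired_ca(moving: AtomicModel, target: AtomicModel
               ) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    target_index = {(cid, num): pos for cid, num, pos in extract_ca(target)[0]}
    keys, mov, tgt = [], [], []
    for cid, num, pos in extract_ca(moving)[0]:
        partner = target_index.get((cid, num))
        if partner is not None:
            keys.append((cid, num))
            mov.append(pos)
            tgt.append(partner)
    if not keys:
        raise NoAnchorsError("models share no (chain, residue-number) pairs")
    return keys, np.array(mov), np.array(tgt)


def _run_fit(mov: np.ndarray, tgt: np.ndarray) -> tuple[RigidTransform, float]:
    """Fit moving run onto target run; returns transform and max pair error."""
    transform, _ = kabsch(tgt, mov)
    moved = transform.apply(mov)
    return transform, float(np.max(np.linalg.norm(moved - tgt, axis=1)))


def find_anchors(moving: AtomicModel, target: AtomicModel,
                 min_anchor: int = 5, match_distance: float = 3.0) -> AnchorSet:
    """Maximal runs of consecutive paired residues matching under local fits.

    Runs are seeded with ``min_anchor`` consecutive pairs and grown greedily
    while every paired CA distance stays strictly below ``match_distance``
    under the run's own least-squares transform.
    """
    keys, mov, tgt = _paired_ca(moving, target)
    n = len(keys)
    # group pair indices into consecutive stretches (same chain, number step 1)
    stretches: list[list[int]] = [[0]]
    for i in range(1, n):
        prev_cid, prev_num = keys[i - 1]
        cid, num = keys[i]
        if cid == prev_cid and num == prev_num + 1:
            stretches[-1].append(i)
        else:
            stretches.append([i])

    anchors: list[Anchor] = []
    for stretch in stretches:
        pos = 0
        while pos + min_anchor <= len(stretch):
            seed = stretch[pos:pos + min_anchor]
            try:
                transform, err = _run_fit(mov[seed], tgt[seed])
            except ComparisonError:
                pos += 1
                continue
            if err >= match_distance:
                pos += 1
                continue
            end = pos + min_anchor
            run = list(seed)
            while end < len(stretch):
                candidate = run + [stretch[end]]
                t2, err2 = _run_fit(mov[candidate], tgt[candidate])
                if err2 >= match_distance:
                    break
                run = candidate
                transform = t2
                end += 1
            anchors.append(Anchor(
                chain_id=keys[run[0]][0],
                moving_range=(keys[run[0]][1], keys[run[-1]][1]),
                target_range=(keys[run[0]][1], keys[run[-1]][1]),
                transform=transform,
                indices=run,
            ))
            pos = end
    if not anchors:
        raise NoAnchorsError(
            f"no run of {min_anchor}+ residues matches within {match_distance} A")
    _refine_anchor_boundaries(anchors, keys, mov, tgt)
    return AnchorSet(anchors)


def _refine_anchor_boundaries(anchors: list[Anchor],
                              keys: list[tuple[str, int]],
                              mov: np.ndarray, tgt: np.ndarray,
                              max_rounds: int = 5) -> None:
    """Reassign hinge residues between adjacent anchors.

    Greedy growth can drag a run across a hinge (errors drift up to the match
    threshold).  Each boundary residue is handed to whichever neighbouring
    anchor's transform fits it better; transforms are refit until stable.
    """

    def err(anchor: Anchor, i: int) -> float:
        return float(np.linalg.norm(anchor.transform.apply(mov[i]) - tgt[i]))

    for _ in range(max_rounds):
        changed = False
        for a, b in zip(anchors, anchors[1:]):
            if a.chain_id != b.chain_id:
                continue
            # migrate trailing residues of a forward into b
            while len(a.indices) > 3 and err(b, a.indices[-1]) < err(a, a.indices[-1]):
                b.indices.insert(0, a.indices.pop())
                changed = True
            # migrate leading residues of b backward into a
            while len(b.indices) > 3 and err(a, b.indices[0]) < err(b, b.indices[0]):
                a.indices.append(b.indices.pop(0))
                changed = True
        if not changed:
            break
        for anchor in anchors:
            anchor.transform, _ = _run_fit(mov[anchor.indices], tgt[anchor.indices])
    for anchor in anchors:
        anchor.moving_range = (keys[anchor.indices[0]][1],
                               keys[anchor.indices[-1]][1])
        anchor.target_range = anchor.moving_range


def _residue_weights(moving: AtomicModel, anchors: AnchorSet
                     ) -> list[np.ndarray]:
    """Per-residue normalized blend weights over the anchors."""
    # sequence position of each residue, per chain
    weights = []
    chain_anchor_spans: dict[str, list[tuple[int, int, int]]] = {}
    for a_idx, anchor in enumerate(anchors):
        chain_anchor_spans.setdefault(anchor.chain_id, []).append(
            (anchor.moving_range[0], anchor.moving_range[1], a_idx))

    n_anchors = len(anchors)
    for cid, residue in moving.iter_chain_residues():
        spans = chain_anchor_spans.get(cid)
        if not spans:
            # chain without anchors: uniform blend over all anchors
            weights.append(np.full(n_anchors, 1.0 / n_anchors))
            continue
        w = np.zeros(n_anchors)
        inside = None
        for start, end, a_idx in spans:
            if start <= residue.number <= end:
                inside = a_idx
                break
        if inside is not None:
            w[inside] = 1.0
        else:
            for start, end, a_idx in spans:
                d_seq = min(abs(residue.number - start), abs(residue.number - end))
                w[a_idx] = np.exp(-d_seq / BLEND_TAU)
            w /= w.sum()
        weights.append(w)
    return weights


def direct_morph(moving: AtomicModel, anchors: AnchorSet) -> AtomicModel:
    """Apply anchor transforms with per-residue blending between anchors.

    Residues inside an anchor move rigidly by its transform; all other
    residues move by x -> sum_a w_a T_a(x) with weights exponential in the
    sequence distance to each anchor (decay length 10 residues), normalized.
    All atoms of a residue share the residue's weights.
    """
    if len(anchors) == 0:
        raise NoAnchorsError("empty anchor set")
    out = moving.copy()
    weights = _residue_weights(moving, anchors)
    transforms = [a.transform for a in anchors]
    for w, (_, residue) in zip(weights, out.iter_chain_residues()):
        active = np.nonzero(w)[0]
        for atom in residue.atoms:
            pos = np.zeros(3)
            for a_idx in active:
                pos += w[a_idx] * transforms[a_idx].apply(atom.position)
            atom.position = pos
    return out


def _max_local_distortion(before: AtomicModel, after: AtomicModel) -> float:
    """Largest difference between the shifts of neighbouring residues (A)."""
    before_ca = {(c, n): p for c, n, p in extract_ca(before)[0]}
    prev_key = None
    prev_shift = None
    worst = 0.0
    for cid, num, pos in extract_ca(after)[0]:
        orig = before_ca.get((cid, num))
        if orig is None:
            continue
        shift = pos - orig
        if prev_key == (cid, num - 1) and prev_shift is not None:
            worst = max(worst, float(np.linalg.norm(shift - prev_shift)))
        prev_key = (cid, num)
        prev_shift = shift
    return worst


def superpose_and_morph(moving: AtomicModel, target: AtomicModel,
                        params: MorphParams | None = None) -> MorphResult:
    """Find anchors against the target and morph the moving model onto them.

    The returned result carries a "max local distortion" metric (largest
    shift difference between neighbouring residues); large values signal an
    implausibly deformed model.
    """
    params = params or MorphParams()
    anchors = find_anchors(moving, target, params.min_anchor,
                           params.match_distance)
    morphed = direct_morph(moving, anchors)
    distortion = _max_local_distortion(moving, morphed)
    return MorphResult(model=morphed, anchors=anchors,
                       max_local_distortion=distortion)
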