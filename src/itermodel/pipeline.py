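"""Cycle orchestration: predict -> place -> morph -> refine -> rebuild -> trim,
with keep-if-better selection and a convergence rule tied to resolution.

External engines (structure prediction, molecular-replacement placement,
reciprocal-space refinement, map-based rebuilding) are pluggable interfaces;
deterministic mock implementations are provided in
:mod:`itermodel.engines` so the orchestration logic is fully testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .confidence import AllTrimmedError, ConfidenceParams, trim_low_confidence
from .density import DensityMap
from .metrics import ComparisonError, compare_models, kabsch
from .model_io import AtomicModel, Chain, extract_ca
from .morphing import NoAnchorsError, MorphParams, superpose_and_morph
from .trimming import AllResiduesTrimmedError, TrimParams, trim_to_map

#: Inter-chain CA distance (A) below which docked chains count as clashing.
CLASH_DISTANCE = 3.0


@dataclass
class PipelineConfig:
    resolution: float = 2.5
    cycle_rmsd_to_resolution_ratio: float = 0.25
    min_cycles: int = 3
    max_cycles: int = 10
    trim: TrimParams = field(default_factory=TrimParams)
    confidence: ConfidenceParams = field(default_factory=ConfidenceParams)
    morph: MorphParams = field(default_factory=MorphParams)
    seeds: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        if self.cycle_rmsd_to_resolution_ratio <= 0:
            raise ValueError("convergence ratio must be positive")
        if self.min_cycles < 1:
            raise ValueError("min_cycles must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class CycleRecord:
    cycle: int
    predicted: AtomicModel
    rebuilt: AtomicModel
    trimmed: AtomicModel
    proxy_free_r: float
    rmsd_to_previous: float
    kept: bool
    converged: bool = False


class Predictor(Protocol):
    def predict(self, sequence: str, template: AtomicModel | None) -> AtomicModel: ...


class MREngine(Protocol):
    def place(self, models: list[AtomicModel], data: object) -> AtomicModel: ...


class Refiner(Protocol):
    def refine(self, model: AtomicModel, density: DensityMap
               ) -> tuple[AtomicModel, float]: ...


class Rebuilder(Protocol):
    def rebuild(self, model: AtomicModel, density: DensityMap
                ) -> tuple[AtomicModel, DensityMap]: ...


@dataclass
class EngineSuite:
    predictor: Predictor
    mr_engine: MREngine
    refiner: Refiner
    rebuilder: Rebuilder


class EngineFailure(Exception):
    """An engine failed; carries the partial trajectory."""

    def __init__(self, message: str, trajectory: list[CycleRecord]):
        super().__init__(message)
        self.trajectory = trajectory


def converged(current: AtomicModel, previous: AtomicModel,
              config: PipelineConfig, cycle: int) -> bool:
    """True iff cycle >= min_cycles and the inter-cycle r.m.s.d. is strictly
    below ratio * resolution.  The r.m.s.d. is over shared residues, with no
    superposition (models live in the same frame)."""
    if cycle < config.min_cycles:
        return False
    try:
        result = compare_models(previous, current, superpose=False)
    except ComparisonError:
        return False
    threshold = config.cycle_rmsd_to_resolution_ratio * config.resolution
    return result.rmsd < threshold


def keep_if_better(candidate: tuple[AtomicModel, float],
                   incumbent: tuple[AtomicModel, float] | None
                   ) -> tuple[tuple[AtomicModel, float], bool]:
    """Select the candidate iff its proxy free-R strictly decreases.

    Returns (selected, kept) where kept is True when the candidate won.
    Ties keep the incumbent.
    """
    if incumbent is None:
        return candidate, True
    if candidate[1] < incumbent[1]:
        return candidate, True
    return incumbent, False


def construct_docked(predictions: dict[str, AtomicModel],
                     rebuilt: AtomicModel) -> tuple[AtomicModel, list[tuple[str, str]]]:
    """Rigidly place one full-length prediction per rebuilt chain.

    Each prediction is superposed (least squares on shared CA atoms) onto its
    corresponding rebuilt chain and the placed predictions are concatenated.
    No morphing is applied, so the result may clash; clashing chain pairs
    (any inter-chain CA pair closer than 3 A) are returned as warnings.
    """
    placed_chains: list[Chain] = []
    for chain in rebuilt.chains:
        prediction = predictions.get(chain.id)
        if prediction is None:
            raise KeyError(f"no prediction supplied for rebuilt chain {chain.id!r}")
        rebuilt_chain_model = AtomicModel([chain.copy()])
        target_ca = {(chain.id, num): pos for _, num, pos
                     in extract_ca(rebuilt_chain_model)[0]}
        mov, tgt = [], []
        for cid, num, pos in extract_ca(prediction)[0]:
            partner = target_ca.get((chain.id, num))
            if partner is not None:
                mov.append(pos)
                tgt.append(partner)
        if len(mov) < 3:
            raise ComparisonError(
                f"fewer than 3 shared CA atoms between prediction and chain {chain.id!r}")
        transform, _ = kabsch(np.array(tgt), np.array(mov))
        placed = prediction.copy()
        placed.set_coordinates(transform.apply(placed.coordinates()))
        for pchain in placed.chains:
            placed_chains.append(Chain(chain.id, pchain.residues))

    docked = AtomicModel(placed_chains, provenance="predicted")
    clashes = []
    for i in range(len(placed_chains)):
        ca_i = np.array([r.ca.position for r in placed_chains[i].residues if r.ca])
        for j in range(i + 1, len(placed_chains)):
            ca_j = np.array([r.ca.position for r in placed_chains[j].residues if r.ca])
            if ca_i.size and ca_j.size:
                d = np.linalg.norm(ca_i[:, None, :] - ca_j[None, :, :], axis=2)
                if d.min() < CLASH_DISTANCE:
                    clashes.append((placed_chains[i].id, placed_chains[j].id))
    return docked, clashes


def run_cycles(config: PipelineConfig, engines: EngineSuite,
               sequence: str = "", data: object = None) -> list[CycleRecord]:
    """Run the iterative build loop until convergence or max_cycles.

    Cycle 1: predict (no template) -> confidence-trim -> MR placement ->
    morph the full-length prediction onto the placed model -> refine ->
    rebuild -> trim to map.  Later cycles use the incumbent trimmed model as
    the prediction template and skip MR.  Rebuilt models are only adopted
    when the proxy free-R decreases (keep-if-better); convergence requires
    at least ``min_cycles`` cycles and an inter-cycle r.m.s.d. strictly
    below ``ratio * resolution``.
    """
    trajectory: list[CycleRecord] = []
    incumbent: tuple[AtomicModel, float] | None = None
    previous_trimmed: AtomicModel | None = None
    template: AtomicModel | None = None
    placed: AtomicModel | None = None
    density: DensityMap | None = None

    for cycle in range(1, config.max_cycles + 1):
        try:
            predicted = engines.predictor.predict(sequence, template)
            try:
                processed = trim_low_confidence(predicted, config.confidence)
            except AllTrimmedError:
                processed = predicted
            if cycle == 1:
                placed = engines.mr_engine.place([processed], data)
            # morph the full-length prediction onto the current working model
            morph_target = placed if placed is not None else predicted
            try:
                morphed = superpose_and_morph(predicted, morph_target,
                                              config.morph).model
            except NoAnchorsError:
                morphed = predicted
            refined, proxy_free_r = engines.refiner.refine(morphed, density) \
                if density is not None else engines.refiner.refine(morphed, None)
            rebuilt, density = engines.rebuilder.rebuild(refined, density)
            try:
                trimmed, _ = trim_to_map(rebuilt, density, config.trim)
            except AllResiduesTrimmedError:
                if incumbent is None:
                    raise EngineFailure(
                        f"cycle {cycle}: trimming removed all residues and no "
                        "incumbent model exists", trajectory) from None
                # a fully rejected rebuild: keep the incumbent, flag not-kept
                trimmed = incumbent[0]
                proxy_free_r = float("inf")
        except EngineFailure:
            raise
        except Exception as exc:  # noqa: BLE001 - engine contract violation
            raise EngineFailure(f"cycle {cycle}: engine failure: {exc}",
                                trajectory) from exc

        selected, kept = keep_if_better((trimmed, proxy_free_r), incumbent)
        incumbent = selected
        working = incumbent[0]  # kept=False => the previous model carried forward

        rmsd_prev = float("inf")
        if previous_trimmed is not None:
            try:
                rmsd_prev = compare_models(previous_trimmed, working,
                                           superpose=False).rmsd
            except ComparisonError:
                rmsd_prev = float("inf")

        record = CycleRecord(cycle=cycle, predicted=predicted, rebuilt=rebuilt,
                             trimmed=working, proxy_free_r=proxy_free_r,
                             rmsd_to_previous=rmsd_prev, kept=kept)
        if previous_trimmed is not None:
            record.converged = converged(working, previous_trimmed, config, cycle)
        trajectory.append(record)

        previous_trimmed = working
        template = working
        placed = working
        if record.converged:
            break
    return trajectory
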