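"""Deterministic mock engines for exercising the cycle orchestrator.

Each mock holds the synthetic "truth" (model and/or map) and a seed, so a
whole trajectory is reproducible bit for bit.  The proxy free-R produced by
the mock refiner is 1 - global map correlation against the truth map, mapped
onto the familiar [0.2, 0.6] range, so keep-if-better logic sees realistic
numbers without any reciprocal-space machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .density import DensityMap, global_cc, smooth_track
from .metrics import kabsch
from .model_io import AtomicModel
from .synthetic import ERROR_TO_PLDDT, PLDDT_CEIL, PLDDT_FLOOR


def proxy_free_r(model: AtomicModel, truth_map: DensityMap) -> float:
    """1 - global cc, rescaled onto [0.2, 0.6] (lower is better)."""
    cc, _, _ = global_cc(model, truth_map, optimize=False)
    return 0.2 + 0.4 * (1.0 - max(cc, 0.0))


@dataclass
class MockPredictor:
    """Returns alpha * template + (1 - alpha) * truth plus seeded noise.

    Without a template it returns the configured initial prediction.  The
    confidence track is rewritten each call to stay anti-correlated with the
    realized local error.
    """

    truth: AtomicModel
    initial_prediction: AtomicModel
    alpha: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0
    _calls: int = 0

    def predict(self, sequence: str, template: AtomicModel | None) -> AtomicModel:
        rng = np.random.default_rng(self.seed + 1000 * self._calls)
        self._calls += 1
        if template is None:
            prediction = self.initial_prediction.copy()
        else:
            prediction = self.truth.copy()
            truth_by_key = {key: res for key, res in zip(
                self.truth.residue_keys(), self.truth.iter_residues())}
            template_by_key = {key: res for key, res in zip(
                template.residue_keys(), template.iter_residues())}
            for key, residue in zip(prediction.residue_keys(),
                                    prediction.iter_residues()):
                t_res = template_by_key.get(key)
                truth_res = truth_by_key[key]
                for atom, truth_atom in zip(residue.atoms, truth_res.atoms):
                    t_atom = None
                    if t_res is not None:
                        for cand in t_res.atoms:
                            if cand.name == atom.name:
                                t_atom = cand
                                break
                    if t_atom is not None:
                        atom.position = (self.alpha * t_atom.position
                                         + (1 - self.alpha) * truth_atom.position)
                    else:
                        atom.position = truth_atom.position.copy()
        if self.noise_sd > 0:
            coords = prediction.coordinates()
            coords = coords + rng.normal(scale=self.noise_sd, size=coords.shape)
            prediction.set_coordinates(coords)
        self._write_confidence(prediction)
        prediction.provenance = "predicted"
        return prediction

    def _write_confidence(self, prediction: AtomicModel) -> None:
        truth_ca = {key: res.ca.position for key, res in zip(
            self.truth.residue_keys(), self.truth.iter_residues()) if res.ca}
        residues = list(prediction.iter_residues())
        keys = prediction.residue_keys()
        errors = np.array([
            np.linalg.norm(res.ca.position - truth_ca[key])
            if (res.ca is not None and key in truth_ca) else 5.0
            for key, res in zip(keys, residues)])
        plddt = np.clip(90.0 - ERROR_TO_PLDDT * smooth_track(errors, 5),
                        PLDDT_FLOOR, PLDDT_CEIL)
        for value, residue in zip(plddt, residues):
            for atom in residue.atoms:
                atom.b_iso = float(value)


@dataclass
class MockMREngine:
    """Places a model by superposing it onto the truth (a known rigid fit)."""

    truth: AtomicModel

    def place(self, models: list[AtomicModel], data: object) -> AtomicModel:
        model = models[0]
        truth_ca = {key: res.ca.position for key, res in zip(
            self.truth.residue_keys(), self.truth.iter_residues()) if res.ca}
        mov, tgt = [], []
        for key, residue in zip(model.residue_keys(), model.iter_residues()):
            if residue.ca is not None and key in truth_ca:
                mov.append(residue.ca.position)
                tgt.append(truth_ca[key])
        transform, _ = kabsch(np.array(tgt), np.array(mov))
        placed = model.copy()
        placed.set_coordinates(transform.apply(placed.coordinates()))
        return placed


@dataclass
class MockRefiner:
    """Identity refinement that scores the model against the truth map."""

    truth_map: DensityMap

    def refine(self, model: AtomicModel, density: DensityMap | None
               ) -> tuple[AtomicModel, float]:
        return model.copy(), proxy_free_r(model, self.truth_map)


@dataclass
class MockRebuilder:
    """Moves each atom a bounded step up the truth map's density gradient."""

    truth_map: DensityMap
    step: float = 0.3  # max displacement per rebuild (A)
    degrade_at_cycle: int | None = None  # cycle index at which to inject noise
    degrade_sd: float = 1.0
    seed: int = 0
    _calls: int = 0

    def rebuild(self, model: AtomicModel, density: DensityMap | None
                ) -> tuple[AtomicModel, DensityMap]:
        self._calls += 1
        rebuilt = model.copy()
        coords = rebuilt.coordinates()
        # one step per residue, smoothed along the chain, so rebuilding moves
        # neighbouring residues coherently and never tears the backbone
        residues = list(rebuilt.iter_residues())
        ca_pos = np.array([r.ca.position if r.ca is not None
                           else r.atoms[0].position for r in residues])
        grad = self._gradient_at(ca_pos)
        norms = np.linalg.norm(grad, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        steps = self.step * grad / norms
        steps = np.stack([smooth_track(steps[:, a], 5) for a in range(3)], axis=1)
        coords = coords + np.repeat(steps, [len(r.atoms) for r in residues], axis=0)
        if self.degrade_at_cycle is not None and self._calls == self.degrade_at_cycle:
            rng = np.random.default_rng(self.seed + self._calls)
            coords = coords + rng.normal(scale=self.degrade_sd, size=coords.shape)
        rebuilt.set_coordinates(coords)
        rebuilt.provenance = "rebuilt"
        return rebuilt, self.truth_map.copy()

    def _gradient_at(self, coords: np.ndarray) -> np.ndarray:
        grids = np.gradient(self.truth_map.values, *self.truth_map.spacing)
        idx = self.truth_map.grid_coordinates(coords).T
        return np.stack([
            map_coordinates(g, idx, order=1, mode="nearest") for g in grids
        ], axis=1)


def make_mock_suite(truth: AtomicModel, initial_prediction: AtomicModel,
                    truth_map: DensityMap, seed: int = 0, alpha: float = 0.5,
                    noise_sd: float = 0.02,
                    degrade_at_cycle: int | None = None):
    """Assemble a full mock engine suite around a synthetic fixture."""
    from .pipeline import EngineSuite

    return EngineSuite(
        predictor=MockPredictor(truth=truth, initial_prediction=initial_prediction,
                                alpha=alpha, noise_sd=noise_sd, seed=seed),
        mr_engine=MockMREngine(truth=truth),
        refiner=MockRefiner(truth_map=truth_map),
        rebuilder=MockRebuilder(truth_map=truth_map, seed=seed,
                                degrade_at_cycle=degrade_at_cycle),
    )
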