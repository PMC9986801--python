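# itermodel

A real-space toolkit for iterative prediction-guided crystallographic model
building. It implements the bespoke computational stages of an iterative
predict → place → morph → refine → rebuild → trim loop:

- **model_io** — PDB/mmCIF atomic models as a chain/residue/atom hierarchy
  (parsing/serialization via biotite), plus symmetry operators.
- **confidence** — processing of predicted models: trimming residues with
  confidence (pLDDT) below 70, converting pLDDT to estimated atomic
  displacement parameters, and splitting models into compact domains.
- **density** — CCP4/MRC maps, model-derived density (one Gaussian per atom),
  per-residue and global map–model correlation with mask-radius and
  side-chain-B optimization, and segment-aware track smoothing.
- **trimming** — the three-step trim of a model against a map: adaptive
  removal of low-correlation segments (mean − 3·sd of the top half), end
  stripping at a higher cutoff (mean − 2·sd), removal of short segments,
  and removal of weak segments (cutoff = max(0.64·m, m − 0.3)).
- **morphing** — superpose-and-morph: rigid anchors found by run-local
  least-squares fits, with smooth exponential blending between anchors.
- **metrics** — Kabsch superposition, Cα r.m.s.d., completeness within 2 Å,
  coverage, symmetry-aware best-operator comparison, and filtered
  prediction assessment.
- **pipeline** — the cycle orchestrator: convergence when the inter-cycle
  r.m.s.d. drops below 0.25 × resolution (after ≥ 3 cycles), keep-if-better
  selection on a proxy free-R, docked-prediction construction, and pluggable
  engine interfaces with deterministic mocks.
- **synthetic** — seeded toy fixtures: ideal helical folds, perturbed
  "predictions" with simulated confidence tracks, and model-derived maps
  with optional noise. All fixtures are generated programmatically.

External engines (structure prediction, molecular replacement, reciprocal-
space refinement, crystallographic rebuilding) are interfaces with mock
implementations; this package contains no reciprocal-space machinery.

## Command line

All functionality is exposed under a single `itermodel` entry point:

```sh
itermodel simulate --fold two_domain --n-res 40 --seed 7 --out-prefix fx_
itermodel process-predicted --model fx_prediction.pdb --split-domains --out-prefix proc_
itermodel cc --model fx_truth.pdb --map fx_map.mrc --per-residue cc.tsv --optimize
itermodel trim-to-map --model fx_truth.pdb --map fx_map.mrc --out trimmed.pdb --report report.json
itermodel morph --moving fx_prediction.pdb --target fx_truth.pdb --out morphed.pdb
itermodel compare --ref fx_truth.pdb --mobile morphed.pdb --superpose
itermodel run-mock-cycles --fixture two_domain --seed 1 --out rundir/
```

Every named parameter of the procedure is exposed as a flag with its default
(`--plddt-cutoff 70`, `--minimum-domain-length 10`, `--cc-sd-ratio 3`,
`--cc-sd-ratio-end 2`, `--reasonable-cc-ratio 0.8`,
`--reasonable-cc-diff 0.15`, ...).

## Layout

```
src/itermodel/      the package (one module per component above, plus cli.py
                    and engines.py with the mock engine suite)
tests/              pytest suite; tests/test_acceptance.py holds the
                    acceptance criteria, tests/oracles.py the independent
                    straight-line re-implementations used as oracles
scripts/acceptance.py   acceptance report generator
```
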