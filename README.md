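# hbstab

Protein-independent probabilistic models of hydrogen-bond stability learned
from molecular-dynamics-style trajectories.

Given a trajectory (multi-model PDB, one `MODEL` per tick), the pipeline:

1. infers covalent topology from interatomic distances and identifies
   donor–hydrogen pairs and acceptors (`hbstab.trajectory`),
2. detects H-bonds per conformation with geometric criteria
   (dist(H,A) ≤ 2.5 Å, dist(D,A) ≤ 3.5 Å, angle(D,H,A) ≥ 90°, all
   configurable) and builds per-bond presence time series (`hbstab.hbonds`),
3. computes per-occurrence predictors — distances/angles of the
   D–H…A(–AA) unit, a Mayo-form hydrogen-bond energy (`FIRST_energy`),
   neighbor-bond environment counts, and static sequence context — with
   trailing-window averaging of time-varying predictors over `l′` ticks
   (`hbstab.predictors`),
4. labels each occurrence with its measured stability `y = m/l`, the
   fraction of the next `l` ticks at which the bond is present, and
   assembles data tables with mixing/validation-split protocols
   (`hbstab.dataset`),
5. trains a binary regression tree with variance-reduction split scoring,
   depth/node-size limits, and adaptive pruning against a validation subset
   (`hbstab.cart`),
6. evaluates models: RMSE, relative base error decrease (RBED) against a
   global-mean or single-predictor base model, identification curves for
   the least stable bonds, predictor importance, and a
   leave-one-protein-out protocol (`hbstab.evaluation`).

Because no reference trajectories are distributed, `hbstab.synthetic`
generates trajectories of fluctuating donor–hydrogen–acceptor clusters with
exact ground-truth presence and stability labels, so every stage is
testable end to end.

Defaults follow the modeled method: `l = 50`, `l′ = 50` ticks (δ = 1 ps),
tree depth ≤ 5, minimum intermediate-node size 10.

## Command line

All stages are driven by one YAML config (see `hbstab.cli.DEFAULT_CONFIG`
for keys and defaults); every artifact embeds the config hash.

```sh
hbstab simulate  -c config.yaml --out-pdb traj.pdb --out-truth truth.csv
hbstab detect    -c config.yaml --pdb traj.pdb --out occurrences.csv
hbstab featurize -c config.yaml --pdb traj.pdb --out table.csv
hbstab train     -c config.yaml --table table.csv --out model.json
hbstab evaluate  -c config.yaml --model model.json --table table.csv \
                 --out report.json --curve-out curve.csv
hbstab importance -c config.yaml --model model.json --out importance.csv
hbstab loo       -c config.yaml --table t0.csv --table t1.csv --out loo.csv
```

`hbstab train --predictor FIRST_energy` (or `hbstab loo --energy-only`)
trains the single-predictor base model used for comparisons.

## Acceptance

Acceptance is property-based (`tests/test_acceptance.py`): split-search
oracle equivalence, exact stability labeling on synthetic ground truth,
noiseless rule recovery, metric closed forms, a scaled-down
leave-one-protein-out mirror, root-split structure, and energy sanity.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end self-check and writes the (empty) target report; the
original headline numbers were computed on six MD trajectories that were
never deposited and are not reproducible offline.
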