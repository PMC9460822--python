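# liftclust

Discovery and validation of lifting-technique phenotypes in chronic low back
pain from joint range-of-motion (ROM) features.

The pipeline covers:

* **Synthetic cohort generation** (`liftclust.cohort`) — lifting trials with
  five sagittal angle traces (trunk, left/right hip, left/right knee) drawn
  from four configurable cluster archetypes.  The defaults reproduce the
  published per-cluster ROM means/SDs, PSEQ/pain score distributions, and
  cluster prevalences (6.76% / 40.80% extremes) for a 473-trial,
  115-participant cohort, so every downstream stage is testable without any
  data download.
* **Kinematics** (`liftclust.kinematics`) — ROM = max − min per trace;
  between-side averaging for hip and knee; the three-feature table.
* **Clustering** (`liftclust.cluster`) — Lloyd K-means with restarts, Ward's
  method via the Lance–Williams recurrence, dendrogram cutting, and
  elbow/silhouette curves for choosing the cluster count.
* **Consensus ensembles** (`liftclust.consensus`) — duplicate-free K-means
  base clusterings combined through the three hypergraph consensus functions
  (CSPA, HGPA, MCLA) with self-contained balanced graph partitioners.
* **Bayesian-regularized neural network** (`liftclust.bnn`) —
  Levenberg–Marquardt training of a tanh three-layer network under
  `G = beta*K_S + alpha*K_W`, MacKay-style hyper-parameter re-estimation,
  Gaussian-approximation log evidence for hidden-node selection, per-class
  recall/precision/accuracy reporting, and stratified 50/50 splitting.
* **Group statistics** (`liftclust.stats`) — one-way MANOVA (Wilks' lambda,
  Rao's F), Tukey–Kramer HSD, unadjusted LSD pairwise tests, partial eta
  squared, and descriptive cluster profiles.
* **Pipeline + CLI** (`liftclust.pipeline`, `liftclust.cli`) — reproducible
  end-to-end orchestration with per-stage seed fan-out and CSV/JSON artifacts.

## Tests

```sh
python -m pytest -q tests/
```

The suite (~2 min) contains unit tests with independent oracles (brute-force
ESS recomputation for Ward, exhaustive minimum-cut enumeration for HGPA,
finite-difference Jacobians, hand-computed instances), property-based tests
(hypothesis), and `tests/test_acceptance.py` with one test per acceptance
criterion.  Three acceptance assertions are expected to fail; they encode
published-value targets that are not attainable from the printed summary
statistics alone (see the analysis in the project notes): the 97.9% BNN
validation accuracy, the ±1.5-point modal-share tolerance, and ARI ≥ 0.9 for
Ward recovery.  All other tests pass.

## CLI

```sh
liftclust simulate --seed 0 --out-dir cohort_out
liftclust extract  --traces cohort_out/traces.csv --out features.csv
liftclust select-k --features cohort_out/features.csv --k-min 2 --k-max 8 --out curve.csv
liftclust cluster  --features cohort_out/features.csv --method ward --k 4 --out labels.csv
liftclust ensemble --features cohort_out/features.csv --k 4 --runs 50 --out consensus.csv
liftclust validate --features cohort_out/features.csv --labels labels.csv --out bnn.json
liftclust stats    --features cohort_out/features.csv --labels labels.csv \
                   --scores cohort_out/trials.csv --out stats.json
liftclust run-all  --seed 0 --out-dir full_run
```

`run-all` also accepts a YAML/JSON config file (`--config`) mirroring
`liftclust.pipeline.PipelineConfig`.

Real-data mode: every stage past simulation consumes the documented CSV
schemas (`participant_id, trial_index, trunk_rom, hip_rom, knee_rom` for
features; long-format `joint, sample_index, angle_deg` for traces), so
precomputed feature tables can be substituted for the synthetic cohort.

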