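# modtrt

Test–retest reliability analysis of modular structure in functional brain
networks.

Resting-state fMRI studies increasingly use *module detection* — decomposing
a functional connectivity (FC) network into communities of densely
inter-correlated regions — and metrics derived from the detected modules as
candidate biomarkers. Before such metrics can carry clinical weight, their
test–retest (TRT) reliability has to be established: how stable are the
detected partition and its derived metrics when the same subject is scanned
twice? `modtrt` implements that whole evaluation pipeline as a reusable,
tested library with a CLI, and ships a synthetic-cohort generator with
planted modular covariance so every stage can be exercised, end to end,
without access to restricted imaging data.

## What it computes

**Network construction.** For each subject, session and run, regional time
series become an FC matrix via Pearson correlation, Fisher r-to-z transform,
element-wise averaging of the session's two runs (LR/RL phase encodings),
and zeroing of negative values. For module detection the network is
proportionally thresholded to keep the strongest 10% of positive
connections, weights preserved.

**Module detection.** Modularity maximization,

```
Q = (1/2m) Σ_ij (a_ij − k_i k_j / 2m) δ(σ_i, σ_j),
```

optimized three ways — Louvain, Tabu search, and leading-eigenvector
spectral bisection — each wrapped in 50-run consensus clustering (recluster
the co-assignment matrix of an ensemble until it stabilizes). An adapter
lets an external executable (e.g. Infomap) act as a fourth detector. Group
partitions come from three frameworks: **Ave** (detect on the
subject-averaged network), **SimMax** (the member partition most similar to
all others), and **Consensus** (recluster the cross-subject association
matrix).

**Modular-relevant metrics.** Modularity Q, intra-/inter-modular FC (mean
weight of within-/between-module positive connections), within-module degree
`WD_n = (K_c^n − K̄_c)/δ_{K_c}`, and participation coefficient
`PC_n = 1 − Σ_c (K_c^n/k_n)²`, all computed on the full positive network.

**Reliability.** Partition agreement by normalized mutual information and
the Rand index; metric reliability by the two-way mixed single-measures
consistency ICC, `(BMS − EMS)/(BMS + (s−1)EMS)`, negative estimates clamped
to 0 and banded poor/fair/moderate/good/excellent.

**Synthetic cohorts.** Subjects × {test, retest} × {LR, RL} multivariate
normal time series whose correlation matrices carry a planted block
structure, with per-subject and per-session additive correlation offsets
(`sigma_subject`, `sigma_session`) controlling between- and within-subject
variance.

## Worked example

```python
from modtrt import SyntheticCohortSpec
from modtrt.pipeline import PipelineConfig, run_individual_pipeline

cfg = PipelineConfig(
    cohort=SyntheticCohortSpec(
        n_subjects=8, n_nodes=40, module_sizes=(5,)*8,
        rho_in=0.8, rho_out=0.05,
        sigma_subject=0.10, sigma_session=0.05,
        n_timepoints=800, seed=7),
    runs=20, seed=7)
report = run_individual_pipeline(cfg)
```

prints (via the report object):

```
network-metric ICCs:
  modularity   0.528 (moderate)
  intra_fc     0.805 (excellent)
  inter_fc     0.766 (good)
nodal ICC means:  {'within_degree': 0.158, 'participation': 0.458}
mean test-retest NMI: 1.0
mean test-retest RI:  1.0
```

With this strong planted signal the detected partitions reproduce perfectly
across sessions (NMI = RI = 1), so partition instability contributes nothing
and the metric ICCs isolate the FC-level variance: intra-/inter-modular FC
track the subject-specific connectivity offsets directly (good–excellent),
modularity responds to them only through the within/between contrast
(moderate here), and the nodal metrics — whose between-subject differences
in this homogeneous cohort are pure sampling noise — sit low, illustrating
why nodal TRT reliability is the harder target.

The same experiment runs from the shell, stage by stage or in one shot:

```
modtrt simulate --n-subjects 8 --n-nodes 40 --module-sizes 5,5,5,5,5,5,5,5 \
    --rho-in 0.8 --rho-out 0.05 --seed 7 --out cohort/
modtrt construct --input-dir cohort/ --output-dir nets/
modtrt detect --input-dir nets/ --output-dir parts/ --method louvain
modtrt run-all --seed 7 --out results/      # full experiment + manifest
```

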