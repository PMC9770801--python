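"""Group-level module detection: the Ave, SimMax and Consensus frameworks.

Three ways of producing one representative partition for a cohort session:

* **Ave** — average the subjects' nonnegative Fisher-z FC matrices, threshold
  the mean network to the working density, and run consensus module detection
  on it.
* **SimMax** — detect per subject and return the member partition with the
  highest mean pairwise NMI to all the others (similarity is measured with
  NMI; the framework only requires "most similar").
* **Consensus** — build the cross-subject association matrix (probability of
  a node pair sharing a module across subjects), threshold it at tau, and
  recluster it with the consensus wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Sequence

import numpy as np

from .construction import FCMatrix, proportional_threshold
from .detection import (
    DEFAULT_RUNS,
    DEFAULT_TAU,
    Detector,
    Partition,
    _association_as_network,
    association_matrix,
    consensus_of_runs,
)
from .reliability import partition_nmi

FRAMEWORKS = ("ave", "simmax", "consensus")


def mean_fc(fcs: Sequence[FCMatrix]) -> FCMatrix:
    """Element-wise mean of the subjects' nonnegative z-matrices."""
    if not fcs:
        raise ValueError("need at least one FC matrix")
    labels = fcs[0].node_labels
    if any(fc.node_labels != labels for fc in fcs):
        raise ValueError("FC matrices cover different node sets")
    if any(fc.stage != "nonnegative" for fc in fcs):
        raise ValueError("group averaging expects stage='nonnegative' matrices")
    mean = np.mean([fc.values for fc in fcs], axis=0)
    return replace(fcs[0], subject_id="group", values=mean)


def group_ave(
    fcs: Sequence[FCMatrix],
    detector: str | Detector = "louvain",
    density: float = 0.10,
    R: int = DEFAULT_RUNS,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
) -> Partition:
    """Detect modules on the subject-averaged, proportionally thresholded network."""
    net = proportional_threshold(mean_fc(fcs), density)
    return consensus_of_runs(net, detector, R=R, tau=tau, seed=seed)


def group_simmax(partitions: Sequence[Partition]) -> Partition:
    """The member partition most similar (mean pairwise NMI) to all others."""
    if not partitions:
        raise ValueError("need at least one partition")
    if len(partitions) == 1:
        warnings.warn("single partition: returning it as the group result")
        return partitions[0]
    n = partitions[0].n_nodes
    if any(p.n_nodes != n for p in partitions):
        raise ValueError("partitions cover different node sets")
    k = len(partitions)
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sim[i, j] = sim[j, i] = partition_nmi(partitions[i], partitions[j])
    mean_sim = sim.sum(axis=1) / (k - 1)
    best = int(np.argmax(mean_sim))  # argmax returns the lowest index on ties
    return partitions[best]


def group_consensus(
    partitions: Sequence[Partition],
    detector: str | Detector = "louvain",
    R: int = DEFAULT_RUNS,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
) -> Partition:
    """Recluster the cross-subject association matrix."""
    if not partitions:
        raise ValueError("need at least one partition")
    assoc = association_matrix(list(partitions))
    net = _association_as_network(assoc, tau)
    if net.total_strength <= 0:
        raise ValueError(f"no group consensus at tau={tau}: thresholded association matrix is empty")
    return consensus_of_runs(net, detector, R=R, tau=tau, seed=seed)
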