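"""Modular-relevant network properties.

Five metrics computed from a partition warped onto a subject's functional
connectivity: modularity Q, intra- and inter-modular FC (mean weight of
within- and between-module positive connections), within-module degree
(the z-score WD_n = (K^n_c - mean K_c) / sd K_c of a node's strength to its
own module) and the participation coefficient
PC_n = 1 - sum_c (K^n_c / k_n)^2.

All positive connections of the (unthresholded) nonnegative FC matrix are
used here — deliberately a different object from the 10%-density network
used for module detection.  Zeros left by negative-value clipping count as
absent edges, not zero-strength edges, so the intra/inter averages run over
strictly positive pairs only.  The standard deviation in WD is the
population form (keeps two-node modules finite); a module with zero spread
gets WD = 0, and an isolated node (k_n = 0) gets PC = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .construction import FCMatrix, WeightedNetwork
from .detection import Partition, modularity

NETWORK_METRICS = ("modularity", "intra_fc", "inter_fc")
NODE_METRICS = ("within_degree", "participation")
ALL_METRICS = NETWORK_METRICS + NODE_METRICS


@dataclass(frozen=True)
class MetricRecord:
    subject_id: str
    session: str
    level: str          # "individual" | "group"
    metric: str
    scope: str          # "network" | "node"
    values: float | np.ndarray


def _check_cover(fc: FCMatrix, p: Partition) -> None:
    if p.n_nodes != fc.n_nodes:
        raise ValueError("partition does not cover the FC matrix's node set")


def node_module_strengths(fc: FCMatrix, p: Partition) -> np.ndarray:
    """K[n, c] = total positive FC strength between node n and module c+1.

    Row sums reproduce each node's total positive strength k_n exactly
    (strength decomposition).
    """
    _check_cover(fc, p)
    w = fc.values
    A = p.n_modules
    K = np.zeros((fc.n_nodes, A))
    for c in range(1, A + 1):
        K[:, c - 1] = w[:, p.members(c)].sum(axis=1)
    return K


def intra_modular_fc(fc: FCMatrix, p: Partition) -> float:
    """Mean weight over within-module positive node pairs (0 if none)."""
    _check_cover(fc, p)
    same = p.labels[:, None] == p.labels[None, :]
    iu = np.triu_indices(fc.n_nodes, k=1)
    w = fc.values[iu]
    sel = same[iu] & (w > 0)
    return float(w[sel].mean()) if sel.any() else 0.0


def inter_modular_fc(fc: FCMatrix, p: Partition) -> float:
    """Mean weight over between-module positive node pairs (0 if none)."""
    _check_cover(fc, p)
    if p.n_modules < 2:
        warnings.warn("single-module partition: no inter-modular connections")
    diff = p.labels[:, None] != p.labels[None, :]
    iu = np.triu_indices(fc.n_nodes, k=1)
    w = fc.values[iu]
    sel = diff[iu] & (w > 0)
    return float(w[sel].mean()) if sel.any() else 0.0


def within_module_degree(fc: FCMatrix, p: Partition) -> np.ndarray:
    """Per-node z-score of within-module strength (WD); 0 where sd = 0."""
    _check_cover(fc, p)
    K = node_module_strengths(fc, p)
    wd = np.zeros(fc.n_nodes)
    for c in range(1, p.n_modules + 1):
        idx = p.members(c)
        vals = K[idx, c - 1]
        sd = vals.std()  # population convention
        if sd > 0:
            wd[idx] = (vals - vals.mean()) / sd
    return wd


def participation_coefficient(fc: FCMatrix, p: Partition) -> np.ndarray:
    """Per-node PC = 1 - sum_c (K^n_c / k_n)^2; 0 for isolated nodes."""
    _check_cover(fc, p)
    K = node_module_strengths(fc, p)
    k = K.sum(axis=1)
    pc = np.zeros(fc.n_nodes)
    nz = k > 0
    pc[nz] = 1.0 - ((K[nz] / k[nz, None]) ** 2).sum(axis=1)
    return pc


def positive_network(fc: FCMatrix) -> WeightedNetwork:
    """All positive connections of the FC matrix as a weighted network."""
    return WeightedNetwork(values=fc.values.copy(), node_labels=fc.node_labels, density=1.0)


def compute_metrics(
    fc: FCMatrix,
    p: Partition,
    level: str = "individual",
    net_for_q: WeightedNetwork | None = None,
) -> list[MetricRecord]:
    """All five modular-relevant metrics for one subject-session.

    Q is evaluated on the full positive-connection network (``net_for_q``
    defaults to exactly that), not on the thresholded detection network.
    """
    _check_cover(fc, p)
    if level not in ("individual", "group"):
        raise ValueError("level must be 'individual' or 'group'")
    net = net_for_q if net_for_q is not None else positive_network(fc)
    sid, ses = fc.subject_id, fc.session
    return [
        MetricRecord(sid, ses, level, "modularity", "network", modularity(net, p)),
        MetricRecord(sid, ses, level, "intra_fc", "network", intra_modular_fc(fc, p)),
        MetricRecord(sid, ses, level, "inter_fc", "network", inter_modular_fc(fc, p)),
        MetricRecord(sid, ses, level, "within_degree", "node", within_module_degree(fc, p)),
        MetricRecord(sid, ses, level, "participation", "node", participation_coefficient(fc, p)),
    ]


def records_to_frame(records: Iterable[MetricRecord], node_labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Long-format table: subject_id, session, level, metric, node_label, value."""
    rows = []
    for rec in records:
        if rec.scope == "network":
            rows.append((rec.subject_id, rec.session, rec.level, rec.metric, "", float(rec.values)))
        else:
            vals = np.asarray(rec.values)
            labs = node_labels if node_labels is not None else [f"n{i + 1:04d}" for i in range(vals.size)]
            for lab, v in zip(labs, vals):
                rows.append((rec.subject_id, rec.session, rec.level, rec.metric, lab, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "session", "level", "metric", "node_label", "value"])


def write_metric_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
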