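"""Functional-connectivity network construction.

Per-run region time series become per-subject, per-session nonnegative
weighted networks through a fixed sequence: Pearson correlation between every
pair of regional time series, Fisher r-to-z transformation, element-wise
averaging of the session's two runs (LR and RL phase encodings), zeroing of
negative connectivity values, and finally proportional thresholding keeping
the strongest fraction (default 10%) of positive connections with their
weights preserved.

Matrices carry a processing-stage tag so the pipeline can assert it is
feeding each step the object the previous step produced.  The diagonal is
excluded everywhere and stored as 0 (atanh(1) diverges).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .synthetic import TimeSeriesRun

logger = logging.getLogger(__name__)

STAGES = ("r", "z", "averaged", "nonnegative")

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric region-by-region connectivity matrix with a stage tag."""

    subject_id: str
    session: str
    stage: str
    values: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if len(self.node_labels) != v.shape[0]:
            raise ValueError("node_labels length must match matrix size")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("FC matrix must be symmetric within 1e-12")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("FC matrix diagonal must be exactly 0")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if self.stage == "r" and off.size and (off.min() < -1.0 or off.max() > 1.0):
            raise ValueError("stage=r requires off-diagonal values in [-1, 1]")
        if self.stage == "nonnegative" and off.size and off.min() < 0.0:
            raise ValueError("stage=nonnegative requires nonnegative values")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightedNetwork:
    """Thresholded nonnegative weighted graph (no self-loops).

    ``strengths`` holds the node strengths k_i = sum_j a_ij and
    ``total_strength`` m = (1/2) sum_ij a_ij, the quantities entering the
    modularity quality function.
    """

    values: np.ndarray
    node_labels: tuple[str, ...]
    density: float

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("adjacency matrix must be symmetric")
        if v.size and v.min() < 0.0:
            raise ValueError("weights must be nonnegative")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("no self-loops allowed")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def total_strength(self) -> float:
        return float(self.values.sum()) / 2.0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.values, 1)))


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def pearson_fc(run: TimeSeriesRun, node_labels: Sequence[str] | None = None) -> FCMatrix:
    """Pearson correlation between every pair of regional time series.

    The diagonal is stored as 0.  A constant time series is an error naming
    the offending node rather than a silent NaN.
    """
    data = run.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    if node_labels is None:
        node_labels = tuple(f"n{i + 1:04d}" for i in range(data.shape[1]))
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = [node_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for node(s): {', '.join(bad)}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return FCMatrix(run.subject_id, run.session, "r", r, tuple(node_labels))


def fisher_z(fc: FCMatrix) -> FCMatrix:
    """Fisher r-to-z transform, z = atanh(r); diagonal stays 0."""
    if fc.stage != "r":
        raise ValueError("fisher_z expects a stage='r' matrix")
    off = fc.values[~np.eye(fc.n_nodes, dtype=bool)]
    if off.size and np.abs(off).max() >= 1.0:
        raise ValueError("|r| >= 1 off-diagonal: duplicate or degenerate regions")
    z = np.arctanh(fc.values)
    np.fill_diagonal(z, 0.0)
    return replace(fc, stage="z", values=z)


def average_runs(z_lr: FCMatrix, z_rl: FCMatrix) -> FCMatrix:
    """Element-wise mean of the two runs' Fisher-z matrices."""
    if z_lr.stage != "z" or z_rl.stage != "z":
        raise ValueError("average_runs expects stage='z' matrices")
    if z_lr.node_labels != z_rl.node_labels:
        raise ValueError("node labels differ between runs")
    if (z_lr.subject_id, z_lr.session) != (z_rl.subject_id, z_rl.session):
        raise ValueError("runs belong to different subject/session")
    return replace(z_lr, stage="averaged", values=(z_lr.values + z_rl.values) / 2.0)


def zero_negatives(fc: FCMatrix) -> FCMatrix:
    """Set negative connectivity values to zero (unclear biological meaning)."""
    if fc.stage != "averaged":
        raise ValueError("zero_negatives expects a stage='averaged' matrix")
    return replace(fc, stage="nonnegative", values=np.maximum(fc.values, 0.0))


def proportional_threshold(fc: FCMatrix, density: float = 0.10) -> WeightedNetwork:
    """Keep the top-``density`` fraction of strongest positive connections.

    Of the E = n(n-1)/2 upper-triangle entries, the ceil(density * E) largest
    strictly positive weights are retained with their values (the analysis
    uses weighted networks); everything else is zeroed.  Ties at the cutoff
    break by weight descending, then row index, then column index, so the
    result is run-to-run identical.
    """
    if fc.stage != "nonnegative":
        raise ValueError("proportional_threshold expects a stage='nonnegative' matrix")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    n = fc.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = fc.values[iu, ju]
    n_possible = w.size
    n_keep = math.ceil(density * n_possible)
    pos = w > 0
    n_pos = int(pos.sum())
    if n_pos < n_keep:
        logger.warning(
            "only %d positive connections available; requested %d — keeping all positives",
            n_pos, n_keep,
        )
        n_keep = n_pos
    # lexsort: last key is primary. Sort by (-w, i, j).
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_keep]
    out = np.zeros_like(fc.values)
    out[iu[keep], ju[keep]] = w[keep]
    out = out + out.T
    return WeightedNetwork(values=out, node_labels=fc.node_labels, density=density)


def construct_session_network(
    run_lr: TimeSeriesRun,
    run_rl: TimeSeriesRun,
    density: float = 0.10,
    node_labels: Sequence[str] | None = None,
) -> tuple[FCMatrix, WeightedNetwork]:
    """Full construction chain for one subject-session.

    Returns the nonnegative FC matrix (used for metric computation on all
    positive connections) and the proportionally thresholded network (used
    for module detection).
    """
    z_lr = fisher_z(pearson_fc(run_lr, node_labels))
    z_rl = fisher_z(pearson_fc(run_rl, node_labels))
    nonneg = zero_negatives(average_runs(z_lr, z_rl))
    return nonneg, proportional_threshold(nonneg, density)


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def write_fc_matrix(fc: FCMatrix, path: str | Path, density: float | None = None) -> Path:
    """Write a matrix as labelled TSV with a JSON sidecar recording the stage."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(fc.node_labels) + "\n")
        for lab, row in zip(fc.node_labels, fc.values):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    sidecar = {
        "subject_id": fc.subject_id,
        "session": fc.session,
        "stage": fc.stage,
    }
    if density is not None:
        sidecar["density"] = density
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_fc_matrix(path: str | Path) -> FCMatrix:
    path = Path(path)
    with open(path) as fh:
        labels = tuple(fh.readline().rstrip("\n").split("\t")[1:])
    raw = np.loadtxt(path, delimiter="\t", skiprows=1, usecols=range(1, len(labels) + 1), ndmin=2)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FCMatrix(
        subject_id=meta["subject_id"],
        session=meta["session"],
        stage=meta["stage"],
        values=raw,
        node_labels=labels,
    )
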