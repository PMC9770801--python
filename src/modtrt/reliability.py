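"""Reliability statistics: partition agreement (NMI, Rand index) and ICC.

Partition agreement between test and retest is scored with normalized mutual
information,

    NMI(A, B) = -2 * sum_ij N_ij log(N_ij N / (N_i. N_.j))
                / [sum_i N_i. log(N_i./N) + sum_j N_.j log(N_.j/N)]

(natural log, 0*log 0 = 0), and the unadjusted Rand index
RI = 2 (n11 + n00) / (n (n-1)), both in [0, 1] with 1 meaning identical
partitions.  Degenerate entropies are defined explicitly: two single-module
partitions agree perfectly (NMI = 1); if exactly one partition is
single-module, NMI = 0.

Test-retest reliability of scalar measures uses the two-way mixed,
single-measures, consistency intraclass correlation

    ICC = (BMS - EMS) / (BMS + (s - 1) EMS)

with BMS the between-subjects mean square and EMS the residual mean square of
the subjects x sessions two-way ANOVA (s = 2 sessions here).  Negative
estimates are clamped to zero, and values are banded as poor [0, 0.2), fair
[0.2, 0.4), moderate [0.4, 0.6), good [0.6, 0.8), excellent [0.8, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .detection import Partition

ICC_BANDS = (
    (0.0, 0.2, "poor"),
    (0.2, 0.4, "fair"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "good"),
    (0.8, 1.0 + 1e-12, "excellent"),
)


# ---------------------------------------------------------------------------
# partition agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionOverlap:
    """Confusion matrix and pair counts between two partitions."""

    confusion: np.ndarray
    n: int
    n11: int
    n00: int
    n10: int
    n01: int

    @property
    def row_sums(self) -> np.ndarray:
        return self.confusion.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.confusion.sum(axis=0)


def partition_overlap(pa: Partition, pb: Partition) -> PartitionOverlap:
    """Cross-tabulate two partitions of the same node set."""
    if pa.n_nodes != pb.n_nodes:
        raise ValueError("partitions cover different node sets")
    n = pa.n_nodes
    A, B = pa.n_modules, pb.n_modules
    conf = np.zeros((A, B), dtype=np.int64)
    np.add.at(conf, (pa.labels - 1, pb.labels - 1), 1)

    def pairs(x: np.ndarray) -> int:
        return int((x * (x - 1) // 2).sum())

    n11 = pairs(conf.ravel())
    same_a = pairs(conf.sum(axis=1))
    same_b = pairs(conf.sum(axis=0))
    n10 = same_a - n11
    n01 = same_b - n11
    total = n * (n - 1) // 2
    n00 = total - n11 - n10 - n01
    return PartitionOverlap(confusion=conf, n=n, n11=n11, n00=n00, n10=n10, n01=n01)


def nmi(o: PartitionOverlap) -> float:
    """Normalized mutual information of a partition overlap, in [0, 1]."""
    if o.n10 == 0 and o.n01 == 0:
        return 1.0  # identical partitions, exactly
    conf = o.confusion.astype(float)
    N = float(o.n)
    ri = conf.sum(axis=1)
    cj = conf.sum(axis=0)
    single_a = (ri > 0).sum() == 1
    single_b = (cj > 0).sum() == 1
    if single_a and single_b:
        return 1.0
    if single_a or single_b:
        return 0.0
    safe = np.where(conf > 0, conf, 1.0)  # 0 * log 0 := 0
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.log(safe * N / np.outer(ri, cj))
    num = -2.0 * np.sum(np.where(conf > 0, conf * logterm, 0.0))
    den = np.sum(ri[ri > 0] * np.log(ri[ri > 0] / N)) + np.sum(cj[cj > 0] * np.log(cj[cj > 0] / N))
    val = num / den
    return float(min(max(val, 0.0), 1.0))


def rand_index(o: PartitionOverlap) -> float:
    """Unadjusted Rand index 2(n11 + n00) / (n(n-1))."""
    if o.n < 2:
        raise ValueError("Rand index needs at least 2 nodes")
    return 2.0 * (o.n11 + o.n00) / (o.n * (o.n - 1))


def partition_nmi(pa: Partition, pb: Partition) -> float:
    return nmi(partition_overlap(pa, pb))


def partition_rand(pa: Partition, pb: Partition) -> float:
    return rand_index(partition_overlap(pa, pb))


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc(table: np.ndarray, clamp: bool = True) -> float:
    """Two-way mixed single-measures consistency ICC of a subjects x sessions table.

    Computed from explicit two-way ANOVA sums of squares (subject and session
    main effects, interaction as error).  Negative estimates clamp to 0 when
    ``clamp`` (the reported convention); a table with zero variance
    everywhere returns 0.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2:
        raise ValueError("measurement table must be 2-D (subjects x sessions)")
    if np.isnan(y).any():
        raise ValueError("measurement table has missing cells")
    n, s = y.shape
    if n < 2 or s < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    grand = y.mean()
    subj = y.mean(axis=1)
    sess = y.mean(axis=0)
    bms = s * np.sum((subj - grand) ** 2) / (n - 1)
    resid = y - subj[:, None] - sess[None, :] + grand
    ems = np.sum(resid**2) / ((n - 1) * (s - 1))
    if bms == 0.0 and ems == 0.0:
        return 0.0
    val = (bms - ems) / (bms + (s - 1) * ems)
    if clamp and val < 0.0:
        return 0.0
    return float(val)


def categorize_icc(v: float) -> str:
    """Reliability band of an ICC value in [0, 1]."""
    if not (0.0 <= v <= 1.0):
        raise ValueError("ICC value must lie in [0, 1] after clamping")
    for lo, hi, name in ICC_BANDS:
        if lo <= v < hi:
            return name
    return "excellent"


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityReport:
    """Per-metric ICCs with bands plus partition-agreement scores."""

    level: str
    icc: dict[str, dict] = field(default_factory=dict)
    nodal_icc: dict[str, dict] = field(default_factory=dict)
    partition_agreement: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "icc": self.icc,
            "nodal_icc": self.nodal_icc,
            "partition_agreement": self.partition_agreement,
            "config": self.config,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text


def _nodal_summary(per_node: np.ndarray) -> dict:
    q1, q2, q3 = np.percentile(per_node, [25, 50, 75])
    return {
        "mean": float(per_node.mean()),
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
    }


def reliability_report(
    network_tables: Mapping[str, np.ndarray],
    nodal_tables: Mapping[str, np.ndarray] | None = None,
    partitions_test: Sequence[Partition] | Partition | None = None,
    partitions_retest: Sequence[Partition] | Partition | None = None,
    level: str = "individual",
    config: Mapping | None = None,
) -> ReliabilityReport:
    """Assemble the reliability report for one analysis level.

    ``network_tables`` maps metric name -> (n_subjects, 2) table; each gets a
    single ICC and band.  ``nodal_tables`` maps metric name -> (n_subjects, 2,
    n_nodes) array; each node gets its own ICC and the per-node distribution
    is summarized by mean and quartiles.  Partitions give per-subject NMI/RI
    (individual level, matched test/retest lists) or a single NMI/RI (group
    level, one partition per session).
    """
    report = ReliabilityReport(level=level, config=dict(config or {}))
    for metric, table in network_tables.items():
        v = icc(table)
        report.icc[metric] = {"value": v, "band": categorize_icc(v)}
    for metric, cube in (nodal_tables or {}).items():
        cube = np.asarray(cube)
        per_node = np.array([icc(cube[:, :, j]) for j in range(cube.shape[2])])
        report.nodal_icc[metric] = {
            "per_node": per_node.tolist(),
            **_nodal_summary(per_node),
        }
    if partitions_test is not None and partitions_retest is not None:
        if isinstance(partitions_test, Partition):
            o = partition_overlap(partitions_test, partitions_retest)
            report.partition_agreement = {"nmi": nmi(o), "rand_index": rand_index(o)}
        else:
            if len(partitions_test) != len(partitions_retest):
                raise ValueError("subject mismatch between sessions")
            nmis, ris = [], []
            for pt, pr in zip(partitions_test, partitions_retest):
                o = partition_overlap(pt, pr)
                nmis.append(nmi(o))
                ris.append(rand_index(o))
            report.partition_agreement = {
                "per_subject_nmi": nmis,
                "per_subject_rand_index": ris,
                "mean_nmi": float(np.mean(nmis)),
                "mean_rand_index": float(np.mean(ris)),
            }
    return report
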