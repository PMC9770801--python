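"""Synthetic test-retest cohorts with planted modular covariance structure.

Emulates the structure of a resting-state test-retest fMRI study — n subjects,
each scanned in two sessions (test / retest) with two runs per session (LR / RL
phase-encoding) — by drawing multivariate-normal region time series whose
correlation matrices carry a block (modular) structure.  Between-subject and
between-session variability enter as additive offsets on the target
correlations:

* a per-subject offset ``b_s ~ N(0, sigma_subject^2)`` drawn once per subject
  and shared by both of its sessions, and
* a per-session offset ``e_{s,t} ~ N(0, sigma_session^2)`` drawn independently
  for each subject-session.

Both runs of one session share the same target correlation matrix, so
run-to-run differences are pure sampling noise.  Target entries are clipped to
[0, 0.99] (keeping Fisher-z finite) and repaired to the nearest positive
semidefinite correlation matrix by eigenvalue clipping when needed.

The model deliberately ignores hemodynamics, autocorrelated BOLD spectra, head
motion and physiological noise: only the correlation structure feeds the
downstream pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

SESSIONS = ("test", "retest")
RUNS = ("LR", "RL")

#: eigenvalues below this are treated as zero during the PSD repair
PSD_TOL = 1e-10

#: correlations are clipped into [0, CLIP_MAX] so atanh stays finite
CLIP_MAX = 0.99


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic test-retest cohort.

    Defaults mirror a 45-subject test-retest cohort with 1200-timepoint runs
    and a four-module planted partition of 40 nodes; within-module correlation
    0.5 against a 0.1 background, with subject-level standard deviation 0.10
    and session-level standard deviation 0.05 on the correlation offsets.
    """

    n_subjects: int = 45
    n_nodes: int = 40
    module_sizes: tuple[int, ...] = (10, 10, 10, 10)
    rho_in: float = 0.5
    rho_out: float = 0.1
    sigma_subject: float = 0.10
    sigma_session: float = 0.05
    n_timepoints: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(int(s) for s in self.module_sizes))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be a positive integer")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be a positive integer")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module_sizes must all be positive")
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)}, expected n_nodes={self.n_nodes}"
            )
        if not (0.0 <= self.rho_in < 1.0):
            raise ValueError("rho_in must lie in [0, 1)")
        if not (0.0 <= self.rho_out <= self.rho_in):
            raise ValueError("rho_out must lie in [0, rho_in]")
        if self.sigma_subject < 0 or self.sigma_session < 0:
            raise ValueError("variance components must be nonnegative")
        if self.n_timepoints < max(3, self.n_nodes // 2):
            raise ValueError("n_timepoints must be >= max(3, n_nodes/2)")

    @property
    def node_labels(self) -> tuple[str, ...]:
        return tuple(f"n{i + 1:04d}" for i in range(self.n_nodes))

    @property
    def planted_labels(self) -> np.ndarray:
        """Planted module assignment, 1-based, block-contiguous."""
        out = np.empty(self.n_nodes, dtype=np.int64)
        start = 0
        for mod, size in enumerate(self.module_sizes, start=1):
            out[start : start + size] = mod
            start += size
        return out


@dataclass(frozen=True)
class TimeSeriesRun:
    """One simulated scan: timepoints x nodes."""

    subject_id: str
    session: str  # "test" | "retest"
    run: str      # "LR" | "RL"
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        if self.run not in RUNS:
            raise ValueError(f"run must be one of {RUNS}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series data must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def filename(self) -> str:
        return f"sub-{self.subject_id}_ses-{self.session}_run-{self.run}.tsv"


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: partition, offsets, variance components."""

    planted_partition: np.ndarray
    subject_offsets: dict[str, float]
    theoretical_icc_inputs: tuple[float, float]  # (sigma_subject, sigma_session)


# ---------------------------------------------------------------------------
# construction of target correlation matrices
# ---------------------------------------------------------------------------

def _nearest_psd_correlation(mat: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Clip negative eigenvalues to zero and renormalise to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= -tol:
        return mat
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    d[d == 0] = 1.0
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def build_target_correlation(
    spec: SyntheticCohortSpec,
    subject_offset: float = 0.0,
    session_offset: float = 0.0,
) -> np.ndarray:
    """Block-constant target correlation matrix for one subject-session.

    Entry (i, j) is ``clip(rho_in + offsets, 0, 0.99)`` when i and j share a
    planted module and ``clip(rho_out + offsets, 0, 0.99)`` otherwise; the
    diagonal is 1.  The result is repaired to the nearest PSD correlation
    matrix if the clipping broke positive semidefiniteness.
    """
    if not (np.isfinite(subject_offset) and np.isfinite(session_offset)):
        raise ValueError("offsets must be finite")
    shift = subject_offset + session_offset
    labels = spec.planted_labels
    same = labels[:, None] == labels[None, :]
    r_in = float(np.clip(spec.rho_in + shift, 0.0, CLIP_MAX))
    r_out = float(np.clip(spec.rho_out + shift, 0.0, CLIP_MAX))
    corr = np.where(same, r_in, r_out)
    np.fill_diagonal(corr, 1.0)
    return _nearest_psd_correlation(corr)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _rng(master_seed: int, *key: int) -> np.random.Generator:
    """Child generator from a master seed and a fixed integer key.

    SeedSequence entropy is the (seed, *key) tuple, so adding subjects or
    sessions never perturbs earlier subjects' draws.
    """
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


def sample_timeseries(
    target_corr: np.ndarray, n_timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. rows from N(0, target_corr) via the matrix square root."""
    vals, vecs = np.linalg.eigh(target_corr)
    if vals.min() < -1e-8:
        raise ValueError("target correlation matrix is not positive semidefinite")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n_timepoints, target_corr.shape[0]))
    return z @ root.T


def sample_run(
    target_corr: np.ndarray,
    n_timepoints: int,
    seed: int,
    subject_id: str = "0001",
    session: str = "test",
    run: str = "LR",
) -> TimeSeriesRun:
    """Draw one run of multivariate-normal time series; deterministic in seed."""
    data = sample_timeseries(target_corr, n_timepoints, np.random.default_rng(seed))
    return TimeSeriesRun(subject_id=subject_id, session=session, run=run, data=data)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def make_cohort(spec: SyntheticCohortSpec) -> tuple[list[TimeSeriesRun], GroundTruth]:
    """Simulate the full n_subjects x 2 sessions x 2 runs cohort.

    Returns the runs in (subject, session, run) order plus the planted ground
    truth.  Identical specs (including seed) give bit-identical cohorts.
    """
    runs: list[TimeSeriesRun] = []
    subject_offsets: dict[str, float] = {}
    for s in range(spec.n_subjects):
        sid = f"{s + 1:04d}"
        b = float(_rng(spec.seed, s, 0).normal(0.0, spec.sigma_subject)) if spec.sigma_subject > 0 else 0.0
        subject_offsets[sid] = b
        for t, session in enumerate(SESSIONS):
            e = float(_rng(spec.seed, s, 1 + t).normal(0.0, spec.sigma_session)) if spec.sigma_session > 0 else 0.0
            target = build_target_correlation(spec, b, e)
            for r, run in enumerate(RUNS):
                gen = _rng(spec.seed, s, 10 + 2 * t + r)
                data = sample_timeseries(target, spec.n_timepoints, gen)
                runs.append(TimeSeriesRun(subject_id=sid, session=session, run=run, data=data))
    truth = GroundTruth(
        planted_partition=spec.planted_labels,
        subject_offsets=subject_offsets,
        theoretical_icc_inputs=(spec.sigma_subject, spec.sigma_session),
    )
    return runs, truth


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def write_run(run: TimeSeriesRun, out_dir: str | Path, node_labels: Sequence[str] | None = None) -> Path:
    """Write one run as TSV (rows = timepoints, header row of node labels)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if node_labels is None:
        node_labels = [f"n{i + 1:04d}" for i in range(run.n_nodes)]
    path = out_dir / run.filename
    header = "\t".join(node_labels)
    np.savetxt(path, run.data, fmt="%.10g", delimiter="\t", header=header, comments="")
    return path


def read_run(path: str | Path) -> tuple[TimeSeriesRun, tuple[str, ...]]:
    """Read a run TSV written by :func:`write_run`; parses ids from the name."""
    path = Path(path)
    with open(path) as fh:
        labels = tuple(fh.readline().rstrip("\n").split("\t"))
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    parts = dict(
        p.split("-", 1) for p in path.stem.split("_") if "-" in p
    )
    run = TimeSeriesRun(
        subject_id=parts.get("sub", "0001"),
        session=parts.get("ses", "test"),
        run=parts.get("run", "LR"),
        data=data,
    )
    return run, labels


def write_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> tuple[list[Path], Path]:
    """Simulate and write a cohort plus its ground-truth partition file."""
    out_dir = Path(out_dir)
    runs, truth = make_cohort(spec)
    labels = spec.node_labels
    paths = [write_run(r, out_dir, labels) for r in runs]
    gt_path = out_dir / "ground_truth_partition.tsv"
    with open(gt_path, "w") as fh:
        for lab, mod in zip(labels, truth.planted_partition):
            fh.write(f"{lab}\t{mod}\n")
    return paths, gt_path
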