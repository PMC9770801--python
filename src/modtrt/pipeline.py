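"""End-to-end test-retest experiment orchestration.

simulate -> construct -> detect -> group-detect -> metrics -> reliability,
with a single structured config, deterministic seed handling, stage-named
errors, and a manifest of written artifacts with checksums so interrupted
experiments can resume from on-disk outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from . import construction, detection, group, metrics, reliability, synthetic
from .construction import FCMatrix, construct_session_network
from .detection import Partition, consensus_of_runs
from .group import FRAMEWORKS
from .metrics import NETWORK_METRICS, NODE_METRICS, compute_metrics, records_to_frame
from .reliability import ReliabilityReport, reliability_report
from .synthetic import SESSIONS, SyntheticCohortSpec, make_cohort

logger = logging.getLogger(__name__)


def configure_logging(verbose: bool = False, log_file: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if log_file is not None:
        Path(log_file).parent.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one experiment needs; validated up front, echoed into outputs."""

    cohort: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    input_dir: str | None = None
    density: float = 0.10
    method: str = "louvain"
    runs: int = 50
    tau: float = 0.5
    frameworks: tuple[str, ...] = ("ave", "simmax", "consensus")
    levels: tuple[str, ...] = ("individual", "group")
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.method not in ("louvain", "tabu", "spectral") and not callable(self.method):
            raise ValueError("method must be louvain | tabu | spectral or a detector callable")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        bad = set(self.frameworks) - set(FRAMEWORKS)
        if bad:
            raise ValueError(f"unknown group frameworks: {sorted(bad)}")
        if set(self.levels) - {"individual", "group"}:
            raise ValueError("levels must be a subset of {individual, group}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        d["cohort"]["module_sizes"] = list(self.cohort.module_sizes)
        d["frameworks"] = list(self.frameworks)
        d["levels"] = list(self.levels)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = SyntheticCohortSpec(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)


# ---------------------------------------------------------------------------
# session-level assembly
# ---------------------------------------------------------------------------

@dataclass
class SessionData:
    """One subject-session after construction: positive FC + detection network."""

    fc: FCMatrix
    net: construction.WeightedNetwork
    partition: Partition | None = None


def _stage(name: str):
    """Decorator-ish guard: re-raise any stage failure with the stage name."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, dt)
            return False

    return _Ctx()


def build_cohort_networks(cfg: PipelineConfig) -> dict[str, dict[str, SessionData]]:
    """Simulate (or read) the cohort and construct every subject-session network."""
    with _stage("simulate"):
        if cfg.input_dir is not None:
            runs = [synthetic.read_run(p)[0] for p in sorted(Path(cfg.input_dir).glob("sub-*.tsv"))]
        else:
            runs, _ = make_cohort(cfg.cohort)
    with _stage("construct"):
        by_key: dict[tuple[str, str], dict[str, synthetic.TimeSeriesRun]] = {}
        for r in runs:
            by_key.setdefault((r.subject_id, r.session), {})[r.run] = r
        out: dict[str, dict[str, SessionData]] = {}
        for (sid, ses), pair in sorted(by_key.items()):
            fc, net = construct_session_network(pair["LR"], pair["RL"], cfg.density)
            out.setdefault(sid, {})[ses] = SessionData(fc=fc, net=net)
    return out


def detect_individual(cohort: dict[str, dict[str, SessionData]], cfg: PipelineConfig) -> None:
    """Consensus module detection on every subject-session's thresholded network."""
    with _stage("detect"):
        for s_idx, (sid, sessions) in enumerate(sorted(cohort.items())):
            for t_idx, ses in enumerate(SESSIONS):
                sd = sessions[ses]
                # disjoint per-subject-session seed blocks keep runs independent
                seed = cfg.seed + (s_idx * len(SESSIONS) + t_idx) * 100_000
                sd.partition = consensus_of_runs(
                    sd.net, cfg.method, R=cfg.runs, tau=cfg.tau, seed=seed
                )


def _metric_tables(
    cohort: dict[str, dict[str, SessionData]],
    partitions: dict[str, dict[str, Partition]],
    level: str,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], list[metrics.MetricRecord]]:
    """Measurement tables (subjects x sessions[, nodes]) for all five metrics."""
    subjects = sorted(cohort)
    n_nodes = cohort[subjects[0]]["test"].fc.n_nodes
    net_tables = {m: np.zeros((len(subjects), 2)) for m in NETWORK_METRICS}
    node_tables = {m: np.zeros((len(subjects), 2, n_nodes)) for m in NODE_METRICS}
    records: list[metrics.MetricRecord] = []
    for i, sid in enumerate(subjects):
        for j, ses in enumerate(SESSIONS):
            sd = cohort[sid][ses]
            recs = compute_metrics(sd.fc, partitions[sid][ses], level=level)
            records.extend(recs)
            for rec in recs:
                if rec.scope == "network":
                    net_tables[rec.metric][i, j] = rec.values
                else:
                    node_tables[rec.metric][i, j, :] = rec.values
    return net_tables, node_tables, records


def run_individual_pipeline(cfg: PipelineConfig) -> ReliabilityReport:
    """Individual-level experiment: own partition per subject-session.

    Constructs each network, consensus-detects modules on the thresholded
    network, computes the five metrics on the positive network with the
    subject's own partition, then scores per-subject test/retest NMI and RI
    and per-metric ICC across subjects.
    """
    logger.info("individual pipeline: seed=%d config=%s", cfg.seed, cfg.config_hash)
    cohort = build_cohort_networks(cfg)
    detect_individual(cohort, cfg)
    partitions = {
        sid: {ses: sd.partition for ses, sd in sessions.items()}
        for sid, sessions in cohort.items()
    }
    with _stage("metrics"):
        net_tables, node_tables, records = _metric_tables(cohort, partitions, "individual")
    with _stage("reliability"):
        subjects = sorted(cohort)
        report = reliability_report(
            network_tables=net_tables,
            nodal_tables=node_tables,
            partitions_test=[partitions[s]["test"] for s in subjects],
            partitions_retest=[partitions[s]["retest"] for s in subjects],
            level="individual",
            config=cfg.to_dict(),
        )
    _maybe_write(cfg, report, records, "individual")
    return report


def group_partition_for_session(
    cohort: dict[str, dict[str, SessionData]],
    cfg: PipelineConfig,
    framework: str,
    session: str,
    seed_offset: int = 0,
) -> Partition:
    subjects = sorted(cohort)
    seed = cfg.seed + 10_000_000 + seed_offset
    if framework == "ave":
        fcs = [cohort[s][session].fc for s in subjects]
        return group.group_ave(fcs, cfg.method, cfg.density, cfg.runs, cfg.tau, seed)
    parts = [cohort[s][session].partition for s in subjects]
    if any(p is None for p in parts):
        raise RuntimeError("group frameworks simmax/consensus need individual partitions first")
    if framework == "simmax":
        return group.group_simmax(parts)
    if framework == "consensus":
        return group.group_consensus(parts, cfg.method, cfg.runs, cfg.tau, seed)
    raise ValueError(f"unknown framework {framework!r}")


def run_group_pipeline(cfg: PipelineConfig) -> dict[str, ReliabilityReport]:
    """Group-level experiment: one report per configured framework.

    Per session, each framework produces a representative partition, which is
    warped onto every subject's positive network for metric computation; the
    report carries the single test/retest NMI and RI between the two
    sessions' group partitions plus per-metric ICCs.
    """
    logger.info("group pipeline: seed=%d config=%s", cfg.seed, cfg.config_hash)
    cohort = build_cohort_networks(cfg)
    if len(cohort) < 2:
        raise ValueError("group pipeline needs at least 2 subjects")
    needs_individual = any(f in cfg.frameworks for f in ("simmax", "consensus"))
    if needs_individual:
        detect_individual(cohort, cfg)
    reports: dict[str, ReliabilityReport] = {}
    for f_idx, framework in enumerate(cfg.frameworks):
        with _stage(f"group-detect[{framework}]"):
            gparts = {
                ses: group_partition_for_session(
                    cohort, cfg, framework, ses, seed_offset=f_idx * 1000 + t * 37
                )
                for t, ses in enumerate(SESSIONS)
            }
        with _stage(f"group-metrics[{framework}]"):
            partitions = {
                sid: {ses: gparts[ses] for ses in SESSIONS} for sid in cohort
            }
            net_tables, node_tables, records = _metric_tables(cohort, partitions, "group")
        report = reliability_report(
            network_tables=net_tables,
            nodal_tables=node_tables,
            partitions_test=gparts["test"],
            partitions_retest=gparts["retest"],
            level="group",
            config={**cfg.to_dict(), "framework": framework},
        )
        _maybe_write(cfg, report, records, f"group_{framework}")
        reports[framework] = report
    return reports


# ---------------------------------------------------------------------------
# artifacts, manifest, resume
# ---------------------------------------------------------------------------

def _maybe_write(cfg: PipelineConfig, report: ReliabilityReport, records, tag: str) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    report.to_json(out / f"reliability_{tag}.json")
    node_labels = cfg.cohort.node_labels if cfg.input_dir is None else None
    metrics.write_metric_table(records_to_frame(records, node_labels), out / f"metrics_{tag}.tsv")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_experiment(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Run individual and group pipelines, write reports and a checksum manifest.

    With ``resume=True``, a pipeline whose report files already exist under
    ``cfg.out_dir`` and match the manifest checksums is skipped.
    """
    if cfg.out_dir is None:
        raise ValueError("run_full_experiment requires cfg.out_dir")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {"config": cfg.to_dict(), "config_hash": cfg.config_hash, "files": {}}
    old = json.loads(manifest_path.read_text()) if (resume and manifest_path.exists()) else {}
    resumable = old.get("config_hash") == cfg.config_hash

    def done(tag: str) -> bool:
        if not (resume and resumable):
            return False
        rel = f"reliability_{tag}.json"
        rec = old.get("files", {}).get(rel)
        p = out / rel
        return bool(rec and p.exists() and _sha256(p) == rec)

    t0 = time.perf_counter()
    if "individual" in cfg.levels:
        if done("individual"):
            logger.info("resume: skipping individual pipeline")
        else:
            run_individual_pipeline(cfg)
    if "group" in cfg.levels and cfg.frameworks:
        if all(done(f"group_{f}") for f in cfg.frameworks):
            logger.info("resume: skipping group pipeline")
        else:
            run_group_pipeline(cfg)
    for p in sorted(out.glob("*.json")) + sorted(out.glob("*.tsv")):
        if p.name != "manifest.json":
            manifest["files"][p.name] = _sha256(p)
    manifest["elapsed_seconds"] = round(time.perf_counter() - t0, 3)
    manifest["seed"] = cfg.seed
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("experiment done: %d artifacts, %.1fs", len(manifest["files"]), manifest["elapsed_seconds"])
    return manifest
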