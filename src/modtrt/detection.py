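"""Individual-level module detection by modularity maximization.

Modules (communities) of a weighted, undirected, nonnegative network are
found by maximizing the modularity quality function

    Q = (1/2m) * sum_ij (a_ij - k_i k_j / 2m) * delta(sigma_i, sigma_j)

where a_ij is the link weight, k_i the node strength, and m the total link
strength.  Three optimizers are provided — the two-phase greedy Louvain
algorithm, a Tabu single-node-move local search, and recursive
leading-eigenvector spectral bisection with Kernighan–Lin-style fine tuning —
plus a consensus-clustering wrapper that stabilizes stochastic detectors by
repeatedly reclustering the co-assignment (association) matrix of an ensemble
of runs.  An adapter lets an external executable (e.g. Infomap) act as a
detector through a simple edge-list / node-module text protocol.

All detectors are deterministic given their seed and return partitions in
canonical form (modules numbered 1..A by first appearance in node order).
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .construction import WeightedNetwork

#: modularity-gain tolerance for greedy moves
GAIN_TOL = 1e-10

#: consensus clustering defaults: ensemble size, association threshold, cap
DEFAULT_RUNS = 50
DEFAULT_TAU = 0.5
CONSENSUS_MAX_ITER = 20


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """Node -> module assignment in canonical form.

    Labels are contiguous integers 1..A, with modules numbered by first
    appearance in node order; two partitions are equal iff their canonical
    label arrays are equal.
    """

    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", canonical_labels(lab))
        self.labels.setflags(write=False)

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def n_modules(self) -> int:
        return int(self.labels.max(initial=0))

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.labels.shape == other.labels.shape and bool(
            np.all(self.labels == other.labels)
        )

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber module labels 1..A by first appearance in node order."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(labels.size, dtype=np.int64)
    for idx, lab in enumerate(labels.ravel()):
        key = int(lab)
        if key not in mapping:
            mapping[key] = len(mapping) + 1
        out[idx] = mapping[key]
    return out


@dataclass(frozen=True)
class AssociationMatrix:
    """Co-assignment frequencies across an ensemble of partitions."""

    values: np.ndarray
    n_sources: int

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("association matrix must be square")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("association matrix must be symmetric")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("association values must lie in [0, 1]")


def association_matrix(partitions: Sequence[Partition]) -> AssociationMatrix:
    """Entry (i, j) = fraction of partitions assigning i and j together."""
    if not partitions:
        raise ValueError("need at least one partition")
    n = partitions[0].n_nodes
    if any(p.n_nodes != n for p in partitions):
        raise ValueError("partitions cover different node sets")
    acc = np.zeros((n, n))
    for p in partitions:
        acc += p.labels[:, None] == p.labels[None, :]
    acc /= len(partitions)
    np.fill_diagonal(acc, 1.0)
    return AssociationMatrix(values=acc, n_sources=len(partitions))


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def modularity(net: WeightedNetwork, p: Partition, resolution: float = 1.0) -> float:
    """Modularity Q of a partition on a weighted network."""
    if p.n_nodes != net.n_nodes:
        raise ValueError("partition does not cover the network's node set")
    A = net.values
    m = net.total_strength
    if m <= 0:
        raise ValueError("empty network: total strength is zero")
    k = net.strengths
    q = 0.0
    for mod in range(1, p.n_modules + 1):
        idx = p.members(mod)
        w_in = A[np.ix_(idx, idx)].sum()  # counts internal pairs twice
        k_tot = k[idx].sum()
        q += w_in / (2.0 * m) - resolution * (k_tot / (2.0 * m)) ** 2
    return float(q)


def _modularity_dense(A: np.ndarray, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Q for a dense adjacency possibly carrying self-loops (internal use)."""
    m2 = A.sum()
    k = A.sum(axis=1)
    q = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        q += A[np.ix_(idx, idx)].sum() / m2 - resolution * (k[idx].sum() / m2) ** 2
    return float(q)


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

def _louvain_phase1(
    A: np.ndarray, rng: np.random.Generator, resolution: float
) -> tuple[np.ndarray, bool]:
    """Greedy local moves until a full sweep changes nothing.

    ``A`` may carry self-loops (aggregated levels store 2x the internal
    weight on the diagonal, so plain row sums remain node strengths).
    """
    n = A.shape[0]
    labels = np.arange(n)
    k = A.sum(axis=1)
    m2 = A.sum()  # 2m
    sigma_tot = k.copy()  # strength sum per community (indexed by label)
    moved_any = False
    order = rng.permutation(n)
    improved = True
    while improved:
        improved = False
        for i in order:
            ci = labels[i]
            ki = k[i]
            # strength from i to each neighbouring community (self excluded)
            nbrs = np.flatnonzero(A[i])
            nbrs = nbrs[nbrs != i]
            if nbrs.size == 0:
                continue
            comms, inv = np.unique(labels[nbrs], return_inverse=True)
            k_to = np.zeros(comms.size)
            np.add.at(k_to, inv, A[i, nbrs])
            # gains evaluated with i removed from its community
            sigma_tot[ci] -= ki
            k_to_ci = float(k_to[comms == ci].sum())
            add = 2.0 * k_to / m2 - resolution * 2.0 * ki * sigma_tot[comms] / (m2 * m2)
            add_ci = 2.0 * k_to_ci / m2 - resolution * 2.0 * ki * sigma_tot[ci] / (m2 * m2)
            gains = add - add_ci
            best_gain = gains.max()
            if best_gain > GAIN_TOL:
                target = int(comms[gains >= best_gain - GAIN_TOL].min())
                if target != ci:
                    labels[i] = target
                    sigma_tot[target] += ki
                    improved = True
                    moved_any = True
                    continue
            sigma_tot[ci] += ki
    return labels, moved_any


def _aggregate(A: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse communities to super-nodes; diagonal = 2x internal weight."""
    comms, inv = np.unique(labels, return_inverse=True)
    c = comms.size
    ind = np.zeros((A.shape[0], c))
    ind[np.arange(A.shape[0]), inv] = 1.0
    return ind.T @ A @ ind, inv


def louvain(net: WeightedNetwork, seed: int = 0, resolution: float = 1.0) -> Partition:
    """Two-phase greedy modularity maximization (Louvain algorithm).

    Phase 1 sweeps nodes in a seed-shuffled order, moving each to the
    neighbouring community with the largest positive modularity gain (ties to
    the lowest community id); phase 2 aggregates communities into super-nodes
    and the two phases repeat until phase 1 makes no move.
    """
    if net.total_strength <= 0:
        raise ValueError("empty network: total strength is zero")
    rng = np.random.default_rng(seed)
    A = net.values.astype(float).copy()
    node_comm = np.arange(net.n_nodes)  # original node -> current level node
    while True:
        labels, moved = _louvain_phase1(A, rng, resolution)
        if not moved:
            break
        A, inv = _aggregate(A, labels)
        node_comm = inv[node_comm]  # inv: level node -> super-node index
    return Partition(labels=node_comm + 1, provenance=f"louvain(seed={seed})")


# ---------------------------------------------------------------------------
# Tabu search
# ---------------------------------------------------------------------------

def tabu_search(
    net: WeightedNetwork,
    seed: int = 0,
    tenure: int | None = None,
    max_iter: int | None = None,
    resolution: float = 1.0,
    patience: int = 200,
) -> Partition:
    """Tabu local search over single-node relabel moves.

    Starts from the all-singletons partition.  Each iteration applies the best
    non-tabu move (node to an adjacent community or to a fresh singleton),
    accepting downhill moves; a reversed (node, old-community) move is tabu
    for ``tenure`` iterations unless it beats the best modularity seen
    (aspiration).  Stops after ``max_iter`` iterations or ``patience``
    consecutive non-improving ones; returns the best partition seen.
    """
    n = net.n_nodes
    m = net.total_strength
    if m <= 0:
        raise ValueError("empty network: total strength is zero")
    if tenure is None:
        tenure = max(5, n // 10)
    if max_iter is None:
        max_iter = 100 * n
    rng = np.random.default_rng(seed)
    A = net.values
    k = net.strengths
    m2 = 2.0 * m

    # community bookkeeping; empty labels are recycled through a free list
    cap = n + 1
    labels = np.arange(n)
    sigma_tot = np.zeros(cap)
    sigma_tot[:n] = k
    size = np.zeros(cap, dtype=np.int64)
    size[:n] = 1
    K = np.zeros((n, cap))  # K[i, c] = strength from i to community c
    for c in range(n):
        K[:, c] = A[:, c]
    free: list[int] = []

    q = _modularity_dense(A, labels, resolution)
    best_q, best_labels = q, labels.copy()
    tabu: dict[tuple[int, int], int] = {}
    stale = 0
    rows = np.arange(n)
    for it in range(max_iter):
        k_own = K[rows, labels]
        sig_own = sigma_tot[labels] - k
        # gain of moving each node i into each community c (c active, c != own,
        # adjacent: K[i, c] > 0)
        gains = (
            2.0 * (K - k_own[:, None]) / m2
            - resolution * 2.0 * k[:, None] * (sigma_tot[None, :] - sig_own[:, None]) / (m2 * m2)
        )
        valid = (K > 0) & (size[None, :] > 0)
        valid[rows, labels] = False
        gains = np.where(valid, gains, -np.inf)
        # fresh-singleton column: only for nodes not already singletons
        g_single = -2.0 * k_own / m2 + resolution * 2.0 * k * sig_own / (m2 * m2)
        g_single = np.where(size[labels] > 1, g_single, -np.inf)
        # tabu: forbid reversals unless they beat the best Q seen (aspiration)
        for (node, lab), expiry in tabu.items():
            if expiry > it and lab < cap and size[lab] > 0:
                if q + gains[node, lab] <= best_q + GAIN_TOL:
                    gains[node, lab] = -np.inf
        best_gain = max(gains.max(), g_single.max())
        if not np.isfinite(best_gain):
            break
        cand = [(int(i), int(c)) for i, c in zip(*np.nonzero(gains >= best_gain - 1e-12))]
        cand += [(int(i), -1) for i in np.flatnonzero(g_single >= best_gain - 1e-12)]
        i, t = cand[int(rng.integers(len(cand)))]
        old = int(labels[i])
        if t == -1:
            if free:
                t = free.pop()
            else:
                t = cap
                cap += 1
                sigma_tot = np.append(sigma_tot, 0.0)
                size = np.append(size, 0)
                K = np.hstack([K, np.zeros((n, 1))])
            K[:, t] = 0.0
        labels[i] = t
        sigma_tot[old] -= k[i]
        sigma_tot[t] += k[i]
        size[old] -= 1
        size[t] += 1
        if size[old] == 0:
            free.append(old)
        K[:, old] -= A[:, i]
        K[:, t] += A[:, i]
        tabu[(i, old)] = it + 1 + tenure
        q += best_gain
        if q > best_q + GAIN_TOL:
            best_q, best_labels = q, labels.copy()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    return Partition(labels=best_labels + 1, provenance=f"tabu(seed={seed})")


# ---------------------------------------------------------------------------
# spectral bisection
# ---------------------------------------------------------------------------

def _fine_tune(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Greedy single-node sign flips while any flip raises s^T Bg s."""
    Bs = Bg @ s
    improved = True
    while improved:
        improved = False
        for i in range(s.size):
            delta = -4.0 * s[i] * (Bs[i] - Bg[i, i] * s[i])
            if delta > 1e-12:
                s[i] = -s[i]
                Bs += 2.0 * s[i] * Bg[:, i]
                improved = True
    return s


def spectral_partition(net: WeightedNetwork, resolution: float = 1.0) -> Partition:
    """Recursive leading-eigenvector bisection of the modularity matrix.

    Works on the generalized subgraph modularity matrix
    B^(g)_ij = B_ij - delta_ij * sum_{l in g} B_il, fine-tunes each split with
    greedy single-node sign flips, and stops splitting a group when the
    leading eigenvalue or the split's modularity contribution is <= 1e-12.
    Deterministic: the eigenvector entry of the lowest-index node is forced
    nonnegative before rounding to signs.
    """
    n = net.n_nodes
    m = net.total_strength
    if m <= 0:
        raise ValueError("empty network: total strength is zero")
    A = net.values
    k = net.strengths
    B = A - resolution * np.outer(k, k) / (2.0 * m)

    labels = np.zeros(n, dtype=np.int64)
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        g = stack.pop()
        if g.size <= 1:
            continue
        Bg = B[np.ix_(g, g)].copy()
        Bg[np.diag_indices(g.size)] -= Bg.sum(axis=1)
        vals, vecs = np.linalg.eigh(Bg)
        lead = vals[-1]
        if lead <= 1e-12:
            continue
        v = vecs[:, -1]
        if v[0] < 0:
            v = -v
        s = np.where(v >= 0, 1.0, -1.0)
        s = _fine_tune(Bg, s)
        dq = float(s @ Bg @ s) / (4.0 * m)
        if dq <= 1e-12 or np.all(s == s[0]):
            continue
        g_pos = g[s > 0]
        g_neg = g[s < 0]
        labels[g_neg] = next_label
        next_label += 1
        stack.append(g_pos)
        stack.append(g_neg)
    return Partition(labels=labels + 1, provenance="spectral")


# ---------------------------------------------------------------------------
# detector registry & external adapter
# ---------------------------------------------------------------------------

Detector = Callable[[WeightedNetwork, int], Partition]


def get_detector(name: str | Detector, **kwargs) -> Detector:
    """Resolve a detector by name ('louvain' | 'tabu' | 'spectral') or pass through."""
    if callable(name):
        return name
    if name == "louvain":
        return lambda net, seed: louvain(net, seed, **kwargs)
    if name == "tabu":
        return lambda net, seed: tabu_search(net, seed, **kwargs)
    if name == "spectral":
        return lambda net, seed: spectral_partition(net, **kwargs)
    raise ValueError(f"unknown detector: {name!r}")


def external_detector(command: Sequence[str]) -> Detector:
    """Adapter for an external module-detection executable.

    The executable is invoked as ``command + [edge_file, seed]`` where
    ``edge_file`` holds one ``i j w`` line per weighted edge (0-based node
    indices), and must print ``node module`` lines to stdout covering every
    node.  Lets detectors such as Infomap plug into the consensus and
    group-level machinery unchanged.
    """

    def run(net: WeightedNetwork, seed: int) -> Partition:
        iu, ju = np.triu_indices(net.n_nodes, k=1)
        mask = net.values[iu, ju] > 0
        with tempfile.NamedTemporaryFile("w", suffix=".edges", delete=False) as fh:
            for i, j in zip(iu[mask], ju[mask]):
                fh.write(f"{i} {j} {net.values[i, j]:.12g}\n")
            edge_file = fh.name
        try:
            out = subprocess.run(
                [*command, edge_file, str(seed)],
                capture_output=True, text=True, check=True,
            ).stdout
        finally:
            Path(edge_file).unlink(missing_ok=True)
        labels = np.full(net.n_nodes, -1, dtype=np.int64)
        for line in out.strip().splitlines():
            node, mod = line.split()[:2]
            labels[int(node)] = int(mod)
        if np.any(labels < 0):
            raise RuntimeError("external detector did not label every node")
        return Partition(labels=labels, provenance=f"external({command[0]})")

    return run


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

def _association_as_network(assoc: AssociationMatrix, tau: float) -> WeightedNetwork:
    w = assoc.values.copy()
    w[w < tau] = 0.0
    np.fill_diagonal(w, 0.0)
    labels = tuple(f"n{i + 1:04d}" for i in range(w.shape[0]))
    return WeightedNetwork(values=w, node_labels=labels, density=1.0)


def consensus_of_runs(
    net: WeightedNetwork,
    detector: str | Detector = "louvain",
    R: int = DEFAULT_RUNS,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
) -> Partition:
    """Consensus clustering over R detector runs.

    Runs the detector R times (seeds seed+1 .. seed+R), builds the
    co-assignment association matrix, zeroes entries below ``tau``, re-runs
    the detector on the thresholded association matrix treated as a weighted
    network, and iterates until all R partitions agree (or 20 iterations; on
    non-convergence the iterate with the highest modularity on the
    association matrix is returned).
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    if R < 1:
        raise ValueError("R must be >= 1")
    det = get_detector(detector)
    parts = [det(net, seed + r) for r in range(1, R + 1)]
    for it in range(CONSENSUS_MAX_ITER):
        if all(p == parts[0] for p in parts):
            return Partition(parts[0].labels, provenance=f"consensus({parts[0].provenance})")
        assoc = association_matrix(parts)
        assoc_net = _association_as_network(assoc, tau)
        parts = [det(assoc_net, seed + (it + 1) * R + r) for r in range(1, R + 1)]
    # non-convergence: best-Q iterate on the final association matrix
    assoc_net = _association_as_network(association_matrix(parts), tau)
    qs = [modularity(assoc_net, p) for p in parts]
    best = parts[int(np.argmax(qs))]
    return Partition(best.labels, provenance=f"consensus-nonconverged({best.provenance})")


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def write_partition(p: Partition, path: str | Path, node_labels: Sequence[str] | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if node_labels is None:
        node_labels = [f"n{i + 1:04d}" for i in range(p.n_nodes)]
    with open(path, "w") as fh:
        for lab, mod in zip(node_labels, p.labels):
            fh.write(f"{lab}\t{mod}\n")
    return path


def read_partition(path: str | Path) -> tuple[Partition, tuple[str, ...]]:
    labels, mods = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            lab, mod = line.split("\t")
            labels.append(lab)
            mods.append(int(mod))
    return Partition(np.array(mods)), tuple(labels)
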