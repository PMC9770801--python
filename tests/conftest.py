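"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (double loops, exhaustive
enumeration) and independent of the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from modtrt import (
    FCMatrix,
    Partition,
    SyntheticCohortSpec,
    WeightedNetwork,
    construct_session_network,
    make_cohort,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_modularity(A: np.ndarray, labels: np.ndarray) -> float:
    """Literal double-sum Q = 1/2m sum_ij (a_ij - k_i k_j / 2m) delta(s_i, s_j)."""
    n = A.shape[0]
    k = A.sum(axis=1)
    m2 = A.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - k[i] * k[j] / m2
    return q / m2


def set_partitions(items: list):
    """All set partitions (Bell-number enumeration) of a list."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def partition_labels_from_blocks(blocks: list[list[int]], n: int) -> np.ndarray:
    labels = np.empty(n, dtype=np.int64)
    for m, block in enumerate(blocks, start=1):
        for i in block:
            labels[i] = m
    return labels


def max_q_exhaustive(A: np.ndarray) -> tuple[float, np.ndarray]:
    """Exhaustive maximum modularity over all set partitions (small n only)."""
    n = A.shape[0]
    best_q, best_labels = -np.inf, None
    for blocks in set_partitions(list(range(n))):
        labels = partition_labels_from_blocks(blocks, n)
        q = brute_modularity(A, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def pair_counts_enum(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int]:
    """Direct enumeration of (n11, n00, n10, n01) over all node pairs."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            if sa and sb:
                n11 += 1
            elif sa and not sb:
                n10 += 1
            elif sb and not sa:
                n01 += 1
            else:
                n00 += 1
    return n11, n00, n10, n01


def anova_icc_oracle(y: np.ndarray) -> float:
    """Two-way ANOVA sums of squares by direct summation; no clamping."""
    n, s = y.shape
    grand = y.sum() / (n * s)
    ss_subj = 0.0
    for i in range(n):
        ss_subj += s * (y[i].mean() - grand) ** 2
    bms = ss_subj / (n - 1)
    ss_err = 0.0
    for i in range(n):
        for j in range(s):
            ss_err += (y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
    ems = ss_err / ((n - 1) * (s - 1))
    return (bms - ems) / (bms + (s - 1) * ems)


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------

def labels_for(n: int) -> tuple[str, ...]:
    return tuple(f"n{i + 1:04d}" for i in range(n))


def net_from_dense(W: np.ndarray, density: float = 1.0) -> WeightedNetwork:
    return WeightedNetwork(values=W, node_labels=labels_for(W.shape[0]), density=density)


def two_cliques_adjacency(clique_size: int = 3, weight: float = 1.0) -> np.ndarray:
    """Two disconnected equal-weight cliques."""
    n = 2 * clique_size
    W = np.zeros((n, n))
    for offset in (0, clique_size):
        for i in range(clique_size):
            for j in range(i + 1, clique_size):
                W[offset + i, offset + j] = W[offset + j, offset + i] = weight
    return W


def planted_fc(
    module_sizes: tuple[int, ...],
    rho_in: float = 0.8,
    rho_out: float = 0.05,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[FCMatrix, Partition]:
    """Direct planted-partition FC matrix: block-constant + iid entry noise."""
    n = sum(module_sizes)
    labels = np.concatenate([np.full(s, m + 1) for m, s in enumerate(module_sizes)])
    rng = np.random.default_rng(seed)
    same = labels[:, None] == labels[None, :]
    vals = np.where(same, rho_in, rho_out).astype(float)
    eps = rng.normal(0, noise, size=(n, n))
    vals += np.triu(eps, 1) + np.triu(eps, 1).T
    vals = np.clip(vals, 0.0, 0.99)
    np.fill_diagonal(vals, 0.0)
    fc = FCMatrix("0001", "test", "nonnegative", vals, labels_for(n))
    return fc, Partition(labels)


@pytest.fixture
def two_cliques_net() -> WeightedNetwork:
    return net_from_dense(two_cliques_adjacency())


@pytest.fixture
def small_cohort_spec() -> SyntheticCohortSpec:
    return SyntheticCohortSpec(
        n_subjects=2,
        n_nodes=12,
        module_sizes=(6, 6),
        rho_in=0.6,
        rho_out=0.1,
        n_timepoints=120,
        seed=7,
    )


def session_network(runs, session: str, density: float = 0.10):
    lr = next(r for r in runs if r.session == session and r.run == "LR")
    rl = next(r for r in runs if r.session == session and r.run == "RL")
    return construct_session_network(lr, rl, density)
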