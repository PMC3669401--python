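"""Synthetic truth networks and the degree-preserving noise model.

The study design: a random bipartite "routes of affection" network (25
effectors x 100 targets, 500 edges by default) defines the truth; the true
cooperativity network connects effectors sharing more than ``coop_min_shared``
targets, and the true co-affection network connects targets sharing at least
one effector.  Noise is injected by degree-preserving double-edge swaps, so
the corrupted seeds keep every node's degree (and the total edge count) of the
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import LabeledBipartiteNetwork, LabeledSymmetricNetwork, SeedNetworks

__all__ = [
    "SimulationTruth",
    "NoiseSpec",
    "simulate_truth",
    "degree_preserving_swap",
    "rewire_edges",
    "make_noisy_seeds",
    "default_noise",
]


@dataclass
class SimulationTruth:
    """True binary W plus the cooperativity/co-affection networks derived
    from it; diagonals of P_true and C_true are structural ones."""

    W_true: np.ndarray
    P_true: np.ndarray
    C_true: np.ndarray
    rng_seed: int

    @property
    def n_tf(self) -> int:
        return self.W_true.shape[0]

    @property
    def n_gene(self) -> int:
        return self.W_true.shape[1]

    @property
    def tf_labels(self) -> list[str]:
        return [f"TF{i+1:03d}" for i in range(self.n_tf)]

    @property
    def gene_labels(self) -> list[str]:
        return [f"G{j+1:03d}" for j in range(self.n_gene)]


@dataclass
class NoiseSpec:
    """Amount of randomization: absolute swap count for W, and a fraction of
    the off-diagonal undirected edge count for P and C."""

    w_swaps: int = 125
    pc_swap_fraction: float = 0.5

    def __post_init__(self):
        if self.w_swaps < 0 or self.pc_swap_fraction < 0:
            raise ValueError("noise amounts must be non-negative")


def default_noise() -> NoiseSpec:
    return NoiseSpec(w_swaps=125, pc_swap_fraction=0.5)


def simulate_truth(
    n_tf: int = 25,
    n_gene: int = 100,
    n_edges: int = 500,
    coop_min_shared: int = 2,
    seed: int = 0,
) -> SimulationTruth:
    """Draw a truth triple.

    W_true places exactly ``n_edges`` distinct edges uniformly at random;
    P_true connects effectors sharing strictly more than ``coop_min_shared``
    targets; C_true connects targets sharing at least one effector.
    Deterministic given ``seed`` (PCG64 generator).
    """
    if not (0 < n_edges <= n_tf * n_gene):
        raise ValueError(f"n_edges must lie in (0, {n_tf * n_gene}], got {n_edges}")
    if coop_min_shared < 1:
        raise ValueError("coop_min_shared must be >= 1")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_tf * n_gene, size=n_edges, replace=False)
    W = np.zeros((n_tf, n_gene))
    W.flat[flat] = 1.0

    shared_targets = W @ W.T          # (i, m): number of common targets
    P = (shared_targets > coop_min_shared).astype(float)
    shared_effectors = W.T @ W        # (j, k): number of common effectors
    C = (shared_effectors > 0).astype(float)
    np.fill_diagonal(P, 1.0)
    np.fill_diagonal(C, 1.0)
    return SimulationTruth(W_true=W, P_true=P, C_true=C, rng_seed=seed)


class SwapBudgetError(RuntimeError):
    """Raised when too few swap proposals succeed; try fewer swaps."""


def degree_preserving_swap(
    grid: np.ndarray,
    n_swaps: int,
    seed: int = 0,
    symmetric: bool = False,
    attempt_factor: int = 100,
) -> np.ndarray:
    """Randomize a binary grid by ``n_swaps`` successful double-edge swaps.

    A swap picks two edges (a, b) and (c, d) with a != c and b != d and
    rewires them to (a, d) and (c, b) when both target slots are free, which
    preserves every row and column sum exactly.  In symmetric mode the grid is
    treated as an undirected graph: swaps act on the upper triangle and are
    mirrored, and the diagonal is never touched.  Rejected proposals do not
    count; after ``attempt_factor * n_swaps`` failed proposals a
    :class:`SwapBudgetError` is raised.
    """
    M = np.asarray(grid)
    vals = np.unique(M)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("grid must be binary")
    out = M.astype(float).copy()
    if n_swaps == 0:
        return out
    rng = np.random.default_rng(seed)

    if symmetric:
        if not np.array_equal(out, out.T):
            raise ValueError("symmetric=True requires a symmetric grid")
        iu, ju = np.triu_indices_from(out, k=1)
        mask = out[iu, ju] > 0
        edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    else:
        ii, jj = np.nonzero(out)
        edges = list(zip(ii.tolist(), jj.tolist()))
    if len(edges) < 2:
        raise SwapBudgetError("fewer than 2 edges; nothing to swap")

    edge_index = {e: k for k, e in enumerate(edges)}
    max_attempts = attempt_factor * n_swaps
    done = 0
    attempts = 0
    n_edges = len(edges)
    while done < n_swaps:
        if attempts >= max_attempts:
            raise SwapBudgetError(
                f"only {done}/{n_swaps} swaps succeeded after {attempts} proposals; "
                "request fewer swaps"
            )
        attempts += 1
        k1, k2 = rng.integers(0, n_edges, size=2)
        if k1 == k2:
            continue
        a, b = edges[k1]
        c, d = edges[k2]
        if symmetric:
            # undirected edges; randomize orientation of the second edge
            if rng.integers(0, 2):
                c, d = d, c
            # proposed new undirected edges {a, d} and {c, b}
            if a == d or c == b or a == c or b == d:
                continue
            e1 = (min(a, d), max(a, d))
            e2 = (min(c, b), max(c, b))
            if out[e1] > 0 or out[e2] > 0:
                continue
            out[a, b] = out[b, a] = 0.0
            out[c, d] = out[d, c] = 0.0
            out[e1] = out[e1[::-1]] = 1.0
            out[e2] = out[e2[::-1]] = 1.0
            old1, old2 = (min(a, b), max(a, b)), (min(c, d), max(c, d))
        else:
            if a == c or b == d:
                continue
            if out[a, d] > 0 or out[c, b] > 0:
                continue
            out[a, b] = out[c, d] = 0.0
            out[a, d] = out[c, b] = 1.0
            e1, e2 = (a, d), (c, b)
            old1, old2 = (a, b), (c, d)
        # keep the edge list and index in sync
        for old, new in ((old1, e1), (old2, e2)):
            k = edge_index.pop(old)
            edges[k] = new
            edge_index[new] = k
        done += 1
    return out


def rewire_edges(grid: np.ndarray, n_moves: int, seed: int = 0) -> np.ndarray:
    """Randomize a symmetric binary network by single-endpoint rewiring.

    Each move picks a random off-diagonal edge {a, b}, keeps one endpoint
    (chosen at random) and reconnects it to a node drawn uniformly from its
    current non-neighbours.  The edge count is conserved exactly but node
    degrees are not, so repeated moves drive the network toward a uniform
    random graph — a harsher randomization than the degree-preserving double
    swap.  The diagonal is never touched.  Deterministic given ``seed``.
    """
    M = np.asarray(grid)
    if not np.array_equal(M, M.T):
        raise ValueError("rewire_edges expects a symmetric grid")
    vals = np.unique(M)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("grid must be binary")
    out = M.astype(float).copy()
    if n_moves == 0:
        return out
    n = out.shape[0]
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    mask = out[iu, ju] > 0
    edges = [(int(a), int(b)) for a, b in zip(iu[mask], ju[mask])]
    if not edges:
        raise ValueError("no off-diagonal edges to rewire")
    for _ in range(n_moves):
        k = int(rng.integers(len(edges)))
        a, b = edges[k]
        if rng.integers(2):
            a, b = b, a
        # new partner for a among its current non-neighbours
        candidates = np.flatnonzero((out[a] == 0) & (np.arange(n) != a))
        if len(candidates) == 0:
            continue
        c = int(candidates[rng.integers(len(candidates))])
        out[a, b] = out[b, a] = 0.0
        out[a, c] = out[c, a] = 1.0
        edges[k] = (min(a, c), max(a, c))
    return out


def make_noisy_seeds(
    truth: SimulationTruth, noise: NoiseSpec | None = None, seed: int = 0
) -> SeedNetworks:
    """Corrupt a truth triple into raw (un-normalized) seed networks.

    W gets ``noise.w_swaps`` degree-preserving double-edge swaps.  P and C
    are randomized by single-endpoint rewiring with
    round(pc_swap_fraction x off-diagonal nonzero entries) moves each and
    diagonals kept at 1; rewiring scrambles degree structure, which for
    these dense derived networks is required to actually destroy seed
    information rather than merely shuffle it.  Independent sub-seeds for
    the three grids are derived from ``seed``.
    """
    noise = noise or default_noise()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    W_noisy = degree_preserving_swap(truth.W_true, noise.w_swaps, seed=sub[0])

    def _sym_noisy(M: np.ndarray, s: int) -> np.ndarray:
        n_off = int(M.sum() - np.trace(M))  # nonzero off-diagonal entries
        n_moves = int(round(noise.pc_swap_fraction * n_off))
        out = rewire_edges(M, n_moves, seed=s)
        np.fill_diagonal(out, 1.0)
        return out

    P_noisy = _sym_noisy(truth.P_true, sub[1])
    C_noisy = _sym_noisy(truth.C_true, sub[2])

    return SeedNetworks(
        LabeledBipartiteNetwork(truth.tf_labels, truth.gene_labels, W_noisy),
        LabeledSymmetricNetwork(truth.tf_labels, P_noisy),
        LabeledSymmetricNetwork(truth.gene_labels, C_noisy),
        normalized=False,
    )
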