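"""The message-passing network refinement loop.

Seeds are first z-score normalized so all three networks live on a common
scale.  Each iteration then computes, for every TF i and gene j, a
responsibility message R_ij (agreement between the TFs cooperating with i and
the TFs targeting j) and an availability message A_ij (agreement between i's
targets and j's co-regulated partners), both scored with a continuous Tanimoto
similarity

    T(x, y) = <x, y> / sqrt(|x|^2 + |y|^2 - |<x, y>|)

on z-scored edge-weight vectors.  The regulatory network W moves a step alpha
toward (R + A)/2, then the cooperativity network P and the co-regulation
network C move toward similarities between rows (resp. columns) of the new W.
Self-similarity diagonals of P and C grow exponentially with the iteration
count, which progressively anchors the messages to the current W and
guarantees convergence; the loop stops once the mean absolute change of W
between successive iterations falls below ``tol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .netio import (
    LabeledBipartiteNetwork,
    LabeledSymmetricNetwork,
    SeedNetworks,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PandaConfig",
    "PandaState",
    "normalize_network",
    "tanimoto_similarity",
    "compute_responsibility",
    "compute_availability",
    "update_regulatory",
    "update_cooperativity",
    "update_coregulation",
    "hamming_distance",
    "run_panda",
    "normalize_seeds",
]


@dataclass
class PandaConfig:
    """Run parameters.

    alpha : update step in (0, 1); each iteration blends (1-alpha) of the old
        network with alpha of the new message evidence.
    tol : convergence threshold on the mean absolute change of W.
    max_iter : iteration budget.
    seed : unused by the deterministic core; carried for provenance.
    use_ppi, use_expression : when False the corresponding seed is replaced by
        the identity before normalization.
    """

    alpha: float = 0.05
    tol: float = 1e-5
    max_iter: int = 500
    seed: int | None = None
    use_ppi: bool = True
    use_expression: bool = True

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not self.tol > 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class PandaState:
    """Current networks plus iteration bookkeeping."""

    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    t: int = 0
    last_distance: float = np.inf
    converged: bool = False
    degenerate_entries: int = 0


def normalize_network(raw: np.ndarray) -> np.ndarray:
    """Z-score a weight grid along both axes: (z_row + z_col) / sqrt(2).

    Row and column z-scores use the sample (n-1) standard deviation.  Where a
    row or column has zero variance, the overall-grid z-score stands in for
    that degenerate component, so the output stays finite whenever the grid is
    not constant.
    """
    A = np.asarray(raw, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError(f"need a grid with >=2 rows and >=2 columns, got shape {A.shape}")
    if np.ptp(A) == 0:
        raise ValueError("constant grid has no scale to normalize")

    mu_r = A.mean(axis=1, keepdims=True)
    sd_r = A.std(axis=1, ddof=1, keepdims=True)
    mu_c = A.mean(axis=0, keepdims=True)
    sd_c = A.std(axis=0, ddof=1, keepdims=True)
    mu_o = A.mean()
    sd_o = A.std(ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        zr = (A - mu_r) / sd_r
        zc = (A - mu_c) / sd_c
    zo = (A - mu_o) / sd_o
    zr = np.where(sd_r == 0, zo, zr)
    zc = np.where(sd_c == 0, zo, zc)
    return (zr + zc) / np.sqrt(2.0)


def tanimoto_similarity(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity between rows of X and columns of Y.

    Entry (i, j) is <x_i, y_j> / sqrt(|x_i|^2 + |y_j|^2 - |<x_i, y_j>|).  The
    score is positive when the vectors agree in sign structure and negative
    when they disagree; a pair of zero vectors scores 0.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[0]:
        raise ValueError(f"inner dimensions disagree: {X.shape} x {Y.shape}")
    dot = X @ Y
    sq_rows = np.einsum("ij,ij->i", X, X)[:, None]
    sq_cols = np.einsum("ij,ij->j", Y, Y)[None, :]
    denom_sq = sq_rows + sq_cols - np.abs(dot)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = dot / np.sqrt(denom_sq)
    # both vectors zero -> 0/0; define as neutral 0
    degenerate = denom_sq <= 0
    if degenerate.any():
        T = np.where(degenerate, 0.0, T)
    return T


def _count_degenerate(X: np.ndarray, Y: np.ndarray) -> int:
    zero_rows = ~np.any(X, axis=1)
    zero_cols = ~np.any(Y, axis=0)
    return int(zero_rows.sum() * zero_cols.sum())


def compute_responsibility(P: np.ndarray, W: np.ndarray) -> np.ndarray:
    """R_ij: similarity between P's row i (i's cooperators) and W's column j
    (the TFs targeting gene j)."""
    return tanimoto_similarity(P, W)


def compute_availability(W: np.ndarray, C: np.ndarray) -> np.ndarray:
    """A_ij: similarity between W's row i (i's targets) and C's column j
    (the genes co-regulated with j)."""
    return tanimoto_similarity(W, C)


def update_regulatory(W: np.ndarray, R: np.ndarray, A: np.ndarray, alpha: float) -> np.ndarray:
    """W' = (1 - alpha) W + alpha (R + A) / 2."""
    if not (W.shape == R.shape == A.shape):
        raise ValueError(f"shape mismatch: W {W.shape}, R {R.shape}, A {A.shape}")
    return (1.0 - alpha) * W + alpha * 0.5 * (R + A)


def _similarity_with_growing_diagonal(vectors: np.ndarray, alpha: float, t: int) -> np.ndarray:
    """Pairwise Tanimoto similarity of the given row vectors, with the
    diagonal replaced by n * sd(off-diagonal candidates per row) * exp(2 alpha t).

    The exponential term is the convergence engine: as t grows the
    self-similarity dwarfs all pairwise scores, so the message grids freeze.
    """
    S = tanimoto_similarity(vectors, vectors.T)
    n = S.shape[0]
    off = S.copy()
    np.fill_diagonal(off, np.nan)
    if n > 2:
        row_sd = np.nanstd(off, axis=1, ddof=1)
    else:  # a single off-diagonal value has no sample spread
        row_sd = np.zeros(n)
    row_sd = np.nan_to_num(row_sd, nan=0.0)
    np.fill_diagonal(S, n * row_sd * np.exp(2.0 * alpha * t))
    return S


def update_cooperativity(P: np.ndarray, W_new: np.ndarray, alpha: float, t: int) -> np.ndarray:
    """P' = (1 - alpha) P + alpha P~ where P~ compares TF target profiles
    (rows of the already-updated W) and the diagonal follows the growth rule."""
    if P.shape[0] != W_new.shape[0]:
        raise ValueError(f"shape mismatch: P {P.shape}, W {W_new.shape}")
    P_cand = _similarity_with_growing_diagonal(W_new, alpha, t)
    P_new = (1.0 - alpha) * P + alpha * P_cand
    return 0.5 * (P_new + P_new.T)  # kill float-level asymmetry


def update_coregulation(C: np.ndarray, W_new: np.ndarray, alpha: float, t: int) -> np.ndarray:
    """C' = (1 - alpha) C + alpha C~ where C~ compares gene regulator profiles
    (columns of the already-updated W)."""
    if C.shape[0] != W_new.shape[1]:
        raise ValueError(f"shape mismatch: C {C.shape}, W {W_new.shape}")
    C_cand = _similarity_with_growing_diagonal(W_new.T, alpha, t)
    C_new = (1.0 - alpha) * C + alpha * C_cand
    return 0.5 * (C_new + C_new.T)


def hamming_distance(W_new: np.ndarray, W_old: np.ndarray) -> float:
    """Mean absolute entrywise difference; scale-free in network size."""
    if W_new.shape != W_old.shape:
        raise ValueError(f"shape mismatch: {W_new.shape} vs {W_old.shape}")
    return float(np.abs(W_new - W_old).mean())


def normalize_seeds(seeds: SeedNetworks, config: PandaConfig | None = None) -> SeedNetworks:
    """Z-score-normalize a raw seed triple (honouring use_ppi/use_expression)."""
    config = config or PandaConfig()
    W0 = seeds.regulatory.weights
    P0 = seeds.cooperativity.weights if config.use_ppi else np.eye(len(seeds.tf_labels))
    C0 = seeds.coregulation.weights if config.use_expression else np.eye(len(seeds.gene_labels))
    return SeedNetworks(
        LabeledBipartiteNetwork(seeds.tf_labels, seeds.gene_labels, normalize_network(W0)),
        LabeledSymmetricNetwork(seeds.tf_labels, _symmetrize(normalize_network(P0))),
        LabeledSymmetricNetwork(seeds.gene_labels, _symmetrize(normalize_network(C0))),
        normalized=True,
    )


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def run_panda(
    seeds: SeedNetworks, config: PandaConfig | None = None
) -> tuple[PandaState, list[float]]:
    """Run the full message-passing loop to convergence.

    Raw seeds are normalized first (already-normalized seeds pass through).
    Each iteration computes R and A from the current state, steps W, then
    steps P and C from the new W.  Terminates when the mean absolute change
    of W drops below ``config.tol`` or the iteration budget is spent.

    Returns the final state and the per-iteration distance trace.
    """
    config = config or PandaConfig()
    if not seeds.normalized:
        seeds = normalize_seeds(seeds, config)
    W = seeds.regulatory.weights.copy()
    P = seeds.cooperativity.weights.copy()
    C = seeds.coregulation.weights.copy()

    state = PandaState(W=W, P=P, C=C)
    trace: list[float] = []
    for t in range(config.max_iter):
        R = compute_responsibility(state.P, state.W)
        A = compute_availability(state.W, state.C)
        state.degenerate_entries += _count_degenerate(state.P, state.W)
        state.degenerate_entries += _count_degenerate(state.W, state.C)
        W_new = update_regulatory(state.W, R, A, config.alpha)
        P_new = update_cooperativity(state.P, W_new, config.alpha, t)
        C_new = update_coregulation(state.C, W_new, config.alpha, t)
        for name, M in (("W", W_new), ("P", P_new), ("C", C_new)):
            if not np.all(np.isfinite(M)):
                raise FloatingPointError(
                    f"non-finite values in {name} at iteration {t}"
                )
        dist = hamming_distance(W_new, state.W)
        state.W, state.P, state.C = W_new, P_new, C_new
        state.t = t + 1
        state.last_distance = dist
        trace.append(dist)
        logger.info("iteration %d: distance %.3e", t, dist)
        if dist < config.tol:
            state.converged = True
            break
    if state.degenerate_entries:
        logger.info("degenerate zero/zero similarity entries: %d", state.degenerate_entries)
    return state, trace
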