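"""MCBFS: supervised multi-scale clustering-based gene weighting.

The algorithm treats the known class labels as fixed clusters and scores each
gene by how compact the samples are around their class centers, measured
through a bank of ``m`` bounded Gaussian-style dissimilarities

    d_n(x, v) = 1 - exp(-gamma_n (x - v)^2),

one per bandwidth gamma_n. Two simplex-constrained weight vectors are learned
by alternating closed-form updates: ``W`` over genes (ridge-regularized, so
weight spreads over several compact genes instead of collapsing onto one) and
``P`` over distance functions (entropy-regularized, so no single scale
dominates). The regularization strengths ``delta`` and ``rho`` are re-derived
each iteration from the current objective value so that all three terms stay
on a comparable scale.

The minimized objective is

    J(W, P) = sum_n P_n sum_k W_k A_nk + delta * sum_k W_k^2
              + rho * sum_n P_n log P_n,
    s.t.  W, P on their simplexes,

where A_nk = sum over samples of d_n(x_jk, v_{class(j),k}) is the within-class
scatter of gene k under distance function n. ``A`` depends only on the data
and labels, so it is computed once per fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import ExpressionDataset, GeneRanking

logger = logging.getLogger(__name__)

__all__ = [
    "McbfsConfig",
    "CenterMatrix",
    "DissimilarityBank",
    "McbfsState",
    "McbfsResult",
    "standardize_values",
    "compute_class_centers",
    "default_sigma_grid",
    "compute_gammas",
    "build_dissimilarity_bank",
    "raw_gene_weights",
    "update_gene_weights",
    "update_function_weights",
    "update_delta",
    "update_rho",
    "objective",
    "fit",
    "top_k",
]

#: default span of the sigma grid (log-spaced, inclusive)
SIGMA_MIN = 1e-2
SIGMA_MAX = 1e2


@dataclass
class McbfsConfig:
    """Tuning parameters of the MCBFS fit.

    m : number of distance functions (bandwidths); 50 by default.
    alpha, beta : scale factors for the adaptive ridge (delta) and entropy
        (rho) strengths; 0.5 each by default.
    max_iter : iteration cap (100 by default).
    tol : convergence threshold on max |dW| and |dP|.
    sigma_grid : optional explicit bandwidth multipliers (length m).
    standardize : per-gene scaling applied before fitting — "zscore"
        (default), "minmax", or None for raw values. The objective compares
        genes by absolute within-class scatter, so genes must be brought to a
        common scale for the weights to reflect class structure rather than
        measurement units.
    rho_fallback : rho used when m == 1 (the entropy term is identically 0).
    seed : recorded for provenance; the algorithm itself is deterministic.
    """

    m: int = 50
    alpha: float = 0.5
    beta: float = 0.5
    max_iter: int = 100
    tol: float = 1e-6
    sigma_grid: Sequence[float] | None = None
    standardize: str | None = "zscore"
    rho_fallback: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.sigma_grid is not None and len(self.sigma_grid) != self.m:
            raise ValueError("sigma_grid length must equal m")
        if self.standardize not in (None, "zscore", "minmax"):
            raise ValueError("standardize must be None, 'zscore' or 'minmax'")


@dataclass
class CenterMatrix:
    """Per-class arithmetic-mean centers (c x p) and class sizes."""

    centers: np.ndarray
    class_sizes: list[int]


@dataclass
class DissimilarityBank:
    """Precomputed within-class scatter A (m x p) plus its sigma/gamma grids."""

    A: np.ndarray
    gammas: np.ndarray
    sigmas: np.ndarray
    gene_ranges: np.ndarray


@dataclass
class McbfsState:
    W: np.ndarray
    P: np.ndarray
    delta: float
    rho: float
    J: float
    iteration: int


@dataclass
class McbfsResult:
    final_state: McbfsState
    trajectory: list[tuple[float, float, float]]  # (J, delta, rho) per iteration
    ranking: GeneRanking
    converged: bool
    gene_ids: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)


def standardize_values(values: np.ndarray, mode: str | None) -> np.ndarray:
    """Per-gene scaling: z-score, min-max to [0, 1], or identity.

    Constant genes are left at zero deviation (they are dropped by
    :func:`fit` anyway).
    """
    if mode is None:
        return np.asarray(values, dtype=float)
    values = np.asarray(values, dtype=float)
    if mode == "zscore":
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (values - mu) / sd
    if mode == "minmax":
        lo = values.min(axis=0)
        span = values.max(axis=0) - lo
        span = np.where(span == 0, 1.0, span)
        return (values - lo) / span
    raise ValueError(f"unknown standardize mode {mode!r}")


def compute_class_centers(data: ExpressionDataset) -> CenterMatrix:
    """Class centers v_ik: the mean of gene k over samples of class i."""
    idx = data.class_indices
    c = idx.max() + 1
    centers = np.empty((c, data.n_genes))
    sizes = []
    for i in range(c):
        mask = idx == i
        if not mask.any():
            raise ValueError(f"class {i} is empty")
        centers[i] = data.values[mask].mean(axis=0)
        sizes.append(int(mask.sum()))
    return CenterMatrix(centers=centers, class_sizes=sizes)


def default_sigma_grid(m: int) -> np.ndarray:
    """Log-spaced bandwidth multipliers from 1e-2 to 1e2 (m = 1 gives [1])."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1:
        return np.array([1.0])
    return np.geomspace(SIGMA_MIN, SIGMA_MAX, m)


def compute_gammas(
    sigmas: Sequence[float], values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Bandwidths gamma_n = sigma_n * (max gene range + min gene range) / 2.

    The gene range u_k is max - min of gene k over all samples. A matrix in
    which every gene is constant has no scale to set and is an error.
    """
    values = np.asarray(values, dtype=float)
    gene_ranges = values.max(axis=0) - values.min(axis=0)
    if np.all(gene_ranges == 0):
        raise ValueError("degenerate data: every gene constant")
    scale = (gene_ranges.max() + gene_ranges.min()) / 2.0
    gammas = np.asarray(sigmas, dtype=float) * scale
    return gammas, gene_ranges


def build_dissimilarity_bank(
    data: ExpressionDataset, centers: CenterMatrix, config: McbfsConfig
) -> DissimilarityBank:
    """A_nk = sum over samples j of (1 - exp(-gamma_n (x_jk - v_{class(j),k})^2)).

    Computed once per fit: the centers are fixed by the labels, so A never
    changes across iterations.
    """
    sigmas = (
        np.asarray(config.sigma_grid, dtype=float)
        if config.sigma_grid is not None
        else default_sigma_grid(config.m)
    )
    gammas, gene_ranges = compute_gammas(sigmas, data.values)
    dev2 = (data.values - centers.centers[data.class_indices]) ** 2  # (s, p)
    # (m, s, p) would be large for big inputs; accumulate per bandwidth.
    A = np.empty((len(gammas), data.n_genes))
    for n, g in enumerate(gammas):
        A[n] = (1.0 - np.exp(-g * dev2)).sum(axis=0)
    return DissimilarityBank(A=A, gammas=gammas, sigmas=sigmas, gene_ranges=gene_ranges)


def raw_gene_weights(
    bank: DissimilarityBank, P: np.ndarray, delta: float
) -> np.ndarray:
    """Closed-form solution of the equality-constrained ridge problem:
        W_k = 1/p + (1/(2 delta)) * (mean_k' T_k' - T_k),  T_k = sum_n P_n A_nk.
    Enforces only sum W = 1; entries may be negative."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    T = np.asarray(P, dtype=float) @ bank.A  # (p,)
    p = T.shape[0]
    return 1.0 / p + (T.mean() - T) / (2.0 * delta)


def update_gene_weights(
    bank: DissimilarityBank, P: np.ndarray, delta: float
) -> np.ndarray:
    """Gene-weight update: the raw closed form with negative entries clipped
    to 0 and the vector renormalized (simplex projection heuristic standard
    in attribute-weighting clustering)."""
    W = raw_gene_weights(bank, P, delta)
    T = np.asarray(P, dtype=float) @ bank.A
    if np.any(W < 0):
        logger.debug("clipping %d negative gene weights", int((W < 0).sum()))
        W = np.clip(W, 0.0, None)
        total = W.sum()
        if total == 0:  # all mass clipped: fall back to the best gene(s)
            W = (T == T.min()).astype(float)
            total = W.sum()
        W = W / total
    return W


def update_function_weights(
    bank: DissimilarityBank, W: np.ndarray, rho: float
) -> np.ndarray:
    """Entropy-regularized update P_n = softmax(-B_n / rho), B_n = sum_k W_k A_nk.

    The constant -1 in the stationarity condition's exponent cancels in the
    normalization; a max-shift keeps the exponentials finite.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    B = bank.A @ np.asarray(W, dtype=float)  # (m,)
    z = -B / rho
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _weighted_scatter(bank: DissimilarityBank, W: np.ndarray, P: np.ndarray) -> float:
    """First objective term: sum_n P_n sum_k W_k A_nk."""
    return float(np.asarray(P) @ (bank.A @ np.asarray(W)))


def update_delta(
    bank: DissimilarityBank, W: np.ndarray, P: np.ndarray, alpha: float
) -> float:
    """delta = alpha * (weighted scatter) / sum_k W_k^2."""
    num = _weighted_scatter(bank, W, P)
    if num == 0:
        raise ValueError("degenerate: zero within-class scatter")
    return float(alpha * num / np.sum(np.asarray(W) ** 2))


def update_rho(
    bank: DissimilarityBank,
    W: np.ndarray,
    P: np.ndarray,
    beta: float,
    rho_fallback: float = 1.0,
) -> float:
    """rho = beta * (weighted scatter) / |sum_n P_n log P_n| (natural log).

    The entropy sum is non-positive; its absolute value is taken so that rho
    stays positive and keeps penalizing concentration of P. For m = 1 the
    entropy is identically zero and ``rho_fallback`` is returned.
    """
    P = np.asarray(P, dtype=float)
    if P.size == 1:
        return float(rho_fallback)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)
    ent = abs(float(plogp.sum()))
    if ent == 0:
        raise ValueError("degenerate: P is one-hot, entropy is zero")
    num = _weighted_scatter(bank, W, P)
    if num == 0:
        raise ValueError("degenerate: zero within-class scatter")
    return float(beta * num / ent)


def objective(bank: DissimilarityBank, state: McbfsState) -> float:
    """J = sum_n P_n B_n + delta sum W^2 + rho sum P log P (0 log 0 := 0)."""
    W, P = np.asarray(state.W), np.asarray(state.P)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)
    return float(
        _weighted_scatter(bank, W, P)
        + state.delta * np.sum(W**2)
        + state.rho * plogp.sum()
    )


def fit(data: ExpressionDataset, config: McbfsConfig | None = None) -> McbfsResult:
    """Run the alternating-update MCBFS fit and return weights and ranking.

    Per iteration t: delta and rho are recomputed from (W, P) of iteration
    t-1, then W is updated, then P from the new W. Stops when both weight
    vectors move less than ``config.tol`` in max-norm, or at ``max_iter``.

    Zero-range (constant) genes carry no class information but would minimize
    the within-class scatter; they are dropped before fitting (with a
    warning) and appended to the ranking with weight 0.
    """
    config = config or McbfsConfig()
    raw_ranges = data.values.max(axis=0) - data.values.min(axis=0)
    keep = raw_ranges > 0
    dropped = [g for g, k in zip(data.gene_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d constant gene(s): %s", len(dropped), dropped[:5])
    if not keep.any():
        raise ValueError("degenerate data: every gene constant")
    gene_ids = [g for g, k in zip(data.gene_ids, keep) if k]
    work = ExpressionDataset(
        values=standardize_values(data.values[:, keep], config.standardize),
        sample_ids=data.sample_ids,
        gene_ids=gene_ids,
        labels=data.labels,
    )

    centers = compute_class_centers(work)
    bank = build_dissimilarity_bank(work, centers, config)
    p = work.n_genes
    m = config.m
    W = np.full(p, 1.0 / p)
    P = np.full(m, 1.0 / m)

    trajectory: list[tuple[float, float, float]] = []
    converged = False
    delta = rho = float("nan")
    J = float("nan")
    for t in range(1, config.max_iter + 1):
        delta = update_delta(bank, W, P, config.alpha)
        rho = update_rho(bank, W, P, config.beta, config.rho_fallback)
        W_new = update_gene_weights(bank, P, delta)
        P_new = (
            np.array([1.0])
            if m == 1
            else update_function_weights(bank, W_new, rho)
        )
        state = McbfsState(W=W_new, P=P_new, delta=delta, rho=rho, J=0.0, iteration=t)
        J = objective(bank, state)
        state.J = J
        trajectory.append((J, delta, rho))
        dW = np.abs(W_new - W).max()
        dP = np.abs(P_new - P).max()
        W, P = W_new, P_new
        if dW < config.tol and dP < config.tol:
            converged = True
            break

    order = np.argsort(-W, kind="stable")  # stable: ties keep input gene order
    ranked_genes = [gene_ids[i] for i in order] + dropped
    ranked_weights = [float(W[i]) for i in order] + [0.0] * len(dropped)
    ranking = GeneRanking(ranked_genes, ranked_weights)
    final = McbfsState(W=W, P=P, delta=delta, rho=rho, J=J, iteration=len(trajectory))
    return McbfsResult(
        final_state=final,
        trajectory=trajectory,
        ranking=ranking,
        converged=converged,
        gene_ids=gene_ids,
        dropped_genes=dropped,
    )


def top_k(result: McbfsResult, k: int) -> GeneRanking:
    """First k entries of the fitted ranking (1 <= k <= p)."""
    return result.ranking.top(k)
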