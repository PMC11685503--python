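"""Multilayer modularity and generalized Louvain community detection.

The quality function scores a joint partition of all node-layer pairs:

    Q = (1/2mu) * sum_{ijsr} [ (A_ijs - gamma * V_ijs) delta_sr
                               + omega * delta_ij ] * delta(sigma_is, sigma_jr)

where ``A_ijs`` is the observed weight of edge (i, j) in layer ``s``,
``V_ijs = k_is * k_js / (2 m_s)`` is the Newman-Girvan configuration null of
that layer, ``gamma`` the structural resolution, and ``omega`` the
inter-layer coupling reward for assigning the same node to the same
community in two different layers.  Subjects (layers) carry no natural
order, so the coupling is categorical: the ``omega`` term runs over *all*
ordered layer pairs ``r != s``, and the normalization is

    2mu = sum_{ijs} A_ijs  +  omega * N * L * (L - 1).

Fisher-z connectivity matrices contain negative weights, for which the
configuration null is ill-defined.  By default the optimizer and the score
drop negative intra-layer weights (their count is logged and recorded) and
compute the null on the positive part; a signed variant that keeps them is
available behind ``signed_null=True``.

The optimizer is a generalized Louvain: randomized single-node local moves
on the supra-graph (node-layer pairs as vertices) until no move improves Q,
then aggregation and dense-matrix Louvain on the community graph, repeated
until Q stops improving.  Consensus over many stochastic runs reclusters the
across-run co-classification matrix with the same routine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import MultilayerNetwork

__all__ = [
    "ResolutionParams",
    "CommunityAssignment",
    "QSurface",
    "null_weight",
    "modularity_score",
    "louvain_optimize",
    "consensus_partition",
    "grid_search",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_OMEGA_GRID",
]

logger = logging.getLogger(__name__)

_GAIN_TOL = 1e-10  # gains below this are treated as zero in local moves
_MAX_SWEEPS = 500

#: Default 2-D search grids for the (gamma, omega) plane.
DEFAULT_GAMMA_GRID = tuple(np.round(np.arange(0.8, 1.61, 0.1), 10))
DEFAULT_OMEGA_GRID = (0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class ResolutionParams:
    """Resolution gamma (> 0) and inter-layer coupling omega (>= 0)."""

    gamma: float = 1.2
    omega: float = 0.1

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.omega < 0:
            raise ValueError(f"omega must be non-negative, got {self.omega}")


@dataclass(frozen=True)
class CommunityAssignment:
    """An N x L integer label matrix: entry (i, s) = community of node i in layer s."""

    labels: np.ndarray
    params: ResolutionParams
    q_value: float
    seed: int | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D (nodes x layers)")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be integers")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", lab)

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.labels).size)

    def layer_labels(self, s: int) -> np.ndarray:
        return self.labels[:, s]

    def to_tsv(self, path, atlas=None, layer_ids=None) -> None:
        cols = list(layer_ids) if layer_ids is not None else list(range(self.n_layers))
        idx = list(atlas.parcel_ids) if atlas is not None else list(range(1, self.n_nodes + 1))
        df = pd.DataFrame(self.labels, index=idx, columns=cols)
        df.index.name = "parcel_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, params: ResolutionParams | None = None) -> "CommunityAssignment":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            labels=df.to_numpy(dtype=np.int64),
            params=params or ResolutionParams(),
            q_value=float("nan"),
        )


@dataclass(frozen=True)
class QSurface:
    """Mean achieved Q over a (gamma, omega) grid, and the best cell."""

    gamma_grid: tuple[float, ...]
    omega_grid: tuple[float, ...]
    mean_q: np.ndarray  # len(gamma_grid) x len(omega_grid)
    best: ResolutionParams

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.mean_q, index=list(self.gamma_grid), columns=list(self.omega_grid)
        )
        df.index.name = "gamma\\omega"
        df.to_csv(path)


# --------------------------------------------------------------------------
# preparation


def _prepare_weights(
    network: MultilayerNetwork, signed_null: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Return (A, strengths k[L,N], 2m per layer, dropped-negative pair count)."""
    W = network.weights()
    if signed_null:
        A = W
        n_dropped = 0
    else:
        A = np.maximum(W, 0.0)
        n_dropped = int(np.count_nonzero(W < 0) // 2)
        if n_dropped:
            logger.info(
                "dropped %d negative intra-layer weights (unordered pairs) for the "
                "configuration null",
                n_dropped,
            )
    k = A.sum(axis=2)
    twom = k.sum(axis=1)
    if np.any(twom <= 0):
        bad = int(np.where(twom <= 0)[0][0])
        raise ValueError(f"layer {bad} has no positive total weight; null model undefined")
    return A, k, twom, n_dropped


def _total_weight(twom: np.ndarray, omega: float, n: int, L: int) -> float:
    return float(twom.sum() + omega * n * L * (L - 1))


def null_weight(
    network: MultilayerNetwork, i: int, j: int, s: int, signed_null: bool = False
) -> float:
    """Configuration-null expected weight V_ijs = k_is * k_js / (2 m_s).

    Computed on the positive part of layer ``s`` unless ``signed_null``.
    """
    _, k, twom, _ = _prepare_weights(network, signed_null)
    n, L = network.n_nodes, network.n_layers
    if not (0 <= i < n and 0 <= j < n and 0 <= s < L):
        raise IndexError("node or layer index out of range")
    return float(k[s, i] * k[s, j] / twom[s])


# --------------------------------------------------------------------------
# scoring


def _q_unnormalized(
    A: np.ndarray, k: np.ndarray, twom: np.ndarray, labels: np.ndarray,
    gamma: float, omega: float,
) -> float:
    """Numerator of Q: intra-layer (A - gamma V) within communities + coupling."""
    L, n, _ = A.shape
    total = 0.0
    for s in range(L):
        ls = labels[:, s]
        same = ls[:, None] == ls[None, :]
        a_within = float(A[s][same].sum())
        kc = np.bincount(ls, weights=k[s])
        total += a_within - gamma * float((kc**2).sum()) / twom[s]
    if omega > 0 and L > 1:
        # for each node, count co-labelled ordered layer pairs (r != s)
        coup = 0
        for i in range(n):
            cnt = np.bincount(labels[i])
            coup += int((cnt**2).sum()) - L
        total += omega * coup
    return total


def modularity_score(
    network: MultilayerNetwork,
    assignment: CommunityAssignment | np.ndarray,
    params: ResolutionParams,
    signed_null: bool = False,
) -> float:
    """Exact multilayer modularity Q of an assignment (categorical coupling)."""
    labels = assignment.labels if isinstance(assignment, CommunityAssignment) else np.asarray(assignment)
    n, L = network.n_nodes, network.n_layers
    if labels.shape != (n, L):
        raise ValueError(f"labels shape {labels.shape} does not match network ({n}, {L})")
    A, k, twom, _ = _prepare_weights(network, signed_null)
    num = _q_unnormalized(A, k, twom, labels, params.gamma, params.omega)
    return num / _total_weight(twom, params.omega, n, L)


# --------------------------------------------------------------------------
# generalized Louvain


def _phase1_sweeps(
    A: np.ndarray, k: np.ndarray, twom: np.ndarray,
    labels_flat: np.ndarray, gamma: float, omega: float, rng: np.random.Generator,
) -> bool:
    """Randomized single-node-layer moves in place; True if anything moved.

    Flat index convention: p = s * N + i.  Candidate communities are those
    reachable through the node's intra-layer edges or its inter-layer
    couplings (plus its current community).
    """
    L, n, _ = A.shape
    nl = n * L
    # K[s, c]: strength (in layer s) of layer-s members of community c
    K = np.zeros((L, nl))
    for s in range(L):
        np.add.at(K[s], labels_flat[s * n:(s + 1) * n], k[s])
    layer_of = np.repeat(np.arange(L), n)
    node_of = np.tile(np.arange(n), L)
    moved_any = False
    for sweep in range(_MAX_SWEEPS):
        order = rng.permutation(nl)
        moved = 0
        for p in order:
            s = layer_of[p]
            i = node_of[p]
            a = labels_flat[p]
            row = A[s, i]
            nz = np.flatnonzero(row)
            lab_layer = labels_flat[s * n:(s + 1) * n]
            within = lab_layer[nz]
            if L > 1:
                cross = np.concatenate(
                    (labels_flat[i:p:n], labels_flat[p + n::n])
                )  # node i in layers != s
                cand = np.unique(np.concatenate((within, cross, (a,))))
            else:
                cross = None
                cand = np.unique(np.concatenate((within, (a,))))
            w = np.zeros(cand.size)
            np.add.at(w, np.searchsorted(cand, within), row[nz])
            if cross is not None and omega > 0:
                np.add.at(w, np.searchsorted(cand, cross), omega)
            kc = K[s, cand].copy()
            apos = np.searchsorted(cand, a)
            kc[apos] -= k[s, i]
            score = w - gamma * k[s, i] * kc / twom[s]
            best = int(np.argmax(score))
            if score[best] > score[apos] + _GAIN_TOL:
                c = cand[best]
                labels_flat[p] = c
                K[s, a] -= k[s, i]
                K[s, c] += k[s, i]
                moved += 1
        if moved:
            moved_any = True
        else:
            break
    return moved_any


def _aggregate(
    A: np.ndarray, k: np.ndarray, twom: np.ndarray,
    labels_flat: np.ndarray, gamma: float, omega: float,
) -> np.ndarray:
    """Dense community-graph matrix B_agg (includes the baked-in null and coupling)."""
    L, n, _ = A.shape
    uniq, inv = np.unique(labels_flat, return_inverse=True)
    nc = uniq.size
    B = np.zeros((nc, nc))
    for s in range(L):
        inv_s = inv[s * n:(s + 1) * n]
        Z = np.zeros((n, nc))
        Z[np.arange(n), inv_s] = 1.0
        B += Z.T @ A[s] @ Z
        kc = np.bincount(inv_s, weights=k[s], minlength=nc)
        B -= gamma * np.outer(kc, kc) / twom[s]
    if omega > 0 and L > 1:
        cnt = np.zeros((n, nc))
        np.add.at(cnt, (np.tile(np.arange(n), L), inv), 1.0)
        coup = cnt.T @ cnt
        coup[np.diag_indices(nc)] -= cnt.sum(axis=0)
        B += omega * coup
    return B


def _dense_louvain_once(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Louvain on a community graph whose null model is baked into B."""
    nc = B.shape[0]
    W = B.copy()
    np.fill_diagonal(W, 0.0)
    labels = np.arange(nc)
    for sweep in range(_MAX_SWEEPS):
        moved = 0
        for p in rng.permutation(nc):
            cw = np.bincount(labels, weights=W[p], minlength=nc)
            a = labels[p]
            best = int(np.argmax(cw))
            if cw[best] > cw[a] + _GAIN_TOL:
                labels[p] = best
                moved += 1
        if not moved:
            break
    return labels


def _louvain_engine(
    A: np.ndarray, k: np.ndarray, twom: np.ndarray,
    gamma: float, omega: float, rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Full generalized Louvain; returns flat labels (p = s * N + i)."""
    L, n, _ = A.shape
    labels = np.arange(n * L) if init is None else init.copy()
    prev_q = _q_unnormalized(A, k, twom, labels.reshape(L, n).T, gamma, omega)
    for round_ in range(100):
        _phase1_sweeps(A, k, twom, labels, gamma, omega, rng)
        # aggregation + dense merges on the community graph, repeated
        for _ in range(100):
            uniq, inv = np.unique(labels, return_inverse=True)
            if uniq.size <= 1:
                break
            B = _aggregate(A, k, twom, labels, gamma, omega)
            agg = _dense_louvain_once(B, rng)
            if np.array_equal(agg, np.arange(uniq.size)):
                break
            labels = agg[inv]
        q = _q_unnormalized(A, k, twom, labels.reshape(L, n).T, gamma, omega)
        if q <= prev_q + _GAIN_TOL:
            break
        prev_q = q
    uniq, inv = np.unique(labels, return_inverse=True)
    return inv


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError("pass an int or SeedSequence where substreams must be spawned")
    return np.random.SeedSequence(seed)


def louvain_optimize(
    network: MultilayerNetwork,
    params: ResolutionParams,
    seed=0,
    signed_null: bool = False,
) -> CommunityAssignment:
    """One stochastic generalized-Louvain maximization of multilayer Q.

    The achieved Q is at least that of the all-singletons partition (local
    moves only ever accept strict improvements starting from singletons).
    """
    A, k, twom, n_dropped = _prepare_weights(network, signed_null)
    rng = _as_rng(seed)
    flat = _louvain_engine(A, k, twom, params.gamma, params.omega, rng)
    n, L = network.n_nodes, network.n_layers
    labels = flat.reshape(L, n).T
    q = _q_unnormalized(A, k, twom, labels, params.gamma, params.omega) / _total_weight(
        twom, params.omega, n, L
    )
    return CommunityAssignment(
        labels=np.ascontiguousarray(labels),
        params=params,
        q_value=q,
        seed=seed if isinstance(seed, int) else None,
        meta={"n_dropped_negative": n_dropped, "signed_null": signed_null},
    )


def _coclassification(flat_labels: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
    eq = flat_labels[:, None] == flat_labels[None, :]
    if out is None:
        return eq.astype(float)
    out[...] = eq
    return out


def _partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two label vectors describe the same partition (up to relabeling)."""
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    # same partition iff the pairing (ia, ib) is a bijection
    pairs = np.unique(np.stack((ia, ib), axis=1), axis=0)
    return pairs.shape[0] == np.unique(ia).size == np.unique(ib).size


def consensus_partition(
    network: MultilayerNetwork,
    params: ResolutionParams,
    n_iter: int = 50,
    seed=0,
    signed_null: bool = False,
) -> CommunityAssignment:
    """Consensus community assignment over ``n_iter`` stochastic runs.

    Runs the optimizer ``n_iter`` times with deterministic substream seeds,
    accumulates the across-run co-classification matrix over node-layer
    pairs, and reclusters it with the same Louvain routine (gamma = 1,
    treating the co-classification matrix as a single-layer graph) until the
    assignment is stable across two successive rounds.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    A, k, twom, n_dropped = _prepare_weights(network, signed_null)
    n, L = network.n_nodes, network.n_layers
    nl = n * L
    base = seed if isinstance(seed, int) else None
    ss = _as_seedseq(seed)
    children = ss.spawn(n_iter + 101)
    D = np.zeros((nl, nl))
    for it in range(n_iter):
        rng = np.random.default_rng(children[it])
        flat = _louvain_engine(A, k, twom, params.gamma, params.omega, rng)
        D += flat[:, None] == flat[None, :]
    D /= n_iter
    np.fill_diagonal(D, 0.0)

    prev = None
    for round_ in range(100):
        rng = np.random.default_rng(children[n_iter + round_])
        kd = D.sum(axis=1)
        twod = kd.sum()
        if twod <= 0:  # all runs fully fragmented: consensus is singletons
            flat = np.arange(nl)
            break
        flat = _louvain_engine(D[None, :, :], kd[None, :], np.array([twod]), 1.0, 0.0, rng)
        if prev is not None and _partitions_equal(flat, prev):
            break
        prev = flat
        _coclassification(flat, out=D)
        np.fill_diagonal(D, 0.0)
    else:
        raise RuntimeError(
            "consensus reclustering did not stabilize within 100 rounds "
            f"(n_iter={n_iter}, params={params}, seed={seed})"
        )
    labels = flat.reshape(L, n).T
    q = _q_unnormalized(A, k, twom, labels, params.gamma, params.omega) / _total_weight(
        twom, params.omega, n, L
    )
    logger.info(
        "consensus over %d runs converged in %d round(s); Q=%.6f", n_iter, round_ + 1, q
    )
    return CommunityAssignment(
        labels=np.ascontiguousarray(labels),
        params=params,
        q_value=q,
        seed=base,
        meta={
            "n_dropped_negative": n_dropped,
            "signed_null": signed_null,
            "n_iter": n_iter,
            "consensus_rounds": round_ + 1,
        },
    )


def grid_search(
    network: MultilayerNetwork,
    gamma_grid=DEFAULT_GAMMA_GRID,
    omega_grid=DEFAULT_OMEGA_GRID,
    repeats: int = 5,
    seed=0,
    signed_null: bool = False,
) -> QSurface:
    """Mean achieved Q over a (gamma, omega) grid; best cell by maximal mean Q.

    Ties are broken toward smaller (gamma, omega), lexicographically.
    """
    gamma_grid = tuple(float(g) for g in gamma_grid)
    omega_grid = tuple(float(w) for w in omega_grid)
    if not gamma_grid or not omega_grid:
        raise ValueError("parameter grids must be non-empty")
    if list(gamma_grid) != sorted(gamma_grid) or list(omega_grid) != sorted(omega_grid):
        raise ValueError("parameter grids must be monotone increasing")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    ss = _as_seedseq(seed)
    children = iter(ss.spawn(len(gamma_grid) * len(omega_grid) * repeats))
    mean_q = np.zeros((len(gamma_grid), len(omega_grid)))
    best = None
    best_q = -np.inf
    for a, gamma in enumerate(gamma_grid):
        for b, omega in enumerate(omega_grid):
            params = ResolutionParams(gamma=gamma, omega=omega)
            qs = [
                louvain_optimize(
                    network, params, seed=np.random.default_rng(next(children)),
                    signed_null=signed_null,
                ).q_value
                for _ in range(repeats)
            ]
            mean_q[a, b] = float(np.mean(qs))
            if mean_q[a, b] > best_q:  # strict: ties keep the earlier (smaller) cell
                best_q = mean_q[a, b]
                best = params
    logger.info("grid search best: gamma=%g omega=%g meanQ=%.6f", best.gamma, best.omega, best_q)
    return QSurface(gamma_grid=gamma_grid, omega_grid=omega_grid, mean_q=mean_q, best=best)
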