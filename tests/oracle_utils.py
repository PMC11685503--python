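"""Independent oracles used by the test suite.

Everything here is deliberately written without reference to the package's
optimized code paths: the modularity evaluator is a direct quadruple loop
over (i, j, s, r), and the maximizer is exhaustive enumeration of all set
partitions of the node-layer pairs.
"""

from __future__ import annotations

import numpy as np

from netlayers import ConnectivityMatrix, ParcelAtlas, assemble_multilayer


def rgs_partitions(n: int):
    """All set partitions of range(n), as restricted-growth label vectors."""

    def rec(prefix: list[int], mx: int):
        if len(prefix) == n:
            yield list(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))

    yield from rec([0], 0)


def brute_force_q(A_layers, labels_nl: np.ndarray, gamma: float, omega: float) -> float:
    """Direct evaluation of multilayer modularity with categorical coupling.

    Positive intra-layer weights only (the package's default null-model
    convention); quadruple loop, no vectorization.
    """
    L = len(A_layers)
    n = A_layers[0].shape[0]
    A = [np.maximum(np.asarray(a, dtype=float), 0.0) for a in A_layers]
    k = [a.sum(axis=1) for a in A]
    twom = [float(kk.sum()) for kk in k]
    total = 0.0
    for s in range(L):
        for r in range(L):
            for i in range(n):
                for j in range(n):
                    if labels_nl[i, s] != labels_nl[j, r]:
                        continue
                    if s == r:
                        total += A[s][i, j] - gamma * k[s][i] * k[s][j] / twom[s]
                    elif i == j:
                        total += omega
    return total / (sum(twom) + omega * n * L * (L - 1))


def enumerate_max_q(A_layers, gamma: float, omega: float):
    """(max Q, argmax labels) over every partition of the node-layer pairs.

    Vectorized over partitions for speed, but algebraically independent of
    the package's scoring code.
    """
    L = len(A_layers)
    n = A_layers[0].shape[0]
    A = [np.maximum(np.asarray(a, dtype=float), 0.0) for a in A_layers]
    k = [a.sum(axis=1) for a in A]
    twom = [float(kk.sum()) for kk in k]
    parts = np.asarray(list(rgs_partitions(n * L)))  # flat order p = s*n + i
    tot = np.zeros(len(parts))
    for s in range(L):
        ls = parts[:, s * n:(s + 1) * n]
        eq = ls[:, :, None] == ls[:, None, :]
        B = A[s] - gamma * np.outer(k[s], k[s]) / twom[s]
        tot += (eq * B).sum(axis=(1, 2))
    if L > 1 and omega != 0:
        for i in range(n):
            li = parts[:, i::n]
            eq = li[:, :, None] == li[:, None, :]
            tot += omega * (eq.sum(axis=(1, 2)) - L)
    tot /= sum(twom) + omega * n * L * (L - 1)
    b = int(np.argmax(tot))
    return float(tot[b]), parts[b].reshape(L, n).T


def two_block_instance(n: int, L: int, seed: int, lo: float = 0.0, hi: float = 0.25):
    """Random planted 2-block weighted layers (within ~U(0.7,1.2), between ~U(lo,hi))."""
    r = np.random.default_rng(seed)
    blocks = np.array([0] * (n // 2) + [1] * (n - n // 2))
    layers = []
    for _ in range(L):
        W = np.where(
            blocks[:, None] == blocks[None, :],
            r.uniform(0.7, 1.2, (n, n)),
            r.uniform(lo, hi, (n, n)),
        )
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        layers.append(W)
    return layers, blocks


def toy_atlas(n: int, sizes=None) -> ParcelAtlas:
    if sizes is None:
        sizes = (n // 2, n - n // 2)
    networks = []
    for idx, size in enumerate(sizes):
        networks += [f"S{idx + 1}"] * size
    return ParcelAtlas(
        parcel_ids=tuple(range(1, n + 1)),
        names=tuple(f"p{i}" for i in range(n)),
        hemispheres=tuple("L" if i < n // 2 else "R" for i in range(n)),
        networks=tuple(networks),
    )


def to_network(A_layers, atlas: ParcelAtlas | None = None, groups=None):
    n = A_layers[0].shape[0]
    atlas = atlas or toy_atlas(n)
    groups = groups or ["A"] * len(A_layers)
    mats = [
        ConnectivityMatrix(values=np.asarray(a, dtype=float), layer_id=i, group=g)
        for i, (a, g) in enumerate(zip(A_layers, groups))
    ]
    return assemble_multilayer(mats, atlas)
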