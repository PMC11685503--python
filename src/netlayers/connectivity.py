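"""Functional-connectivity construction and the multilayer container.

Each subject's parcel time series becomes a symmetric weighted connectivity
matrix: pairwise Pearson correlation of parcel columns, Fisher z-transformed,
with the diagonal forced to zero (self-connectivity is excluded).  A cohort's
matrices, aligned on one parcel atlas, form a :class:`MultilayerNetwork` in
which every subject is one layer.

Negative Fisher-z weights are retained in the stored matrices; how they enter
the modularity null model is decided once, in the community-detection module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas

__all__ = [
    "fisher_z",
    "build_connectivity",
    "assemble_multilayer",
    "ConnectivityMatrix",
    "MultilayerNetwork",
]

logger = logging.getLogger(__name__)

_CLAMP_EPS = 1e-7


def fisher_z(r):
    """Fisher z-transform ``atanh(r)`` of a correlation (scalar or array).

    Values with ``|r| >= 1 - 1e-7`` are clamped to ``+/-(1 - 1e-7)`` before
    the transform (a warning is logged), so perfectly correlated pairs yield
    a large finite weight instead of an infinity.  ``|r| > 1`` is a domain
    error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError("correlation outside [-1, 1]")
    limit = 1.0 - _CLAMP_EPS
    n_clamped = int(np.count_nonzero(np.abs(arr) > limit))
    if n_clamped:
        logger.warning("fisher_z: clamped %d correlation(s) with |r| >= 1 - 1e-7", n_clamped)
        arr = np.clip(arr, -limit, limit)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N matrix of Fisher-z connectivity weights for one layer."""

    values: np.ndarray
    layer_id: int
    group: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if not np.array_equal(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ValueError("connectivity diagonal must be zero")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path, atlas: ParcelAtlas) -> None:
        df = pd.DataFrame(self.values, index=list(atlas.parcel_ids), columns=list(atlas.parcel_ids))
        df.index.name = "parcel_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, layer_id: int, group: str) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        v = df.to_numpy(dtype=float)
        v = (v + v.T) / 2.0  # guard against round-tripped asymmetry at 1e-17
        np.fill_diagonal(v, 0.0)
        return cls(values=v, layer_id=layer_id, group=group)


def build_connectivity(
    ts: pd.DataFrame | np.ndarray, atlas: ParcelAtlas, layer_id: int = 0, group: str = ""
) -> ConnectivityMatrix:
    """Pearson-correlate parcel columns and Fisher z-transform the result.

    ``ts`` is a T x N table (T >= 3 timepoints).  Constant columns and NaNs
    are rejected with the offending parcel named.  The output is exactly
    symmetric with a zero diagonal.
    """
    X = np.asarray(ts, dtype=float)
    if X.ndim != 2:
        raise ValueError("time series must be 2-D (timepoints x parcels)")
    if X.shape[0] < 3:
        raise ValueError(f"need at least 3 timepoints, got {X.shape[0]}")
    if X.shape[1] != atlas.n_parcels:
        raise ValueError(
            f"time series has {X.shape[1]} columns but atlas has {atlas.n_parcels} parcels"
        )
    if np.any(~np.isfinite(X)):
        bad = np.where(~np.isfinite(X).all(axis=0))[0]
        names = [atlas.names[i] for i in bad[:5]]
        raise ValueError(f"non-finite values in time series of parcel(s) {names}")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        names = [atlas.names[i] for i in bad[:5]]
        raise ValueError(f"constant time series for parcel(s) {names}")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)  # self-correlation is discarded, do not warn on it
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(values=z, layer_id=layer_id, group=group)


@dataclass(frozen=True)
class MultilayerNetwork:
    """Node-aligned stack of L weighted connectivity layers.

    Layers share one :class:`ParcelAtlas`; layer order is meaningful only as
    an index (subjects carry no natural order).  Group labels per layer are
    kept for downstream group statistics.
    """

    layers: tuple[ConnectivityMatrix, ...]
    atlas: ParcelAtlas
    _stack: np.ndarray = field(init=False, repr=False, compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("multilayer network needs at least one layer")
        n = self.atlas.n_parcels
        for k, layer in enumerate(self.layers):
            if layer.n_nodes != n:
                raise ValueError(
                    f"layer {k} (id={layer.layer_id}) has {layer.n_nodes} nodes, atlas has {n}"
                )
        object.__setattr__(
            self, "_stack", np.stack([layer.values for layer in self.layers], axis=0)
        )

    @property
    def n_nodes(self) -> int:
        return self.atlas.n_parcels

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(layer.group for layer in self.layers)

    def weights(self) -> np.ndarray:
        """All layer weights as an (L, N, N) array (a copy is not made)."""
        return self._stack

    def subset(self, indices) -> "MultilayerNetwork":
        """A new network restricted to the given layer indices (in order)."""
        return MultilayerNetwork(
            layers=tuple(self.layers[int(k)] for k in indices), atlas=self.atlas
        )


def assemble_multilayer(
    matrices: list[ConnectivityMatrix], atlas: ParcelAtlas
) -> MultilayerNetwork:
    """Stack connectivity matrices (input order preserved) into one network."""
    return MultilayerNetwork(layers=tuple(matrices), atlas=atlas)
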