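"""Module allegiance and recruitment / integration coefficients.

From a multilayer community assignment, each layer yields a binary
co-occurrence matrix (1 where two nodes share a community label); averaging
co-occurrence over the layers of a cohort gives the module-allegiance matrix
``P``, whose entry ``P_ij`` is the fraction of layers in which nodes i and j
are co-assigned.

Against a predefined network grouping S, node-level coefficients summarize P:

    recruitment  R_iS = (1/n_s)     * sum_{j in S}     P_ij
    integration  I_iS = (1/(N-n_s)) * sum_{j not in S} P_ij

The recruitment sum runs over *all* j in S including j = i (P_ii = 1), which
floors R_iS at 1/n_s; some of the literature excludes the diagonal, so the
exclusion variant is available behind ``include_diagonal=False``.  The two
coefficients satisfy the identity

    n_s * R_iS + (N - n_s) * I_iS = sum_j P_ij        (diagonal included)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .community import CommunityAssignment

__all__ = [
    "CooccurrenceMatrix",
    "AllegianceMatrix",
    "cooccurrence",
    "allegiance_matrix",
    "recruitment",
    "integration",
    "coefficient_table",
    "summarize_by_network",
]


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Binary N x N co-classification matrix of one layer (diagonal = 1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AllegianceMatrix:
    """N x N matrix of co-classification fractions over ``n_layers`` layers."""

    values: np.ndarray
    n_layers: int
    cohort: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("allegiance matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path, atlas: ParcelAtlas) -> None:
        df = pd.DataFrame(self.values, index=list(atlas.parcel_ids), columns=list(atlas.parcel_ids))
        df.index.name = "parcel_id"
        df.to_csv(path)


def cooccurrence(labels_one_layer: np.ndarray) -> CooccurrenceMatrix:
    """Binary co-occurrence matrix of one layer's label vector."""
    lab = np.asarray(labels_one_layer)
    if lab.ndim != 1:
        raise ValueError("expected one label per node (1-D vector)")
    if lab.size == 0:
        raise ValueError("empty label vector")
    if not np.issubdtype(lab.dtype, np.integer):
        if np.any(pd.isna(lab)):
            raise ValueError("missing community label")
        lab = lab.astype(np.int64)
    eq = (lab[:, None] == lab[None, :]).astype(np.int8)
    return CooccurrenceMatrix(values=eq)


def cooccurrence_stack(assignment: CommunityAssignment | np.ndarray) -> np.ndarray:
    """(L, N, N) stack of per-layer co-occurrence matrices."""
    labels = assignment.labels if isinstance(assignment, CommunityAssignment) else np.asarray(assignment)
    return (labels.T[:, :, None] == labels.T[:, None, :]).astype(float)


def allegiance_matrix(
    assignment: CommunityAssignment | np.ndarray,
    layer_subset=None,
    cohort: str = "",
) -> AllegianceMatrix:
    """Elementwise mean of per-layer co-occurrence matrices over a layer subset.

    Every entry is an exact multiple of 1/L for the subset size L; the matrix
    is symmetric with unit diagonal.
    """
    labels = assignment.labels if isinstance(assignment, CommunityAssignment) else np.asarray(assignment)
    if labels.ndim != 2:
        raise ValueError("labels must be 2-D (nodes x layers)")
    if layer_subset is None:
        sub = np.arange(labels.shape[1])
    else:
        sub = np.asarray(list(layer_subset), dtype=np.intp)
    if sub.size == 0:
        raise ValueError("layer subset is empty")
    cols = labels[:, sub]
    P = np.zeros((labels.shape[0], labels.shape[0]))
    for s in range(cols.shape[1]):
        P += cols[:, s][:, None] == cols[:, s][None, :]
    P /= sub.size
    return AllegianceMatrix(values=P, n_layers=int(sub.size), cohort=cohort)


def _coeff_arrays(
    P: AllegianceMatrix | np.ndarray, atlas: ParcelAtlas, include_diagonal: bool
) -> tuple[np.ndarray, np.ndarray]:
    v = P.values if isinstance(P, AllegianceMatrix) else np.asarray(P, dtype=float)
    n = atlas.n_parcels
    if v.shape != (n, n):
        raise ValueError(f"allegiance matrix shape {v.shape} does not match atlas ({n})")
    R = np.empty(n)
    I = np.empty(n)
    for net in atlas.network_labels:
        members = atlas.network_members(net)
        n_s = members.size
        if n_s == n:
            raise ValueError(
                f"network {net!r} covers every parcel; integration is undefined"
            )
        inside = v[:, members].sum(axis=1)
        total = v.sum(axis=1)
        if include_diagonal:
            R[members] = inside[members] / n_s
        else:
            if n_s < 2:
                raise ValueError(f"network {net!r} too small to exclude the diagonal")
            R[members] = (inside[members] - np.diagonal(v)[members]) / (n_s - 1)
        I[members] = (total[members] - inside[members]) / (n - n_s)
    # exact values lie in [0, 1]; remove the floating-point cancellation dust
    np.clip(R, 0.0, 1.0, out=R)
    np.clip(I, 0.0, 1.0, out=I)
    return R, I


def recruitment(
    P: AllegianceMatrix | np.ndarray, atlas: ParcelAtlas, include_diagonal: bool = True
) -> np.ndarray:
    """Per-node recruitment R_iS: mean allegiance to the node's own network."""
    return _coeff_arrays(P, atlas, include_diagonal)[0]


def integration(P: AllegianceMatrix | np.ndarray, atlas: ParcelAtlas) -> np.ndarray:
    """Per-node integration I_iS: mean allegiance to nodes outside the network."""
    return _coeff_arrays(P, atlas, include_diagonal=True)[1]


def coefficient_table(
    P: AllegianceMatrix | np.ndarray,
    atlas: ParcelAtlas,
    include_diagonal: bool = True,
) -> pd.DataFrame:
    """Per-parcel coefficient table (parcel_id, network, hemisphere, R, I)."""
    R, I = _coeff_arrays(P, atlas, include_diagonal)
    return pd.DataFrame(
        {
            "parcel_id": list(atlas.parcel_ids),
            "network": list(atlas.networks),
            "hemisphere": list(atlas.hemispheres),
            "recruitment": R,
            "integration": I,
        }
    )


def summarize_by_network(table: pd.DataFrame, atlas: ParcelAtlas | None = None) -> pd.DataFrame:
    """Mean recruitment / integration per (network, hemisphere) cell.

    Cells with no parcels (a network confined to one hemisphere) are simply
    absent from the output.  The per-parcel values in ``table`` remain the
    record of the full distributions (e.g. for box plots).
    """
    required = {"network", "hemisphere", "recruitment", "integration"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"coefficient table is missing columns: {sorted(missing)}")
    out = (
        table.groupby(["network", "hemisphere"], sort=False)[["recruitment", "integration"]]
        .mean()
        .reset_index()
    )
    return out
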