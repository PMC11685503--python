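"""Parcel atlas: the node roster shared by every layer of a multilayer network.

A :class:`ParcelAtlas` plays the role of a cortical parcellation table: each
parcel (node) has a 1-based id, a name, a hemisphere tag and a predefined
functional-network label (e.g. the seven canonical resting-state systems).
The predefined networks provide the reference grouping *S* used by the
recruitment and integration coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ParcelAtlas", "SEVEN_NETWORK_LABELS"]

#: Canonical labels of the seven resting-state systems (visual, sensorimotor,
#: dorsal attention, salience/ventral attention, limbic, frontoparietal,
#: default mode), used when an atlas with exactly seven networks is built.
SEVEN_NETWORK_LABELS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")


@dataclass(frozen=True)
class ParcelAtlas:
    """Immutable roster of N parcels with hemisphere and network metadata.

    Parameters
    ----------
    parcel_ids
        1-based integer ids, ``1..N`` with no gaps or duplicates.
    names
        Human-readable parcel names.
    hemispheres
        ``"L"`` or ``"R"`` per parcel.
    networks
        Predefined network label per parcel.
    """

    parcel_ids: tuple[int, ...]
    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    networks: tuple[str, ...]
    _network_index: dict[str, np.ndarray] = field(
        init=False, repr=False, compare=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        n = len(self.parcel_ids)
        if not (len(self.names) == len(self.hemispheres) == len(self.networks) == n):
            raise ValueError("atlas columns must have identical length")
        if list(self.parcel_ids) != list(range(1, n + 1)):
            raise ValueError("parcel_ids must be 1..N with no gaps or duplicates")
        bad = sorted(set(self.hemispheres) - {"L", "R"})
        if bad:
            raise ValueError(f"hemisphere tags must be 'L' or 'R', got {bad}")
        idx: dict[str, list[int]] = {}
        for i, s in enumerate(self.networks):
            idx.setdefault(s, []).append(i)
        object.__setattr__(
            self, "_network_index", {s: np.asarray(v, dtype=np.intp) for s, v in idx.items()}
        )

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def network_labels(self) -> tuple[str, ...]:
        """Distinct network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.networks:
            seen.setdefault(s)
        return tuple(seen)

    def network_members(self, network: str) -> np.ndarray:
        """0-based node indices of the parcels in ``network``."""
        try:
            return self._network_index[network]
        except KeyError:
            raise KeyError(f"unknown network label {network!r}") from None

    def network_size(self, network: str) -> int:
        return int(self.network_members(network).size)

    def network_codes(self) -> np.ndarray:
        """Integer network code per parcel (codes follow first-appearance order)."""
        order = {s: k for k, s in enumerate(self.network_labels)}
        return np.asarray([order[s] for s in self.networks], dtype=np.intp)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": list(self.parcel_ids),
                "name": list(self.names),
                "hemisphere": list(self.hemispheres),
                "network": list(self.networks),
            }
        )

    def to_tsv(self, path) -> None:
        """Write the parcel table as TSV (columns parcel_id, name, hemisphere, network)."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParcelAtlas":
        required = {"parcel_id", "name", "hemisphere", "network"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parcel table is missing columns: {sorted(missing)}")
        df = df.sort_values("parcel_id")
        return cls(
            parcel_ids=tuple(int(x) for x in df["parcel_id"]),
            names=tuple(str(x) for x in df["name"]),
            hemispheres=tuple(str(x) for x in df["hemisphere"]),
            networks=tuple(str(x) for x in df["network"]),
        )

    @classmethod
    def from_tsv(cls, path) -> "ParcelAtlas":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
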