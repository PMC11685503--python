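"""Synthetic cohort generator with planted community structure.

Emulates the study design that motivates the pipeline: two cohorts of
subjects (layers), each subject contributing a parcel-averaged time-series
table whose correlation matrix is block-structured around predefined
functional networks.  One cohort may carry a planted perturbation — a single
network split into two subclusters with reduced correlation between them —
mimicking a within-network segregation such as the sensorimotor split
reported in clinical cohorts.  Because the downstream analysis consumes only
second-order structure (Pearson correlation -> Fisher z), the generator uses
the simplest model with the required structure: a compound-symmetry block
correlation template, sampled as i.i.d. multivariate-normal timepoints.

Every layer is drawn from its own deterministic RNG substream keyed by
``(seed, group, layer)``, so any layer can be regenerated independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas, SEVEN_NETWORK_LABELS

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "GenerationError",
    "make_atlas",
    "correlation_template",
    "simulate_timeseries",
    "simulate_cohorts",
    "save_cohorts",
]

#: Default network sizes: seven networks over 200 parcels, approximating the
#: parcel counts of the canonical seven-system 200-parcel cortical atlas.
DEFAULT_NETWORK_SIZES = (31, 35, 26, 23, 13, 30, 42)

#: Cohort labels. Group "B" carries the planted split when one is requested.
GROUP_A = "A"
GROUP_B = "B"


class GenerationError(RuntimeError):
    """Raised when a parameter combination cannot generate valid data."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-cohort synthetic study.

    Attributes
    ----------
    n_nodes
        Number of parcels N.
    network_sizes
        Sizes of the predefined networks; must sum to ``n_nodes`` and each
        must be at least 2.
    n_layers_per_group
        Subjects (layers) per cohort.
    within_block_corr, between_block_corr
        Compound-symmetry correlation inside / across planted communities,
        with ``0 <= between < within < 1``.
    split_network
        Network label to split in cohort B, or ``None`` for the null
        (no-difference) regime.
    split_fraction
        Fraction of the split network's parcels assigned to subcluster 2.
    split_between_corr
        Correlation for pairs straddling the planted split (cohort B only);
        must be below ``within_block_corr``.
    layer_noise_sd
        SD of the per-layer jitter added to each block's correlation level,
        emulating inter-subject variability in network coupling strength.
    n_timepoints
        Samples T per simulated time series.
    seed
        Top-level RNG seed; all substreams derive from it.
    """

    n_nodes: int = 200
    network_sizes: tuple[int, ...] = DEFAULT_NETWORK_SIZES
    n_layers_per_group: int = 32
    within_block_corr: float = 0.6
    between_block_corr: float = 0.15
    split_network: str | None = None
    split_fraction: float = 0.5
    split_between_corr: float = 0.1
    layer_noise_sd: float = 0.02
    n_timepoints: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.network_sizes)
        object.__setattr__(self, "network_sizes", sizes)
        if sum(sizes) != self.n_nodes:
            raise ValueError(
                f"network_sizes {sizes} sum to {sum(sizes)}, expected n_nodes={self.n_nodes}"
            )
        if any(s < 2 for s in sizes):
            raise ValueError("every network must contain at least 2 parcels")
        if not 0.0 <= self.between_block_corr < self.within_block_corr < 1.0:
            raise ValueError(
                "require 0 <= between_block_corr < within_block_corr < 1, got "
                f"between={self.between_block_corr}, within={self.within_block_corr}"
            )
        if not self.split_between_corr < self.within_block_corr:
            raise ValueError("split_between_corr must be below within_block_corr")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.n_layers_per_group < 1 or self.n_timepoints < 3:
            raise ValueError("need n_layers_per_group >= 1 and n_timepoints >= 3")
        if self.layer_noise_sd < 0:
            raise ValueError("layer_noise_sd must be non-negative")

    @property
    def network_labels(self) -> tuple[str, ...]:
        if len(self.network_sizes) == 7:
            return SEVEN_NETWORK_LABELS
        return tuple(f"S{k + 1}" for k in range(len(self.network_sizes)))


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated two-cohort study.

    ``true_labels`` maps each group label to the integer community label per
    node (0-based node order).  ``perturbed_pairs`` holds the unordered
    0-based node pairs that straddle the planted split; it is empty in the
    null regime, in which case the two groups share identical labels.
    """

    true_labels: dict[str, np.ndarray]
    perturbed_pairs: frozenset[tuple[int, int]]
    atlas: ParcelAtlas
    spec: CohortSpec = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "true_labels": {g: [int(x) for x in v] for g, v in self.true_labels.items()},
            "perturbed_pairs": sorted([i + 1, j + 1] for i, j in self.perturbed_pairs),
            "spec": {**asdict(self.spec), "network_sizes": list(self.spec.network_sizes)},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def make_atlas(spec: CohortSpec) -> ParcelAtlas:
    """Build the parcel atlas implied by a cohort spec.

    Network labels are assigned contiguously following ``network_sizes``; the
    first half of the roster is tagged left-hemisphere, the rest right.
    Deterministic for a given spec.
    """
    labels = spec.network_labels
    networks: list[str] = []
    for lab, size in zip(labels, spec.network_sizes):
        networks.extend([lab] * size)
    half = spec.n_nodes // 2
    hemis = ["L"] * half + ["R"] * (spec.n_nodes - half)
    names = [f"{net}_{h}_{i + 1}" for i, (net, h) in enumerate(zip(networks, hemis))]
    return ParcelAtlas(
        parcel_ids=tuple(range(1, spec.n_nodes + 1)),
        names=tuple(names),
        hemispheres=tuple(hemis),
        networks=tuple(networks),
    )


def _community_labels(spec: CohortSpec, atlas: ParcelAtlas, group_id: str) -> np.ndarray:
    """Planted community label per node for one cohort (0-based codes)."""
    codes = atlas.network_codes()
    if spec.split_network is not None and group_id == GROUP_B:
        if spec.split_network not in atlas.network_labels:
            raise ValueError(f"split_network {spec.split_network!r} not in atlas")
        members = atlas.network_members(spec.split_network)
        n2 = int(round(spec.split_fraction * members.size))
        if n2 == 0 or n2 == members.size:
            raise ValueError("split_fraction leaves one subcluster empty")
        # subcluster 2 = the trailing n2 members (deterministic)
        codes = codes.copy()
        codes[members[members.size - n2:]] = codes.max() + 1
    return codes


def correlation_template(
    spec: CohortSpec, atlas: ParcelAtlas, group_id: str
) -> np.ndarray:
    """Noise-free block correlation matrix for one cohort.

    Within planted communities the correlation is ``within_block_corr``,
    across them ``between_block_corr``, and across the planted split (group B
    only) ``split_between_corr``.
    """
    labels = _community_labels(spec, atlas, group_id)
    same = labels[:, None] == labels[None, :]
    R = np.where(same, spec.within_block_corr, spec.between_block_corr)
    if spec.split_network is not None and group_id == GROUP_B:
        members = atlas.network_members(spec.split_network)
        in_split = np.zeros(spec.n_nodes, dtype=bool)
        in_split[members] = True
        straddle = in_split[:, None] & in_split[None, :] & ~same
        R = np.where(straddle, spec.split_between_corr, R)
    np.fill_diagonal(R, 1.0)
    return R


def _layer_rng(spec: CohortSpec, group_id: str, layer_id: int) -> np.random.Generator:
    gidx = {GROUP_A: 0, GROUP_B: 1}.get(group_id, zlib.crc32(str(group_id).encode()))
    ss = np.random.SeedSequence([int(spec.seed), int(gidx), int(layer_id)])
    return np.random.default_rng(ss)


def _check_psd(R: np.ndarray, context: str) -> np.ndarray:
    """Validate positive semi-definiteness; return a Cholesky-ready matrix."""
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10:
        raise GenerationError(
            f"correlation template is not positive semi-definite ({context}); "
            f"smallest eigenvalue {w.min():.3g}"
        )
    # tiny ridge so Cholesky succeeds at exact semi-definiteness
    return R + np.eye(R.shape[0]) * max(0.0, 1e-12 - w.min())


def simulate_timeseries(
    atlas: ParcelAtlas, spec: CohortSpec, group_id: str, layer_id: int
) -> pd.DataFrame:
    """Simulate one subject's parcel-averaged time series (T rows x N parcels).

    Draws ``n_timepoints`` i.i.d. samples from a zero-mean multivariate
    normal whose correlation matrix is the cohort's block template plus this
    layer's block-level jitter.  Reproducible per ``(seed, group, layer)``.
    """
    R = correlation_template(spec, atlas, group_id)
    rng = _layer_rng(spec, group_id, layer_id)
    if spec.layer_noise_sd > 0:
        labels = _community_labels(spec, atlas, group_id)
        k = labels.max() + 1
        J = rng.normal(0.0, spec.layer_noise_sd, size=(k, k))
        J = (J + J.T) / 2.0
        R = np.clip(R + J[labels][:, labels], -0.99, 0.99)
        np.fill_diagonal(R, 1.0)
    R = _check_psd(
        R,
        f"group={group_id}, layer={layer_id}, within={spec.within_block_corr}, "
        f"between={spec.between_block_corr}, split_between={spec.split_between_corr}, "
        f"layer_noise_sd={spec.layer_noise_sd}",
    )
    chol = np.linalg.cholesky(R)
    X = rng.standard_normal((spec.n_timepoints, spec.n_nodes)) @ chol.T
    return pd.DataFrame(X, columns=list(atlas.parcel_ids))


def simulate_cohorts(
    spec: CohortSpec,
) -> tuple[list[pd.DataFrame], list[pd.DataFrame], GroundTruth]:
    """Simulate both cohorts and return their layers plus the ground truth.

    Cohort B carries the planted split iff ``spec.split_network`` is set; in
    the null regime the cohorts are exchangeable by construction.
    """
    atlas = make_atlas(spec)
    layers_a = [
        simulate_timeseries(atlas, spec, GROUP_A, k) for k in range(spec.n_layers_per_group)
    ]
    layers_b = [
        simulate_timeseries(atlas, spec, GROUP_B, k) for k in range(spec.n_layers_per_group)
    ]
    labels_a = _community_labels(spec, atlas, GROUP_A)
    labels_b = _community_labels(spec, atlas, GROUP_B)
    pairs: set[tuple[int, int]] = set()
    if spec.split_network is not None:
        members = atlas.network_members(spec.split_network)
        for i in members:
            for j in members:
                if i < j and labels_b[i] != labels_b[j]:
                    pairs.add((int(i), int(j)))
    truth = GroundTruth(
        true_labels={GROUP_A: labels_a, GROUP_B: labels_b},
        perturbed_pairs=frozenset(pairs),
        atlas=atlas,
        spec=spec,
    )
    return layers_a, layers_b, truth


def save_cohorts(outdir, spec: CohortSpec) -> pd.DataFrame:
    """Simulate and write a full synthetic study to ``outdir``.

    Writes the parcel table (TSV), one time-series CSV per layer named
    ``<group>_<layer:03d>.csv``, a layer manifest (TSV: file, layer_id,
    group) and the ground truth (JSON).  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layers_a, layers_b, truth = simulate_cohorts(spec)
    truth.atlas.to_tsv(outdir / "parcels.tsv")
    rows = []
    for group, layers in ((GROUP_A, layers_a), (GROUP_B, layers_b)):
        for k, ts in enumerate(layers):
            fname = f"{group}_{k:03d}.csv"
            ts.to_csv(outdir / fname, index=False)
            rows.append({"file": fname, "layer_id": k, "group": group})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "layers.tsv", sep="\t", index=False)
    truth.to_json(outdir / "ground_truth.json")
    return manifest
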