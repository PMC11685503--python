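"""Permutation tests for group differences, with Benjamini-Hochberg FDR.

The group comparison shuffles cohort labels over layers (subjects) while the
community assignment itself stays fixed: the statistic is recomputed from the
per-layer co-occurrence matrices under each shuffle, so the null distribution
reflects exchangeability of subjects, not re-detection of communities.

Two families of elementwise tests are provided: allegiance-matrix entries
(upper triangle only; the matrix is symmetric) and per-parcel recruitment /
integration coefficients (corrected separately per coefficient type).
P-values follow the add-one convention p = (1 + #{|null| >= |obs|}) /
(1 + n_permutations) and are therefore never zero; when the number of
distinct group splits does not exceed the permutation budget the test
enumerates all splits and the p-values are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas import ParcelAtlas
from .allegiance import _coeff_arrays, cooccurrence_stack
from .community import CommunityAssignment

__all__ = [
    "StatsConfig",
    "PermutationResult",
    "bh_fdr",
    "permute_allegiance",
    "permute_coefficients",
]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class StatsConfig:
    """Permutation-test configuration."""

    n_permutations: int = 20_000
    q_threshold: float = 0.05
    sidedness: str = "two-sided"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.sidedness not in ("two-sided", "greater", "less"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass(frozen=True)
class PermutationResult:
    """Elementwise permutation-test output for one family of tests.

    ``observed`` is the group-A-minus-group-B statistic per element,
    ``elements`` a DataFrame describing each element (row order matches the
    arrays), ``exact`` whether the full-enumeration path was taken, and
    ``n_permutations`` the number of (distinct or sampled) shuffles used.
    """

    observed: np.ndarray
    p_values: np.ndarray
    fdr_mask: np.ndarray
    n_permutations: int
    seed: int
    exact: bool
    sidedness: str
    elements: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = self.elements.copy()
        df["observed_diff"] = self.observed
        df["p_value"] = self.p_values
        df["fdr_rejected"] = self.fdr_mask
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


# --------------------------------------------------------------------------
# permutation engine


def _group_indices(groups) -> tuple[str, str, np.ndarray, np.ndarray]:
    groups = [str(g) for g in groups]
    distinct: list[str] = []
    for g in groups:
        if g not in distinct:
            distinct.append(g)
    if len(distinct) != 2:
        raise ValueError(f"need exactly two groups, got {distinct}")
    ga, gb = distinct
    ia = np.asarray([k for k, g in enumerate(groups) if g == ga], dtype=np.intp)
    ib = np.asarray([k for k, g in enumerate(groups) if g == gb], dtype=np.intp)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("each group needs at least 2 layers for a permutation test")
    return ga, gb, ia, ib


def _null_count(null: np.ndarray, obs: np.ndarray, sidedness: str) -> np.ndarray:
    """Per element, count of null draws at least as extreme as the observed."""
    if sidedness == "two-sided":
        return (np.abs(null) >= np.abs(obs)[:, None] - _TIE_EPS).sum(axis=1)
    if sidedness == "greater":
        return (null >= obs[:, None] - _TIE_EPS).sum(axis=1)
    return (null <= obs[:, None] + _TIE_EPS).sum(axis=1)


def _permutation_pvalues(
    F: np.ndarray, ia: np.ndarray, ib: np.ndarray, config: StatsConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Permutation p-values for the group mean difference of feature rows.

    ``F`` is (n_features, L).  Returns (observed, p, exact, n_used).
    """
    L = F.shape[1]
    na, nb = ia.size, ib.size
    obs = F[:, ia].mean(axis=1) - F[:, ib].mean(axis=1)
    total = F.sum(axis=1)

    def diffs_for(subsets: np.ndarray) -> np.ndarray:
        # subsets: (n_perm, na) index arrays for group A
        Z = np.zeros((L, subsets.shape[0]))
        rows = subsets.T
        Z[rows, np.arange(subsets.shape[0])[None, :]] = 1.0
        sa = F @ Z
        return sa / na - (total[:, None] - sa) / nb

    n_distinct = comb(L, na)
    exact = n_distinct <= config.n_permutations
    if exact:
        subsets = np.asarray(list(combinations(range(L), na)), dtype=np.intp)
        counts = np.zeros(F.shape[0])
        for lo in range(0, subsets.shape[0], 512):
            null = diffs_for(subsets[lo:lo + 512])
            counts += _null_count(null, obs, config.sidedness)
        p = counts / n_distinct
        n_used = n_distinct
    else:
        counts = np.zeros(F.shape[0])
        done = 0
        while done < config.n_permutations:
            m = min(512, config.n_permutations - done)
            subsets = np.empty((m, na), dtype=np.intp)
            for t in range(m):
                subsets[t] = rng.permutation(L)[:na]
            null = diffs_for(subsets)
            counts += _null_count(null, obs, config.sidedness)
            done += m
        p = (1.0 + counts) / (1.0 + config.n_permutations)
        n_used = config.n_permutations
    return obs, p, exact, n_used


def _labels_array(assignment) -> np.ndarray:
    if isinstance(assignment, CommunityAssignment):
        return assignment.labels
    lab = np.asarray(assignment)
    if lab.ndim != 2:
        raise ValueError("labels must be 2-D (nodes x layers)")
    return lab


def permute_allegiance(
    assignment,
    groups,
    config: StatsConfig = StatsConfig(),
    atlas: ParcelAtlas | None = None,
) -> PermutationResult:
    """Elementwise group comparison of module-allegiance matrices.

    ``assignment`` is the N x L label matrix (layers of both cohorts in
    order) and ``groups`` the cohort label per layer.  The statistic per
    upper-triangle element is the difference of group allegiance fractions
    (first-appearing group minus the other); the FDR family is the
    N (N - 1) / 2 upper-triangle elements.
    """
    labels = _labels_array(assignment)
    n, L = labels.shape
    if len(groups) != L:
        raise ValueError(f"{len(groups)} group labels for {L} layers")
    ga, gb, ia, ib = _group_indices(groups)
    iu, ju = np.triu_indices(n, k=1)
    stack = cooccurrence_stack(labels)  # (L, N, N)
    F = stack[:, iu, ju].T  # (n_elements, L)
    rng = np.random.default_rng(config.seed)
    obs, p, exact, n_used = _permutation_pvalues(F, ia, ib, config, rng)
    mask = bh_fdr(p, config.q_threshold)
    ids = np.asarray(atlas.parcel_ids) if atlas is not None else np.arange(1, n + 1)
    elements = pd.DataFrame({"parcel_i": ids[iu], "parcel_j": ids[ju]})
    if atlas is not None:
        nets = np.asarray(atlas.networks)
        elements["network_i"] = nets[iu]
        elements["network_j"] = nets[ju]
    return PermutationResult(
        observed=obs, p_values=p, fdr_mask=mask, n_permutations=n_used,
        seed=config.seed, exact=exact, sidedness=config.sidedness, elements=elements,
    )


def permute_coefficients(
    assignment,
    groups,
    atlas: ParcelAtlas,
    config: StatsConfig = StatsConfig(),
    include_diagonal: bool = True,
) -> dict[str, PermutationResult]:
    """Group comparison of per-parcel recruitment and integration coefficients.

    Both coefficient types are tested over the same shuffles; BH-FDR is
    applied separately per type (each family = all parcels).
    """
    labels = _labels_array(assignment)
    n, L = labels.shape
    if n != atlas.n_parcels:
        raise ValueError("assignment and atlas disagree on parcel count")
    if len(groups) != L:
        raise ValueError(f"{len(groups)} group labels for {L} layers")
    ga, gb, ia, ib = _group_indices(groups)
    stack = cooccurrence_stack(labels)
    FR = np.empty((n, L))
    FI = np.empty((n, L))
    for s in range(L):
        R, I = _coeff_arrays(stack[s], atlas, include_diagonal)
        FR[:, s] = R
        FI[:, s] = I
    elements = pd.DataFrame(
        {
            "parcel_id": list(atlas.parcel_ids),
            "network": list(atlas.networks),
            "hemisphere": list(atlas.hemispheres),
        }
    )
    out: dict[str, PermutationResult] = {}
    for name, F in (("recruitment", FR), ("integration", FI)):
        rng = np.random.default_rng(config.seed)  # same shuffles for both families
        obs, p, exact, n_used = _permutation_pvalues(F, ia, ib, config, rng)
        out[name] = PermutationResult(
            observed=obs, p_values=p, fdr_mask=bh_fdr(p, config.q_threshold),
            n_permutations=n_used, seed=config.seed, exact=exact,
            sidedness=config.sidedness, elements=elements.copy(),
        )
    return out
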