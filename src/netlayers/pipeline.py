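"""End-to-end pipeline: generate/load -> connectivity -> communities ->
allegiance -> coefficients -> group statistics.

Every stage reads and writes flat CSV/TSV/JSON artifacts in the run's output
directory, so each stage is independently runnable and inspectable.  A run
is fully reproducible from its manifest (config echo + seed); inputs are
never mutated.  On a stage failure a ``FAILED`` marker naming the stage is
left next to whatever partial outputs exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import ParcelAtlas
from .synth import CohortSpec, save_cohorts
from .connectivity import ConnectivityMatrix, build_connectivity, assemble_multilayer
from .community import (
    CommunityAssignment,
    ResolutionParams,
    consensus_partition,
    grid_search,
)
from .allegiance import allegiance_matrix, coefficient_table, summarize_by_network
from .stats import StatsConfig, permute_allegiance, permute_coefficients

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)

_MODES = ("synthetic", "timeseries", "matrices")

_COHORT_SPEC_KEYS = (
    "n_nodes", "network_sizes", "n_layers_per_group", "within_block_corr",
    "between_block_corr", "split_network", "split_fraction", "split_between_corr",
    "layer_noise_sd", "n_timepoints",
)


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of one pipeline run (mirrors the YAML config file)."""

    mode: str = "synthetic"
    out_dir: str = "run"
    seed: int = 0
    # input paths (timeseries / matrices modes)
    parcel_table: str | None = None
    layer_manifest: str | None = None
    data_dir: str | None = None
    # synthetic mode
    cohort: CohortSpec | None = None
    # community detection
    gamma: float = 1.2
    omega: float = 0.1
    use_grid: bool = False
    grid_gammas: tuple[float, ...] | None = None
    grid_omegas: tuple[float, ...] | None = None
    grid_repeats: int = 5
    n_iter: int = 50
    per_cohort_networks: bool = True
    signed_null: bool = False
    include_diagonal: bool = True
    # statistics
    n_permutations: int = 20_000
    q_threshold: float = 0.05
    sidedness: str = "two-sided"

    def resolution(self) -> ResolutionParams:
        return ResolutionParams(gamma=self.gamma, omega=self.omega)

    def stats(self) -> StatsConfig:
        return StatsConfig(
            n_permutations=self.n_permutations,
            q_threshold=self.q_threshold,
            sidedness=self.sidedness,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.cohort is not None:
            d["cohort"] = {**asdict(self.cohort), "network_sizes": list(self.cohort.network_sizes)}
        for key in ("grid_gammas", "grid_omegas"):
            if d.get(key) is not None:
                d[key] = [float(x) for x in d[key]]
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        spec_kwargs = {k: raw.pop(k) for k in list(raw) if k in _COHORT_SPEC_KEYS}
        cohort = raw.pop("cohort", None)
        if isinstance(cohort, dict):
            spec_kwargs = {**cohort, **spec_kwargs}
        seed = int(raw.get("seed", 0))
        mode = raw.get("mode", "synthetic")
        if mode == "synthetic":
            spec_kwargs.setdefault("seed", seed)
            if "network_sizes" in spec_kwargs:
                spec_kwargs["network_sizes"] = tuple(int(x) for x in spec_kwargs["network_sizes"])
            raw["cohort"] = CohortSpec(**spec_kwargs)
        for key in ("grid_gammas", "grid_omegas"):
            if raw.get(key) is not None:
                raw[key] = tuple(float(x) for x in raw[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a flat key: value mapping")
        return cls.from_dict(raw)


def validate_inputs(config: RunConfig) -> list[str]:
    """Return a report of *all* configuration violations (empty if valid)."""
    issues: list[str] = []
    if config.mode not in _MODES:
        issues.append(f"mode must be one of {_MODES}, got {config.mode!r}")
    if config.mode == "synthetic":
        if config.cohort is None:
            issues.append("synthetic mode requires cohort parameters")
        elif config.cohort.n_layers_per_group < 2:
            issues.append(
                "n_layers_per_group must be >= 2: the permutation test needs at "
                "least 2 layers per group"
            )
    else:
        for name in ("parcel_table", "layer_manifest"):
            path = getattr(config, name)
            if path is None:
                issues.append(f"{config.mode} mode requires {name}")
            elif not Path(path).exists():
                issues.append(f"{name} not found: {path}")
        if config.parcel_table and Path(config.parcel_table).exists():
            try:
                ParcelAtlas.from_tsv(config.parcel_table)
            except Exception as exc:  # report, do not raise
                issues.append(f"invalid parcel table {config.parcel_table}: {exc}")
        if config.layer_manifest and Path(config.layer_manifest).exists():
            try:
                manifest = pd.read_csv(config.layer_manifest, sep="\t")
                base = Path(config.data_dir or Path(config.layer_manifest).parent)
                missing = {"file", "layer_id", "group"} - set(manifest.columns)
                if missing:
                    issues.append(f"layer manifest missing columns: {sorted(missing)}")
                else:
                    for f in manifest["file"]:
                        if not (base / f).exists():
                            issues.append(f"manifest references missing file: {base / f}")
                    counts = manifest["group"].value_counts()
                    if len(counts) != 2:
                        issues.append(
                            f"need exactly two groups in the manifest, got {list(counts.index)}"
                        )
                    for g, c in counts.items():
                        if c < 2:
                            issues.append(
                                f"group {g!r} has {c} layer(s); the permutation test "
                                "requires at least 2 per group"
                            )
            except Exception as exc:
                issues.append(f"invalid layer manifest {config.layer_manifest}: {exc}")
    try:
        config.resolution()
    except ValueError as exc:
        issues.append(str(exc))
    try:
        config.stats()
    except ValueError as exc:
        issues.append(str(exc))
    if config.n_iter < 1:
        issues.append("n_iter must be >= 1")
    if config.use_grid and config.grid_repeats < 1:
        issues.append("grid_repeats must be >= 1")
    return issues


# --------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    save_cohorts(outdir, config.cohort)


def _load_manifest(config: RunConfig, outdir: Path) -> tuple[ParcelAtlas, pd.DataFrame, Path]:
    if config.mode == "synthetic":
        atlas = ParcelAtlas.from_tsv(outdir / "parcels.tsv")
        manifest = pd.read_csv(outdir / "layers.tsv", sep="\t")
        base = outdir
    else:
        atlas = ParcelAtlas.from_tsv(config.parcel_table)
        manifest = pd.read_csv(config.layer_manifest, sep="\t")
        base = Path(config.data_dir or Path(config.layer_manifest).parent)
    manifest = manifest.sort_values(["group", "layer_id"]).reset_index(drop=True)
    return atlas, manifest, base


def stage_connectivity(config: RunConfig, outdir: Path) -> None:
    """Turn per-layer time series into Fisher-z connectivity matrices."""
    atlas, manifest, base = _load_manifest(config, outdir)
    conn_dir = outdir / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    rows = []
    for rec in manifest.itertuples():
        ts = pd.read_csv(base / rec.file)
        cm = build_connectivity(ts, atlas, layer_id=int(rec.layer_id), group=str(rec.group))
        fname = f"conn_{rec.group}_{int(rec.layer_id):03d}.csv"
        cm.to_csv(conn_dir / fname, atlas)
        rows.append({"file": f"connectivity/{fname}", "layer_id": rec.layer_id, "group": rec.group})
    pd.DataFrame(rows).to_csv(outdir / "connectivity.tsv", sep="\t", index=False)


def _load_networks(config: RunConfig, outdir: Path):
    """Assemble the multilayer network(s) from on-disk matrices."""
    if config.mode == "matrices":
        atlas, manifest, base = _load_manifest(config, outdir)
    else:
        atlas = ParcelAtlas.from_tsv(
            outdir / "parcels.tsv" if config.mode == "synthetic" else config.parcel_table
        )
        manifest = pd.read_csv(outdir / "connectivity.tsv", sep="\t")
        base = outdir
    matrices = [
        ConnectivityMatrix.from_csv(base / rec.file, int(rec.layer_id), str(rec.group))
        for rec in manifest.itertuples()
    ]
    groups_in_order: list[str] = []
    for g in manifest["group"].astype(str):
        if g not in groups_in_order:
            groups_in_order.append(g)
    if config.per_cohort_networks:
        nets = {
            g: assemble_multilayer([m for m in matrices if m.group == g], atlas)
            for g in groups_in_order
        }
    else:
        nets = {"all": assemble_multilayer(matrices, atlas)}
    return atlas, nets, groups_in_order


def stage_communities(config: RunConfig, outdir: Path) -> None:
    """Optional (gamma, omega) grid search, then consensus partitions."""
    atlas, nets, _ = _load_networks(config, outdir)
    meta: dict[str, dict] = {}
    for idx, (name, net) in enumerate(sorted(nets.items())):
        params = config.resolution()
        if config.use_grid:
            from .community import DEFAULT_GAMMA_GRID, DEFAULT_OMEGA_GRID

            surface = grid_search(
                net,
                gamma_grid=config.grid_gammas or DEFAULT_GAMMA_GRID,
                omega_grid=config.grid_omegas or DEFAULT_OMEGA_GRID,
                repeats=config.grid_repeats,
                seed=np.random.SeedSequence([config.seed, 7, idx]),
                signed_null=config.signed_null,
            )
            surface.to_csv(outdir / f"q_surface_{name}.csv")
            params = surface.best
        assignment = consensus_partition(
            net,
            params,
            n_iter=config.n_iter,
            seed=np.random.SeedSequence([config.seed, 11, idx]),
            signed_null=config.signed_null,
        )
        layer_ids = [layer.layer_id for layer in net.layers]
        assignment.to_tsv(outdir / f"assignment_{name}.tsv", atlas=atlas, layer_ids=layer_ids)
        meta[name] = {
            "gamma": params.gamma,
            "omega": params.omega,
            "q": assignment.q_value,
            "n_communities": assignment.n_communities,
            **assignment.meta,
        }
    (outdir / "communities.json").write_text(json.dumps(meta, indent=1))


def _load_assignments(config: RunConfig, outdir: Path):
    atlas = ParcelAtlas.from_tsv(
        outdir / "parcels.tsv" if config.mode == "synthetic" else config.parcel_table
    )
    _, manifest, _ = (
        _load_manifest(config, outdir)
        if config.mode != "timeseries"
        else (None, pd.read_csv(outdir / "connectivity.tsv", sep="\t"), None)
    )
    groups_in_order: list[str] = []
    for g in manifest["group"].astype(str):
        if g not in groups_in_order:
            groups_in_order.append(g)
    if config.per_cohort_networks:
        per_cohort = {}
        for g in groups_in_order:
            a = CommunityAssignment.from_tsv(outdir / f"assignment_{g}.tsv")
            per_cohort[g] = a.labels
    else:
        a = CommunityAssignment.from_tsv(outdir / "assignment_all.tsv")
        glabels = manifest["group"].astype(str).tolist()
        per_cohort = {
            g: a.labels[:, [k for k, gg in enumerate(glabels) if gg == g]]
            for g in groups_in_order
        }
    return atlas, per_cohort, groups_in_order


def stage_allegiance(config: RunConfig, outdir: Path) -> None:
    """Per-cohort allegiance matrices, coefficient tables and network summaries."""
    atlas, per_cohort, _ = _load_assignments(config, outdir)
    for g, labels in per_cohort.items():
        P = allegiance_matrix(labels, cohort=g)
        P.to_csv(outdir / f"allegiance_{g}.csv", atlas)
        table = coefficient_table(P, atlas, include_diagonal=config.include_diagonal)
        table.to_csv(outdir / f"coefficients_{g}.tsv", sep="\t", index=False)
        summarize_by_network(table).to_csv(
            outdir / f"network_summary_{g}.tsv", sep="\t", index=False
        )


def stage_stats(config: RunConfig, outdir: Path) -> None:
    """Permutation group comparison of allegiance and coefficients, with FDR."""
    atlas, per_cohort, groups_in_order = _load_assignments(config, outdir)
    ga, gb = groups_in_order[0], groups_in_order[1]
    labels = np.concatenate([per_cohort[ga], per_cohort[gb]], axis=1)
    groups = [ga] * per_cohort[ga].shape[1] + [gb] * per_cohort[gb].shape[1]
    cfg = config.stats()
    res_alleg = permute_allegiance(labels, groups, cfg, atlas=atlas)
    res_alleg.to_csv(outdir / "stats_allegiance.csv")
    res_coeff = permute_coefficients(
        labels, groups, atlas, cfg, include_diagonal=config.include_diagonal
    )
    for name, res in res_coeff.items():
        res.to_csv(outdir / f"stats_{name}.csv")
    # significant parcels: any FDR-rejected allegiance element or coefficient
    nets = np.asarray(atlas.networks)
    alleg_df = res_alleg.to_frame()
    sig_elements = alleg_df[alleg_df["fdr_rejected"]]
    sig_parcels = sorted(
        set(sig_elements["parcel_i"]).union(sig_elements["parcel_j"]).union(
            *(
                set(res.to_frame().loc[res.fdr_mask, "parcel_id"])
                for res in res_coeff.values()
            )
        )
    )
    pd.DataFrame({"parcel_id": sig_parcels}).merge(
        atlas.to_frame(), on="parcel_id"
    ).to_csv(outdir / "significant_parcels.tsv", sep="\t", index=False)
    summary = {
        "config": {"n_permutations": cfg.n_permutations, "q_threshold": cfg.q_threshold,
                   "sidedness": cfg.sidedness, "seed": cfg.seed},
        "exact_enumeration": bool(res_alleg.exact),
        "n_rejected_allegiance": int(res_alleg.fdr_mask.sum()),
        "n_rejected_recruitment": int(res_coeff["recruitment"].fdr_mask.sum()),
        "n_rejected_integration": int(res_coeff["integration"].fdr_mask.sum()),
        "rejections_per_network": {
            net: int(((nets[np.asarray(alleg_df["parcel_i"]) - 1] == net)
                      | (nets[np.asarray(alleg_df["parcel_j"]) - 1] == net))[
                         np.asarray(alleg_df["fdr_rejected"])].sum())
            for net in atlas.network_labels
        },
    }
    (outdir / "stats_summary.json").write_text(json.dumps(summary, indent=1))


_STAGES = (
    ("simulate", stage_simulate),
    ("connectivity", stage_connectivity),
    ("communities", stage_communities),
    ("allegiance", stage_allegiance),
    ("stats", stage_stats),
)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order; returns the output directory.

    Stage failures abort the run, leaving partial outputs plus a ``FAILED``
    marker naming the stage and the offending input.
    """
    issues = validate_inputs(config)
    if issues:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(issues))
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = set()
    if config.mode != "synthetic":
        skip.add("simulate")
    if config.mode == "matrices":
        skip.add("connectivity")
    timings: dict[str, float] = {}
    for name, fn in _STAGES:
        if name in skip:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            fn(config, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage: {name}\nerror: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.2fs", name, timings[name])
    (outdir / "FAILED").unlink(missing_ok=True)
    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "netlayers_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "timings_s": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
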