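"""Orchestration, configuration and tabular I/O for end-to-end runs.

All tabular artifacts are plain CSV: spectra in long format (plant_id,
week, event, wavelength_nm, value, channel) or wide format (one column per
wavelength), design and trait tables one row per plant.  A run is driven
by a :class:`RunConfig` (loadable from YAML or JSON) with stage toggles;
``run_all`` executes the enabled stages and writes a manifest recording
seeds, parameters and output digests so every artifact is reproducible
from the manifest alone.

One global seed is split into per-stage streams by hashing stable stage
names, so toggling one stage never perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import groundtruth
from .nclassify import GridSpec, cross_week_evaluate
from .reflectance import SpectraSet, accession_mean, scans_to_spectraset, weekly_average
from .synth import RawScan, SyntheticConfig, generate_experiment
from .traitpredict import RReliefFParams, SplitSpec, hyperparameter_grid, run_trait_model, transfer_experiment

__all__ = [
    "RunConfig",
    "stage_seed",
    "write_spectra_long",
    "read_spectra_long",
    "write_spectra_wide",
    "read_spectra_wide",
    "load_tables",
    "run_all",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# Tabular I/O


def write_spectra_long(scans: list[RawScan], path) -> None:
    """Long-format raw-scan CSV with plant/white/dark channels."""
    frames = []
    for scan in scans:
        base = {"plant_id": scan.plant_id, "week": scan.week, "event": scan.event,
                "wavelength_nm": scan.wavelengths}
        for channel, vec in (("plant", scan.plant_dn), ("white", scan.white_dn),
                             ("dark", scan.dark_dn)):
            frames.append(pd.DataFrame({**base, "channel": channel, "value": vec}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_long(path) -> list[RawScan]:
    df = pd.read_csv(path)
    required = {"plant_id", "week", "event", "wavelength_nm", "channel", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spectra CSV missing columns: {sorted(missing)}")
    if df["value"].isna().any():
        bad = df.index[df["value"].isna()][0]
        raise ValueError(f"non-numeric or missing value at spectra row {bad}")
    dup = df.duplicated(["plant_id", "week", "event", "wavelength_nm", "channel"])
    if dup.any():
        raise ValueError(f"duplicate spectra key at row {df.index[dup][0]}")
    scans = []
    for (pid, week, event), g in df.groupby(["plant_id", "week", "event"], sort=True):
        wide = g.pivot(index="wavelength_nm", columns="channel", values="value").sort_index()
        scans.append(RawScan(
            wavelengths=wide.index.to_numpy(dtype=float),
            plant_dn=wide["plant"].to_numpy(),
            white_dn=wide["white"].to_numpy(),
            dark_dn=wide["dark"].to_numpy(),
            plant_id=pid, week=int(week), event=str(event),
        ))
    return scans


def write_spectra_wide(spectra: SpectraSet, path) -> None:
    """Wide-format reflectance CSV: metadata columns then one column per
    wavelength (header = wavelength in nm)."""
    vals = pd.DataFrame(spectra.values,
                        columns=[f"{wl:g}" for wl in spectra.wavelengths])
    pd.concat([spectra.meta.reset_index(drop=True), vals], axis=1).to_csv(
        path, index=False)


def read_spectra_wide(path, level: str = "plant") -> SpectraSet:
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c.replace(".", "", 1).replace("-", "", 1).isdigit()]
    meta_cols = [c for c in df.columns if c not in wl_cols]
    wl = np.array([float(c) for c in wl_cols])
    order = np.argsort(wl)
    values = df[wl_cols].to_numpy(dtype=float)[:, order]
    return SpectraSet(wl[order], values, df[meta_cols], level=level)


def load_tables(design_path, spectra_path, traits_path):
    """Load and cross-validate the three input tables.

    Spectra may be long-format raw scans (calibrated downstream) or
    wide-format reflectance.  Every spectra plant_id must appear in the
    design; violations are reported with the offending identifier.
    """
    design = pd.read_csv(design_path)
    for col in ("plant_id", "accession", "subpopulation", "treatment", "replicate"):
        if col not in design.columns:
            raise ValueError(f"design table missing column {col!r}")
    if design["plant_id"].duplicated().any():
        dup = design.loc[design["plant_id"].duplicated(), "plant_id"].iloc[0]
        raise ValueError(f"duplicate plant_id in design: {dup!r}")
    traits = pd.read_csv(traits_path)
    if "plant_id" not in traits.columns:
        raise ValueError("trait table missing column 'plant_id'")

    head = pd.read_csv(spectra_path, nrows=1)
    if "channel" in head.columns:
        scans = read_spectra_long(spectra_path)
        spectra = scans_to_spectraset(scans)
    else:
        spectra = read_spectra_wide(spectra_path)
    unknown = set(spectra.meta["plant_id"]) - set(design["plant_id"])
    if unknown:
        raise ValueError(f"spectra reference unknown plant_id {sorted(unknown)[0]!r}")
    unknown_t = set(traits["plant_id"]) - set(design["plant_id"])
    if unknown_t:
        raise ValueError(f"traits reference unknown plant_id {sorted(unknown_t)[0]!r}")
    return design, spectra, traits


# ---------------------------------------------------------------------------
# Run configuration and orchestration


@dataclass
class RunConfig:
    """End-to-end run: either input paths or a synthetic block, stage
    toggles and per-stage parameters."""

    output_dir: str = "ricehsi_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    design_path: str | None = None
    spectra_path: str | None = None
    traits_path: str | None = None
    run_groundtruth: bool = True
    run_classification: bool = True
    run_prediction: bool = True
    run_transfer: bool = False
    run_hypergrid: bool = False
    prediction_traits: tuple[str, ...] = ("N", "C:N")
    n_wavelengths: int = 400
    transfer_n_wavelengths: int = 300
    hypergrid_iterations: int = 10
    grid_spec: GridSpec = field(default_factory=GridSpec)
    relieff: RReliefFParams = field(default_factory=RReliefFParams)

    def __post_init__(self) -> None:
        paths = (self.design_path, self.spectra_path, self.traits_path)
        has_paths = all(p is not None for p in paths)
        if has_paths == (self.synthetic is not None):
            raise ValueError("exactly one of {input paths, synthetic block} must be set")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "grid_spec" in raw:
            raw["grid_spec"] = GridSpec(**raw["grid_spec"])
        if "relieff" in raw:
            raw["relieff"] = RReliefFParams(**raw["relieff"])
        for tup in ("prediction_traits",):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    t0 = time.perf_counter()
    if config.synthetic is not None:
        scans, traits, design = generate_experiment(
            config.synthetic, seed=stage_seed(config.seed, "synthetic"))
        spectra = scans_to_spectraset(scans)
        manifest["stages"]["synthetic"] = dataclasses.asdict(config.synthetic)
    else:
        design, spectra, traits = load_tables(
            config.design_path, config.spectra_path, config.traits_path)

    weekly = weekly_average(spectra)
    traits = groundtruth.add_derived_traits(traits)
    traits = groundtruth.transform_traits(traits)
    design.to_csv(out / "design.csv", index=False)
    traits.to_csv(out / "traits.csv", index=False)
    write_spectra_wide(weekly, out / "weekly_reflectance.csv")
    manifest["stages"]["calibration"] = {"rows": int(weekly.values.shape[0]),
                                         "wavelengths": int(len(weekly.wavelengths))}

    if config.run_groundtruth:
        corr, mask = groundtruth.correlation_analysis(traits)
        corr.to_csv(out / "trait_correlations.csv")
        acc_tr = groundtruth.accession_mean_traits(traits)
        pca = groundtruth.trait_pca(acc_tr)
        clust = groundtruth.cluster_accessions(acc_tr)
        (out / "trait_dendrogram.nwk").write_text(clust.newick + "\n")
        manifest["stages"]["groundtruth"] = {
            "pc1_variance": float(pca.explained_variance_ratio[0]),
            "n_significant_pairs": int(mask.to_numpy().sum() - len(mask)) // 2,
        }

    if config.run_classification:
        spec = dataclasses.replace(config.grid_spec,
                                   seed=stage_seed(config.seed, "classification"))
        matrix, runs, _ = cross_week_evaluate(weekly, design, spec)
        matrix.to_csv(out / "svm_accuracy_matrix.csv")
        manifest["stages"]["classification"] = {
            "accuracy_min": float(matrix.to_numpy().min()),
            "accuracy_max": float(matrix.to_numpy().max()),
        }

    trait_week_spectra = None
    if config.run_prediction or config.run_transfer or config.run_hypergrid:
        week = (config.synthetic.trait_week if config.synthetic is not None
                else sorted(weekly.meta["week"].unique())[0])
        trait_week_spectra = weekly.select_week(week)
        full_traits = traits.merge(design[["plant_id", "subpopulation"]]
                                   .drop_duplicates(), on="plant_id", how="left",
                                   suffixes=("", "_design"))

    if config.run_prediction:
        results = {}
        for trait in config.prediction_traits:
            run = run_trait_model(
                trait_week_spectra, full_traits, trait,
                n_wavelengths=config.n_wavelengths,
                split=SplitSpec(seed=stage_seed(config.seed, f"predict:{trait}")),
                relieff=config.relieff)
            entry = {"fittable": run.fittable, "n_components": run.n_components}
            if run.fittable:
                entry.update({
                    "calibration_r2": run.calibration_metrics.r2,
                    "calibration_rmsep": run.calibration_metrics.rmsep,
                    "validation_r2": run.validation_metrics.r2,
                    "validation_rmsep": run.validation_metrics.rmsep,
                    "validation_pct_rmsep": run.validation_metrics.pct_rmsep,
                })
                if run.predictions is not None:
                    safe = trait.replace(":", "")
                    run.predictions.to_csv(out / f"predictions_{safe}.csv", index=False)
            results[trait] = entry
        manifest["stages"]["prediction"] = results

    if config.run_transfer:
        results = {}
        for trait in config.prediction_traits:
            for var, levels in (("treatment", sorted(design["treatment"].unique())),
                                ("subpopulation", sorted(design["subpopulation"].unique()))):
                for lv in levels:
                    run = transfer_experiment(
                        trait_week_spectra, full_traits, trait, var, lv,
                        n_wavelengths=config.transfer_n_wavelengths,
                        relieff=config.relieff,
                        seed=stage_seed(config.seed, f"transfer:{trait}:{var}:{lv}"))
                    results[f"{trait}|{var}|{lv}"] = {
                        "fittable": run.fittable,
                        "calibration_r2": (run.calibration_metrics.r2
                                           if run.fittable else None),
                        "validation_r2": (run.validation_metrics.r2
                                          if run.fittable else None),
                    }
        manifest["stages"]["transfer"] = results

    if config.run_hypergrid:
        grid = hyperparameter_grid(
            trait_week_spectra, full_traits, "N",
            iterations=config.hypergrid_iterations,
            seed=stage_seed(config.seed, "hypergrid"), relieff=config.relieff)
        grid.table.to_csv(out / "hyperparameter_grid.csv", index=False)
        manifest["stages"]["hypergrid"] = {"cells": int(len(grid.table))}

    manifest["wall_time_s"] = round(time.perf_counter() - t0, 2)
    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.nwk")):
        manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
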