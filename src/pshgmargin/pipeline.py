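"""End-to-end orchestration: phantom -> polarimetry -> texture -> PCA ->
clustering -> margin, behind one configuration object.

Every stage is deterministic given the configured seed; per-stage seeds are
derived from it by fixed offsets so a stage rerun in isolation reproduces
the full-run result.  ``run_pipeline`` writes all artifacts (parameter maps,
feature CSV, PCA JSON, per-subset cluster grids and pseudo-color maps,
margin report) into an output directory together with a manifest listing
every file with its stage of origin.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, decomposition, margin, phantom, polarimetry, texture

log = logging.getLogger("pshgmargin")

# fixed per-stage seed offsets (kept below 2**31 after expansion)
_SEED_OFFSETS = {"phantom": 0, "snr": 101, "kmeans": 211}


@dataclass
class PipelineConfig:
    """Stage parameters of a full phantom-to-margin run."""

    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    min_snr: float = 1.0
    n_levels: int = texture.DEFAULT_N_LEVELS
    min_density: float = 0.1
    subsets: tuple[str, ...] = decomposition.SUBSET_NAMES
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _SEED_OFFSETS[stage]) % (2**31 - 1)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "phantom" in raw and isinstance(raw["phantom"], dict):
            ph = raw["phantom"]
            for key in ("tumor", "normal"):
                if key in ph and isinstance(ph[key], dict):
                    ph[key] = phantom.RegionParams(**ph[key])
            ph["exclusions"] = tuple(tuple(e) for e in ph.get("exclusions") or ())
            raw["phantom"] = phantom.PhantomConfig(**ph)
        if "subsets" in raw:
            raw["subsets"] = tuple(raw["subsets"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory results of a full run (see ``run_pipeline`` for file output)."""

    truth: phantom.PhantomTruth
    maps: polarimetry.PolarimetricMaps
    grid: texture.SubImageGrid
    feature_table: pd.DataFrame
    pca: decomposition.PCAModel
    std_model: decomposition.StandardizationModel
    rows: pd.Index
    cluster_results: dict[str, clustering.ClusterResult]
    subset_comparison: pd.DataFrame
    margin_report: margin.MarginReport
    ground_truth: margin.GroundTruth


def analyze_phantom(config: PipelineConfig) -> PipelineResult:
    """Run all stages in memory on a freshly generated phantom."""
    pcfg = dataclasses.replace(config.phantom, seed=config.stage_seed("phantom"))
    truth = phantom.generate_phantom(pcfg)
    stack = phantom.synthesize_stack(truth, pcfg)
    log.info("phantom: %s px, %d fiber pixels", truth.region_label.shape,
             int(truth.fiber_mask.sum()))

    calibration = None
    if pcfg.noise != "none":
        cal_cfg = dataclasses.replace(
            pcfg, n_frames=max(pcfg.n_frames, 8), seed=config.stage_seed("snr")
        )
        calibration = polarimetry.fit_snr_calibration(
            phantom.synthesize_stack(truth, cal_cfg)
        )
        log.info("SNR calibration: a=%.3f b=%.3f", calibration.a, calibration.b)
    maps = polarimetry.compute_parameter_maps(
        stack, calibration=calibration, min_snr=config.min_snr
    )

    grid = texture.tile_grid(*truth.region_label.shape, pcfg.tile_size)
    exclusion = truth.region_label == phantom.EXCLUDED
    table = texture.build_feature_table(
        maps, grid,
        exclusion_mask=exclusion if exclusion.any() else None,
        min_density=config.min_density, n_levels=config.n_levels,
    )
    log.info("feature table: %d retained tiles of %d", len(table), grid.n_tiles)

    z, std_model, rows = decomposition.standardize(table)
    pca = decomposition.run_pca(z)
    retained = decomposition.kaiser_retain(pca)
    log.info("PCA: %d Kaiser-retained components, top eigenvalues %s",
             len(retained), np.round(pca.eigenvalues[:4], 2).tolist())

    seed_km = config.stage_seed("kmeans")
    results = {
        name: clustering.cluster_subset(table, pca, name, seed=seed_km, rows=rows)
        for name in config.subsets
    }
    comparison = clustering.compare_subsets(
        table, pca, subsets=config.subsets, seed=seed_km, rows=rows
    )

    truth_tiles = margin.GroundTruth(
        tile_labels=truth.tile_region_labels(pcfg.tile_size),
        boundary_column=truth.boundary_column / pcfg.tile_size,
    )
    report = margin.build_margin_report(results, truth_tiles)
    log.info("margin: best subset %s (IIOD=%.3f)", report.best_subset,
             report.table.loc[report.table["best"], "iiod"].iloc[0])
    return PipelineResult(
        truth=truth, maps=maps, grid=grid, feature_table=table, pca=pca,
        std_model=std_model, rows=rows, cluster_results=results,
        subset_comparison=comparison, margin_report=report,
        ground_truth=truth_tiles,
    )


def _write_map_png(path, grid: np.ndarray, title: str, boundary_col: float | None = None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, cmap="spring", vmin=1.0, vmax=2.0)
    if boundary_col is not None:
        ax.axvline(boundary_col - 0.5, color="black", lw=1.5)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="C")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Full run with file outputs; returns the artifact manifest."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}

    def record(stage: str, path: Path) -> Path:
        manifest.setdefault(stage, []).append(str(path.relative_to(outdir)))
        return path

    res = analyze_phantom(config)
    config.to_yaml(record("config", outdir / "config.yaml"))

    for name, arr in res.maps.as_dict().items():
        tifffile.imwrite(
            record("polarimetry", outdir / f"map_{name}.tif"), arr.astype(np.float32)
        )
    tifffile.imwrite(
        record("polarimetry", outdir / "valid_mask.tif"),
        res.maps.valid.astype(np.uint8),
    )

    res.feature_table.to_csv(record("texture", outdir / "features.csv"), index=False)
    with open(record("texture", outdir / "grid.json"), "w") as fh:
        json.dump(dataclasses.asdict(res.grid), fh, indent=1)

    scores = pd.DataFrame(
        res.pca.scores[:, :4],
        columns=[f"PC{k + 1}" for k in range(min(4, res.pca.scores.shape[1]))],
        index=res.rows,
    )
    res.feature_table.join(scores).to_csv(
        record("pca", outdir / "features_with_scores.csv"), index=False
    )
    with open(record("pca", outdir / "pca.json"), "w") as fh:
        json.dump(res.pca.to_json_dict(), fh, indent=1)

    gshape = (res.ground_truth.n_rows, res.ground_truth.n_cols)
    for name, cres in res.cluster_results.items():
        tag = name.replace("+", "_")
        raw = cres.to_grid(*gshape)
        filt = cres.to_grid(*gshape, filtered=True)
        np.savetxt(record("clustering", outdir / f"cmap_{tag}.csv"), raw, delimiter=",")
        np.savetxt(
            record("clustering", outdir / f"cmap_{tag}_median.csv"), filt, delimiter=","
        )
        _write_map_png(
            record("clustering", outdir / f"cmap_{tag}.png"), filt, name,
            boundary_col=res.ground_truth.boundary_column,
        )
    res.subset_comparison.to_csv(
        record("clustering", outdir / "subset_comparison.csv"), index=False
    )

    res.margin_report.table.to_csv(
        record("margin", outdir / "margin_report.csv"), index=False
    )
    with open(record("margin", outdir / "margin_report.json"), "w") as fh:
        json.dump(
            {
                "best_subset": res.margin_report.best_subset,
                "true_boundary_column": res.ground_truth.boundary_column,
                "subsets": res.margin_report.table.drop(columns="best").to_dict(
                    orient="records"
                ),
            },
            fh,
            indent=1,
        )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
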