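"""End-to-end run: register → map cells → reconstruct volumes → quantify axons → connectivity.

A run is driven by a single YAML config whose defaults mirror the analysis
conventions used throughout the package (100 μm voxel grid; 10 smoothing
iterations at λ = 0.5; connectivity thresholds include > 1 %, edge > 5 %,
cap 20 %). Every parameter — explicit or defaulted — is serialized into the
run's ``provenance.json`` so each output number is traceable to a logged
parameter set. The pipeline itself draws no random numbers: identical config
and inputs reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, axon_quant, connectivity, volume3d
from .atlas import load_atlas
from .cell_mapping import class_counts, map_cells, summarize_distribution
from .errors import AtlasTraceError, ConfigurationError
from .registration import fit_all, load_control_points, save_transforms

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run (YAML-serializable)."""

    atlas_volume: str
    atlas_regions: str
    out_dir: str
    control_points: str | None = None
    cells: str | None = None
    outlines: str | None = None
    axon_manifest: str | None = None
    cortex_acronym: str = "Iso"
    overlap_targets: list[str] = field(default_factory=list)
    voxel_size_um: float = volume3d.DEFAULT_VOXEL_SIZE_UM
    smoothing_iterations: int = volume3d.DEFAULT_SMOOTH_ITERATIONS
    smoothing_lambda: float = volume3d.DEFAULT_SMOOTH_LAMBDA
    include_pct: float = connectivity.DEFAULT_INCLUDE_PCT
    edge_pct: float = connectivity.DEFAULT_EDGE_PCT
    cap_pct: float = connectivity.DEFAULT_CAP_PCT
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.include_pct <= self.edge_pct <= self.cap_pct:
            raise ConfigurationError(
                f"thresholds must satisfy 0 ≤ include ≤ edge ≤ cap, got "
                f"{self.include_pct}, {self.edge_pct}, {self.cap_pct}"
            )
        if self.voxel_size_um <= 0:
            raise ConfigurationError("voxel_size_um must be positive")
        if self.smoothing_iterations < 0 or not 0 < self.smoothing_lambda <= 1:
            raise ConfigurationError("smoothing: iterations ≥ 0 and 0 < lambda ≤ 1 required")
        for name in ("atlas_volume", "atlas_regions"):
            if not Path(getattr(self, name)).exists():
                raise ConfigurationError(f"{name} does not exist: {getattr(self, name)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages in order; returns the provenance record.

    Stages with missing inputs are skipped (logged); any stage error is
    re-raised annotated with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("atlastrace")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    provenance: dict = {
        "package": "atlastrace",
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    stage = "load-atlas"
    try:
        atlas = load_atlas(config.atlas_volume, config.atlas_regions)
        provenance["stages"][stage] = {
            "shape": list(atlas.labels.shape),
            "voxel_size_um": atlas.voxel_size_um,
            "n_regions": len(atlas.regions),
        }

        transforms = None
        if config.control_points:
            stage = "register"
            frames = load_control_points(config.control_points)
            transforms = fit_all(frames)
            save_transforms(transforms, out / "transforms.json")
            provenance["stages"][stage] = {
                "n_sections": len(transforms),
                "max_rms_um": max(t.fit_rms_um for t in transforms.values()),
                "output": "transforms.json",
            }

        if config.cells and transforms is not None:
            stage = "map-cells"
            cells_in = pd.read_csv(config.cells, dtype={"section_id": str})
            cortex_id = atlas.regions.by_acronym(config.cortex_acronym).region_id
            records = map_cells(transforms, cells_in, atlas, cortex_id)
            records.to_csv(out / "cell_records.csv", index=False)
            counts = class_counts(records)
            counts.to_csv(out / "class_counts.csv", index=False)
            summary = summarize_distribution(records)
            summary.to_csv(out / "axis_summary.csv", index=False)
            provenance["stages"][stage] = {
                "n_cells": len(records),
                "n_out_of_extent": int((~records["in_extent"]).sum()),
                "outputs": ["cell_records.csv", "class_counts.csv", "axis_summary.csv"],
            }

        solids: dict[str, volume3d.VoxelSolid] = {}
        if config.outlines:
            stage = "reconstruct-volume"
            clouds = volume3d.load_outlines(config.outlines)
            results = []
            for (animal, label), cloud in sorted(clouds.items()):
                _, solid = volume3d.reconstruct(
                    cloud.points,
                    voxel_size_um=config.voxel_size_um,
                    smooth_iterations=config.smoothing_iterations,
                    smooth_lambda=config.smoothing_lambda,
                    label=label,
                )
                solids[label] = solid
                for acronym in config.overlap_targets:
                    rid = atlas.regions.by_acronym(acronym).region_id
                    target = atlas.region_voxels(rid)
                    if target:
                        results.append(volume3d.percent_overlap(
                            solid, target,
                            target_voxel_size_um=atlas.voxel_size_um,
                            target_label=acronym,
                        ))
            labels = sorted(solids)
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    results.append(volume3d.percent_overlap(solids[a], solids[b]))
            volume3d.overlap_table(results).to_csv(out / "overlaps.csv", index=False)
            volumes = pd.DataFrame(
                [{"label": lb, "n_voxels": len(s), "volume_mm3": s.volume_mm3}
                 for lb, s in sorted(solids.items())]
            )
            volumes.to_csv(out / "injection_volumes.csv", index=False)
            provenance["stages"][stage] = {
                "n_volumes": len(solids),
                "smoothing": {"iterations": config.smoothing_iterations,
                              "lambda": config.smoothing_lambda},
                "voxel_size_um": config.voxel_size_um,
                "outputs": ["injection_volumes.csv", "overlaps.csv"],
            }

        fractions = None
        if config.axon_manifest:
            stage = "quantify-axons"
            fractions = axon_quant.quantify_from_manifest(config.axon_manifest)
            manifest_df = pd.read_csv(config.axon_manifest, dtype={"animal_id": str})
            if "group" in manifest_df.columns:
                groups = manifest_df[["animal_id", "group"]].drop_duplicates()
                fractions = fractions.merge(groups, on="animal_id", how="left")
            fractions.to_csv(out / "innervation_fractions.csv", index=False)
            provenance["stages"][stage] = {
                "n_animals": fractions["animal_id"].nunique(),
                "n_regions": fractions["region_id"].nunique(),
                "output": "innervation_fractions.csv",
            }

        if fractions is not None and "group" in fractions.columns:
            stage = "connectivity"
            stats = connectivity.group_means(fractions)
            maps = connectivity.build_map(
                stats, config.include_pct, config.edge_pct, config.cap_pct
            )
            connectivity.maps_to_json(maps, out / "connectivity.json")
            connectivity.maps_to_table(maps).to_csv(out / "connectivity.csv", index=False)
            provenance["stages"][stage] = {
                "thresholds": {"include_pct": config.include_pct,
                               "edge_pct": config.edge_pct, "cap_pct": config.cap_pct},
                "n_groups": len(maps),
                "outputs": ["connectivity.json", "connectivity.csv"],
            }
    except AtlasTraceError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return provenance
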