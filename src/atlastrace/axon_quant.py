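"""Region-masked axon-collateral quantification.

Downstream of an external segmentation tool that exports one binary mask per
(section, brainstem region), the per-region signal is the masked intensity sum

    Q_i = Σ_pixels R_i · S_i

where R_i is the binary region mask and S_i the fluorescence signal channel of
the same section. Region size is the count of active mask pixels. Raw sums are
accumulated across sections per (animal, region) and normalized within each
animal to innervation fractions

    fraction_i = Q_i / Σ_j Q_j    (sum over all regions of that animal),

which compare relative signal distributions across animals regardless of total
labeling strength.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DimensionError, MaskValidationError, NormalizationError

logger = logging.getLogger(__name__)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise MaskValidationError(
            f"mask is not binary: values outside {{0, 1}} present (e.g. {vals[~np.isin(vals, (0, 1))][:3]})"
        )
    return mask


def region_signal(mask: np.ndarray, image: np.ndarray) -> float:
    """Masked intensity sum Q = Σ mask·image; exact (int64) for integer inputs."""
    mask = _check_mask(mask)
    image = np.asarray(image)
    if mask.shape != image.shape:
        raise DimensionError(f"mask shape {mask.shape} != image shape {image.shape}")
    if np.issubdtype(image.dtype, np.floating) and (
        not np.isfinite(image).all() or (image < 0).any()
    ):
        raise ValueError("signal image must be finite and non-negative")
    if np.issubdtype(image.dtype, np.integer):
        if (image < 0).any():
            raise ValueError("signal image must be non-negative")
        return int(np.sum(mask.astype(np.int64) * image.astype(np.int64)))
    return float(np.sum(mask * image))


def region_area(mask: np.ndarray) -> int:
    """Region size: the number of active (1) pixels in the binary mask."""
    return int(np.sum(_check_mask(mask), dtype=np.int64))


def aggregate_and_normalize(per_section: pd.DataFrame) -> pd.DataFrame:
    """Per-animal region table with in-animal normalized innervation fractions.

    Input: long table with columns animal_id, region_id, raw_sum, area_px (one
    row per section × region). Raw sums and areas are first summed across
    sections per (animal, region); fractions divide each region's sum by the
    animal's total. An animal with zero total raises
    :class:`NormalizationError` (fractions undefined).
    """
    required = {"animal_id", "region_id", "raw_sum", "area_px"}
    missing = required - set(per_section.columns)
    if missing:
        raise ValueError(f"per-section table missing columns: {sorted(missing)}")
    agg = (
        per_section.groupby(["animal_id", "region_id"], sort=True)[["raw_sum", "area_px"]]
        .sum()
        .reset_index()
    )
    totals = agg.groupby("animal_id")["raw_sum"].transform("sum")
    zero = agg.loc[totals == 0, "animal_id"].unique()
    if len(zero):
        raise NormalizationError(f"zero total signal for animal(s): {sorted(map(str, zero))}")
    agg["norm_fraction"] = agg["raw_sum"] / totals
    return agg


def quantify_sections(entries) -> pd.DataFrame:
    """Per-section quantification from in-memory (animal, section, region, mask, image) tuples."""
    rows = []
    for animal_id, section_id, region_id, mask, image in entries:
        rows.append(
            {
                "animal_id": animal_id,
                "section_id": section_id,
                "region_id": region_id,
                "raw_sum": region_signal(mask, image),
                "area_px": region_area(mask),
            }
        )
    return pd.DataFrame(rows)


def quantify_from_manifest(manifest_path: str | Path, base_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the full quantification from a manifest CSV linking TIFF files.

    Manifest columns: animal_id, section_id, region_id, channel, mask_path,
    signal_path (paths relative to the manifest's directory unless absolute).
    Masks of distinct regions are allowed to overlap at boundaries; any overlap
    within a section is counted and logged as a warning, never an error.

    Returns the per-animal normalized table from :func:`aggregate_and_normalize`.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    mf = pd.read_csv(manifest_path, dtype={"animal_id": str, "section_id": str})

    rows = []
    for (animal, section), grp in mf.groupby(["animal_id", "section_id"], sort=True):
        occupancy = None
        for _, r in grp.iterrows():
            mask = tifffile.imread(base / r["mask_path"])
            image = tifffile.imread(base / r["signal_path"])
            rows.append(
                {
                    "animal_id": animal,
                    "section_id": section,
                    "region_id": int(r["region_id"]),
                    "raw_sum": region_signal(mask, image),
                    "area_px": region_area(mask),
                }
            )
            occupancy = mask.astype(np.int64) if occupancy is None else occupancy + mask
        if occupancy is not None:
            n_overlap = int(np.sum(occupancy > 1))
            if n_overlap:
                logger.warning(
                    "animal %s section %s: %d pixels shared by multiple region masks",
                    animal, section, n_overlap,
                )
    per_section = pd.DataFrame(rows)
    return aggregate_and_normalize(per_section)
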