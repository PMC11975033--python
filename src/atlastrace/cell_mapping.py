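"""Map annotated cells into atlas space and classify them into mediolateral bins.

Each cortical hemisphere is divided into 5 equal-width bins spanning from the
midline to the lateral edge of cortex in the same anterior-posterior (AP)
slice. Bin 0 (most medial) is cingulate cortex, bins 1-2 medial cortex and
bins 3-4 lateral cortex. Cells are first carried from section pixel space into
atlas μm via the fitted per-section affine transforms, then assigned a
hemisphere, a bin and (where the atlas has a label) a region id.

Conventions (documented tie rules):

* a cell exactly on the midline is assigned to the right hemisphere;
* bins are half-open ``[k·w/5, (k+1)·w/5)`` in distance from the midline, with
  a point at exactly the full width clamped into bin 4;
* points lateral of the cortical edge are flagged out-of-extent and excluded
  from bin counts (the flag is preserved in the output table).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import Atlas, region_mask
from .errors import EmptyExtentError, MissingTransformError
from .registration import PlanarAffine3D, apply_affine

logger = logging.getLogger(__name__)

N_BINS = 5
ML_CLASS_OF_BIN = {0: "cingulate", 1: "medial", 2: "medial", 3: "lateral", 4: "lateral"}
ML_CLASSES = ("cingulate", "medial", "lateral")

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class HemisphereExtent:
    """Mediolateral span of cortex for one AP slice and hemisphere.

    ``ml_min_um`` is the midline; ``ml_max_um`` is the midline plus the lateral
    width of cortex, so the same half-open 5-bin rule applies symmetrically to
    both hemispheres via the distance ``|ml − midline|``.
    """

    slice_id: str
    hemisphere: str
    ml_min_um: float
    ml_max_um: float

    def __post_init__(self):
        if not self.ml_max_um > self.ml_min_um:
            raise EmptyExtentError(
                f"extent for {self.slice_id}/{self.hemisphere}: "
                f"ml_max ({self.ml_max_um}) must exceed ml_min ({self.ml_min_um})"
            )

    @property
    def width_um(self) -> float:
        return self.ml_max_um - self.ml_min_um


def assign_hemisphere(ml_um: float, midline_ml_um: float) -> str:
    """Right iff ml ≥ midline (midline ties go right, by convention)."""
    if not np.isfinite(ml_um):
        raise ValueError("non-finite mediolateral coordinate")
    return RIGHT if ml_um >= midline_ml_um else LEFT


def cortical_extent(atlas: Atlas, ap_slice_index: int, hemisphere: str, cortex_region_id: int) -> HemisphereExtent:
    """Extent of cortex in one AP slice and hemisphere: midline to the far edge
    of the lateral-most cortex voxel (half-open voxel convention).
    """
    if hemisphere not in (LEFT, RIGHT):
        raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    if not 0 <= ap_slice_index < atlas.labels.shape[0]:
        raise EmptyExtentError(f"AP slice {ap_slice_index} outside the atlas grid")
    mask = region_mask(atlas, cortex_region_id)[ap_slice_index]  # (DV, ML)
    ml_idx = np.nonzero(mask.any(axis=0))[0]
    vs = atlas.voxel_size_um
    mid = atlas.midline_ml_um
    centers = (ml_idx + 0.5) * vs
    side = ml_idx[centers >= mid] if hemisphere == RIGHT else ml_idx[centers < mid]
    if side.size == 0:
        raise EmptyExtentError(
            f"no cortex voxels in AP slice {ap_slice_index}, hemisphere {hemisphere}"
        )
    if hemisphere == RIGHT:
        width = (side.max() + 1) * vs - mid
    else:
        width = mid - side.min() * vs
    return HemisphereExtent(str(ap_slice_index), hemisphere, mid, mid + width)


def ml_bin(ml_um: float, extent: HemisphereExtent) -> int | None:
    """Bin index 0-4 for a point, or None if lateral of the cortical edge.

    bin = floor(5·|ml − midline| / width), half-open, with the exact far edge
    clamped into bin 4.
    """
    d = abs(ml_um - extent.ml_min_um)
    w = extent.width_um
    if d > w:
        return None
    if d == w:
        return N_BINS - 1
    return int(np.floor(N_BINS * d / w))


def map_cells(
    transforms: dict[str, PlanarAffine3D],
    cells: pd.DataFrame,
    atlas: Atlas,
    cortex_region_id: int,
    extent_overrides: dict[str, dict[str, HemisphereExtent]] | None = None,
) -> pd.DataFrame:
    """Transform annotated cells to atlas space and bin them mediolaterally.

    Parameters
    ----------
    transforms
        Fitted per-section transforms, keyed by section_id.
    cells
        Annotation table with columns section_id, animal_id, group, channel,
        u_px, v_px. May be empty.
    atlas
        Reference atlas; provides the midline, the cortical extents and the
        region label lookup.
    cortex_region_id
        Region id (with descendants) defining "cortex" for extent computation.
    extent_overrides
        Optional ``{section_id: {hemisphere: HemisphereExtent}}`` for sections
        without atlas support (e.g. early-postnatal brains lacking a reference
        atlas): the same 5-bin rule applied to a user-supplied manual extent.

    Returns
    -------
    DataFrame with one row per input cell: atlas coordinates, hemisphere,
    ml_bin, ml_class, region_id (nullable Int64) and the in_extent flag.
    """
    required = {"section_id", "u_px", "v_px"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")

    out_cols = [
        "animal_id", "group", "channel", "section_id",
        "x_um", "y_um", "z_um", "hemisphere", "ml_bin", "ml_class",
        "region_id", "in_extent",
    ]
    if len(cells) == 0:
        return pd.DataFrame(columns=out_cols)

    absent = sorted(set(cells["section_id"].astype(str)) - set(transforms))
    if absent:
        raise MissingTransformError(f"no fitted transform for sections: {absent}")

    rows = []
    extent_cache: dict[tuple[int, str], HemisphereExtent | None] = {}
    n_out = 0
    for _, cell in cells.iterrows():
        sid = str(cell["section_id"])
        xyz = apply_affine(transforms[sid], [[cell["u_px"], cell["v_px"]]])[0]
        hemi = assign_hemisphere(xyz[2], atlas.midline_ml_um)

        extent: HemisphereExtent | None
        if extent_overrides and sid in extent_overrides:
            extent = extent_overrides[sid][hemi]
        else:
            ap = int(np.floor(xyz[0] / atlas.voxel_size_um))
            key = (ap, hemi)
            if key not in extent_cache:
                try:
                    extent_cache[key] = cortical_extent(atlas, ap, hemi, cortex_region_id)
                except EmptyExtentError:
                    extent_cache[key] = None
            extent = extent_cache[key]

        bin_idx = ml_bin(xyz[2], extent) if extent is not None else None
        in_extent = bin_idx is not None
        if not in_extent:
            n_out += 1
        rows.append({
            "animal_id": cell.get("animal_id", ""),
            "group": cell.get("group", ""),
            "channel": cell.get("channel", ""),
            "section_id": sid,
            "x_um": xyz[0], "y_um": xyz[1], "z_um": xyz[2],
            "hemisphere": hemi,
            "ml_bin": bin_idx if in_extent else pd.NA,
            "ml_class": ML_CLASS_OF_BIN[bin_idx] if in_extent else pd.NA,
            "region_id": atlas.label_at(xyz),
            "in_extent": in_extent,
        })
    if n_out:
        logger.warning("%d cells fell outside the cortical extent and were flagged", n_out)
    df = pd.DataFrame(rows, columns=out_cols)
    df["ml_bin"] = df["ml_bin"].astype("Int64")
    df["region_id"] = df["region_id"].astype("Int64")
    return df


def class_counts(cells: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Counts of in-extent cells per (group, ml_class), all classes present."""
    kept = cells[cells["in_extent"]] if "in_extent" in cells else cells
    tab = (
        kept.groupby([by, "ml_class"], observed=False).size().rename("n_cells").reset_index()
        if len(kept)
        else pd.DataFrame(columns=[by, "ml_class", "n_cells"])
    )
    return tab


def summarize_distribution(cells: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Per-group mean ± SEM of the rostro-caudal (X) and dorso-ventral (Z)
    coordinates; SEM uses the n−1 sample standard deviation. Groups of one
    cell report a null SEM with a warning.
    """
    if len(cells) == 0:
        raise ValueError("no cells to summarize")
    recs = []
    for grp, sub in cells.groupby(by, sort=True):
        n = len(sub)
        rec = {by: grp, "n": n}
        for label, col in (("x", "x_um"), ("z", "y_um")):
            vals = sub[col].to_numpy(dtype=float)
            rec[f"mean_{label}_um"] = float(vals.mean())
            if n > 1:
                rec[f"sem_{label}_um"] = float(vals.std(ddof=1) / np.sqrt(n))
            else:
                rec[f"sem_{label}_um"] = np.nan
        if n == 1:
            warnings.warn(f"group {grp!r} has a single cell; SEM undefined", stacklevel=2)
        recs.append(rec)
    return pd.DataFrame(recs)
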