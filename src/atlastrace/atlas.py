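"""Reference atlas: labeled volume plus region hierarchy.

The atlas anchors every downstream quantity. Conventions, fixed here and
validated at load time:

* axis 0 = rostro-caudal (X), axis 1 = dorso-ventral (Z), axis 2 = medio-lateral (ML)
* voxel ``i`` along any axis spans the half-open physical interval
  ``[i * voxel_size_um, (i + 1) * voxel_size_um)`` in micrometres, 0-based
* label 0 is background; every nonzero label must exist in the region table
* the midline is at half the ML physical extent

The on-disk formats mirror the Allen CCFv3 distribution style: an integer
label volume (NRRD or NIfTI) and a structure-graph-like region table (JSON,
with a CSV equivalent). Real CCFv3 volumes load through the same code path;
nothing in the package requires them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AtlasValidationError, FormatError, RegionLookupError

AXES = ("rostrocaudal_x", "dorsoventral_z", "mediolateral")
CATEGORIES = ("motor", "sensory", "behavior", "other")

OUTSIDE = "outside"


@dataclass(frozen=True)
class RegionNode:
    """One node of the region hierarchy (Allen structure-graph style)."""

    region_id: int
    acronym: str
    name: str
    parent_id: int | None  # None only for the root
    category: str = "other"

    def __post_init__(self):
        if self.region_id <= 0:
            raise AtlasValidationError(f"region_id must be positive, got {self.region_id}")
        if self.category not in CATEGORIES:
            raise AtlasValidationError(
                f"category {self.category!r} not in {CATEGORIES} (region {self.acronym})"
            )


class RegionTable:
    """Validated region hierarchy with tree queries.

    Invariants checked on construction: unique ids and acronyms, exactly one
    root, every parent_id present, and no cycles (the parent graph is a tree).
    """

    def __init__(self, nodes: list[RegionNode]):
        self.nodes: dict[int, RegionNode] = {}
        acronyms: dict[str, int] = {}
        for node in nodes:
            if node.region_id in self.nodes:
                raise AtlasValidationError(f"duplicate region_id {node.region_id}")
            if node.acronym in acronyms:
                raise AtlasValidationError(f"duplicate acronym {node.acronym!r}")
            self.nodes[node.region_id] = node
            acronyms[node.acronym] = node.region_id
        self._acronyms = acronyms

        roots = [n for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise AtlasValidationError(f"expected exactly one root region, found {len(roots)}")
        self.root_id = roots[0].region_id

        self._children: dict[int, list[int]] = {rid: [] for rid in self.nodes}
        for node in nodes:
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise AtlasValidationError(
                        f"region {node.region_id} ({node.acronym}) has unknown "
                        f"parent_id {node.parent_id}"
                    )
                self._children[node.parent_id].append(node.region_id)

        # cycle check: walking up from every node must reach the root
        for node in nodes:
            seen = set()
            cur = node
            while cur.parent_id is not None:
                if cur.region_id in seen:
                    raise AtlasValidationError(f"cycle in region hierarchy at {cur.region_id}")
                seen.add(cur.region_id)
                cur = self.nodes[cur.parent_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self.nodes

    def __getitem__(self, region_id: int) -> RegionNode:
        try:
            return self.nodes[region_id]
        except KeyError:
            raise RegionLookupError(f"unknown region_id {region_id}") from None

    def by_acronym(self, acronym: str) -> RegionNode:
        try:
            return self.nodes[self._acronyms[acronym]]
        except KeyError:
            raise RegionLookupError(f"unknown acronym {acronym!r}") from None

    def children(self, region_id: int) -> list[int]:
        self[region_id]
        return list(self._children[region_id])

    def descendants(self, region_id: int, include_self: bool = True) -> set[int]:
        """All tree descendants of ``region_id`` (depth-first)."""
        self[region_id]
        out: set[int] = {region_id} if include_self else set()
        stack = list(self._children[region_id])
        while stack:
            rid = stack.pop()
            out.add(rid)
            stack.extend(self._children[rid])
        return out

    def leaves(self) -> list[int]:
        return [rid for rid in self.nodes if not self._children[rid]]

    # ---- serialization -------------------------------------------------

    def to_records(self) -> list[dict]:
        return [
            {
                "id": n.region_id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_structure_id": n.parent_id,
                "category": n.category,
            }
            for n in self.nodes.values()
        ]

    @classmethod
    def from_records(cls, records: list[dict]) -> "RegionTable":
        nodes = []
        for r in records:
            parent = r.get("parent_structure_id")
            if parent is not None and (parent == "" or (isinstance(parent, float) and np.isnan(parent))):
                parent = None
            nodes.append(
                RegionNode(
                    region_id=int(r["id"]),
                    acronym=str(r["acronym"]),
                    name=str(r["name"]),
                    parent_id=None if parent is None else int(parent),
                    category=str(r.get("category", "other")),
                )
            )
        return cls(nodes)


@dataclass
class AtlasVolume:
    """3D integer label grid with fixed axis semantics (see module docstring)."""

    labels: np.ndarray
    voxel_size_um: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"label volume must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"label volume must be integer-typed, got {self.labels.dtype}")
        if self.voxel_size_um <= 0:
            raise FormatError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def midline_ml_um(self) -> float:
        """Half the medio-lateral physical extent."""
        return 0.5 * self.shape[2] * self.voxel_size_um

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size_um for s in self.shape)


@dataclass
class Atlas:
    """Label volume + validated region table; the frame of every measurement."""

    volume: AtlasVolume
    regions: RegionTable
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        present = np.unique(self.volume.labels)
        present = present[present != 0]
        unknown = [int(v) for v in present if int(v) not in self.regions]
        if unknown:
            raise AtlasValidationError(
                f"label volume contains region ids absent from the region table: {unknown}"
            )

    # convenient passthroughs
    @property
    def labels(self) -> np.ndarray:
        return self.volume.labels

    @property
    def voxel_size_um(self) -> float:
        return self.volume.voxel_size_um

    @property
    def midline_ml_um(self) -> float:
        return self.volume.midline_ml_um

    def region_voxels(self, region_id: int, include_descendants: bool = True) -> set[tuple[int, int, int]]:
        """Voxel index triples painted with ``region_id`` (optionally with all descendants)."""
        return region_voxels(self, region_id, include_descendants)

    def point_to_voxel(self, point_um) -> tuple[int, int, int] | str:
        return point_to_voxel(self, point_um)

    def label_at(self, point_um) -> int | None:
        """Region id at a physical point, or None if outside the grid / background."""
        vox = point_to_voxel(self, point_um)
        if vox == OUTSIDE:
            return None
        lab = int(self.labels[vox])
        return lab if lab != 0 else None


# ---------------------------------------------------------------------------
# operations


def region_voxels(atlas: Atlas, region_id: int, include_descendants: bool = True) -> set[tuple[int, int, int]]:
    """Set of voxel index triples belonging to a region.

    With ``include_descendants`` the union over the region and all its tree
    descendants is returned. The background id 0 is not a region.
    """
    if region_id == 0:
        raise RegionLookupError("0 is the background label, not a region")
    ids = atlas.regions.descendants(region_id) if include_descendants else {region_id}
    atlas.regions[region_id]  # raises for unknown ids
    mask = np.isin(atlas.labels, sorted(ids))
    return set(zip(*(idx.tolist() for idx in np.nonzero(mask))))


def region_mask(atlas: Atlas, region_id: int, include_descendants: bool = True) -> np.ndarray:
    """Boolean volume for a region (cheaper than the explicit voxel set)."""
    if region_id == 0:
        raise RegionLookupError("0 is the background label, not a region")
    atlas.regions[region_id]
    ids = atlas.regions.descendants(region_id) if include_descendants else {region_id}
    return np.isin(atlas.labels, sorted(ids))


def point_to_voxel(atlas: Atlas | AtlasVolume, point_um) -> tuple[int, int, int] | str:
    """Map a physical point (μm) to its voxel index triple, or ``"outside"``.

    Half-open convention: a coordinate at exactly ``(i+1) * voxel_size`` belongs
    to voxel ``i+1``.
    """
    vol = atlas.volume if isinstance(atlas, Atlas) else atlas
    p = np.asarray(point_um, dtype=float)
    idx = np.floor(p / vol.voxel_size_um).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(vol.shape)):
        return OUTSIDE
    return tuple(int(i) for i in idx)


# ---------------------------------------------------------------------------
# I/O


def _read_volume_file(path: Path) -> tuple[np.ndarray, float]:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    elif name.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        zooms = img.GetSpacing()[::-1]  # sitk spacing is fastest-axis first
    else:
        raise FormatError(f"unsupported atlas volume format: {path.name} (use .nrrd or .nii)")
    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int32)
        else:
            raise FormatError(f"{path.name}: label volume has non-integer values")
    if len(set(np.round(zooms, 9))) != 1:
        raise FormatError(f"{path.name}: anisotropic voxels not supported (spacing {zooms})")
    return data, float(zooms[0])


def _write_volume_file(path: Path, labels: np.ndarray, voxel_size_um: float) -> None:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([voxel_size_um] * 3 + [1.0])
        nib.save(nib.Nifti1Image(labels.astype(np.int32), affine), str(path))
    elif name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(labels.astype(np.int32))
        img.SetSpacing((voxel_size_um,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported atlas volume format: {path.name} (use .nrrd or .nii)")


def load_regions(path: str | Path) -> RegionTable:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = payload["regions"] if isinstance(payload, dict) else payload
        return RegionTable.from_records(records)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        records = df.where(pd.notna(df), None).to_dict("records")
        return RegionTable.from_records(records)
    raise FormatError(f"unsupported region table format: {path.name} (use .json or .csv)")


def save_regions(table: RegionTable, path: str | Path) -> None:
    path = Path(path)
    records = table.to_records()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"axes": list(AXES), "regions": records}, indent=2) + "\n")
    elif path.suffix.lower() == ".csv":
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    else:
        raise FormatError(f"unsupported region table format: {path.name} (use .json or .csv)")


def load_atlas(volume_path: str | Path, regions_path: str | Path) -> Atlas:
    """Load and validate an atlas (NRRD/NIfTI label volume + JSON/CSV region table)."""
    labels, voxel_size = _read_volume_file(Path(volume_path))
    regions = load_regions(regions_path)
    return Atlas(AtlasVolume(labels, voxel_size), regions)


def save_atlas(atlas: Atlas, volume_path: str | Path, regions_path: str | Path) -> None:
    _write_volume_file(Path(volume_path), atlas.labels, atlas.voxel_size_um)
    save_regions(atlas.regions, regions_path)
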