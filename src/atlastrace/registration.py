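"""Per-section planar affine registration.

Each histological section is a plane embedded in atlas space. Annotators mark
control points: pixel coordinates ``(u, v)`` in the section image paired with
atlas coordinates ``(x, y, z)`` in μm. The transform is the 9-parameter planar
affine map

    (x, y, z) = A · (u, v) + b,      A ∈ R^{3×2}, b ∈ R^3,

fitted by least squares over the control points. This replaces the interactive
histology-alignment step of typical workflows with explicit, reproducible
control-point files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InsufficientPointsError

#: relative tolerance on the smallest singular value of the centered pixel
#: coordinates; below this the points are considered collinear
_DEGENERACY_RTOL = 1e-10


@dataclass(frozen=True)
class PlanarAffine3D:
    """Affine map from 2D section pixels to 3D atlas μm: p ↦ A·p + b."""

    A: np.ndarray  # (3, 2)
    b: np.ndarray  # (3,)
    fit_rms_um: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float).reshape(3, 2))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float).reshape(3))
        if self.fit_rms_um < 0:
            raise ValueError("fit_rms_um must be non-negative")
        cross = np.cross(self.A[:, 0], self.A[:, 1])
        if np.linalg.norm(cross) == 0:
            raise DegenerateGeometryError("affine columns are parallel: degenerate plane")

    def __call__(self, points_uv) -> np.ndarray:
        return apply_affine(self, points_uv)

    def to_dict(self) -> dict:
        return {"A": self.A.tolist(), "b": self.b.tolist(), "fit_rms_um": self.fit_rms_um}

    @classmethod
    def from_dict(cls, d: dict) -> "PlanarAffine3D":
        return cls(np.array(d["A"]), np.array(d["b"]), float(d.get("fit_rms_um", 0.0)))


@dataclass
class SectionFrame:
    """Control points of one section: pixel (u, v) ↔ atlas (x, y, z) μm pairs."""

    section_id: str
    animal_id: str = ""
    bregma_mm: float | None = None
    pixel_uv: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    atlas_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self):
        self.pixel_uv = np.asarray(self.pixel_uv, dtype=float).reshape(-1, 2)
        self.atlas_xyz = np.asarray(self.atlas_xyz, dtype=float).reshape(-1, 3)
        if len(self.pixel_uv) != len(self.atlas_xyz):
            raise ValueError("pixel and atlas control points differ in length")
        if not np.all(np.isfinite(self.pixel_uv)):
            raise ValueError(f"section {self.section_id}: non-finite pixel coordinates")

    def fit(self) -> PlanarAffine3D:
        return fit_affine(self.pixel_uv, self.atlas_xyz)


def fit_affine(pixel_uv, atlas_xyz) -> PlanarAffine3D:
    """Least-squares fit of the planar affine map from ≥3 control-point pairs.

    Minimizes Σ‖A·p + b − q‖² via an orthogonal (QR/SVD-backed) solve; the
    minimizer is unique when the pixel points are not collinear.

    Raises
    ------
    InsufficientPointsError
        fewer than 3 pairs.
    DegenerateGeometryError
        collinear pixel points (the normal system is singular).
    """
    P = np.asarray(pixel_uv, dtype=float).reshape(-1, 2)
    Q = np.asarray(atlas_xyz, dtype=float).reshape(-1, 3)
    n = len(P)
    if n < 3 or len(Q) != n:
        raise InsufficientPointsError(f"need ≥3 control-point pairs, got {n}")

    centered = P - P.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] <= _DEGENERACY_RTOL * max(sv[0], 1.0):
        raise DegenerateGeometryError("pixel control points are collinear")

    design = np.hstack([P, np.ones((n, 1))])  # (n, 3)
    coef, *_ = np.linalg.lstsq(design, Q, rcond=None)  # (3, 3): rows u, v, 1
    A = coef[:2].T  # (3, 2)
    b = coef[2]
    resid = design @ coef - Q
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return PlanarAffine3D(A, b, rms)


def apply_affine(transform: PlanarAffine3D, points_uv) -> np.ndarray:
    """Map pixel points (n, 2) to atlas coordinates (n, 3) in μm; order-preserving."""
    P = np.asarray(points_uv, dtype=float).reshape(-1, 2)
    return P @ transform.A.T + transform.b


# ---------------------------------------------------------------------------
# I/O: control-point CSV and transform JSON


def load_control_points(path: str | Path) -> dict[str, SectionFrame]:
    """Read a control-point CSV (section_id, u_px, v_px, x_um, y_um, z_um [, animal_id])."""
    df = pd.read_csv(path, dtype={"section_id": str})
    frames: dict[str, SectionFrame] = {}
    for sid, grp in df.groupby("section_id", sort=True):
        frames[sid] = SectionFrame(
            section_id=sid,
            animal_id=str(grp["animal_id"].iloc[0]) if "animal_id" in grp else "",
            pixel_uv=grp[["u_px", "v_px"]].to_numpy(),
            atlas_xyz=grp[["x_um", "y_um", "z_um"]].to_numpy(),
        )
    return frames


def fit_all(frames: dict[str, SectionFrame]) -> dict[str, PlanarAffine3D]:
    return {sid: frame.fit() for sid, frame in sorted(frames.items())}


def save_transforms(transforms: dict[str, PlanarAffine3D], path: str | Path) -> None:
    payload = {sid: t.to_dict() for sid, t in sorted(transforms.items())}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_transforms(path: str | Path) -> dict[str, PlanarAffine3D]:
    payload = json.loads(Path(path).read_text())
    return {sid: PlanarAffine3D.from_dict(d) for sid, d in payload.items()}
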