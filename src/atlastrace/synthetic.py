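"""Synthetic histology experiments with serialized ground truth.

Real tracing studies of this kind rest on per-animal histology that is rarely
deposited in reusable form, so every quantitative behavior of this package is
exercised on synthetic data generated here: a toy atlas shaped like the real
use case (a mediolaterally extended cortical shell plus a set of brainstem
nuclei with a two-level hierarchy), sections embedded by known planar affine
frames, cell cohorts realizing exact planted mediolateral class counts,
ellipsoidal injection volumes with closed-form volumes and brute-force voxel
oracles, and axon signal images with planted per-region density fractions
under Poisson photon-count noise.

Every generator is deterministic per seed and records a ground-truth manifest
sufficient to recompute each expected downstream output independently of the
pipeline code being tested.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .atlas import Atlas, AtlasVolume, RegionNode, RegionTable, save_atlas
from .cell_mapping import ML_CLASS_OF_BIN
from .registration import PlanarAffine3D

DEFAULT_SHAPE = (60, 40, 80)  # (rostro-caudal, dorso-ventral, medio-lateral)
DEFAULT_VOXEL_SIZE_UM = 100.0
NUCLEUS_SIZE = 8  # voxels per side of each brainstem nucleus block

#: class → the mediolateral bins it comprises
BINS_OF_CLASS = {"cingulate": [0], "medial": [1, 2], "lateral": [3, 4]}

# region ids of the toy hierarchy (root → CTX/MB/MY → leaves)
ROOT_ID, CTX_ID, MB_ID, MY_ID = 1, 2, 3, 4
CORTEX_ID = 10
_MB_NUCLEI = [("MRN", 21, "motor"), ("SC", 22, "sensory"), ("PAG", 23, "behavior")]
_MY_NUCLEI = [("SPV", 31, "sensory"), ("IRN", 32, "motor"),
              ("PARN", 33, "motor"), ("GRN", 34, "motor")]


def make_toy_atlas(
    seed: int = 1,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> tuple[Atlas, dict]:
    """Toy reference atlas: cortical shell + 7 brainstem nucleus blocks.

    The cortical shell is a dorsal band spanning a known mediolateral range in
    each hemisphere over a rostral AP range; each nucleus is an 8×8×8 block
    placed on a fixed slot grid with a small seeded jitter (slots are spaced so
    jittered blocks can never overlap). Deterministic per seed.
    """
    if min(shape) < 20:
        raise ValueError("toy atlas needs ≥20 voxels per axis")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    nx, nz, nml = shape
    mid_idx = nml // 2

    # cortical shell: rostral AP band, dorsal DV band, symmetric ML span
    ap_lo, ap_hi = 6, min(34, nx - 2)
    dv_lo, dv_hi = 2, 10
    ml_margin = 5
    labels[ap_lo:ap_hi, dv_lo:dv_hi, ml_margin:nml - ml_margin] = CORTEX_ID

    # brainstem nuclei: caudal bands, jittered block corners on disjoint slots
    nuclei: dict[str, dict] = {}
    bands = [
        (_MB_NUCLEI, 37, 16, [12, 36, 60]),
        (_MY_NUCLEI, 50, 22, [8, 28, 48, 66]),
    ]
    for group, ap_base, dv_base, ml_slots in bands:
        for (acronym, rid, _cat), ml_base in zip(group, ml_slots):
            jitter = rng.integers(-2, 3, size=3)
            corner = np.array([ap_base, dv_base, ml_base]) + jitter
            corner = np.clip(corner, 0, np.array(shape) - NUCLEUS_SIZE)
            a, d, m = corner
            labels[a:a + NUCLEUS_SIZE, d:d + NUCLEUS_SIZE, m:m + NUCLEUS_SIZE] = rid
            nuclei[acronym] = {"region_id": rid, "corner": corner.tolist(), "size": NUCLEUS_SIZE}

    nodes = [
        RegionNode(ROOT_ID, "root", "toy brain root", None, "other"),
        RegionNode(CTX_ID, "CTX", "cerebral cortex", ROOT_ID, "other"),
        RegionNode(MB_ID, "MB", "midbrain", ROOT_ID, "other"),
        RegionNode(MY_ID, "MY", "medulla", ROOT_ID, "other"),
        RegionNode(CORTEX_ID, "Iso", "isocortex shell", CTX_ID, "other"),
    ]
    for acronym, rid, cat in _MB_NUCLEI:
        nodes.append(RegionNode(rid, acronym, f"{acronym} nucleus", MB_ID, cat))
    for acronym, rid, cat in _MY_NUCLEI:
        nodes.append(RegionNode(rid, acronym, f"{acronym} nucleus", MY_ID, cat))

    atlas = Atlas(AtlasVolume(labels, voxel_size_um), RegionTable(nodes))
    manifest = {
        "seed": int(seed),
        "shape": list(shape),
        "voxel_size_um": voxel_size_um,
        "midline_ml_um": atlas.midline_ml_um,
        "cortex": {
            "region_id": CORTEX_ID,
            "ap_range": [ap_lo, ap_hi],
            "dv_range": [dv_lo, dv_hi],
            "ml_left": [ml_margin, mid_idx],
            "ml_right": [mid_idx, nml - ml_margin],
        },
        "nuclei": nuclei,
    }
    atlas.manifest = manifest
    return atlas, manifest


# ---------------------------------------------------------------------------
# sections + cells


def _random_section_transform(rng: np.random.Generator, x_um: float) -> PlanarAffine3D:
    """Random in-plane pixel frame for a coronal plane at the given AP position."""
    theta = rng.uniform(0, 2 * np.pi)
    su, sv = rng.uniform(2.0, 5.0, size=2)  # μm per pixel
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    M = rot @ np.diag([su, sv])
    offset = rng.uniform(500.0, 1500.0, size=2)
    A = np.zeros((3, 2))
    A[1:, :] = M
    b = np.array([x_um, offset[0], offset[1]])
    return PlanarAffine3D(A, b)


def _exact_class_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n cells over the three classes."""
    if not np.isclose(sum(proportions.values()), 1.0):
        raise ValueError("class proportions must sum to 1")
    keys = sorted(proportions)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_sections_and_cells(
    atlas: Atlas,
    manifest: dict,
    cells_per_group: dict[str, int],
    proportions: dict[str, dict[str, float]],
    n_sections: int = 4,
    pixel_noise_sigma: float = 0.0,
    seed: int = 0,
    hemisphere: str = "right",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sections with known planar affine frames + a cohort realizing exact
    planted mediolateral class counts.

    Cells are placed at mediolateral offsets chosen inside their target bin
    (relative position in (0.05, 0.95) of the bin width, so jitter below half
    a bin cannot move them), carried into pixel space through the inverse of
    the section's true transform, then optionally jittered by isotropic pixel
    noise. Ground truth records every true transform and per-cell bin/class.

    Returns (control_points, cells, truth).
    """
    rng = np.random.default_rng(seed)
    vs = atlas.voxel_size_um
    cortex = manifest["cortex"]
    ap_lo, ap_hi = cortex["ap_range"]
    ap_indices = np.unique(np.linspace(ap_lo + 1, ap_hi - 2, n_sections).round().astype(int))

    sections: dict[str, dict] = {}
    cp_rows = []
    corner_px = [(0.0, 0.0), (2000.0, 0.0), (0.0, 2000.0), (2000.0, 2000.0), (1000.0, 700.0)]
    for ap in ap_indices:
        sid = f"sec{ap:02d}"
        t = _random_section_transform(rng, (ap + 0.5) * vs)
        sections[sid] = {"ap_index": int(ap), "transform": t}
        for u, v in corner_px:
            xyz = t([[u, v]])[0]
            du, dv = rng.normal(0.0, pixel_noise_sigma, size=2) if pixel_noise_sigma > 0 else (0.0, 0.0)
            cp_rows.append({
                "section_id": sid, "animal_id": "synthA",
                "u_px": u + du, "v_px": v + dv,
                "x_um": xyz[0], "y_um": xyz[1], "z_um": xyz[2],
            })

    mid = atlas.midline_ml_um
    if hemisphere == "right":
        width = cortex["ml_right"][1] * vs - mid
    elif hemisphere == "left":
        width = mid - cortex["ml_left"][0] * vs
    else:
        raise ValueError("hemisphere must be 'left' or 'right'")
    dv_lo_um, dv_hi_um = (cortex["dv_range"][0] + 0.2) * vs, (cortex["dv_range"][1] - 0.2) * vs

    cell_rows = []
    truth_counts: dict[str, dict[str, int]] = {}
    sids = sorted(sections)
    for group in sorted(cells_per_group):
        n = cells_per_group[group]
        counts = _exact_class_counts(n, proportions[group])
        truth_counts[group] = counts
        cell_i = 0
        for cls in ("cingulate", "medial", "lateral"):
            bins = BINS_OF_CLASS[cls]
            for j in range(counts[cls]):
                b = bins[j % len(bins)]
                rel = rng.uniform(0.05, 0.95)
                d = (b + rel) * width / 5.0
                ml = mid + d if hemisphere == "right" else mid - d
                sid = sids[cell_i % len(sids)]
                t: PlanarAffine3D = sections[sid]["transform"]
                y = rng.uniform(dv_lo_um, dv_hi_um)
                uv = np.linalg.solve(t.A[1:, :], np.array([y, ml]) - t.b[1:])
                if pixel_noise_sigma > 0:
                    uv = uv + rng.normal(0.0, pixel_noise_sigma, size=2)
                cell_rows.append({
                    "section_id": sid, "animal_id": "synthA", "group": group,
                    "channel": "ch0", "u_px": uv[0], "v_px": uv[1],
                    "true_bin": b, "true_class": ML_CLASS_OF_BIN[b],
                    "true_hemisphere": hemisphere,
                })
                cell_i += 1

    cells_full = pd.DataFrame(
        cell_rows,
        columns=["section_id", "animal_id", "group", "channel", "u_px", "v_px",
                 "true_bin", "true_class", "true_hemisphere"],
    )
    cells = cells_full[["section_id", "animal_id", "group", "channel", "u_px", "v_px"]].copy()
    control_points = pd.DataFrame(cp_rows)
    truth = {
        "seed": int(seed),
        "pixel_noise_sigma": pixel_noise_sigma,
        "hemisphere": hemisphere,
        "sections": {sid: {"ap_index": s["ap_index"], **s["transform"].to_dict()}
                     for sid, s in sections.items()},
        "class_counts": truth_counts,
        "cells": cells_full,
    }
    return control_points, cells, truth


# ---------------------------------------------------------------------------
# injection volumes


def fibonacci_ellipsoid(center_um, radii_um, n: int) -> np.ndarray:
    """Quasi-uniform (Fibonacci-lattice) sampling of an ellipsoid surface.

    Used where surface coverage, not annotation realism, matters: the convex
    hull of n random surface points underestimates the enclosed volume by
    O(n^{-2/3}), while the lattice keeps the deficit negligible at moderate n.
    """
    i = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    d = np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
    return np.asarray(center_um, dtype=float) + d * np.asarray(radii_um, dtype=float)


def ellipsoid_volume_mm3(radii_um) -> float:
    a, b, c = (np.asarray(radii_um, dtype=float) / 1000.0)
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_voxel_oracle(center_um, radii_um, voxel_size_um: float,
                           label_volume: np.ndarray | None = None) -> set[tuple[int, int, int]]:
    """Brute-force voxel set of an analytic ellipsoid: explicit per-voxel loop
    testing each voxel center against the ellipsoid inequality. Independent of
    the mesh/voxelization code path.
    """
    c = np.asarray(center_um, dtype=float)
    r = np.asarray(radii_um, dtype=float)
    lo = np.floor((c - r) / voxel_size_um).astype(int)
    hi = np.ceil((c + r) / voxel_size_um).astype(int)
    out = set()
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                p = (np.array([i, j, k]) + 0.5) * voxel_size_um
                if np.sum(((p - c) / r) ** 2) <= 1.0:
                    out.add((i, j, k))
    return out


def simulate_injection(
    center_um,
    radii_um,
    n_boundary_points: int = 500,
    seed: int = 0,
    animal_id: str = "synthA",
    label: str = "inj",
    atlas: Atlas | None = None,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> tuple[pd.DataFrame, dict]:
    """Boundary points sampled on an analytic ellipsoid surface + ground truth.

    Truth carries the closed-form volume and, when an atlas is given, brute
    force per-region overlap percentages computed by the independent voxel
    oracle (re-runnable from the recorded parameters alone).
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(center_um, dtype=float)
    r = np.asarray(radii_um, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    dirs = rng.normal(size=(n_boundary_points, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = c + dirs * r

    outlines = pd.DataFrame({
        "animal_id": animal_id, "label": label,
        "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2],
    })
    truth: dict = {
        "center_um": c.tolist(),
        "radii_um": r.tolist(),
        "n_boundary_points": n_boundary_points,
        "seed": int(seed),
        "analytic_volume_mm3": float(ellipsoid_volume_mm3(r)),
        "voxel_size_um": voxel_size_um,
    }
    if atlas is not None:
        ell = ellipsoid_voxel_oracle(c, r, voxel_size_um)
        overlaps = {}
        if np.isclose(voxel_size_um, atlas.voxel_size_um):
            for rid in atlas.regions.leaves():
                tgt = atlas.region_voxels(rid)
                if tgt:
                    overlaps[atlas.regions[rid].acronym] = {
                        "overlap_voxels": len(ell & tgt),
                        "target_voxels": len(tgt),
                        "percent": 100.0 * len(ell & tgt) / len(tgt),
                    }
        truth["oracle_voxel_count"] = len(ell)
        truth["oracle_overlaps"] = overlaps
    return outlines, truth


# ---------------------------------------------------------------------------
# axon signal images


def simulate_axon_images(
    atlas: Atlas,
    manifest: dict,
    out_dir: str | Path,
    animals: dict[str, str],
    fractions: dict[str, dict[str, float]],
    total_expected_counts: float = 2.0e6,
    n_sections: int = 6,
    noise: str = "poisson",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Region masks + signal-channel TIFFs with planted innervation fractions.

    Sections are atlas AP slices guaranteed to intersect every nucleus (half in
    the midbrain band, half in the medullary band). For a region with planted
    fraction f and N mask pixels across an animal's sections, the per-pixel
    Poisson rate is λ = f · total_expected_counts / N, so the expected masked
    sum is exactly f · total per region and the expected recovered fraction is
    f. ``noise="none"`` writes λ itself (float64) for exact-identity checks.

    Returns (manifest table, truth).
    """
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    nuclei = manifest["nuclei"]
    for group, fr in fractions.items():
        if not np.isclose(sum(fr.values()), 1.0):
            raise ValueError(f"fractions for group {group!r} must sum to 1")
        if set(fr) - set(nuclei):
            raise ValueError(f"unknown nuclei in fractions for group {group!r}")

    # AP slices common to every block of each band
    mb = [nuclei[a] for a, _, _ in _MB_NUCLEI if a in nuclei]
    my = [nuclei[a] for a, _, _ in _MY_NUCLEI if a in nuclei]
    sections_ap: list[int] = []
    for band, count in ((mb, n_sections // 2), (my, n_sections - n_sections // 2)):
        lo = max(n["corner"][0] for n in band)
        hi = min(n["corner"][0] + n["size"] for n in band)
        sections_ap.extend(np.unique(np.linspace(lo, hi - 1, count).round().astype(int)).tolist())

    rows = []
    truth_lambdas: dict[str, dict[str, float]] = {}
    for animal in sorted(animals):
        group = animals[animal]
        fr = fractions[group]
        adir = out_dir / animal
        adir.mkdir(exist_ok=True)
        # total mask pixels per region across this animal's sections
        npix = {}
        for acr in sorted(fr):
            rid = nuclei[acr]["region_id"]
            npix[acr] = sum(int((atlas.labels[ap] == rid).sum()) for ap in sections_ap)
        lam = {acr: fr[acr] * total_expected_counts / npix[acr] for acr in sorted(fr)}
        truth_lambdas[animal] = lam

        for ap in sections_ap:
            sid = f"s{ap:02d}"
            signal = np.zeros(atlas.labels.shape[1:], dtype=np.float64)
            section_rows = []
            for acr in sorted(fr):
                rid = nuclei[acr]["region_id"]
                mask = (atlas.labels[ap] == rid).astype(np.uint8)
                if mask.sum() == 0:
                    continue
                if noise == "poisson":
                    vals = rng.poisson(lam[acr], size=int(mask.sum())).astype(np.float64)
                else:
                    vals = np.full(int(mask.sum()), lam[acr])
                signal[mask.astype(bool)] = vals
                mask_path = f"{animal}/{sid}_{acr}_mask.tif"
                tifffile.imwrite(adir / f"{sid}_{acr}_mask.tif", mask)
                section_rows.append({
                    "animal_id": animal, "group": group, "section_id": sid,
                    "region_id": rid, "region_acronym": acr, "channel": "axons",
                    "mask_path": mask_path,
                    "signal_path": f"{animal}/{sid}_axons.tif",
                })
            if noise == "poisson":
                signal = signal.astype(np.uint32)
            tifffile.imwrite(adir / f"{sid}_axons.tif", signal)
            rows.extend(section_rows)

    table = pd.DataFrame(rows)
    truth = {
        "seed": int(seed),
        "noise": noise,
        "total_expected_counts": total_expected_counts,
        "sections_ap": [int(a) for a in sections_ap],
        "fractions": fractions,
        "animals": animals,
        "lambdas": truth_lambdas,
    }
    return table, truth


# ---------------------------------------------------------------------------
# one-stop dataset


#: study-condition defaults for the end-to-end synthetic experiment
DEFAULT_GROUP_PROPORTIONS = {
    "medialSCPN": {"cingulate": 0.25, "medial": 0.60, "lateral": 0.15},
    "lateralSCPN": {"cingulate": 0.05, "medial": 0.15, "lateral": 0.80},
}
DEFAULT_CELLS_PER_GROUP = {"medialSCPN": 1000, "lateralSCPN": 1000}
DEFAULT_AXON_FRACTIONS = {
    "medialSCPN": {"SC": 0.35, "PAG": 0.20, "MRN": 0.10, "SPV": 0.10,
                   "IRN": 0.08, "PARN": 0.07, "GRN": 0.10},
    "lateralSCPN": {"MRN": 0.15, "PAG": 0.08, "SC": 0.10, "IRN": 0.12,
                    "SPV": 0.20, "PARN": 0.22, "GRN": 0.13},
}
DEFAULT_AXON_ANIMALS = {
    "med1": "medialSCPN", "med2": "medialSCPN", "med3": "medialSCPN",
    "lat1": "lateralSCPN", "lat2": "lateralSCPN", "lat3": "lateralSCPN",
}


def simulate_all(out_dir: str | Path, seed: int = 1) -> dict:
    """Write a complete runnable synthetic dataset + ground-truth manifest.

    Produces atlas.nrrd + regions.json, control_points.csv, cells.csv,
    outlines.csv, per-animal mask/signal TIFFs with axon_manifest.csv, and
    ground_truth.json. Deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atlas, manifest = make_toy_atlas(seed=seed)
    save_atlas(atlas, out_dir / "atlas.nrrd", out_dir / "regions.json")

    cp, cells, cell_truth = simulate_sections_and_cells(
        atlas, manifest,
        cells_per_group=DEFAULT_CELLS_PER_GROUP,
        proportions=DEFAULT_GROUP_PROPORTIONS,
        n_sections=4, pixel_noise_sigma=0.0, seed=seed + 101,
    )
    cp.to_csv(out_dir / "control_points.csv", index=False)
    cells.to_csv(out_dir / "cells.csv", index=False)

    vs = atlas.voxel_size_um
    mid = atlas.midline_ml_um
    cortex = manifest["cortex"]
    inj_center = np.array([
        (sum(cortex["ap_range"]) / 2) * vs,
        (sum(cortex["dv_range"]) / 2) * vs,
        mid + 1500.0,
    ])
    out1, inj1_truth = simulate_injection(
        inj_center, (800.0, 600.0, 500.0), seed=seed + 202,
        label="cortical_inj", atlas=atlas, voxel_size_um=vs,
    )
    mrn = manifest["nuclei"]["MRN"]
    mrn_center = (np.array(mrn["corner"]) + mrn["size"] / 2) * vs
    out2, inj2_truth = simulate_injection(
        mrn_center, (500.0, 500.0, 500.0), seed=seed + 203,
        label="mrn_sphere", atlas=atlas, voxel_size_um=vs,
    )
    pd.concat([out1, out2], ignore_index=True).to_csv(out_dir / "outlines.csv", index=False)

    axon_table, axon_truth = simulate_axon_images(
        atlas, manifest, out_dir / "axon_images",
        animals=DEFAULT_AXON_ANIMALS, fractions=DEFAULT_AXON_FRACTIONS,
        noise="poisson", seed=seed + 304,
    )
    # manifest lives one level above the image tree: make paths manifest-relative
    for col in ("mask_path", "signal_path"):
        axon_table[col] = "axon_images/" + axon_table[col]
    axon_table.to_csv(out_dir / "axon_manifest.csv", index=False)

    truth = {
        "seed": int(seed),
        "atlas": manifest,
        "cells": {
            "class_counts": cell_truth["class_counts"],
            "pixel_noise_sigma": cell_truth["pixel_noise_sigma"],
            "hemisphere": cell_truth["hemisphere"],
            "sections": cell_truth["sections"],
        },
        "injections": {"cortical_inj": inj1_truth, "mrn_sphere": inj2_truth},
        "axons": axon_truth,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    cell_truth["cells"].to_csv(out_dir / "cells_truth.csv", index=False)
    return truth
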