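import numpy as np
import pandas as pd
import pytest

from atlastrace import synthetic
from atlastrace.cell_mapping import (
    HemisphereExtent,
    assign_hemisphere,
    class_counts,
    cortical_extent,
    map_cells,
    ml_bin,
    summarize_distribution,
)
from atlastrace.errors import EmptyExtentError, MissingTransformError
from atlastrace.registration import PlanarAffine3D


class TestAssignHemisphere:
    def test_left_of_midline(self):
        assert assign_hemisphere(3999.0, 4000.0) == "left"

    def test_midline_tie_goes_right(self):
        assert assign_hemisphere(4000.0, 4000.0) == "right"

    def test_matches_sign_oracle_off_midline(self):
        rng = np.random.default_rng(17)
        mid = 4000.0
        for ml in rng.uniform(0, 8000, size=1000):
            if ml != mid:
                assert assign_hemisphere(ml, mid) == ("right" if ml - mid > 0 else "left")


class TestCorticalExtent:
    def test_extent_from_manifest(self, toy_atlas):
        """Extent equals the generator's declared cortical ML range."""
        atlas, manifest = toy_atlas
        vs = atlas.voxel_size_um
        ap = manifest["cortex"]["ap_range"][0] + 1
        ext = cortical_extent(atlas, ap, "right", manifest["cortex"]["region_id"])
        assert ext.ml_min_um == atlas.midline_ml_um
        assert ext.ml_max_um == manifest["cortex"]["ml_right"][1] * vs

    def test_left_right_mirror_symmetric_atlas(self, toy_atlas):
        """Symmetric toy cortex: left and right widths agree within one voxel."""
        atlas, manifest = toy_atlas
        ap = manifest["cortex"]["ap_range"][0] + 1
        cid = manifest["cortex"]["region_id"]
        left = cortical_extent(atlas, ap, "left", cid)
        right = cortical_extent(atlas, ap, "right", cid)
        assert abs(left.width_um - right.width_um) <= atlas.voxel_size_um

    def test_slice_without_cortex(self, toy_atlas):
        atlas, manifest = toy_atlas
        with pytest.raises(EmptyExtentError):
            cortical_extent(atlas, 0, "right", manifest["cortex"]["region_id"])


class TestMlBin:
    EXT = HemisphereExtent("s", "right", 4000.0, 7500.0)

    @pytest.mark.parametrize(
        "rel,expected",
        [(0.50, 2), (0.20, 1), (0.0, 0), (0.999, 4), (1.0, 4)],
        ids=["midpoint", "half-open-boundary", "midline", "near-edge", "exact-edge-clamped"],
    )
    def test_boundaries(self, rel, expected):
        ml = self.EXT.ml_min_um + rel * self.EXT.width_um
        assert ml_bin(ml, self.EXT) == expected

    def test_lateral_of_extent_flagged(self):
        assert ml_bin(self.EXT.ml_max_um + 1.0, self.EXT) is None

    def test_left_hemisphere_uses_distance_from_midline(self):
        ext = HemisphereExtent("s", "left", 4000.0, 7500.0)
        assert ml_bin(4000.0 - 0.5 * ext.width_um, ext) == 2

    def test_uniform_positions_give_uniform_bins(self):
        """10^4 uniform draws: each bin within 3 sigma of n/5 (binomial)."""
        rng = np.random.default_rng(23)
        n = 10_000
        mls = rng.uniform(self.EXT.ml_min_um, self.EXT.ml_max_um, size=n)
        bins = np.array([ml_bin(ml, self.EXT) for ml in mls])
        counts = np.bincount(bins, minlength=5)
        assert counts.sum() == n
        sigma = np.sqrt(n * 0.2 * 0.8)
        assert np.all(np.abs(counts - n / 5) < 3 * sigma)


def identity_section(x_um):
    """Transform embedding pixels 1:1 into the coronal plane at x_um."""
    return PlanarAffine3D([[0, 0], [1, 0], [0, 1]], [x_um, 0, 0])


class TestMapCells:
    def test_zero_cells(self, toy_atlas):
        atlas, manifest = toy_atlas
        out = map_cells({}, pd.DataFrame(columns=["section_id", "u_px", "v_px"]),
                        atlas, manifest["cortex"]["region_id"])
        assert len(out) == 0

    def test_missing_transform_lists_sections(self, toy_atlas):
        atlas, manifest = toy_atlas
        cells = pd.DataFrame({"section_id": ["sX"], "u_px": [0.0], "v_px": [0.0]})
        with pytest.raises(MissingTransformError, match="sX"):
            map_cells({}, cells, atlas, manifest["cortex"]["region_id"])

    def test_point_outside_grid_has_null_region_but_is_binned(self, toy_atlas):
        """A cell above the grid (negative DV) still gets a bin from its extent."""
        atlas, manifest = toy_atlas
        ap = manifest["cortex"]["ap_range"][0] + 1
        t = identity_section((ap + 0.5) * atlas.voxel_size_um)
        cells = pd.DataFrame({"section_id": ["s"], "u_px": [-50.0],
                              "v_px": [atlas.midline_ml_um + 100.0]})
        out = map_cells({"s": t}, cells, atlas, manifest["cortex"]["region_id"])
        assert pd.isna(out.loc[0, "region_id"])
        assert out.loc[0, "in_extent"]
        assert out.loc[0, "ml_bin"] == 0

    def test_planted_proportions_recovered_exactly(self, toy_atlas):
        """Noiseless end-to-end: 70/20/10 lateral/medial/cingulate over 1000 cells."""
        atlas, manifest = toy_atlas
        cp, cells, truth = synthetic.simulate_sections_and_cells(
            atlas, manifest, cells_per_group={"g": 1000},
            proportions={"g": {"lateral": 0.7, "medial": 0.2, "cingulate": 0.1}},
            pixel_noise_sigma=0.0, seed=12,
        )
        transforms = {
            sid: PlanarAffine3D(np.array(s["A"]), np.array(s["b"]))
            for sid, s in truth["sections"].items()
        }
        out = map_cells(transforms, cells, atlas, manifest["cortex"]["region_id"])
        counts = class_counts(out).set_index("ml_class")["n_cells"]
        assert counts["lateral"] == 700
        assert counts["medial"] == 200
        assert counts["cingulate"] == 100
        # per-cell agreement with planted truth, not just margins
        assert (out["ml_bin"].to_numpy() == truth["cells"]["true_bin"].to_numpy()).all()

    def test_bins_partition_in_extent_cells(self, toy_atlas):
        atlas, manifest = toy_atlas
        _, cells, truth = synthetic.simulate_sections_and_cells(
            atlas, manifest, cells_per_group={"g": 300},
            proportions={"g": {"lateral": 0.5, "medial": 0.3, "cingulate": 0.2}},
            pixel_noise_sigma=2.0, seed=4,
        )
        transforms = {
            sid: PlanarAffine3D(np.array(s["A"]), np.array(s["b"]))
            for sid, s in truth["sections"].items()
        }
        out = map_cells(transforms, cells, atlas, manifest["cortex"]["region_id"])
        in_ext = out[out["in_extent"]]
        assert int(in_ext.groupby("ml_bin", observed=True).size().sum()) == len(in_ext)
        # class is a pure function of bin, row-wise
        mapping = {0: "cingulate", 1: "medial", 2: "medial", 3: "lateral", 4: "lateral"}
        assert all(mapping[b] == c for b, c in zip(in_ext["ml_bin"], in_ext["ml_class"]))

    def test_binning_invariant_to_pixel_reparameterization(self, toy_atlas):
        """Rotating/scaling the pixel frame and refitting leaves all bins identical."""
        atlas, manifest = toy_atlas
        _, cells, truth = synthetic.simulate_sections_and_cells(
            atlas, manifest, cells_per_group={"g": 200},
            proportions={"g": {"lateral": 0.4, "medial": 0.4, "cingulate": 0.2}},
            pixel_noise_sigma=0.0, seed=8,
        )
        transforms = {
            sid: PlanarAffine3D(np.array(s["A"]), np.array(s["b"]))
            for sid, s in truth["sections"].items()
        }
        cid = manifest["cortex"]["region_id"]
        base = map_cells(transforms, cells, atlas, cid)

        # rigid in-plane reparameterization: u' = R s u + t
        theta, s, t = 0.7, 2.5, np.array([120.0, -40.0])
        R = s * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        from atlastrace.registration import fit_affine

        rng = np.random.default_rng(0)
        cells2 = cells.copy()
        transforms2 = {}
        for sid, tr in transforms.items():
            uv = rng.uniform(0, 2000, size=(6, 2))
            xyz = uv @ tr.A.T + tr.b
            transforms2[sid] = fit_affine(uv @ R.T + t, xyz)
        uv = cells[["u_px", "v_px"]].to_numpy()
        cells2[["u_px", "v_px"]] = uv @ R.T + t
        re = map_cells(transforms2, cells2, atlas, cid)
        assert (base["ml_bin"].to_numpy() == re["ml_bin"].to_numpy()).all()


class TestSummarizeDistribution:
    def test_identical_points_sem_zero(self):
        cells = pd.DataFrame({"group": "g", "x_um": [5.0] * 4, "y_um": [2.0] * 4})
        out = summarize_distribution(cells)
        assert out.loc[0, "sem_x_um"] == 0 and out.loc[0, "sem_z_um"] == 0

    def test_closed_form_sem(self):
        cells = pd.DataFrame({"group": "g", "x_um": [1.0, 2.0, 3.0], "y_um": [0.0] * 3})
        out = summarize_distribution(cells)
        assert out.loc[0, "mean_x_um"] == pytest.approx(2.0)
        assert out.loc[0, "sem_x_um"] == pytest.approx(1 / np.sqrt(3))

    def test_single_cell_group_warns_null_sem(self):
        cells = pd.DataFrame({"group": "g", "x_um": [1.0], "y_um": [1.0]})
        with pytest.warns(UserWarning, match="single cell"):
            out = summarize_distribution(cells)
        assert np.isnan(out.loc[0, "sem_x_um"])

    def test_mean_recovers_known_normal(self):
        """500 draws from N(mu, sd): sample mean within 3 SEM of mu (seeded)."""
        rng = np.random.default_rng(99)
        mu, sd, n = 3200.0, 400.0, 500
        cells = pd.DataFrame({
            "group": "g",
            "x_um": rng.normal(mu, sd, n),
            "y_um": rng.normal(mu, sd, n),
        })
        out = summarize_distribution(cells)
        assert abs(out.loc[0, "mean_x_um"] - mu) < 3 * out.loc[0, "sem_x_um"]
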