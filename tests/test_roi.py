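import numpy as np
import pytest

from msientropy import (
    EllipseROI,
    MaskROI,
    PolygonROI,
    annotate,
    ion_image,
    rank_candidates,
    resolve_roi,
    roi_channel_sums,
)
from msientropy.roi import parse_roi_file


class TestResolveRoi:
    def test_ellipse_covering_grid_selects_all(self, random_dataset):
        roi = EllipseROI(2, 2, 10, 10)
        assert resolve_roi(roi, random_dataset).size == 25

    def test_unit_polygon_selects_single_pixel(self, random_dataset):
        roi = PolygonROI(((1.5, 1.5), (2.5, 1.5), (2.5, 2.5), (1.5, 2.5)))
        idx = resolve_roi(roi, random_dataset)
        assert idx.size == 1
        np.testing.assert_array_equal(random_dataset.coords[idx[0]], [2, 2])

    def test_ellipse_matches_analytic_oracle(self, random_dataset):
        roi = EllipseROI(2.0, 1.5, 2.0, 1.2, rotation_deg=30.0)
        idx = set(resolve_roi(roi, random_dataset).tolist())
        theta = np.deg2rad(30.0)
        for i, (c, r) in enumerate(random_dataset.coords):
            dx, dy = c - 2.0, r - 1.5
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            inside = (u / 2.0) ** 2 + (v / 1.2) ** 2 <= 1.0
            assert (i in idx) == inside

    def test_mask_roi(self, random_dataset):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, :2] = True
        idx = resolve_roi(MaskROI(mask), random_dataset)
        assert {tuple(random_dataset.coords[i]) for i in idx} == {(0, 0), (1, 0)}

    def test_empty_intersection_rejected(self, random_dataset):
        with pytest.raises(ValueError, match="intersect"):
            resolve_roi(EllipseROI(50, 50, 1, 1), random_dataset)

    @pytest.mark.parametrize("content, expected_type", [
        ("shape=ellipse\ncenter_col=2\ncenter_row=2\nsemi_col=1\nsemi_row=1\n",
         EllipseROI),
        ("shape=polygon\nvertices=0:0;4:0;4:4;0:4\n", PolygonROI),
    ])
    def test_parse_roi_file(self, tmp_path, content, expected_type,
                            random_dataset):
        path = tmp_path / "roi.txt"
        path.write_text(content)
        roi = parse_roi_file(str(path))
        assert isinstance(roi, expected_type)
        assert resolve_roi(roi, random_dataset).size > 0

    def test_parse_mask_roi_file(self, tmp_path, random_dataset):
        np.savetxt(tmp_path / "mask.csv", np.eye(5), delimiter=",")
        (tmp_path / "roi.txt").write_text("shape=mask\npath=mask.csv\n")
        roi = parse_roi_file(str(tmp_path / "roi.txt"))
        assert resolve_roi(roi, random_dataset).size == 5


class TestChannelSums:
    def test_single_pixel(self, random_dataset):
        sums = roi_channel_sums(random_dataset, np.array([3]))
        np.testing.assert_allclose(sums, random_dataset.intensities[3])

    def test_two_identical_pixels_double(self, random_dataset):
        ds = random_dataset.replace(
            intensities=np.tile(random_dataset.intensities[:1], (25, 1)),
            coords=random_dataset.coords)
        sums = roi_channel_sums(ds, np.array([0, 1]))
        np.testing.assert_allclose(sums, 2 * ds.intensities[0], rtol=1e-12)

    def test_matches_loop_oracle(self, random_dataset, rng):
        pixels = rng.choice(25, size=10, replace=False)
        sums = roi_channel_sums(random_dataset, pixels)
        expected = np.zeros(random_dataset.n_channels)
        for i in pixels:
            expected += random_dataset.intensities[i]
        np.testing.assert_allclose(sums, expected, rtol=1e-12)

    def test_out_of_grid_rejected(self, random_dataset):
        with pytest.raises(ValueError, match="outside"):
            roi_channel_sums(random_dataset, np.array([99]))
        with pytest.raises(ValueError, match="empty"):
            roi_channel_sums(random_dataset, np.array([], dtype=int))


class TestRankCandidates:
    def test_identical_conditions_all_ratios_one(self, rng):
        sums = rng.gamma(2.0, 1.0, size=50)
        result = rank_candidates({"A": sums, "B": sums.copy()}, reference="A")
        np.testing.assert_allclose(result.table["ratio"], 1.0, rtol=1e-12)

    def test_planted_fold_attains_extremes(self, rng):
        base = rng.gamma(5.0, 1.0, size=100) + 1.0
        test = base.copy()
        test[17] *= 4.0
        test[60] *= 0.25
        result = rank_candidates({"young": base, "old": test},
                                 reference="young")
        assert result.top_channel == 17
        assert result.bottom_channel == 60
        assert result.max_ratio > 1.0 > result.min_ratio

    def test_rank_invariant_to_condition_rescaling(self, rng):
        a = rng.gamma(2.0, 1.0, size=40) + 0.1
        b = rng.gamma(2.0, 1.0, size=40) + 0.1
        r1 = rank_candidates({"A": a, "B": b}, reference="A")
        r2 = rank_candidates({"A": 3.7 * a, "B": 0.2 * b}, reference="A")
        np.testing.assert_array_equal(r1.table["rank"], r2.table["rank"])
        np.testing.assert_allclose(r1.table["ratio"], r2.table["ratio"],
                                   rtol=1e-12)

    def test_normalization_choice_shifts_ratios_by_constant(self, rng):
        a = rng.gamma(2.0, 1.0, size=40) + 0.1
        b = rng.gamma(2.0, 1.0, size=40) + 0.1
        r_cond = rank_candidates({"A": a, "B": b}, reference="A",
                                 normalize="condition_total")
        r_ref = rank_candidates({"A": a, "B": b}, reference="A",
                                normalize="reference_total")
        ratio_of_ratios = (r_ref.table["ratio"] / r_cond.table["ratio"]).to_numpy()
        np.testing.assert_allclose(ratio_of_ratios, ratio_of_ratios[0],
                                   rtol=1e-12)
        np.testing.assert_array_equal(r_cond.table["rank"], r_ref.table["rank"])

    def test_extremes_match_brute_force(self, rng):
        a = rng.gamma(2.0, 1.0, size=200) + 0.1
        b = rng.gamma(2.0, 1.0, size=200) + 0.1
        result = rank_candidates({"A": a, "B": b}, reference="A")
        ratios = (b / b.sum()) / (a / a.sum())
        assert result.top_channel == int(np.argmax(ratios))
        assert result.bottom_channel == int(np.argmin(ratios))

    def test_epsilon_guard_excludes_tiny_reference_sums(self):
        a = np.array([1.0, 1.0, 1e-20, 1.0])
        b = np.array([1.0, 2.0, 5.0, 0.5])
        result = rank_candidates({"A": a, "B": b}, reference="A")
        row = result.table.iloc[2]
        assert not row["defined"]
        assert np.isnan(row["rank"])
        assert result.top_channel != 2

    def test_validation(self):
        with pytest.raises(ValueError, match="reference"):
            rank_candidates({"A": np.ones(3)}, reference="Z")
        with pytest.raises(ValueError, match="two conditions"):
            rank_candidates({"A": np.ones(3)}, reference="A")
        with pytest.raises(ValueError, match="axis"):
            rank_candidates({"A": np.ones(3), "B": np.ones(4)}, reference="A")
        with pytest.raises(ValueError, match="all-zero"):
            rank_candidates({"A": np.zeros(3), "B": np.ones(3)}, reference="A")


class TestAnnotate:
    @pytest.mark.parametrize("observed, name, expected_ppm", [
        (766.4701, "PS(35:5)", 4.70),
        (778.5387, "PE-NMe(38:5)", 0.64),
    ])
    def test_reference_lipid_ppm_errors(self, lipid_table, observed, name,
                                        expected_ppm):
        hits = annotate(observed, lipid_table, tolerance=0.2)
        row = hits.loc[hits["name"] == name].iloc[0]
        assert round(float(row["ppm_error"]), 2) == expected_ppm

    def test_exact_match_zero_ppm(self, lipid_table):
        hits = annotate(885.5493, lipid_table, tolerance=0.2)
        assert round(float(hits.iloc[0]["ppm_error"]), 2) == 0.00
        assert hits.iloc[0]["name"] == "PI(38:4)"

    def test_tolerance_filters_and_sorts(self, lipid_table):
        hits = annotate(770.0, lipid_table, tolerance=10.0)
        assert list(hits["ppm_error"]) == sorted(hits["ppm_error"])
        assert len(annotate(770.0, lipid_table, tolerance=0.2)) == 0

    def test_empty_table_rejected(self, lipid_table):
        with pytest.raises(ValueError, match="empty"):
            annotate(700.0, lipid_table.iloc[:0], tolerance=0.2)


class TestIonImage:
    def test_single_channel_window(self, random_dataset):
        target = float(random_dataset.axis.centers[7])
        grid = ion_image(random_dataset, target, window=0.4)
        expected = random_dataset.to_grid(random_dataset.intensities[:, 7])
        np.testing.assert_allclose(grid, expected, rtol=1e-12)

    def test_full_window_is_total_ion_image(self, random_dataset):
        grid = ion_image(random_dataset, 560.0, window=100.0)
        expected = random_dataset.to_grid(random_dataset.intensities.sum(axis=1))
        np.testing.assert_allclose(grid, expected, rtol=1e-12)

    def test_matches_loop_oracle(self, random_dataset):
        target, window = 555.0, 2.3
        grid = ion_image(random_dataset, target, window)
        sel = np.abs(random_dataset.axis.centers - target) <= window
        for (c, r), spectrum in zip(random_dataset.coords,
                                    random_dataset.intensities):
            assert grid[r, c] == pytest.approx(spectrum[sel].sum(), rel=1e-12)

    def test_empty_window_rejected(self, random_dataset):
        with pytest.raises(ValueError, match="no channel"):
            ion_image(random_dataset, 400.0, window=0.1)
        with pytest.raises(ValueError, match="positive"):
            ion_image(random_dataset, 560.0, window=0.0)
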