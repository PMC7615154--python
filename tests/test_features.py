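"""Featurization: masked GLCM texture, spacing statistics, well extraction."""

import numpy as np
import pandas as pd
import pytest

from aceid.features import (
    extract_features,
    extract_well_features,
    spacing_features,
    texture_features,
)
from aceid.manifest import feature_names


# ---------------------------------------------------------------------------
# independent brute-force GLCM oracle
# ---------------------------------------------------------------------------


def glcm_oracle(image, mask, levels=16):
    """Explicit-loop co-occurrence statistics; independent of the package's
    vectorized implementation."""
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    vals = img[m]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.clip(((img - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    else:
        q = np.zeros(img.shape, dtype=int)
    h, w = img.shape
    out = []
    for dr, dc in [(0, 1), (-1, 1), (-1, 0), (-1, -1)]:
        P = np.zeros((levels, levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and m[r, c] and m[r2, c2]:
                    P[q[r, c], q[r2, c2]] += 1
                    P[q[r2, c2], q[r, c]] += 1
        if P.sum() == 0:
            continue
        P /= P.sum()
        i = np.arange(levels)[:, None]
        j = np.arange(levels)[None, :]
        pi = P.sum(axis=1)
        mu = (np.arange(levels) * pi).sum()
        var = ((np.arange(levels) - mu) ** 2 * pi).sum()
        corr = ((P * (i - mu) * (j - mu)).sum() / var) if var > 0 else 0.0
        nz = P[P > 0]
        out.append(
            {
                "contrast": (P * (i - j) ** 2).sum(),
                "correlation": corr,
                "energy": (P**2).sum(),
                "homogeneity": (P / (1 + (i - j) ** 2)).sum(),
                "entropy": -(nz * np.log(nz)).sum(),
            }
        )
    return {k: float(np.mean([d[k] for d in out])) for k in out[0]}


class TestTexture:
    def test_constant_region(self):
        tx = texture_features(np.full((8, 8), 5.0), np.ones((8, 8), bool))
        assert tx["contrast"] == 0.0
        assert tx["energy"] == 1.0
        assert tx["homogeneity"] == 1.0
        assert tx["entropy"] == 0.0
        assert tx["correlation"] == 0.0  # zero marginal variance, by convention

    def test_checkerboard_matches_enumeration(self):
        img = np.indices((4, 4)).sum(axis=0) % 2 * 10.0
        mask = np.ones((4, 4), bool)
        tx = texture_features(img, mask)
        oracle = glcm_oracle(img, mask)
        for k, v in oracle.items():
            assert tx[k] == pytest.approx(v, rel=1e-12), k

    def test_random_images_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            img = rng.integers(0, 200, size=(9, 11)).astype(float)
            mask = rng.random((9, 11)) > 0.3
            if mask.sum() < 4:
                continue
            tx = texture_features(img, mask)
            oracle = glcm_oracle(img, mask)
            for k, v in oracle.items():
                assert tx[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_transpose_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.random((12, 12))
        mask = np.ones((12, 12), bool)
        a = texture_features(img, mask)
        b = texture_features(img.T, mask.T)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_empty_mask_gives_nan(self):
        tx = texture_features(np.ones((4, 4)), np.zeros((4, 4), bool))
        assert all(np.isnan(v) for v in tx.values())


class TestSpacing:
    def test_square_lattice_nn_distance(self):
        s = 10.0
        pts = np.array([(r * s, c * s) for r in range(5) for c in range(5)])
        sp = spacing_features(pts, (100, 100), pixel_size_um=1.0)
        assert sp["nn_distance_mean_um"] == pytest.approx(s)
        assert sp["nn_distance_sd_um"] == pytest.approx(0.0, abs=1e-9)
        assert sp["cell_count"] == 25

    def test_empty_population(self):
        sp = spacing_features(np.empty((0, 2)), (100, 100))
        assert sp["cell_count"] == 0
        assert np.isnan(sp["nn_distance_mean_um"])
        assert np.isnan(sp["clark_evans_ratio"])

    def test_single_cell_has_no_nn(self):
        sp = spacing_features(np.array([[5.0, 5.0]]), (100, 100))
        assert sp["cell_count"] == 1
        assert np.isnan(sp["nn_distance_mean_um"])

    def test_poisson_clark_evans_near_one(self):
        """Complete spatial randomness: Clark–Evans ratio 1.0 +/- 0.1 at n=500."""
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 1000, size=(500, 2))
        sp = spacing_features(pts, (1000, 1000), pixel_size_um=1.0)
        assert sp["clark_evans_ratio"] == pytest.approx(1.0, abs=0.1)


class TestExtraction:
    def test_hand_computed_cell_mean(self):
        """A 3x3 'cell' holding marker values 1..9 has per-cell mean 5."""
        from aceid.segmentation import partition_zones
        from aceid.simulate import ImageSet
        from aceid.spots import SpotSet

        marker = np.zeros((8, 8), dtype=np.uint16)
        marker[2:5, 2:5] = np.arange(1, 10).reshape(3, 3)
        nuclei_img = np.zeros((8, 8), dtype=np.uint16)
        cells = np.zeros((8, 8), dtype=np.int32)
        cells[2:5, 2:5] = 1
        nuclei = np.zeros((8, 8), dtype=np.int32)
        nuclei[3, 3] = 1
        zones = partition_zones(cells, nuclei)
        images = ImageSet(nuclei=nuclei_img, marker=marker, pixel_size_um=1.0)
        empty = SpotSet(pd.DataFrame(columns=["spot_id", "cell_id", "zone", "row", "col",
                                              "area_px", "area_um2", "intensity"]),
                        (1, 5), 0.0)
        row = extract_features(images, nuclei, cells, zones, empty, "dextran")
        assert row["dextran_marker_whole_cell_intensity_mean_median"] == pytest.approx(5.0)
        assert row["dextran_marker_whole_cell_intensity_integrated_median"] == pytest.approx(45.0)
        assert row["dextran_marker_whole_cell_spots_count_median"] == 0.0

    def test_row_covers_manifest(self, segmented_fixture):
        well = segmented_fixture[0]
        row = extract_features(
            well["images"], well["nuclei"], well["cells"], well["zones"], well["spots"], "dextran"
        )
        assert list(row.index[:-1]) == feature_names()
        assert row.index[-1] == "cell_count"
        # dextran + shared nuclei blocks populated; other assays missing
        assert row.filter(like="dextran_marker_").notna().all()
        assert row.filter(like="transferrin_marker_").isna().all()
        assert row["nuclei_common_nuclei_population_spacing_cell_count"] == row["cell_count"]

    def test_extraction_deterministic(self, standard_fixture):
        images = standard_fixture[0][0]
        a = extract_well_features(images, "dextran")
        b = extract_well_features(images, "dextran")
        pd.testing.assert_series_equal(a, b)

    def test_intensity_scales_morphology_invariant(self, segmented_fixture):
        """Doubling intensities doubles intensity features and leaves
        morphology and texture energy unchanged."""
        from aceid.simulate import ImageSet

        well = segmented_fixture[0]
        images = well["images"]
        scaled = ImageSet(
            nuclei=(images.nuclei.astype(float) * 2).astype(np.uint16),
            marker=(images.marker.astype(float) * 2).astype(np.uint16),
            pixel_size_um=images.pixel_size_um,
        )
        args = (well["nuclei"], well["cells"], well["zones"], well["spots"])
        a = extract_features(images, *args, "dextran")
        b = extract_features(scaled, *args, "dextran")
        assert b["dextran_marker_whole_cell_intensity_mean_median"] == pytest.approx(
            2 * a["dextran_marker_whole_cell_intensity_mean_median"], rel=1e-3
        )
        assert b["nuclei_common_nuclei_nucleus_morphology_area_um2_median"] == (
            a["nuclei_common_nuclei_nucleus_morphology_area_um2_median"]
        )
        assert b["nuclei_common_nuclei_nucleus_texture_energy_median"] == pytest.approx(
            a["nuclei_common_nuclei_nucleus_texture_energy_median"], rel=0.02
        )
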