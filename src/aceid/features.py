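"""Per-well phenotypic featurization against the 850-feature manifest.

Per-cell measures (morphology, region intensities, masked co-occurrence
texture, per-region spot statistics) are aggregated to well level by the
statistic each manifest entry names — the median across cells by default,
with the cross-cell SD as a companion — plus population-level
spacing/clustering features.  A well only fills the manifest columns of
its own assay (and the shared nuclei-stain block); all other columns are
emitted as missing and resolved when replicates are joined across assays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import spatial
from skimage import measure

from aceid.manifest import TEXTURE_MEASURES, SPACING_MEASURES, feature_names
from aceid.segmentation import (
    ZonePartition,
    exclude_border_cells,
    partition_zones,
    segment_cells,
    segment_nuclei,
)
from aceid.simulate import ImageSet
from aceid.spots import SpotSet, detect_spots

__all__ = [
    "texture_features",
    "spacing_features",
    "extract_features",
    "extract_well_features",
]

_GLCM_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees


def texture_features(image: np.ndarray, mask: np.ndarray, *, levels: int = 16) -> dict:
    """Gray-level co-occurrence texture statistics within a mask.

    The masked pixels are quantized to ``levels`` gray levels between their
    min and max; co-occurrences are counted symmetrically at offset 1 px in
    four directions (only pairs with both pixels in the mask) and the five
    statistics — contrast, correlation, energy (angular second moment),
    homogeneity (inverse difference moment) and entropy (natural log) —
    are averaged over directions.

    Degenerate cases: an empty mask yields all-NaN; a constant region has
    contrast 0, energy 1, homogeneity 1, entropy 0, and correlation is
    defined as 0 (zero marginal variance).
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return {k: float("nan") for k in TEXTURE_MEASURES}
    vals = img[m]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q = np.clip(((img - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    else:
        q = np.zeros(img.shape, dtype=int)

    per_dir = []
    for dr, dc in _GLCM_DIRECTIONS:
        a, am, b, bm = _shift_pair(q, m, dr, dc)
        valid = am & bm
        if not valid.any():
            continue
        P = np.zeros((levels, levels))
        np.add.at(P, (a[valid], b[valid]), 1.0)
        P = P + P.T  # symmetric counting
        P /= P.sum()
        per_dir.append(_glcm_stats(P, levels))
    if not per_dir:
        return {k: float("nan") for k in TEXTURE_MEASURES}
    return {k: float(np.mean([d[k] for d in per_dir])) for k in TEXTURE_MEASURES}


def _shift_pair(q, m, dr, dc):
    """Align (q, m) with its copy shifted by (dr, dc)."""
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    am = m[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    bm = m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a, am, b, bm


def _glcm_stats(P: np.ndarray, levels: int) -> dict:
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    diff2 = (i - j) ** 2
    pi = P.sum(axis=1)
    mu_i = float((np.arange(levels) * pi).sum())
    var_i = float(((np.arange(levels) - mu_i) ** 2 * pi).sum())
    # symmetric matrix: both marginals identical
    if var_i > 0:
        corr = float((P * (i - mu_i) * (j - mu_i)).sum() / var_i)
    else:
        corr = 0.0
    nz = P[P > 0]
    return {
        "contrast": float((P * diff2).sum()),
        "correlation": corr,
        "energy": float((P**2).sum()),
        "homogeneity": float((P / (1.0 + diff2)).sum()),
        "entropy": float(-(nz * np.log(nz)).sum()),
    }


def spacing_features(
    centroids: np.ndarray, image_shape: tuple, pixel_size_um: float = 1.0
) -> dict:
    """Population spacing/clustering features from cell centroids.

    Includes count, density per mm^2, nearest-neighbor distance summary,
    the Clark–Evans aggregation ratio (observed mean NN distance over the
    0.5/sqrt(density) expected under complete spatial randomness),
    neighbor counts within 50/100 um, and convex-hull occupancy of the
    imaged field.  With fewer than 2 cells the NN features are missing.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float)) * pixel_size_um
    if pts.size == 0:
        pts = np.empty((0, 2))
    n = len(pts)
    area_um2 = image_shape[0] * image_shape[1] * pixel_size_um**2
    out = {k: float("nan") for k in SPACING_MEASURES}
    out["cell_count"] = float(n)
    out["cell_density_per_mm2"] = n / (area_um2 / 1e6)
    if n >= 2:
        tree = spatial.cKDTree(pts)
        nn, _ = tree.query(pts, k=2)
        d = nn[:, 1]
        out["nn_distance_mean_um"] = float(d.mean())
        out["nn_distance_sd_um"] = float(d.std(ddof=1)) if n > 1 else float("nan")
        out["nn_distance_cv"] = (
            out["nn_distance_sd_um"] / out["nn_distance_mean_um"]
            if out["nn_distance_mean_um"] > 0
            else float("nan")
        )
        out["nn_distance_median_um"] = float(np.median(d))
        out["nn_distance_min_um"] = float(d.min())
        out["nn_distance_max_um"] = float(d.max())
        density = n / area_um2
        out["clark_evans_ratio"] = float(d.mean() / (0.5 / np.sqrt(density)))
        for radius in (50.0, 100.0):
            counts = np.array([len(tree.query_ball_point(p, radius)) - 1 for p in pts], dtype=float)
            out[f"neighbors_within_{int(radius)}um_mean"] = float(counts.mean())
            out[f"neighbors_within_{int(radius)}um_sd"] = (
                float(counts.std(ddof=1)) if n > 1 else float("nan")
            )
    if n >= 3:
        try:
            hull = spatial.ConvexHull(pts)
            out["convex_hull_occupancy"] = float(hull.volume / area_um2)
        except spatial.QhullError:
            pass
    return out


def _region_masks(cell_region, nucleus_region, zones_crop, n_zones):
    peri_hi = n_zones // 2
    cyto = cell_region & (zones_crop > 0)
    masks = {
        "whole_cell": cell_region,
        "nucleus": nucleus_region,
        "cytoplasm": cyto,
        "perinuclear": cell_region & (zones_crop >= 1) & (zones_crop <= peri_hi),
    }
    for k in range(1, n_zones + 1):
        masks[f"zone{k}"] = cell_region & (zones_crop == k)
    return masks


def _intensity_stats(vals: np.ndarray) -> dict:
    if vals.size == 0:
        return {m: float("nan") for m in ("mean", "integrated", "sd", "mad")}
    med = np.median(vals)
    return {
        "mean": float(vals.mean()),
        "integrated": float(vals.sum()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "mad": float(np.median(np.abs(vals - med))),
    }


def _morphology(region) -> dict:
    per = region.perimeter
    major, minor = region.axis_major_length, region.axis_minor_length
    return {
        "area_px": float(region.area),
        "perimeter_px": float(per),
        "roundness": float(4 * np.pi * region.area / per**2) if per > 0 else float("nan"),
        "eccentricity": float(region.eccentricity),
        "solidity": float(region.solidity),
        "major_axis_px": float(major),
        "minor_axis_px": float(minor),
        "aspect_ratio": float(major / minor) if minor > 0 else float("nan"),
        "extent": float(region.extent),
        "equivalent_diameter_px": float(region.equivalent_diameter_area),
    }


_MORPH_TO_MANIFEST = {
    "area_um2": ("area_px", 2),  # (pixel measure, pixel-size exponent)
    "perimeter_um": ("perimeter_px", 1),
    "roundness": ("roundness", 0),
    "eccentricity": ("eccentricity", 0),
    "solidity": ("solidity", 0),
    "major_axis_um": ("major_axis_px", 1),
    "minor_axis_um": ("minor_axis_px", 1),
    "aspect_ratio": ("aspect_ratio", 0),
    "extent": ("extent", 0),
    "equivalent_diameter_um": ("equivalent_diameter_px", 1),
}

_SPOT_REGION_ZONES = {
    "whole_cell": None,  # all of the cell's spots
    "cytoplasm": "cyto",  # zone >= 1
    "perinuclear": "peri",
    "zone1": 1,
    "zone2": 2,
    "zone3": 3,
    "zone4": 4,
}


def extract_features(
    image_set: ImageSet,
    nuclei_mask: np.ndarray,
    cell_mask: np.ndarray,
    zones: ZonePartition,
    spot_set: SpotSet,
    assay: str,
) -> pd.Series:
    """One well's row of the 850-feature table.

    Fills the shared nuclei-stain block and the marker block of ``assay``;
    every other manifest column is NaN.  Cells without a valid zone
    partition (border-excluded or multi-nucleus) do not contribute.
    Returns a Series over the manifest columns plus ``cell_count``.
    """
    names = feature_names()
    row = pd.Series(np.nan, index=names, dtype=float)
    px = image_set.pixel_size_um
    n_zones = zones.n_zones

    valid_cells = sorted(zones.zone_areas)
    nuc_props = {r.label: r for r in measure.regionprops(nuclei_mask)}
    cell_props = {r.label: r for r in measure.regionprops(cell_mask)}

    percell: dict[str, list] = {}

    def push(key: str, value: float) -> None:
        percell.setdefault(key, []).append(value)

    spot_df = spot_set.table
    for cid in valid_cells:
        creg = cell_props.get(cid)
        # matched nucleus: the single nucleus inside this cell
        in_cell = cell_mask == cid
        nuc_ids = np.unique(nuclei_mask[in_cell])
        nuc_ids = nuc_ids[nuc_ids > 0]
        if creg is None or len(nuc_ids) != 1:
            continue
        nreg = nuc_props[int(nuc_ids[0])]

        # ---- morphology (nuclei-stain block) ----
        for region_name, props in (("nucleus", nreg), ("whole_cell", creg)):
            m = _morphology(props)
            for mf, (pm, exp) in _MORPH_TO_MANIFEST.items():
                push(f"nuclei_common_nuclei_{region_name}_morphology_{mf}", m[pm] * px**exp)
        push(
            "nuclei_common_nuclei_cytoplasm_morphology_area_um2",
            (creg.area - nreg.area) * px**2,
        )

        # ---- region masks on a crop around the cell ----
        rs, cs = _bbox_slices(creg.bbox, cell_mask.shape, pad=1)
        cell_crop = cell_mask[rs, cs] == cid
        nuc_crop = (nuclei_mask[rs, cs] == nreg.label) & cell_crop
        zones_crop = zones.zones[rs, cs]
        masks = _region_masks(cell_crop, nuc_crop, zones_crop, n_zones)

        # ---- nuclei-channel intensity + texture ----
        nuc_img = image_set.nuclei[rs, cs].astype(float)
        for region_name in ("nucleus", "whole_cell", "cytoplasm"):
            st = _intensity_stats(nuc_img[masks[region_name]])
            for meas in ("mean", "integrated", "sd", "mad"):
                push(f"nuclei_common_nuclei_{region_name}_intensity_{meas}", st[meas])
        for region_name in ("nucleus", "whole_cell"):
            tx = texture_features(nuc_img, masks[region_name])
            for meas, val in tx.items():
                push(f"nuclei_common_nuclei_{region_name}_texture_{meas}", val)

        # ---- marker-channel intensity, ratios, texture, spots ----
        mk_img = image_set.marker[rs, cs].astype(float)
        stats_by_region = {}
        for region_name, m in masks.items():
            st = _intensity_stats(mk_img[m])
            stats_by_region[region_name] = st
            for meas in ("mean", "integrated", "sd"):
                push(f"{assay}_marker_{region_name}_intensity_{meas}", st[meas])

        cyto_int = stats_by_region["cytoplasm"]["integrated"]
        peri_int = stats_by_region["perinuclear"]["integrated"]
        push(
            f"{assay}_marker_perinuclear_intensity_perinuclear_intensity_fraction",
            peri_int / cyto_int if cyto_int else float("nan"),
        )
        cell_mean = stats_by_region["whole_cell"]["mean"]
        push(
            f"{assay}_marker_nucleus_intensity_nucleus_cell_mean_ratio",
            stats_by_region["nucleus"]["mean"] / cell_mean if cell_mean else float("nan"),
        )
        for k in range(1, n_zones + 1):
            zint = stats_by_region[f"zone{k}"]["integrated"]
            push(
                f"{assay}_marker_zone{k}_intensity_zone_intensity_fraction",
                zint / cyto_int if cyto_int else float("nan"),
            )
        for region_name in ("whole_cell", "cytoplasm"):
            tx = texture_features(mk_img, masks[region_name])
            for meas, val in tx.items():
                push(f"{assay}_marker_{region_name}_texture_{meas}", val)

        cell_spots = (
            spot_df[spot_df["cell_id"] == cid] if len(spot_df) else spot_df
        )
        peri_hi = n_zones // 2
        for region_name, sel in _SPOT_REGION_ZONES.items():
            if len(cell_spots) == 0:
                sub = cell_spots
            elif sel is None:
                sub = cell_spots
            elif sel == "cyto":
                sub = cell_spots[cell_spots["zone"] >= 1]
            elif sel == "peri":
                sub = cell_spots[(cell_spots["zone"] >= 1) & (cell_spots["zone"] <= peri_hi)]
            else:
                sub = cell_spots[cell_spots["zone"] == sel]
            area_um2 = float(masks[region_name].sum()) * px**2
            count = float(len(sub))
            total_area = float(sub["area_um2"].sum()) if count else 0.0
            vals = {
                "count": count,
                "total_area_um2": total_area,
                "density_per_100um2": (count / area_um2 * 100.0) if area_um2 > 0 else float("nan"),
                "mean_area_um2": (total_area / count) if count else 0.0,
                "integrated_intensity": float(sub["intensity"].sum()) if count else 0.0,
            }
            for meas, val in vals.items():
                push(f"{assay}_marker_{region_name}_spots_{meas}", val)

    # ---- aggregate per-cell measures to well level ----
    for key, values in percell.items():
        arr = np.asarray(values, dtype=float)
        ok = arr[np.isfinite(arr)]
        med = float(np.median(ok)) if ok.size else float("nan")
        sd = float(ok.std(ddof=1)) if ok.size > 1 else float("nan")
        if f"{key}_median" in row.index:
            row[f"{key}_median"] = med
        if f"{key}_sd" in row.index:
            row[f"{key}_sd"] = sd

    # ---- population spacing (nuclei-stain block) ----
    centroids = np.array([cell_props[c].centroid for c in valid_cells if c in cell_props])
    sp = spacing_features(centroids, image_set.nuclei.shape, px)
    for meas, val in sp.items():
        row[f"nuclei_common_nuclei_population_spacing_{meas}"] = val

    row["cell_count"] = float(len(valid_cells))
    return row


def _bbox_slices(bbox, shape, pad=0):
    r0, c0, r1, c1 = bbox
    return (
        slice(max(0, r0 - pad), min(shape[0], r1 + pad)),
        slice(max(0, c0 - pad), min(shape[1], c1 + pad)),
    )


def extract_well_features(
    image_set: ImageSet,
    assay: str,
    *,
    n_zones: int = 4,
    max_expansion_px: float = 15.0,
    spot_kwargs: dict | None = None,
) -> pd.Series:
    """Segment, zone, detect spots and featurize one well in one call."""
    nuclei = segment_nuclei(image_set.nuclei)
    cells = exclude_border_cells(segment_cells(nuclei, max_expansion_px=max_expansion_px))
    nuclei = np.where(cells > 0, nuclei, 0)
    zones = partition_zones(cells, nuclei, n_zones=n_zones)
    spot_set = detect_spots(
        image_set.marker,
        cells,
        zones,
        pixel_size_um=image_set.pixel_size_um,
        **(spot_kwargs or {}),
    )
    return extract_features(image_set, nuclei, cells, zones, spot_set, assay)
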