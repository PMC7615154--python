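"""The 850-feature phenotypic fingerprint manifest.

Each treated cell population is described by exactly 850 named features
spanning five families — morphology, intensity, texture, spots (puncta) and
spacing (cell clustering) — measured on the nuclei stain common to every
assay and on the marker channel of each of the five imaging assays
(functional delivery, LNP uptake, transferrin, 70 kDa dextran, protein
synthesis).

The taxonomy is deliberate and versioned:

* ``nuclei_common`` block (100 features): nuclear & whole-cell morphology,
  nuclei-stain intensity and texture, and population spacing/clustering.
  These are measured from the nuclei channel of every assay's wells and
  aggregated across assays when replicates are joined.
* per-assay marker block (150 features x 5 assays): intensity in eight
  regions (whole cell, nucleus, cytoplasm, four concentric cytoplasmic
  zones, and the perinuclear region = inner half of the cytoplasm width),
  intensity-distribution ratios, texture, and spot features per region —
  including the headline perinuclear dextran spot total-area and density.

Per-cell measures are aggregated to well level by the statistic named in
each definition (median across cells by default, with the cross-cell SD as
a companion feature).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import pandas as pd

__all__ = [
    "FeatureDef",
    "feature_manifest",
    "manifest_frame",
    "feature_names",
    "MANIFEST_VERSION",
    "DEFAULT_INFORMATIVE_FEATURES",
    "N_FEATURES",
]

MANIFEST_VERSION = "1.0"
N_FEATURES = 850

ASSAY_BLOCKS = ("delivery", "lnp_uptake", "transferrin", "dextran", "protein_synthesis")

MORPHOLOGY_MEASURES = (
    "area_um2",
    "perimeter_um",
    "roundness",
    "eccentricity",
    "solidity",
    "major_axis_um",
    "minor_axis_um",
    "aspect_ratio",
    "extent",
    "equivalent_diameter_um",
)
INTENSITY_MEASURES = ("mean", "integrated", "sd", "mad")
MARKER_INTENSITY_MEASURES = ("mean", "integrated", "sd")
TEXTURE_MEASURES = ("contrast", "correlation", "energy", "homogeneity", "entropy")
SPOT_MEASURES = (
    "count",
    "total_area_um2",
    "density_per_100um2",
    "mean_area_um2",
    "integrated_intensity",
)
SPACING_MEASURES = (
    "cell_count",
    "cell_density_per_mm2",
    "nn_distance_mean_um",
    "nn_distance_sd_um",
    "nn_distance_cv",
    "nn_distance_median_um",
    "nn_distance_min_um",
    "nn_distance_max_um",
    "clark_evans_ratio",
    "neighbors_within_50um_mean",
    "neighbors_within_50um_sd",
    "neighbors_within_100um_mean",
    "neighbors_within_100um_sd",
    "convex_hull_occupancy",
)
# region in which each intensity-distribution ratio is reported
RATIO_MEASURES = {
    "perinuclear_intensity_fraction": "perinuclear",
    "nucleus_cell_mean_ratio": "nucleus",
    "zone_intensity_fraction": ("zone1", "zone2", "zone3", "zone4"),
}
MARKER_REGIONS = (
    "whole_cell",
    "nucleus",
    "cytoplasm",
    "zone1",
    "zone2",
    "zone3",
    "zone4",
    "perinuclear",
)
SPOT_REGIONS = ("whole_cell", "cytoplasm", "zone1", "zone2", "zone3", "zone4", "perinuclear")
AGGREGATES = ("median", "sd")


@dataclass(frozen=True)
class FeatureDef:
    """One named feature: what is measured, where, and how it is aggregated."""

    name: str
    assay: str  # delivery | lnp_uptake | transferrin | dextran | protein_synthesis | nuclei_common
    channel: str  # nuclei | marker
    region: str  # whole_cell | nucleus | cytoplasm | zone1..zone4 | perinuclear | population
    family: str  # morphology | intensity | texture | spots | spacing
    statistic: str  # well-level aggregation of the per-cell measure
    measure: str  # the per-cell (or population) quantity


def _name(assay: str, channel: str, region: str, family: str, measure: str, agg: str) -> str:
    parts = [assay, channel, region, family, measure]
    if agg != "population":
        parts.append(agg)
    return "_".join(parts)


def _emit(defs, assay, channel, region, family, measure, agg="median"):
    defs.append(
        FeatureDef(
            name=_name(assay, channel, region, family, measure, agg),
            assay=assay,
            channel=channel,
            region=region,
            family=family,
            statistic=agg,
            measure=measure,
        )
    )


@lru_cache(maxsize=1)
def feature_manifest() -> tuple:
    """The full, ordered, versioned manifest of 850 feature definitions.

    Deterministic: the same tuple (same order, same names) on every call.
    """
    defs: list[FeatureDef] = []

    # --- nuclei_common block: 100 features -------------------------------
    a, ch = "nuclei_common", "nuclei"
    for region in ("nucleus", "whole_cell"):
        for m in MORPHOLOGY_MEASURES:
            for agg in AGGREGATES:
                _emit(defs, a, ch, region, "morphology", m, agg)  # 2*10*2 = 40
    for agg in AGGREGATES:
        _emit(defs, a, ch, "cytoplasm", "morphology", "area_um2", agg)  # 2
    for region in ("nucleus", "whole_cell", "cytoplasm"):
        for m in INTENSITY_MEASURES:
            for agg in AGGREGATES:
                _emit(defs, a, ch, region, "intensity", m, agg)  # 3*4*2 = 24
    for region in ("nucleus", "whole_cell"):
        for m in TEXTURE_MEASURES:
            for agg in AGGREGATES:
                _emit(defs, a, ch, region, "texture", m, agg)  # 2*5*2 = 20
    for m in SPACING_MEASURES:
        _emit(defs, a, ch, "population", "spacing", m, "population")  # 14

    # --- per-assay marker blocks: 150 features x 5 -----------------------
    for a in ASSAY_BLOCKS:
        ch = "marker"
        for region in MARKER_REGIONS:
            for m in MARKER_INTENSITY_MEASURES:
                for agg in AGGREGATES:
                    _emit(defs, a, ch, region, "intensity", m, agg)  # 8*3*2 = 48
        for m, regions in RATIO_MEASURES.items():
            for region in (regions,) if isinstance(regions, str) else regions:
                for agg in AGGREGATES:
                    _emit(defs, a, ch, region, "intensity", m, agg)  # 6*2 = 12
        for region in ("whole_cell", "cytoplasm"):
            for m in TEXTURE_MEASURES:
                for agg in AGGREGATES:
                    _emit(defs, a, ch, region, "texture", m, agg)  # 2*5*2 = 20
        for region in SPOT_REGIONS:
            for m in SPOT_MEASURES:
                for agg in AGGREGATES:
                    _emit(defs, a, ch, region, "spots", m, agg)  # 7*5*2 = 70

    names = [d.name for d in defs]
    assert len(defs) == N_FEATURES, f"manifest has {len(defs)} features, expected {N_FEATURES}"
    assert len(set(names)) == len(names), "duplicate feature names in manifest"
    return tuple(defs)


def feature_names() -> list:
    """Manifest feature names, in manifest order."""
    return [d.name for d in feature_manifest()]


def manifest_frame() -> pd.DataFrame:
    """Manifest as a DataFrame (one row per feature), for CSV export."""
    df = pd.DataFrame([vars(d) for d in feature_manifest()])
    df.attrs["manifest_version"] = MANIFEST_VERSION
    return df


# Default delivery-predictive phenotype: larger, rounder, more intensely
# stained nuclei; more perinuclear dextran spot area and density; plus one
# readout from each remaining assay.  Used by the synthetic generator as the
# planted informative set.
DEFAULT_INFORMATIVE_FEATURES = (
    "nuclei_common_nuclei_nucleus_morphology_area_um2_median",
    "nuclei_common_nuclei_nucleus_morphology_roundness_median",
    "nuclei_common_nuclei_nucleus_intensity_mean_median",
    "nuclei_common_nuclei_nucleus_intensity_integrated_median",
    "nuclei_common_nuclei_whole_cell_intensity_mean_median",
    "dextran_marker_perinuclear_spots_total_area_um2_median",
    "dextran_marker_perinuclear_spots_density_per_100um2_median",
    "protein_synthesis_marker_whole_cell_intensity_mean_median",
    "lnp_uptake_marker_whole_cell_intensity_mean_median",
    "transferrin_marker_whole_cell_texture_correlation_median",
)
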