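"""End-to-end orchestration: simulate -> segment -> extract -> screen -> ml.

Each stage reads its parameters from a :class:`~aceid.config.RunConfig`,
writes its outputs under the run directory, and stamps them with the
config hash.  A stage whose upstream artifacts are missing raises
:class:`DependencyError` naming the stage that must run first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from aceid import io as aio
from aceid.config import RunConfig
from aceid.decay import fit_density_decay, normalize_by_density
from aceid.design import generate_design, parse_well
from aceid.features import extract_well_features
from aceid.ml import prepare_dataset, rfe_select, smote_oversample, split_stratified, train_and_evaluate
from aceid.screen import call_hits
from aceid.simulate import (
    EffectModel,
    Optics,
    render_well_images,
    simulate_screen,
    simulate_well_truth,
)

__all__ = ["run_pipeline", "validate_inputs", "smoke_config", "DependencyError", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "extract", "screen", "ml")


class DependencyError(RuntimeError):
    """An upstream stage's outputs are missing."""

    def __init__(self, stage: str, missing: str, needed_by: str):
        super().__init__(
            f"stage {needed_by!r} needs {missing} — run stage {stage!r} first"
        )
        self.stage = stage


def smoke_config(seed: int = 0) -> RunConfig:
    """A minimal end-to-end configuration: 4 conditions x 2 replicates,
    64x64 px wells with small cells — completes in seconds."""
    cfg = RunConfig(seed=seed)
    cfg.design = {
        "n_test_conditions": 4,
        "n_positive_conditions": 2,
        "replicate_allocation": {f"C{i:03d}": 3 for i in range(1, 5)},
        "n_control_replicates": 12,
        "control_density_series": [500, 2000, 3500, 5000, 6500, 8000],
        "density_series_replicates": 2,
        "assays": ["delivery", "dextran"],
    }
    cfg.optics = {"shape": [64, 64]}
    cfg.simulate.update(
        {"n_cells_per_well": 3, "nucleus_radius_px": 4.0, "cell_radius_px": 9.0, "noise_cv": 0.1}
    )
    cfg.segmentation.update({"min_area_px": 10, "min_peak_distance": 4, "max_expansion_px": 6.0})
    cfg.effects["delivery_multiplier"] = 2.0
    return cfg


def _design(config: RunConfig):
    overrides = dict(config.design)
    if "control_density_series" in overrides:
        overrides["control_density_series"] = tuple(overrides["control_density_series"])
    if "assays" in overrides:
        overrides["assays"] = tuple(overrides["assays"])
    return generate_design(**overrides)


def _optics(config: RunConfig) -> Optics:
    kw = dict(config.optics)
    if "shape" in kw:
        kw["shape"] = tuple(kw["shape"])
    return Optics(**kw)


def _effects(config: RunConfig, design) -> dict:
    mult = float(config.effects.get("delivery_multiplier", 1.5))
    shift = float(config.effects.get("feature_shift", 1.5))
    pos = set(design.positive_conditions)
    return {
        c: EffectModel.default_positive(mult, shift) if c in pos else EffectModel.null()
        for c in design.condition_ids
    }


def _stamp(outdir: Path, config: RunConfig) -> None:
    (outdir / "config_hash.txt").write_text(config.config_hash() + "\n")


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    design = _design(config)
    optics = _optics(config)
    effects = _effects(config, design)
    sim = config.simulate
    seed = config.stage_seed("simulate")

    screen_table = simulate_screen(
        design,
        effects,
        noise_cv=float(sim.get("noise_cv", 0.15)),
        seed=seed,
    )
    aio.write_table(screen_table, outdir / "screen_table.csv")

    if not sim.get("render_images", True):
        return
    img_root = outdir / "images"
    truth_root = outdir / "truth"
    rng = np.random.default_rng(seed + 1)
    n_nominal = int(sim.get("n_cells_per_well", 9))
    pos = set(design.positive_conditions)
    for assay in design.assays:
        layout = simulate_screen(design, effects, seed=seed, assay=assay)
        aio.write_plate_map(
            layout[aio.PLATE_MAP_COLUMNS], outdir / f"plate_map_{assay}.csv"
        )
        (img_root / assay).mkdir(parents=True, exist_ok=True)
        (truth_root / assay).mkdir(parents=True, exist_ok=True)
        for _, well in layout.iterrows():
            n_cells = max(
                1, round(n_nominal * well.seeded_cells / design.nominal_density)
            )
            positive = well.role == "test" and well.condition_id in pos
            truth = None
            while truth is None and n_cells >= 1:
                try:
                    truth = simulate_well_truth(
                        n_cells,
                        optics,
                        rng,
                        nucleus_radius_px=float(sim.get("nucleus_radius_px", 8.0))
                        * (1.1 if positive else 1.0),
                        cell_radius_px=float(sim.get("cell_radius_px", 20.0)),
                        nucleus_amplitude=3000.0 * (1.25 if positive else 1.0),
                        mcherry_mean=float(well.delivery),
                        spot_zone_weights=(0.4, 0.4, 0.1, 0.1)
                        if positive
                        else (0.25, 0.25, 0.25, 0.25),
                        min_spot_separation_px=8.0,
                    )
                except RuntimeError:
                    n_cells -= 1  # field too crowded at this density
            images = render_well_images(truth, optics, rng)
            stem = f"{well.plate}_{well.well}"
            aio.write_well_tiff(images, img_root / assay / f"{stem}.tif", assay=assay)
            aio.write_truth(truth, truth_root / assay / f"{stem}.truth.json")


def stage_segment(config: RunConfig, outdir: Path) -> None:
    from aceid.segmentation import (
        exclude_border_cells,
        partition_zones,
        segment_cells,
        segment_nuclei,
    )
    from aceid.spots import detect_spots
    import tifffile

    img_root = outdir / "images"
    if not img_root.exists():
        raise DependencyError("simulate", "well images", "segment")
    seg = config.segmentation
    spot_kw = dict(config.spots)
    if "sigma_range" in spot_kw:
        spot_kw["sigma_range"] = tuple(spot_kw["sigma_range"])
    mask_root = outdir / "masks"
    spot_tables = []
    for assay_dir in sorted(img_root.iterdir()):
        (mask_root / assay_dir.name).mkdir(parents=True, exist_ok=True)
        for tif in sorted(assay_dir.glob("*.tif")):
            images, _ = aio.read_well_tiff(tif)
            nuclei = segment_nuclei(
                images.nuclei,
                smoothing_sigma=float(seg.get("smoothing_sigma", 2.0)),
                min_area_px=int(seg.get("min_area_px", 40)),
                min_peak_distance=int(seg.get("min_peak_distance", 7)),
            )
            cells = exclude_border_cells(
                segment_cells(nuclei, max_expansion_px=float(seg.get("max_expansion_px", 15.0)))
            )
            nuclei = np.where(cells > 0, nuclei, 0)
            zones = partition_zones(cells, nuclei, n_zones=int(seg.get("n_zones", 4)))
            spot_set = detect_spots(
                images.marker, cells, zones, pixel_size_um=images.pixel_size_um, **spot_kw
            )
            stem = tif.stem
            tifffile.imwrite(
                mask_root / assay_dir.name / f"{stem}.nuclei.tif", nuclei.astype(np.uint16)
            )
            tifffile.imwrite(
                mask_root / assay_dir.name / f"{stem}.cells.tif", cells.astype(np.uint16)
            )
            tifffile.imwrite(
                mask_root / assay_dir.name / f"{stem}.zones.tif",
                zones.zones.astype(np.uint16),
            )
            t = spot_set.table.copy()
            t.insert(0, "well_image", stem)
            t.insert(0, "assay", assay_dir.name)
            spot_tables.append(t)
    nonempty = [t for t in spot_tables if len(t)]
    spots = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=["assay", "well_image"])
    )
    aio.write_table(spots, outdir / "spots.csv")


def stage_extract(config: RunConfig, outdir: Path) -> None:
    img_root = outdir / "images"
    if not img_root.exists():
        raise DependencyError("simulate", "well images", "extract")
    seg = config.segmentation
    spot_kw = dict(config.spots)
    if "sigma_range" in spot_kw:
        spot_kw["sigma_range"] = tuple(spot_kw["sigma_range"])
    rows = []
    for assay_dir in sorted(img_root.iterdir()):
        assay = assay_dir.name
        plate_map = aio.read_plate_map(outdir / f"plate_map_{assay}.csv")
        by_stem = {
            f"{r.plate}_{r.well}": r for r in plate_map.itertuples(index=False)
        }
        for tif in sorted(assay_dir.glob("*.tif")):
            images, _ = aio.read_well_tiff(tif)
            row = extract_well_features(
                images,
                assay,
                n_zones=int(seg.get("n_zones", 4)),
                max_expansion_px=float(seg.get("max_expansion_px", 15.0)),
                spot_kwargs=spot_kw,
            )
            meta = by_stem[tif.stem]
            rows.append(
                pd.concat(
                    [
                        pd.Series(
                            {
                                "plate": meta.plate,
                                "well": meta.well,
                                "condition_id": meta.condition_id,
                                "role": meta.role,
                                "replicate_id": meta.replicate_id,
                                "assay": assay,
                            }
                        ),
                        row,
                    ]
                )
            )
    features = pd.DataFrame(rows).reset_index(drop=True)
    aio.write_table(features, outdir / "features.csv", parquet=True)


def stage_screen(config: RunConfig, outdir: Path) -> None:
    path = outdir / "screen_table.csv"
    if not path.exists():
        raise DependencyError("simulate", "screen_table.csv", "screen")
    table = aio.read_table(path)
    norm = config.normalization
    density = table[table.role == "density_series"]
    fit = fit_density_decay(density.cell_count, density.delivery)
    table = table.copy()
    table["normalized"] = normalize_by_density(
        table.delivery, table.cell_count, fit, method=str(norm.get("method", "ratio"))
    )
    ctrl = table[table.role == "neutral_control"]["normalized"].to_numpy()
    cond_vals = {
        c: g["normalized"].to_numpy()
        for c, g in table[table.role == "test"].groupby("condition_id")
    }
    calls = call_hits(cond_vals, ctrl, n_sd=float(norm.get("n_sd", 3.0)))
    hits = pd.DataFrame(
        {
            "condition_id": [c.condition_id for c in calls],
            "mean_normalized": [c.mean_normalized for c in calls],
            "label": [c.label for c in calls],
            "n_replicates": [c.n_replicates for c in calls],
        }
    )
    aio.write_table(hits, outdir / "hits.csv")
    summary = {
        "config_hash": config.config_hash(),
        "decay_fit": {
            "y0": fit.params.y0,
            "plateau": fit.params.plateau,
            "k": fit.params.k,
            "residual_sd": fit.residual_sd,
            "n": fit.n,
            "converged": fit.converged,
            "k_identifiable": fit.k_identifiable,
        },
        "control": {
            "mean": float(np.mean(ctrl)),
            "sd": float(np.std(ctrl, ddof=1)),
            "n": int(len(ctrl)),
        },
        "n_increase": int((hits.label == "increase").sum()),
        "n_decrease": int((hits.label == "decrease").sum()),
    }
    (outdir / "screen_summary.json").write_text(json.dumps(summary, indent=1))


def stage_ml(config: RunConfig, outdir: Path) -> None:
    fpath = outdir / "features.csv"
    hpath = outdir / "hits.csv"
    if not fpath.exists():
        raise DependencyError("extract", "features.csv", "ml")
    if not hpath.exists():
        raise DependencyError("screen", "hits.csv", "ml")
    features = aio.read_table(fpath)
    hits = aio.read_table(hpath)
    labels = dict(zip(hits.condition_id, hits.label))
    mlcfg = config.ml
    seed = config.stage_seed("ml")

    dataset = prepare_dataset(
        features.drop(columns=["plate", "well", "assay"], errors="ignore"), labels
    )
    train, test = split_stratified(
        dataset, train_fraction=float(mlcfg.get("train_fraction", 0.8)), seed=seed
    )
    k = int(mlcfg.get("smote_k", 5))
    try:
        train = smote_oversample(train, k_neighbors=k, seed=seed)
    except ValueError as exc:
        log.warning("SMOTE skipped: %s", exc)
    selected = rfe_select(
        train,
        n_features=int(mlcfg.get("n_features", 10)),
        step=float(mlcfg.get("rfe_step", 0.1)),
        seed=seed,
    )
    report = train_and_evaluate(train, test, selected, seed=seed)
    (outdir / "model_report.json").write_text(report.to_json())
    pd.DataFrame({"feature": selected}).to_csv(outdir / "selected_features.csv", index=False)


_STAGE_FN = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "extract": stage_extract,
    "screen": stage_screen,
    "ml": stage_ml,
}


def run_pipeline(config: RunConfig, outdir, stages=None) -> Path:
    """Run the requested stages (default: all) in pipeline order.

    Returns the run directory.  Rerunning with an identical config
    produces byte-identical CSV/JSON outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)} (valid: {STAGES})")
    _stamp(outdir, config)
    for stage in wanted:
        log.info("stage %s (seed %d)", stage, config.stage_seed(stage))
        _STAGE_FN[stage](config, outdir)
    return outdir


# --------------------------------------------------------------------------
# input validation
# --------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """All findings from validating user-supplied inputs (empty = clean)."""

    findings: list = field(default_factory=list)

    def add(self, kind: str, message: str, **context) -> None:
        self.findings.append({"kind": kind, "message": message, **context})

    @property
    def ok(self) -> bool:
        return not self.findings


def validate_inputs(plate_map_path, image_dir=None) -> ValidationReport:
    """Check a plate map and (optionally) an image directory.

    Verifies 384-well name grammar (A01–P24), required columns, image
    presence per well and 16-bit two-channel shape.  Collects every
    failure rather than stopping at the first.
    """
    import tifffile

    report = ValidationReport()
    try:
        df = pd.read_csv(plate_map_path)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        report.add("unreadable_plate_map", str(exc), path=str(plate_map_path))
        return report
    for col in aio.PLATE_MAP_COLUMNS:
        if col not in df.columns:
            report.add("missing_column", f"plate map lacks column {col!r}")
    if "well" in df.columns:
        for i, w in enumerate(df["well"]):
            try:
                parse_well(str(w))
            except ValueError as exc:
                report.add("invalid_well", str(exc), row=i)
    if image_dir is None:
        return report
    image_dir = Path(image_dir)
    if not image_dir.exists():
        report.add("missing_image_dir", f"{image_dir} does not exist")
        return report
    if {"plate", "well"} <= set(df.columns):
        for r in df.itertuples(index=False):
            path = image_dir / f"{r.plate}_{r.well}.tif"
            if not path.exists():
                report.add("missing_image", f"no image for well {r.well}", well=str(r.well))
                continue
            stack = tifffile.imread(path)
            if stack.ndim != 3 or stack.shape[0] != 2:
                report.add(
                    "missing_channel",
                    f"{path.name}: expected 2 channels (nuclei, marker), got shape {stack.shape}",
                    well=str(r.well),
                )
            elif stack.dtype != np.uint16:
                report.add(
                    "wrong_bit_depth",
                    f"{path.name}: expected 16-bit, got {stack.dtype}",
                    well=str(r.well),
                )
    return report
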