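"""Screen designs and 384-well plate layouts.

The default design emulates the study-scale screen: 106 test conditions
(36 that genuinely increase functional delivery, 70 biologically active but
delivery-neutral), 2–5 technical replicates each for 490 replicate wells in
total, plus neutral-control wells at nominal density and a neutral-control
density series used to fit the one-phase decay.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenDesign",
    "generate_design",
    "plate_layout",
    "well_name",
    "parse_well",
    "ASSAYS",
]

ASSAYS = ("delivery", "lnp_uptake", "transferrin", "dextran", "protein_synthesis")

_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well plate: rows A–P, columns 1–24
_WELL_RE = re.compile(r"^([A-Pa-p])(0[1-9]|1[0-9]|2[0-4])$")


def well_name(index: int) -> str:
    """Row-major well name on a 384-well grid: 0 -> 'A01', 383 -> 'P24'."""
    if not 0 <= index < 384:
        raise ValueError(f"well index {index} outside 384-well plate")
    return f"{_ROWS[index // 24]}{index % 24 + 1:02d}"


def parse_well(name: str) -> tuple[int, int]:
    """Parse 'A01'-style well name to (row, col), zero-based; case-insensitive."""
    m = _WELL_RE.match(name.strip())
    if not m:
        raise ValueError(f"invalid 384-well name {name!r} (expected A01–P24)")
    return _ROWS.index(m.group(1).upper()), int(m.group(2)) - 1


@dataclass(frozen=True)
class ScreenDesign:
    """Counts, replicate allocation and control structure of one screen.

    Attributes
    ----------
    n_test_conditions : int
        Number of treatment conditions (positives + neutral-activity).
    n_positive_conditions : int
        How many of those genuinely increase functional delivery; by
        convention the first ``n_positive_conditions`` condition ids.
    replicate_allocation : dict[str, int]
        Technical replicates per condition id.  The default allocates 5
        replicates to the first 66 conditions and 4 to the remaining 40,
        totaling 490 replicate wells.
    control_density_series : tuple[int, ...]
        Seeded-cell counts of the neutral-control density series (>= 6
        distinct values) used to fit the one-phase decay.
    density_series_replicates : int
        Wells per density-series point.
    n_control_replicates : int
        Neutral-control wells at nominal density, the reference for hit
        calling and robust-Z normalization.
    nominal_density : int
        Seeded cells per test/control well.
    assays : tuple[str, ...]
        Which imaging assays the screen runs.
    seed : int
        Seed recorded with the design for downstream generators.
    """

    n_test_conditions: int = 106
    n_positive_conditions: int = 36
    replicate_allocation: dict = field(default_factory=dict)
    control_density_series: tuple = tuple(np.linspace(500, 8000, 8).round().astype(int))
    density_series_replicates: int = 4
    n_control_replicates: int = 16
    nominal_density: int = 4000
    assays: tuple = ASSAYS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive_conditions > self.n_test_conditions:
            raise ValueError("n_positive_conditions must be <= n_test_conditions")
        if not self.replicate_allocation:
            object.__setattr__(
                self, "replicate_allocation", _default_allocation(self.n_test_conditions)
            )
        alloc = self.replicate_allocation
        if len(alloc) != self.n_test_conditions:
            raise ValueError(
                f"replicate allocation covers {len(alloc)} conditions, "
                f"design has {self.n_test_conditions}"
            )
        if any(r < 2 for r in alloc.values()):
            raise ValueError("every condition needs >= 2 technical replicates")
        if len(set(self.control_density_series)) < 6:
            raise ValueError("control_density_series needs >= 6 distinct densities")
        unknown = set(self.assays) - set(ASSAYS)
        if unknown:
            raise ValueError(f"unknown assays: {sorted(unknown)}")

    @property
    def condition_ids(self) -> list:
        return sorted(self.replicate_allocation)

    @property
    def positive_conditions(self) -> list:
        return self.condition_ids[: self.n_positive_conditions]

    @property
    def n_test_wells(self) -> int:
        return sum(self.replicate_allocation.values())


def _default_allocation(n_conditions: int) -> dict:
    """5 replicates for the first 66 conditions, 4 thereafter (490 at n=106)."""
    width = max(3, len(str(n_conditions)))
    return {
        f"C{i + 1:0{width}d}": (5 if i < 66 else 4) for i in range(n_conditions)
    }


def generate_design(**overrides) -> ScreenDesign:
    """Build a validated ScreenDesign from the study-scale defaults.

    Any ``ScreenDesign`` field may be overridden by keyword; the default
    design has 106 conditions summing to 490 replicate wells.
    """
    return ScreenDesign(**overrides)


def plate_layout(design: ScreenDesign, assay: str = "delivery") -> pd.DataFrame:
    """Lay a design out onto 384-well plates for one assay.

    Wells are assigned row-major in order: test conditions (by condition
    id, replicates consecutive), nominal-density neutral controls, then the
    neutral-control density series.  A new plate starts whenever the
    current one is full.

    Returns
    -------
    pandas.DataFrame
        Columns ``plate, well, condition_id, role, replicate_id,
        seeded_cells`` (one row per well).
    """
    if assay not in design.assays:
        raise ValueError(f"assay {assay!r} not in design (has {design.assays})")
    rows = []
    for cond in design.condition_ids:
        for rep in range(1, design.replicate_allocation[cond] + 1):
            rows.append((cond, "test", rep, design.nominal_density))
    for rep in range(1, design.n_control_replicates + 1):
        rows.append(("NEUTRAL", "neutral_control", rep, design.nominal_density))
    for dens in design.control_density_series:
        for rep in range(1, design.density_series_replicates + 1):
            rows.append(("NEUTRAL", "density_series", rep, int(dens)))

    out = []
    for i, (cond, role, rep, dens) in enumerate(rows):
        plate = f"{assay}_P{i // 384 + 1:02d}"
        out.append((plate, well_name(i % 384), cond, role, rep, dens))
    return pd.DataFrame(
        out, columns=["plate", "well", "condition_id", "role", "replicate_id", "seeded_cells"]
    )
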