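"""Protocol arithmetic: dehydration stoichiometry, section undersampling, shrinkage.

Constants
---------
2,2-dimethoxypropane (DMP, C5H12O2) hydrolyses 1:1 with water, yielding
methanol and acetone.  Molar masses: DMP 104.15 g/mol, water 18.02 g/mol
(standard atomic weights); DMP density 0.847 g/mL at 25 degrees C (supplier
data).  Note the mass-derived equivalent volume for 1 g of water is
5.78 g / 0.847 g/mL ~= 6.8 mL; practical protocols quote a larger volume,
which implies an excess factor beyond the 1:1 stoichiometric minimum.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .errors import LspostError


@dataclass(frozen=True)
class ReagentConstants:
    molar_mass_dmp: float = 104.15  # g/mol, C5H12O2
    molar_mass_water: float = 18.02  # g/mol
    density_dmp: float = 0.847  # g/mL

    def __post_init__(self) -> None:
        if min(self.molar_mass_dmp, self.molar_mass_water, self.density_dmp) <= 0:
            raise LspostError("reagent constants must be positive")


DEFAULT_CONSTANTS = ReagentConstants()


def dmp_mass_for_water(
    water_mass: float, constants: ReagentConstants = DEFAULT_CONSTANTS
) -> float:
    """Grams of DMP consumed by ``water_mass`` grams of water at 1:1 stoichiometry.

    ``water_mass * molar_mass_dmp / molar_mass_water``; 1.0 g of water gives
    5.78 g (rounds to 5.8 g).  Linear and homogeneous in the water mass.
    """
    if water_mass < 0:
        raise LspostError(f"water mass must be nonnegative, got {water_mass}")
    return water_mass * constants.molar_mass_dmp / constants.molar_mass_water


def dmp_volume_for_water(
    water_mass: float, constants: ReagentConstants = DEFAULT_CONSTANTS
) -> float:
    """Millilitres of DMP for ``water_mass`` grams of water, via the density."""
    return dmp_mass_for_water(water_mass, constants) / constants.density_dmp


def undersampling_factor(
    block_thickness_um: float, section_thickness_um: float, n_sections: int = 1
) -> float:
    """Ratio of block thickness to the total thickness of the sections examined.

    A 3,000 um block sampled by one 5 um section is undersampled 600-fold;
    a 4,000 um block, 800-fold.
    """
    if block_thickness_um <= 0 or section_thickness_um <= 0:
        raise LspostError("thicknesses must be positive")
    if n_sections < 1:
        raise LspostError(f"n_sections must be >= 1, got {n_sections}")
    return block_thickness_um / (section_thickness_um * n_sections)


@dataclass(frozen=True)
class ShrinkageRecord:
    """Pre/post treatment volumes (mm^3) for one sample."""

    sample_id: str
    treatment: str
    pre_volume: float
    post_volume: float

    def __post_init__(self) -> None:
        if self.pre_volume <= 0:
            raise LspostError(
                f"sample {self.sample_id!r}: pre-treatment volume must be positive"
            )
        if self.post_volume < 0:
            raise LspostError(
                f"sample {self.sample_id!r}: post-treatment volume must be nonnegative"
            )

    @classmethod
    def from_dimensions(
        cls,
        sample_id: str,
        treatment: str,
        pre_mm: tuple[float, float, float],
        post_mm: tuple[float, float, float],
    ) -> "ShrinkageRecord":
        """Build a record from (length, width, height) triples via the rectangular product."""
        pre = pre_mm[0] * pre_mm[1] * pre_mm[2]
        post = post_mm[0] * post_mm[1] * post_mm[2]
        return cls(sample_id, treatment, pre, post)

    @property
    def shrinkage_percent(self) -> float:
        """(1 - V_post / V_pre) * 100; negative values indicate swelling."""
        return (1.0 - self.post_volume / self.pre_volume) * 100.0


def volume_shrinkage_percent(
    records: list[ShrinkageRecord],
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-record shrinkage percentages and unweighted per-treatment group means."""
    if not records:
        raise LspostError("at least one shrinkage record is required")
    per_record = {r.sample_id: r.shrinkage_percent for r in records}
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.treatment, []).append(r.shrinkage_percent)
    group_means = {t: sum(v) / len(v) for t, v in groups.items()}
    return per_record, group_means


def read_shrinkage_csv(path: str | Path) -> list[ShrinkageRecord]:
    """Read records from a CSV with columns id, treatment, pre, post (volumes)."""
    path = Path(path)
    if not path.exists():
        raise LspostError(f"shrinkage CSV does not exist: {path}")
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "treatment", "pre", "post"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise LspostError(f"shrinkage CSV must have columns {sorted(required)}")
        for row in reader:
            records.append(
                ShrinkageRecord(
                    sample_id=row["id"],
                    treatment=row["treatment"],
                    pre_volume=float(row["pre"]),
                    post_volume=float(row["post"]),
                )
            )
    if not records:
        raise LspostError(f"shrinkage CSV {path} contains no data rows")
    return records
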