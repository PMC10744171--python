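"""Virus-like particle (VLP) enumeration from epifluorescence microscopy.

Counts of fluorescently stained particles per microscope field are converted
to a concentration: the mean per-field count is multiplied by the sample
dilution factor and the microscope conversion factor (filter area / field of
view area) and divided by the filtered sample volume.  When the faecal mass
per volume of the original suspension is known, a per-gram value is derived
as well.  Filter and field areas are caller-supplied: the effective
filtration area of a nominal 13 mm disc depends on the filter holder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["EfmRun", "vlp_concentration"]


@dataclass(frozen=True)
class EfmRun:
    per_field_counts: Sequence[int]
    dilution_factor: float = 1.0
    filter_area: float = 1.0        # mm^2
    field_area: float = 1.0         # mm^2
    sample_volume: float = 1.0      # mL
    faecal_mass_per_volume: float | None = None  # g/mL

    def validate(self) -> "EfmRun":
        if not self.per_field_counts:
            raise ValueError("need at least one per-field count")
        if any(c < 0 for c in self.per_field_counts):
            raise ValueError("per-field counts must be non-negative")
        if self.field_area <= 0 or self.sample_volume <= 0:
            raise ValueError("field_area and sample_volume must be positive")
        if self.field_area > self.filter_area:
            raise ValueError("field_area cannot exceed filter_area")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.faecal_mass_per_volume is not None and self.faecal_mass_per_volume <= 0:
            raise ValueError("faecal_mass_per_volume must be positive when given")
        return self


def vlp_concentration(run: EfmRun) -> dict[str, float]:
    """VLP concentration per mL (and per g when a mass density is given).

    mean(per-field counts) x dilution x (filter area / field area) / volume.
    """
    run.validate()
    mean_count = sum(run.per_field_counts) / len(run.per_field_counts)
    per_ml = (mean_count * run.dilution_factor
              * (run.filter_area / run.field_area) / run.sample_volume)
    out = {"vlp_per_ml": per_ml, "mean_per_field": mean_count}
    if run.faecal_mass_per_volume is not None:
        out["vlp_per_g"] = per_ml / run.faecal_mass_per_volume
    return out
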