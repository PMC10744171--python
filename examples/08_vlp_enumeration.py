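"""VLP concentration from epifluorescence microscopy field counts.

mean(per-field counts) x dilution x (filter area / field area) / volume.
"""

from viromix import EfmRun, vlp_concentration

run = EfmRun(
    per_field_counts=[23, 27, 25, 24, 26] * 4,  # 20 imaged fields
    dilution_factor=50,
    filter_area=100.0,      # mm^2, effective filtration area of the disc
    field_area=0.01,        # mm^2, one field of view at 100x
    sample_volume=0.02,     # mL filtered onto the membrane
    faecal_mass_per_volume=0.1,  # g/mL of the original suspension
)
result = vlp_concentration(run)
for key, value in result.items():
    print(f"  {key}: {value:.3g}")
# 25 particles/field scales to 6.25e8 VLP per mL (6.25e9 per g) after the
# dilution and the filter-to-field area conversion.
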