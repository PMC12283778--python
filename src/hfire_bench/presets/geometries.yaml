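# Electrode geometry presets (SI units).
#
# potato_plate: 6 mm thick, 6 mm diameter biopsy-punched tissue cylinder
# between parallel flat plates.
# potato_needle_*: 1 mm diameter monopolar probes (radius 0.5 mm), 1.0 cm
# exposure, at 1.0 or 1.5 cm center-to-center spacing, inserted 2.5 cm deep.
# cardiac_needle: 0.45 mm diameter acupuncture needles at 1.0 cm spacing;
# 4 mm exposure / 8 mm insertion per the bench description (a 5 mm / 10 mm
# variant also appears in some records; the shorter values are used here).
potato_plate:
  kind: plate
  thickness_m: 0.006
  diameter_m: 0.006

potato_needle_1.0cm:
  kind: needle_pair
  center_spacing_m: 0.010
  electrode_radius_m: 0.0005
  exposure_m: 0.010
  insertion_depth_m: 0.025

potato_needle_1.5cm:
  kind: needle_pair
  center_spacing_m: 0.015
  electrode_radius_m: 0.0005
  exposure_m: 0.010
  insertion_depth_m: 0.025

cardiac_needle:
  kind: needle_pair
  center_spacing_m: 0.010
  electrode_radius_m: 0.000225
  exposure_m: 0.004
  insertion_depth_m: 0.008
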