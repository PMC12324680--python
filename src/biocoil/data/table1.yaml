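# Reference water-cooled Helmholtz exposure system: winding geometry and
# measured electrical parameters of the as-built pair, plus the default
# incubator operating point.  Lengths carry explicit unit suffixes.
coil:
  wire_diameter_mm: 0.71          # packing pitch of the 22 AWG magnet wire
  wire_conductor_diameter_mm: 0.644  # bare-copper diameter of 22 AWG
  holder_inner_diameter_mm: 80.0
  winding_width_mm: 16.0
  n_turns: 96
  spacing_mm: 43.4                # centroid-to-centroid, Helmholtz condition
operating:
  current_a: 1.0
  frequency_hz: 0.0
  toggle_time_ms: 130.0           # measured full on+off toggle of the supply
  voltage_v: 2.75
electrical:
  resistance_ohm: 2.74            # measured, series pair
  inductance_uh: 870.0            # measured
coolant:
  flow_lpm: 1.0
  inlet_temp_c: 37.0
air:
  temperature_c: 37.0
  relative_humidity_pct: 60.0
region:                           # 35 mm dish with ~5 mm of medium
  shape: cylinder
  radius_mm: 17.5
  height_mm: 5.0
  axial_center_mm: 0.0
  grid_step_mm: 0.5
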