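# Reference-room configuration: 3.0 x 4.0 x 2.8 m office, closed door,
# 1 air change per hour, volumetric source calibrated from the analytical
# ventilation sweep. Run with:
#   radonroom simulate examples/config.yaml --out results/
room:
  lx: 3.0
  ly: 4.0
  lz: 2.8
window:
  wall: x1            # centred on the x = Lx wall
  center: [2.0, 1.4]  # (y, z) metres
  width: 1.2
  height: 0.8
door:
  wall: y0            # left-hand side of the front wall
  center: [0.6, 1.1]  # (x, z) metres
  width: 1.0
  height: 2.2
door_gap_height: 0.03
scenario: closed       # or: open
grid:
  resolution: 10       # cells per metre -> 30 x 40 x 28
ventilation:
  ach: 1.0
air:
  temperature_c: 24.0
  relative_humidity: 0.5
  pressure_pa: 101325.0
source:
  exhalation_bq_m2_h: 3.1
  outdoor_bq_m3: 10.0
  mode: volumetric           # or: boundary_flux
  generation_bq_m3_h: calibrated   # number, null (= from exhalation), or 'calibrated'
solver:
  closure: constant_nu_eff   # or: k_epsilon
  tolerance: 1.0e-6
dose:
  equilibrium_factor: 0.4
  occupancy_h: 2000
  coefficient_nsv: 12
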