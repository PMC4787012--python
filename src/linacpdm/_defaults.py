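"""Default study configuration tables.

Single source of truth for the monitored text-log parameters (schema, Sp
rules, synthetic-machine nominals and noise), the recorded axis list and the
fault-injection magnitudes of the default error suite.  The registry module
consumes the schema columns; the simulate module consumes the machine-model
and error columns.

Where the deviation magnitude of a parameter is specified as one standard
deviation of the fleet operating value, the synthetic machine's noise sigma
is pinned to that same value; all other nominals/sigmas are fixed,
field-realistic choices for a modern C-band digital accelerator and are
documented in docs/methods.md.
"""

from __future__ import annotations

# Operational groups (9).
GROUP_RF = "RF generation"
GROUP_GUN = "Electron gun"
GROUP_BEND = "Bending & energy"
GROUP_STEER = "Beam steering & uniformity"
GROUP_DC = "DC power supplies"
GROUP_COOL = "Cooling & gas"
GROUP_COLL = "Collimation"
GROUP_GANTRY = "Gantry"
GROUP_MLC = "MLC"

GROUPS = (
    GROUP_RF,
    GROUP_GUN,
    GROUP_BEND,
    GROUP_STEER,
    GROUP_DC,
    GROUP_COOL,
    GROUP_COLL,
    GROUP_GANTRY,
    GROUP_MLC,
)

# Monitored text-log parameters (35).  Columns:
#   id, name, units, group,
#   nominal, sigma                      -- synthetic machine model
#   sp_basis, sp_reference, sp_fraction -- hybrid-limit inflation rule
#   error_mode, error_level, error_desc -- default injection scenario
# error_mode: "add_shift" | "scale" ; level 0 rows are negative controls.
TEXT_PARAMETERS = (
    ("pfn_hv_current", "PFN High Voltage Power Supply Current", "A", GROUP_RF,
     100.0, 0.8, "operating_range", 20.0, 0.10, "scale", 1.05, "5 % based on operating ranges"),
    ("pfn_voltage", "PFN Actual Voltage", "kV", GROUP_RF,
     15.0, 0.12, "operating_range", 3.0, 0.10, "scale", 1.05, "5 % based on operating ranges"),
    ("rf_driver_voltage", "RF Driver Voltage", "V", GROUP_RF,
     5.0, 0.5, "empirical", 0.0, 1.0, "add_shift", 0.5, "1STD"),
    ("rf_forward_power", "RF Forward Power", "W", GROUP_RF,
     4.0, 0.11, "empirical", 0.0, 1.0, "add_shift", 0.11, "1STD"),
    ("afc_error", "AFC Error", "V", GROUP_RF,
     0.0, 0.03, "empirical", 0.0, 1.0, "add_shift", 0.03, "1STD"),
    ("gun_current", "Gun Current", "A", GROUP_GUN,
     0.16, 0.002, "operating_range", 0.04, 0.10, "add_shift", 0.0, "No change - add"),
    ("gun_high_voltage", "Gun High Voltage", "V", GROUP_GUN,
     18000.0, 559.0, "empirical", 0.0, 1.0, "add_shift", 559.0, "1STD"),
    ("gun_grid_voltage", "Gun Grid Voltage", "V", GROUP_GUN,
     120.0, 7.94, "empirical", 0.0, 1.0, "add_shift", 7.94, "1STD"),
    ("gun_filament_step_voltage", "Gun Filament Step Voltage", "V", GROUP_GUN,
     5.8, 0.02, "empirical", 0.05, 1.0, "add_shift", 0.1, "Half of minor fault change"),
    ("gun_filament_voltage", "Gun Filament Voltage", "V", GROUP_GUN,
     5.2, 0.02, "empirical", 0.05, 1.0, "add_shift", 0.1, "Half of minor fault change"),
    ("bend_magnet_current", "Bend Magnet Current", "A", GROUP_BEND,
     85.0, 0.17, "qc_published", 85.0, 0.002, "scale", 1.01, "1 % change"),
    ("bend_magnet_voltage", "Bend Magnet Voltage", "V", GROUP_BEND,
     40.0, 0.4, "empirical", 0.4, 1.0, "scale", 1.05, "5 % change"),
    ("accel_solenoid_current", "Accelerator Solenoid Current", "A", GROUP_BEND,
     110.0, 1.0, "empirical", 0.0, 1.0, "add_shift", 1.0, "1STD"),
    ("klystron_solenoid_current", "Klystron Solenoid Current", "A", GROUP_RF,
     35.0, 0.02, "empirical", 0.03, 1.0, "add_shift", 0.1, ".100 A change"),
    ("radial_symmetry", "Radial Symmetry", "%", GROUP_STEER,
     0.0, 0.1, "qc_published", 2.0, 0.01, "add_shift", 0.5, "0.5 % added"),
    ("transverse_symmetry", "Transverse Symmetry", "%", GROUP_STEER,
     0.0, 0.1, "qc_published", 2.0, 0.01, "add_shift", 0.5, "0.5 % added"),
    ("target_current", "Target Current", "nC", GROUP_BEND,
     380.0, 11.0, "empirical", 0.0, 1.0, "add_shift", 11.0, "1STD"),
    ("buncher_radial_current", "Buncher Radial Current", "A", GROUP_BEND,
     1.2, 0.13, "empirical", 0.0, 1.0, "add_shift", 0.13, "1STD"),
    ("buncher_transverse_current", "Buncher Transverse Current", "A", GROUP_BEND,
     1.0, 0.1, "empirical", 0.0, 1.0, "add_shift", 0.1, "1STD"),
    ("angle_radial_current", "Angle Radial Current", "A", GROUP_STEER,
     2.5, 0.04, "empirical", 0.05, 1.0, "add_shift", 0.2, "Shift/add 0.2 A"),
    ("angle_transverse_current", "Angle Transverse Current", "A", GROUP_STEER,
     1.8, 0.04, "empirical", 0.05, 1.0, "add_shift", 0.2, "Shift/add 0.2 A"),
    ("position_radial_current", "Position Radial Current", "A", GROUP_STEER,
     3.2, 0.04, "empirical", 0.05, 1.0, "add_shift", 0.2, "Shift/add 0.2 A"),
    ("position_transverse_current", "Position Transverse Current", "A", GROUP_STEER,
     2.1, 0.04, "empirical", 0.05, 1.0, "add_shift", 0.2, "Shift/add 0.2 A"),
    ("trim_current", "Trim Current", "A", GROUP_STEER,
     0.5, 0.055, "empirical", 0.0, 1.0, "add_shift", 0.055, "1STD"),
    ("vacion_current", "Accelerator Vacion Current", "uA", GROUP_COOL,
     0.05, 0.0015, "empirical", 0.002, 1.0, "add_shift", 0.007, "Add .1 % of Vac2 fault value"),
    ("positive_5v_dc", "Positive 5 V dc", "V", GROUP_DC,
     5.0, 0.02, "empirical", 0.02, 1.0, "add_shift", 0.1, "Shift/add 0.1 V"),
    ("positive_24v_dc", "Positive 24 V dc", "V", GROUP_DC,
     24.0, 0.02, "empirical", 0.02, 1.0, "add_shift", 0.1, "Shift/add 0.1 V"),
    ("analog_negative_5v_dc", "Analog Negative 5 V dc", "V", GROUP_DC,
     -5.0, 0.02, "empirical", 0.02, 1.0, "add_shift", 0.1, "Shift/add 0.1 V"),
    ("analog_positive_5v_dc", "Analog Positive 5 V dc", "V", GROUP_DC,
     5.0, 0.02, "empirical", 0.02, 1.0, "add_shift", 0.1, "Shift/add 0.1 V"),
    ("negative_12v_dc", "Negative 12 V dc", "V", GROUP_DC,
     -12.0, 0.02, "empirical", 0.02, 1.0, "add_shift", 0.1, "Shift/add 0.1 V"),
    ("positive_3v_dc", "Positive 3 V dc", "V", GROUP_DC,
     3.0, 0.02, "empirical", 0.02, 1.0, "add_shift", 0.1, "Shift/add 0.1 V"),
    ("node_power_supply_voltage", "Node Power Supply Voltage", "V", GROUP_DC,
     24.0, 0.02, "empirical", 0.02, 1.0, "add_shift", 0.1, "Shift/add 0.1 V"),
    ("water_level", "Water Level", "%", GROUP_COOL,
     92.0, 0.3, "operating_range", 10.0, 0.05, "add_shift", 0.0, "No change - add"),
    ("water_supply_temperature", "Internal Water Supply Temperature", "degC", GROUP_COOL,
     18.0, 0.25, "empirical", 0.2, 1.0, "add_shift", 1.0, "1 degree change"),
    ("gas_pressure", "Gas Pressure", "PSI", GROUP_COOL,
     32.0, 0.25, "empirical", 0.2, 1.0, "add_shift", 1.0, "1 psi"),
)

# Text-log values recorded in every snapshot but not monitored (10), so a
# snapshot carries 45 named scalars while only 35 feed the SPC charts.
# Columns: id, name, units, nominal, sigma.
TEXT_EXTRAS = (
    ("vac2_current", "Accelerator Vacion VAC2 Current", "uA", 0.02, 0.001),
    ("ion_chamber_temperature", "Ion Chamber Temperature", "degC", 22.0, 0.2),
    ("ion_chamber_pressure", "Ion Chamber Pressure", "kPa", 101.3, 0.3),
    ("sf6_tank_pressure", "SF6 Tank Pressure", "PSI", 28.0, 0.2),
    ("city_water_temperature", "City Water Supply Temperature", "degC", 14.0, 0.5),
    ("city_water_flow", "City Water Flow", "L/min", 40.0, 0.5),
    ("klystron_filament_current", "Klystron Filament Current", "A", 19.0, 0.05),
    ("modulator_cabinet_temperature", "Modulator Cabinet Temperature", "degC", 30.0, 0.3),
    ("stand_cabinet_temperature", "Stand Cabinet Temperature", "degC", 24.0, 0.3),
    ("line_voltage", "Line Voltage", "V", 208.0, 0.5),
)

# Recorded axes (131): gantry, 4 jaws, 2 MLC carriages, 120 MLC leaves,
# 4 couch axes.  The couch axes are recorded but never monitored (127
# monitored axes).
GANTRY_AXIS = "gantry"
JAW_AXES = ("jaw_x1", "jaw_x2", "jaw_y1", "jaw_y2")
CARRIAGE_AXES = ("carriage_a", "carriage_b")
MLC_AXES_A = tuple(f"mlc_a{i:02d}" for i in range(1, 61))
MLC_AXES_B = tuple(f"mlc_b{i:02d}" for i in range(1, 61))
MLC_AXES = MLC_AXES_A + MLC_AXES_B
COUCH_AXES = ("couch_vrt", "couch_lng", "couch_lat", "couch_rtn")

RECORDED_AXES = (GANTRY_AXIS,) + JAW_AXES + CARRIAGE_AXES + MLC_AXES + COUCH_AXES
MONITORED_AXES = (GANTRY_AXIS,) + JAW_AXES + CARRIAGE_AXES + MLC_AXES

# Synthetic machine positional noise per axis class (1 sigma).
AXIS_SIGMA_GANTRY_DEG = 0.05
AXIS_SIGMA_MLC_CM = 0.02
AXIS_SIGMA_JAW_CM = 0.02
AXIS_SIGMA_CARRIAGE_CM = 0.02
AXIS_SIGMA_COUCH = 0.0

# Hybrid-limit Sp rules for trajectory-derived parameters, keyed by metric
# class: (basis, reference_value, fraction).  Jaw/carriage positions use the
# published 2 mm positional QA tolerance; the remainder are empirical values
# from the synthetic commissioning study (docs/methods.md).
SP_JAW_POSITION = ("qc_published", 0.2, 0.01)       # 1 % of 0.2 cm
SP_CARRIAGE_POSITION = ("qc_published", 0.2, 0.01)
SP_GANTRY_SPEED = ("empirical", 0.02, 1.0)          # deg/s
SP_GANTRY_CC_VALUE = ("empirical", 0.005, 1.0)      # unitless
SP_GANTRY_CC_LOCATION = ("empirical", 1.0, 1.0)     # snapshots
SP_MLC_SPEED = ("empirical", 0.02, 1.0)             # cm/s
SP_MLC_CC_VALUE = ("empirical", 0.005, 1.0)
SP_MLC_CC_LOCATION = ("empirical", 0.5, 1.0)

# Default fault magnitudes for trajectory scenarios.
JAW_SHIFT_CM = 0.2
CARRIAGE_SHIFT_CM = 0.2
GANTRY_SPEED_SHIFT = 0.2       # deg/s, both speed segments
GANTRY_TRACE_SHIFT = 10        # snapshots
MLC_SPEED_SHIFT = 0.1          # cm/s, both speed segments, every leaf
MLC_TRACE_SHIFT = 2            # snapshots, every leaf
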