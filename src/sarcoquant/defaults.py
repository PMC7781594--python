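"""Central registry of measurement constants and analysis defaults.

Every protocol constant used by more than one stage lives here exactly once,
so that configuration files and the CLI share a single source of truth.
"""

# --- acquisition / protocol constants ---------------------------------------
SAMPLING_HZ = 1000.0            # force-trace sampling rate
SLACK_SL_UM = 2.2               # slack sarcomere length at protocol start
RAMP_STEP_UM = 0.2              # per-step stretch amplitude
RAMP_SPEED_UM_PER_S = 0.2       # commanded stretch speed
N_RAMP_STEPS = 6                # stretch-hold steps per passive protocol
HOLD_S = 10.0                   # isometric hold between steps
TIMECOURSE_SAMPLE_MIN = (0, 1, 2, 3, 4, 5, 10, 15, 20, 25, 30)
ACTIVATION_PLATEAU_S = 120.0    # time to steady-state active force
ACTIVE_STEADY_WINDOW_S = 10.0   # terminal window for steady-state estimate

# --- immunogold / immunofluorescence ----------------------------------------
MIN_GOLD_DIAMETER_NM = 8.0      # inclusion gate for gold particles
IBAND_ROI_MARGIN_NM = 20.0      # ROI margin around the I-band incl. Z-disk
FILAMENT_PAIR_GATE_NM = 20.0    # transverse gate for per-filament pairing

# --- AFM nanoindentation -----------------------------------------------------
BEAD_RADIUS_UM = 5.0            # half of the 10 um polystyrene bead
TRIGGER_FORCE_NN = 3.0          # pre-set indentation force
POISSON_RATIO = 0.5             # incompressible-tissue assumption
SPRING_CONSTANT_N_PER_M = 0.035  # midpoint of the 0.03-0.04 N/m range
HERTZ_MAX_DELTA_FRACTION = 0.4  # fit domain cap: delta <= 0.4 R

# --- Z-disk fracture metric --------------------------------------------------
THETA_REF_DEG = 45.0            # angular scale of the affine residual weight
MIN_SEGMENT_LENGTH_NM = 500.0   # shortest Z-disk segment kept
ORIENTATION_GATE_DEG = 30.0     # gate around the dominant transverse direction
RIDGE_THRESHOLD_QUANTILE = 0.90  # optional fixed-quantile mode (default: Otsu)
SMOOTHING_SIGMA_NM = 16.0        # pre-filter scale, calibrated in nm

# --- synthetic data ----------------------------------------------------------
DEFAULT_NM_PER_PX = 4.0         # typical EM pixel size
DEFAULT_NOISE_FRACTION = 0.05   # Gaussian noise SD as fraction of range
ZDISK_WIDTH_NM = 70.0           # rendered Z-disk band width
ABAND_LENGTH_NM = 1600.0        # normal thick-filament length

# --- titin epitope offsets from the Z-disk centre (nm), long-SL fibres ------
EPITOPE_OFFSETS_NM = {
    "T12": 50.0,
    "N2A": 250.0,
    "N2B": 250.0,
    "PEVK": 550.0,
    "HaloTag": 700.0,
}

# --- thick-filament centering force balance ---------------------------------
N_TITINS_PER_HALF_FILAMENT = 6
FILAMENT_DENSITY_PER_UM2 = 500.0
MBAND_MAX_EXTENSION_NM = 70.0
PER_MOLECULE_FORCE_PN = 12.0    # at the reference displacement
REFERENCE_DISPLACEMENT_NM = 35.0
TARGET_LOAD_PN = 120.0          # upper-estimate opposing load
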