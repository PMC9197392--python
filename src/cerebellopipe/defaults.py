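"""Analysis constants and simulation defaults, collected in one place.

Every constant the underlying study protocol leaves open is defined here
with its default so a run configuration can override it explicitly.
"""

# ---------------------------------------------------------------------------
# PSTH / evoked-response quantification
# ---------------------------------------------------------------------------

#: PSTH bin width (s).
BIN_WIDTH_S = 0.010
#: Baseline window preceding each stimulation onset (s).
BASELINE_S = 0.300
#: Responsiveness criterion: a stimulation bin must exceed the baseline mean
#: by more than this multiple of the baseline-bin SD.
RESPONSIVE_K = 4.0
#: Mean-rate threshold separating slow- from fast-spiking striatal units (Hz).
FAST_SPIKING_THRESHOLD_HZ = 6.0

#: Region-specific 10-ms afferent-volley windows relative to light onset (s):
#: direct excitation in the DN, disynaptic in thalamus, trisynaptic in cortex.
#: The striatal window is not specified by the protocol; it defaults to the
#: cortical (disynaptic-like) window and is overridable.
VOLLEY_WINDOWS_S = {
    "DN": (0.000, 0.010),
    "VAL": (0.004, 0.014),
    "CL": (0.004, 0.014),
    "M1": (0.007, 0.017),
    "DLS": (0.007, 0.017),
}

# ---------------------------------------------------------------------------
# Stimulation protocols
# ---------------------------------------------------------------------------

#: Low-frequency probing protocol: 100 ms pulses at 0.25 Hz.
LOW_FREQ_PERIOD_S = 4.0
LOW_FREQ_PULSE_S = 0.100
#: Theta-burst protocol: 20 ms pulses at 8.33 Hz, two 40 s trains separated
#: by a 2 min pause.
THETA_RATE_HZ = 8.33
THETA_PULSE_S = 0.020
THETA_TRAIN_S = 40.0
THETA_PAUSE_S = 120.0
THETA_N_TRAINS = 2

# ---------------------------------------------------------------------------
# Spike sorting
# ---------------------------------------------------------------------------

#: Number of principal components retained from the waveform snippets.
N_PCS = 3
#: k-means restarts per candidate k.
KMEANS_RESTARTS = 10
#: Minimum mean silhouette for accepting a multi-cluster solution in the
#: cluster-count sweep; below it the waveform set is treated as one unit.
#: A k-means split of a single isotropic cluster in 3 PCs already reaches
#: silhouettes near 0.25, while genuinely separated units score well above
#: 0.5, so the floor sits between those regimes.
SILHOUETTE_FLOOR = 0.3

# ---------------------------------------------------------------------------
# Simulation defaults (simulation choices, not measured values)
# ---------------------------------------------------------------------------

#: Tonic baseline firing rates per region (Hz), typical of awake rodents:
#: cerebellar nuclei fire tonically fast, thalamic relays and cortex slower,
#: striatal projection neurons slowest.
BASELINE_RATE_HZ = {"DN": 40.0, "VAL": 12.0, "CL": 10.0, "M1": 8.0, "DLS": 5.0}
#: Added rate during the stimulus-locked response window (Hz).
EVOKED_DELTA_HZ = {"DN": 20.0, "VAL": 15.0, "CL": 12.0, "M1": 10.0, "DLS": 6.0}
#: Response onset latency per region (s), matching the afferent-volley onset.
RESPONSE_LATENCY_S = {"DN": 0.000, "VAL": 0.004, "CL": 0.004,
                      "M1": 0.007, "DLS": 0.007}
#: Response window duration per region (s); latency + window spans the
#: 100 ms pulse.
RESPONSE_WINDOW_S = {"DN": 0.100, "VAL": 0.096, "CL": 0.096,
                     "M1": 0.093, "DLS": 0.093}

#: Evoked-response multiplier per genotype: the mutant shows an increased
#: cerebello-thalamic excitability.
GENOTYPE_GAIN = {"WT": 1.0, "GNAL": 1.3}
#: Baseline-rate multiplier per pharmacological state: the cholinergic
#: agonist depresses tonic firing.
STATE_RATE_FACTOR = {"naive_saline": 1.0, "oxo": 0.7, "post_oxo_saline": 1.0}
#: Post/pre theta-burst evoked-gain per (genotype, state): potentiation in
#: wild types under saline, absent potentiation in mutants, depression in
#: mutants under the agonist.
PLASTICITY_GAIN = {
    ("WT", "naive_saline"): 1.5,
    ("WT", "post_oxo_saline"): 1.5,
    ("WT", "oxo"): 1.0,
    ("GNAL", "naive_saline"): 1.0,
    ("GNAL", "post_oxo_saline"): 1.0,
    ("GNAL", "oxo"): 0.7,
}

# ---------------------------------------------------------------------------
# Open field
# ---------------------------------------------------------------------------

#: Arena radius (cm): 38 cm diameter circular arena.
ARENA_RADIUS_CM = 19.0
#: Default recording session length (s): 5 min open-field session.
OPENFIELD_DURATION_S = 300.0
#: Thigmotaxis zone: samples with radial distance beyond this fraction of
#: the arena radius count as wall-hugging.  Center zone: within this
#: fraction.  Conventional zone definitions, not protocol values.
THIGMOTAXIS_FRACTION = 0.75
CENTER_FRACTION = 0.5
#: Occupancy histogram resolution (bins per axis).
OCCUPANCY_BINS = 20
#: Sliding window for speed averaging (s).
SPEED_WINDOW_S = 1.0
#: Active-wake scoring: window speed at or above this threshold counts as
#: active, and bouts shorter than the minimum are dissolved.  Documented
#: defaults, not protocol values.
ACTIVE_SPEED_CM_S = 1.0
MIN_BOUT_S = 1.0

# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------

#: Binary threshold (8-bit intensity) separating the dark animal from the
#: light background.
BINARY_THRESHOLD = 128
#: Gaussian blur sigma (px) applied after the edge-preserving filter.
TRACK_GAUSSIAN_SIGMA = 1.2
#: Bilateral (edge-preserving) filter parameters.
TRACK_BILATERAL_SIGMA_SPATIAL = 2.0
TRACK_BILATERAL_SIGMA_COLOR = 0.3
#: Fraction of frames allowed to need imputation before a hard warning.
MAX_IMPUTED_FRACTION = 0.10
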