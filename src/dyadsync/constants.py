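"""Shared physical constants and canonical defaults.

The forward signal generator and the inverse preprocessing chain must use
the *same* optical constants so that the round trip (concentration ->
optical density -> intensity -> optical density -> concentration) is exact
up to added noise.  Everything optical lives here for that reason.
"""

from __future__ import annotations

import numpy as np

# --- acquisition defaults -------------------------------------------------

SAMPLING_RATE_HZ = 10.0
N_CHANNELS = 22
WAVELENGTHS_NM = (690.0, 830.0)
SOURCE_DETECTOR_DISTANCE_CM = 3.0
DIFFERENTIAL_PATHLENGTH_FACTOR = 6.0  # same value at both wavelengths

# Canonical block design: rest / task / rest / task / rest, seconds.
SEGMENT_LABELS = ("rest1", "task1", "rest2", "task2", "rest3")
SEGMENT_DURATIONS_S = (30.0, 150.0, 30.0, 150.0, 30.0)
TASK_SEGMENTS = ("task1", "task2")
REST_BASELINE_SEGMENTS = ("rest2",)

# Analysis band (period, seconds) for band-averaged coherence.
BAND_PERIOD_LO_S = 3.2
BAND_PERIOD_HI_S = 12.8

# --- optics ---------------------------------------------------------------

# Molar extinction coefficients, 1/(mM * cm), rows = wavelength (690, 830),
# columns = chromophore (HbO, HbR).  Values are the usual tabulated ones at
# these wavelengths; only invertibility and shared use matter here.
EXTINCTION_MM_CM = np.array(
    [
        [0.35, 2.10],  # 690 nm: HbO weak, HbR strong
        [1.00, 0.78],  # 830 nm: HbO strong, HbR weaker
    ]
)

CHROMOPHORES = ("hbo", "hbr")

# --- behavioral task defaults --------------------------------------------

TRIALS_PER_BLOCK = 20
N_BLOCKS = 2
CUE_DELAY_RANGE_S = (0.6, 1.5)
RESPONSE_TIMEOUT_S = 4.0
THRESHOLD_DIVISOR = 8.0
FEEDBACK_DURATION_S = 2.0
INTER_TRIAL_INTERVAL_S = 1.5

# Default cohort composition (delayed / immediate / none).
DEFAULT_GROUP_SIZES = {"delayed": 17, "immediate": 16, "none": 10}
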