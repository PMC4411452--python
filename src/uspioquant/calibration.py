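"""Reference group summaries the cohort simulator is calibrated to.

The values below are the published group medians and interquartile ranges
from the murine renal-transplant USPIO study this pipeline reproduces:
nine allograft and six isograft animals, imaged before and 48 h after
ferumoxytol infusion, with the graft's R2* increase indexed to the native
(contralateral) kidney and to skeletal muscle to normalise blood-pool
contrast.  Each entry is a ``(q1, median, q3)`` triple; the two-piece
uniform sampler in :mod:`uspioquant.phantom` turns a triple into a
distribution whose population median equals the printed median exactly and
whose support is the printed interquartile range.

All rates are in s^-1; indexed ratios are unitless.
"""

from __future__ import annotations

# Graft deltaR2* divided by native-kidney deltaR2*, per group.
INDEXED_TO_NATIVE: dict[str, tuple[float, float, float]] = {
    "allograft": (1.12, 1.24, 1.36),
    "isograft": (0.92, 0.96, 1.04),
}

# DeltaR2* divided by skeletal-muscle deltaR2*.  "native" entries are the
# native kidneys of the corresponding transplant group.
INDEXED_TO_MUSCLE: dict[str, tuple[float, float, float]] = {
    "allograft": (5.63, 6.24, 13.51),
    "allograft_native": (1.11, 2.91, 6.46),
    "isograft": (0.78, 3.83, 6.24),
    "isograft_native": (1.00, 3.63, 5.33),
}

# Raw deltaR2* (48 h minus baseline), s^-1.
DELTA_R2STAR: dict[str, tuple[float, float, float]] = {
    "allograft": (14.0, 30.15, 68.0),
    "allograft_native": (4.5, 15.7, 26.8),
    "isograft": (7.53, 23.24, 71.2),
    "isograft_native": (3.71, 26.4, 86.9),
}

# Baseline R2*, s^-1 (similar across groups pre-contrast).
BASELINE_R2STAR: dict[str, tuple[float, float, float]] = {
    "native": (38.5, 42.8, 50.5),
    "graft": (39.6, 44.2, 52.8),
    # Muscle baseline is not reported; 40 s^-1 (T2* = 25 ms) is a typical
    # skeletal-muscle value at 7 T and is held in a narrow band.
    "muscle": (36.0, 40.0, 44.0),
}

# Percent positive F4/80 staining area: (mean, sd) over ten fields.
HISTOLOGY_PERCENT_AREA: dict[str, tuple[float, float]] = {
    "allograft": (2.70, 0.84),
    "isograft": (0.52, 0.44),
}

# Significance bounds reported for the headline comparisons.
P_BOUND_ALLO_VS_ISO_INDEXED = 0.01
P_BOUND_GRAFT_VS_NATIVE_PAIRED = 0.01
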