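"""Published benchmark-table values used as test inputs.

Metric columns (and their parenthesized competition ranks) as printed for the
pathological-image benchmark, plus the Cp/Sp columns printed for the planed
surface at 1.25 um step distance.  Operator order: SMD, Roberts, Tenengrad,
Brenner, EOG, EOL, SML, Variance, Vollath, FFT, DCT, DWT.
"""

import math

NAN = math.nan

#: column -> (ranking direction, printed values, printed ranks; NaN = unranked)
PATHOLOGY_TABLE = {
    "Ws": (
        "asc",
        [7.91, 6.71, 6.94, 7.26, 6.65, 5.58, 5.59, 8.52, 7.94, 7.59, 7.58, 5.26],
        [10, 5, 6, 7, 4, 2, 3, 12, 11, 9, 8, 1],
    ),
    "Rsg": (
        "desc",
        [3.4821, 4.6123, 4.6608, 5.0280, 4.6285, 7.6830, 7.5626, 2.0959,
         3.4270, 3.2517, 3.2801, 10.3261],
        [8, 7, 5, 4, 6, 2, 3, 12, 9, 11, 10, 1],
    ),
    "Cp": (
        "desc",
        [0.2196, 0.4374, 0.4099, 0.4432, 0.4416, 0.5273, 0.5290, 0.1204,
         0.2428, 0.2930, 0.2992, 0.5885],
        [11, 6, 7, 4, 5, 3, 2, 12, 10, 9, 8, 1],
    ),
    "RRMSE": (
        "asc",
        [0.4870, 0.3287, 0.0726, 0.2002, 0.6012, 2.9718, 2.8498, 0.0045,
         0.4213, 0.1047, 0.1122, 3.0205],
        [8, 6, 2, 5, 9, 11, 10, 1, 7, 3, 4, 12],
    ),
    "FWHM": (
        "asc",
        [7.11, 4.03, 4.19, 4.27, 4.03, 3.52, 3.47, NAN, 6.95, 5.54, 5.46, 3.18],
        [11, 4, 6, 7, 4, 3, 2, NAN, 10, 9, 8, 1],
    ),
    "Sp": (
        "desc",
        [0.1100, 0.2194, 0.2058, 0.2216, 0.2214, 0.2637, 0.2646, 0.0604,
         0.1215, 0.1476, 0.1507, 0.2953],
        [11, 6, 7, 4, 5, 3, 2, 12, 10, 9, 8, 1],
    ),
    "time_ms": (
        "asc",
        [24.4, 25.0, 31.9, 23.5, 26.8, 33.8, 36.2, 6.9, 16.8, 48.5, 88.1, 75.6],
        [4, 5, 7, 3, 6, 8, 9, 1, 2, 10, 12, 11],
    ),
}

#: planed surface, 1.25 um step: Cp and Sp columns with their printed ranges
PLANED_CP = [0.0127, 0.0244, 0.0227, 0.0246, 0.0242, 0.0391, 0.0400, 0.0068,
             0.0151, 0.0169, 0.0170, 0.0394]
PLANED_SP = [0.0064, 0.0122, 0.0113, 0.0123, 0.0121, 0.0196, 0.0200, 0.0034,
             0.0076, 0.0085, 0.0085, 0.0197]
PLANED_CP_RANGE = 0.0332
PLANED_SP_RANGE = 0.0166
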