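"""Worked-example data: published germination trait means of the tomato IL trial.

Line-level means of the three germination vigor traits (final percent, T50 in
days, SD-plate in days) for the M82 control and a subset of S. pennellii
introgression lines, under fresh-water (SDF) and saline (SDS) maternal
irrigation.  These serve as the package's worked example for the salinity
fold-change computation: FC = SDS mean / SDF mean per line and trait.
"""

import pandas as pd

__all__ = ["germination_line_means", "SALINITY_FC_EXPECTED"]

_ROWS = [
    # line,      condition, percent, t50,  sd_plate
    ("M82",      "SDF", 95.13, 2.66, 1.00),
    ("M82",      "SDS", 90.75, 3.42, 1.82),
    ("IL1-1-3",  "SDF", 79.24, 5.00, 1.49),
    ("IL1-1-3",  "SDS", 93.94, 3.08, 0.94),
    ("IL2-1-1",  "SDF", 97.91, 3.00, 1.41),
    ("IL2-1-1",  "SDS", 100.00, 2.50, 0.93),
    ("IL2-5",    "SDF", 98.67, 3.00, 1.14),
    ("IL2-5",    "SDS", 91.87, 3.00, 1.07),
    ("IL3-4",    "SDF", 85.71, 4.00, 0.85),
    ("IL3-4",    "SDS", 99.00, 4.00, 1.18),
    ("IL4-1",    "SDF", 92.58, 3.00, 2.21),
    ("IL4-1",    "SDS", 95.98, 3.00, 1.28),
    ("IL8-3-1",  "SDF", 97.22, 2.33, 0.58),
    ("IL8-3-1",  "SDS", 100.00, 2.33, 1.01),
    ("IL11-4",   "SDF", 100.00, 3.50, 0.68),
    ("IL11-4",   "SDS", 96.67, 3.00, 1.19),
]

# published fold-change values those means reproduce (ratio SDS/SDF,
# printed to three decimals)
SALINITY_FC_EXPECTED = {
    ("M82", "fc_percent"): 0.954,
    ("M82", "fc_t50"): 1.286,
    ("IL1-1-3", "fc_percent"): 1.186,
    ("IL2-1-1", "fc_percent"): 1.021,
    ("IL2-1-1", "fc_t50"): 0.833,
    ("IL2-5", "fc_percent"): 0.931,
    ("IL3-4", "fc_percent"): 1.155,
    ("IL8-3-1", "fc_percent"): 1.029,
    ("IL11-4", "fc_percent"): 0.967,
    ("IL4-1", "fc_sd_plate"): 0.579,
}


def germination_line_means(condition: str) -> pd.DataFrame:
    """Line-indexed trait means for one maternal irrigation condition."""
    if condition not in ("SDF", "SDS"):
        raise ValueError("condition must be 'SDF' or 'SDS'")
    rows = [(r[0], r[2], r[3], r[4]) for r in _ROWS if r[1] == condition]
    return pd.DataFrame(rows, columns=["line", "percent", "t50", "sd_plate"]
                        ).set_index("line")
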