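"""Reference cohort summary used for arithmetic validation.

Group-level summary statistics (mean and SD of subfoveal choroidal
areas, in um^2) from a published two-centre clinical cohort of 40 CSC
eyes, their 40 fellow eyes and 40 age-matched control eyes, measured
with the same binarization protocol this package implements.  The
per-eye data are not public; the printed group summaries serve as
fixture inputs for exact arithmetic checks: additivity of the
compartments (hypo + hyper = total, inner + outer = whole) and the
between-group percent ratios of means.

Also included is the cohort's sex distribution, used to validate the
Pearson chi-square test.
"""

from __future__ import annotations

import pandas as pd

#: mean (SD) choroidal areas in um^2 per group and compartment.
REFERENCE_AREAS: dict[str, dict[str, dict[str, tuple[int, int]]]] = {
    "control": {
        "whole": {"total": (442877, 137153), "hypo": (301696, 101640), "hyper": (141181, 43339)},
        "inner": {"total": (86646, 18200), "hypo": (66016, 12998), "hyper": (20630, 8128)},
        "outer": {"total": (356231, 128928), "hypo": (235680, 97352), "hyper": (120551, 40045)},
    },
    "CSC": {
        "whole": {"total": (702101, 160652), "hypo": (520020, 132420), "hyper": (182081, 49484)},
        "inner": {"total": (109111, 30665), "hypo": (73471, 22797), "hyper": (35640, 10229)},
        "outer": {"total": (592990, 146632), "hypo": (446549, 121214), "hyper": (146441, 49822)},
    },
    "fellow": {
        "whole": {"total": (580833, 155547), "hypo": (428276, 141512), "hyper": (152557, 29996)},
        "inner": {"total": (96730, 24579), "hypo": (73822, 19008), "hyper": (22908, 8522)},
        "outer": {"total": (484103, 146470), "hypo": (354455, 135816), "hyper": (129648, 28847)},
    },
}

#: eyes per group in the reference cohort.
REFERENCE_N = 40

#: sex distribution (male, female) of the CSC and control arms.
REFERENCE_SEX_TABLE: dict[str, tuple[int, int]] = {
    "CSC": (31, 9),
    "control": (26, 14),
}


def reference_means_frame() -> pd.DataFrame:
    """The reference group means as a tidy frame (one row per group,
    columns ``<layer>_<component>_um2``), convenient for
    :func:`chorobin.quantification.ratio_report`-style arithmetic."""
    rows = []
    for group, layers in REFERENCE_AREAS.items():
        row: dict[str, object] = {"case_id": f"{group}-mean", "group": group}
        for layer, comps in layers.items():
            for comp, (mean, _sd) in comps.items():
                row[f"{layer}_{comp}_um2"] = float(mean)
        rows.append(row)
    return pd.DataFrame(rows)
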