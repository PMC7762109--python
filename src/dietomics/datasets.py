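"""Bundled reference data: stool metabolome log2 peak areas.

A small published reference table from a pediatric Crohn's diet-intervention
trial: GC-MS global-fraction log2 peak areas for 19 metabolites in five
patients at baseline and at week 2 (after two weeks on a strict specific
carbohydrate diet), together with the p-values and direction labels
reported alongside them.  One week-2 measurement (stigmasterol, patient
P005) is missing, which exercises the unequal-group-size path of the
two-sample test.  Values are printed to two decimals, so p-values
recomputed from this table match the reported ones to roughly 1e-3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import AbundanceMatrix, Arm, SampleMeta, Semantics, Timepoint

__all__ = ["global_metabolites_baseline_week2", "reported_pvalues"]

_PATIENTS = ["P001", "P005", "P007", "P010", "P015"]

# metabolite: (baseline areas P001..P015, week-2 areas P001..P015,
#              reported p, reported pattern)
_ROWS: dict[str, tuple[list[float], list[float | None], float, str]] = {
    "oleic acid": ([26.24, 26.56, 27.35, 26.88, 27.19],
                   [27.38, 27.99, 27.65, 28.50, 28.13], 0.0048, "Up"),
    "campesterol": ([21.53, 22.16, 22.54, 23.25, 21.90],
                    [20.21, 20.92, 21.32, 21.09, 21.41], 0.0076, "Down"),
    "stigmasterol": ([21.48, 20.63, 20.75, 21.86, 21.06],
                     [20.17, None, 20.10, 19.81, 20.56], 0.0113, "Down"),
    "lignoceric acid": ([21.17, 20.91, 20.99, 21.94, 21.43],
                        [21.50, 22.00, 21.83, 22.07, 22.62], 0.0248, "Up"),
    "1-eicosanol": ([23.06, 20.75, 20.28, 23.03, 22.01],
                    [19.97, 19.97, 20.49, 19.16, 20.81], 0.0254, "Down"),
    "phosphate ion": ([24.61, 24.37, 25.55, 24.11, 25.10],
                      [24.74, 26.81, 25.87, 26.26, 25.67], 0.0312, "Up"),
    "1-monolinolein": ([21.56, 22.50, 22.64, 21.70, 22.05],
                       [22.41, 22.93, 22.32, 22.88, 23.18], 0.0404, "Up"),
    "pimelic acid": ([19.87, 21.15, 19.46, 19.30, 22.11],
                     [21.97, 21.42, 21.78, 21.27, 21.96], 0.0490, "Up"),
    "maltose": ([19.82, 20.24, 20.92, 19.64, 20.95],
                [20.37, 19.32, 18.83, 18.60, 19.65], 0.0494, "Down"),
    "L-cysteine": ([20.97, 21.22, 20.77, 21.31, 22.76],
                   [21.75, 24.69, 23.15, 22.23, 22.19], 0.0585, "Up"),
    "stearic acid": ([22.72, 23.86, 23.65, 24.28, 23.32],
                     [22.32, 22.96, 23.31, 22.85, 23.01], 0.0587, "Down"),
    "3-hydroxypyridine": ([17.18, 18.72, 19.59, 17.45, 16.97],
                          [19.76, 20.44, 21.08, 19.89, 17.28], 0.0706, "Up"),
    "methyl oleate": ([21.96, 22.40, 23.10, 22.88, 21.08],
                      [20.87, 24.64, 24.61, 25.62, 25.39], 0.0715, "Up"),
    "L-glutamic acid": ([26.25, 25.79, 26.05, 25.64, 23.79],
                        [26.62, 27.65, 26.05, 26.49, 26.12], 0.0734, "Up"),
    "N-acetyl-D-mannosamine": ([22.94, 24.14, 24.32, 25.04, 23.36],
                               [22.55, 20.95, 23.72, 23.19, 23.34], 0.0833, "Down"),
    "heptadecanoic acid": ([23.77, 24.25, 23.90, 26.11, 24.01],
                           [23.27, 23.42, 24.06, 22.90, 23.75], 0.0863, "Down"),
    "myristic acid": ([24.76, 24.77, 24.39, 25.79, 24.69],
                      [24.16, 23.84, 25.08, 23.59, 24.32], 0.0865, "Down"),
    "2-oleoylglycerol": ([20.83, 20.88, 21.44, 20.83, 21.34],
                         [20.90, 21.78, 21.16, 22.25, 21.85], 0.0970, "Up"),
    "palmitic acid": ([24.91, 25.86, 25.52, 26.46, 25.59],
                      [24.59, 25.15, 25.51, 25.17, 25.20], 0.0998, "Down"),
}


def global_metabolites_baseline_week2() -> tuple[AbundanceMatrix, list[SampleMeta]]:
    """The reference log2-area matrix and its sample metadata.

    Columns are the five baseline samples followed by the five week-2
    samples; the single unmeasured cell is NaN.
    """
    sample_ids = [f"{p}_baseline" for p in _PATIENTS] + [f"{p}_week2" for p in _PATIENTS]
    rows = []
    for met, (base, week2, _, _) in _ROWS.items():
        rows.append([v if v is not None else np.nan for v in base + week2])
    matrix = AbundanceMatrix(
        pd.DataFrame(rows, index=list(_ROWS), columns=sample_ids),
        Semantics.LOG2_AREA,
    )
    arms = {"P001": Arm.WF, "P005": Arm.MSCD, "P007": Arm.MSCD,
            "P010": Arm.MSCD, "P015": Arm.WF}
    meta = [
        SampleMeta(f"{p}_{t.value}", p, t, arms[p])
        for p in _PATIENTS
        for t in (Timepoint.BASELINE, Timepoint.WEEK2)
    ]
    return matrix, meta


def reported_pvalues() -> dict[str, tuple[float, str]]:
    """Reported p-value and direction label per metabolite."""
    return {met: (p, pattern) for met, (_, _, p, pattern) in _ROWS.items()}
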