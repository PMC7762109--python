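"""Independent brute-force re-implementations used as test oracles.

These are written directly against the plain-language screening rules and
stay deliberately naive (no vectorization, no shared code with the package)
so they can serve as an independent cross-check.
"""

from __future__ import annotations

import math
import statistics


def brute_force_screen(
    per_patient_log2fc: dict[str, float],
    fold_threshold: float,
    require_mean_gt_sd: bool,
    min_patients_hit: int,
    min_patients_hit_decrease: int | None = None,
) -> str:
    """Direction verdict for one feature, evaluated rule by rule.

    Rule 1: at least ``min_patients_hit`` patients changed at least
    ``fold_threshold``-fold, and every such patient moved the same way.
    Rule 2: no patient changed at least ``fold_threshold``-fold the
    opposite way.  Rule 3 (optional): the magnitude of the mean log2 fold
    change across all patients exceeds the sample standard deviation
    (vacuously true for one patient).
    """
    if min_patients_hit_decrease is None:
        min_patients_hit_decrease = min_patients_hit
    L = math.log2(fold_threshold)
    vals = list(per_patient_log2fc.values())
    ups = [v for v in vals if v >= L]
    downs = [v for v in vals if v <= -L]

    def crit3() -> bool:
        if not require_mean_gt_sd or len(vals) < 2:
            return True
        return abs(statistics.mean(vals)) > statistics.stdev(vals)

    if ups and not downs and len(ups) >= min_patients_hit and crit3():
        return "increase"
    if downs and not ups and len(downs) >= min_patients_hit_decrease and crit3():
        return "decrease"
    return "none"
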