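"""Cross-patient fold-change consistency screening.

Small longitudinal cohorts rarely support formal significance testing, so
features (EC classes, taxa) are screened with a consistency heuristic on
per-patient fold changes between two timepoints.  A feature is reported
when (1) it changed at least ``fold_threshold``-fold in at least
``min_patients_hit`` patients, all such hits agreeing in direction; (2) no
patient shows an opposite change of the same magnitude; and (3), when
required, the magnitude of the mean fold change across all patients exceeds
its standard deviation.  All three criteria are evaluated on log2 fold
changes: the log scale makes increases and decreases symmetric, and the
mean-versus-SD comparison is ill-behaved on raw ratios.  The ratio scale
for criterion (3) remains available via ``crit3_scale="ratio"``.

The same machinery covers both screen variants used in practice: the
2-fold three-criterion screen for EC profiles and the 10-fold
k-of-n screen (criterion 3 off, several patients required) for taxa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_core import (
    AbundanceMatrix,
    DataError,
    SampleMeta,
    Semantics,
    Timepoint,
    get_logger,
    sample_for,
)

log = get_logger("screening")

__all__ = [
    "FoldChangeSet",
    "ScreenVerdict",
    "default_pseudocount",
    "fold_changes",
    "consistency_screen",
    "kofn_screen",
]

#: slack for the inclusive fold-threshold boundary under float log2 arithmetic
_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class FoldChangeSet:
    """Per-patient log2 fold changes of one feature between two timepoints."""

    feature_id: str
    per_patient_log2fc: dict[str, float]

    def __post_init__(self) -> None:
        if not self.per_patient_log2fc:
            raise DataError(f"feature {self.feature_id!r}: no patients")
        for pid, v in self.per_patient_log2fc.items():
            if not math.isfinite(v):
                raise DataError(
                    f"feature {self.feature_id!r}, patient {pid!r}: non-finite log2fc"
                )


@dataclass(frozen=True)
class ScreenVerdict:
    """Screening outcome for one feature.

    ``direction`` is ``increase``/``decrease`` only when every active
    criterion passes, else ``none``.  ``n_patients_hit`` counts patients at
    or beyond the fold threshold in the candidate direction.
    """

    feature_id: str
    direction: str  # "increase" | "decrease" | "none"
    crit1_pass: bool
    crit2_pass: bool
    crit3_pass: bool
    n_patients_hit: int
    mean_log2fc: float
    sd_log2fc: float


def default_pseudocount(matrix: AbundanceMatrix) -> float:
    """Half the smallest non-zero value in the matrix (global, data-scaled)."""
    arr = matrix.values.to_numpy()
    positive = arr[(~np.isnan(arr)) & (arr > 0)]
    if positive.size == 0:
        raise DataError("matrix has no positive values; cannot derive pseudocount")
    return float(positive.min() / 2.0)


def fold_changes(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    t1: Timepoint,
    t2: Timepoint,
    patients: Sequence[str],
    pseudocount: float | None = None,
) -> list[FoldChangeSet]:
    """Per-patient log2 fold changes of every feature between two timepoints.

    ``log2fc = log2((a2 + c) / (a1 + c))`` with pseudocount ``c`` (default:
    half the smallest non-zero value in the matrix).  Missing entries are
    treated as unobserved, i.e. 0 abundance; a feature absent at both
    timepoints yields log2fc = 0 for that patient.
    """
    if matrix.semantics not in (
        Semantics.RELATIVE_ABUNDANCE,
        Semantics.READ_COUNT,
        Semantics.PSM_COUNT,
    ):
        raise DataError(
            f"fold_changes expects count-like or relative semantics, "
            f"got {matrix.semantics.value}"
        )
    t1, t2 = Timepoint(t1), Timepoint(t2)
    if pseudocount is None:
        pseudocount = default_pseudocount(matrix)
    if pseudocount < 0:
        raise DataError("pseudocount must be >= 0")
    cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pid in patients:
        pair = []
        for t in (t1, t2):
            sm = sample_for(meta, pid, t)
            if sm is None or sm.sample_id not in matrix.sample_ids:
                raise DataError(
                    f"patient {pid!r} has no sample at timepoint {t.value!r}"
                )
            pair.append(np.nan_to_num(matrix.column(sm.sample_id).to_numpy(), nan=0.0))
        cols[pid] = (pair[0], pair[1])

    out: list[FoldChangeSet] = []
    for i, fid in enumerate(matrix.feature_ids):
        per_patient = {}
        for pid, (a1, a2) in cols.items():
            if a1[i] == 0 and a2[i] == 0:
                per_patient[pid] = 0.0
            else:
                per_patient[pid] = float(
                    np.log2((a2[i] + pseudocount) / (a1[i] + pseudocount))
                )
        out.append(FoldChangeSet(feature_id=fid, per_patient_log2fc=per_patient))
    return out


def _screen_one(
    fcs: FoldChangeSet,
    L: float,
    require_mean_gt_sd: bool,
    min_patients_hit: int,
    min_patients_hit_decrease: int,
    crit3_scale: str,
) -> ScreenVerdict:
    vals = np.array(list(fcs.per_patient_log2fc.values()), dtype=float)
    up_hits = int(np.sum(vals >= L - _BOUNDARY_EPS))
    down_hits = int(np.sum(vals <= -L + _BOUNDARY_EPS))
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    if up_hits > 0 and down_hits > 0:
        # hits disagree in sign: no candidate direction, and the opposite
        # change rule is violated by construction
        return ScreenVerdict(fcs.feature_id, "none", False, False, False,
                             max(up_hits, down_hits), mean, sd)
    if up_hits > 0:
        candidate, hits, needed = "increase", up_hits, min_patients_hit
    elif down_hits > 0:
        candidate, hits, needed = "decrease", down_hits, min_patients_hit_decrease
    else:
        crit3 = _crit3(vals, mean, sd, crit3_scale) if require_mean_gt_sd else True
        return ScreenVerdict(fcs.feature_id, "none", False, True, crit3, 0, mean, sd)

    crit1 = hits >= needed
    crit2 = True  # no opposite hit by construction of the branch above
    crit3 = _crit3(vals, mean, sd, crit3_scale) if require_mean_gt_sd else True
    direction = candidate if (crit1 and crit2 and crit3) else "none"
    return ScreenVerdict(fcs.feature_id, direction, crit1, crit2, crit3, hits, mean, sd)


def _crit3(vals: np.ndarray, mean: float, sd: float, scale: str) -> bool:
    """Mean magnitude exceeds SD; vacuously true for a single patient."""
    if len(vals) < 2:
        return True
    if scale == "ratio":
        ratios = np.exp2(vals)
        return abs(float(np.mean(ratios))) > float(np.std(ratios, ddof=1))
    return abs(mean) > sd


def consistency_screen(
    fcs: Iterable[FoldChangeSet],
    fold_threshold: float = 2.0,
    require_mean_gt_sd: bool = True,
    min_patients_hit: int = 1,
    min_patients_hit_decrease: int | None = None,
    crit3_scale: str = "log2",
) -> list[ScreenVerdict]:
    """Apply the three-criterion consistency screen to every feature.

    ``fold_threshold`` is on the ratio scale (2.0 means two-fold either
    way); the boundary is inclusive.  ``crit3_scale`` selects whether the
    mean-versus-SD comparison runs on log2 fold changes (default) or raw
    ratios.
    """
    if fold_threshold <= 1.0:
        raise DataError(f"fold_threshold must exceed 1, got {fold_threshold}")
    if crit3_scale not in ("log2", "ratio"):
        raise DataError(f"unknown crit3_scale {crit3_scale!r}")
    L = math.log2(fold_threshold)
    if min_patients_hit_decrease is None:
        min_patients_hit_decrease = min_patients_hit
    return [
        _screen_one(f, L, require_mean_gt_sd, min_patients_hit,
                    min_patients_hit_decrease, crit3_scale)
        for f in fcs
    ]


def kofn_screen(
    fcs: Iterable[FoldChangeSet],
    fold_threshold: float = 10.0,
    min_patients_hit: int = 4,
    min_patients_hit_decrease: int | None = None,
) -> list[ScreenVerdict]:
    """Large-fold k-of-n screen for taxon abundance shifts.

    Equivalent to :func:`consistency_screen` with the mean-versus-SD rule
    disabled, a 10-fold default threshold and a requirement that at least
    ``min_patients_hit`` patients move concordantly (decrease side
    symmetric unless given its own count).
    """
    return consistency_screen(
        fcs,
        fold_threshold=fold_threshold,
        require_mean_gt_sd=False,
        min_patients_hit=min_patients_hit,
        min_patients_hit_decrease=min_patients_hit_decrease,
    )


def verdict_frame(verdicts: Sequence[ScreenVerdict]):
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": [v.feature_id for v in verdicts],
            "direction": [v.direction for v in verdicts],
            "crit1_pass": [v.crit1_pass for v in verdicts],
            "crit2_pass": [v.crit2_pass for v in verdicts],
            "crit3_pass": [v.crit3_pass for v in verdicts],
            "n_patients_hit": [v.n_patients_hit for v in verdicts],
            "mean_log2fc": [v.mean_log2fc for v in verdicts],
            "sd_log2fc": [v.sd_log2fc for v in verdicts],
        }
    )
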