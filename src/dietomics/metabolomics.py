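"""Metabolite group comparison and baseline normalization.

Two GC-MS fractions are handled separately.  The *global* fraction arrives
as log2-transformed peak areas and is compared between two sample groups
with a two-sided pooled-variance two-sample t-test per metabolite (missing
values dropped per metabolite, so group sizes can differ between
metabolites).  The *volatile* fraction arrives as raw peak areas and is
expressed per patient as percent of that patient's baseline area, then
classified into increase/decrease trends by a cross-patient majority rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    AbundanceMatrix,
    DataError,
    SampleMeta,
    Semantics,
    Timepoint,
    get_logger,
    sample_for,
)

log = get_logger("metabolomics")

__all__ = [
    "MetaboliteTestResult",
    "group_ttest",
    "significant_set",
    "normalize_to_baseline",
    "trend_classify",
    "paired_baseline_test",
]


@dataclass(frozen=True)
class MetaboliteTestResult:
    """Two-group comparison of one metabolite's log2 areas.

    ``pattern`` is "Up" when the second group's mean exceeds the first's,
    else "Down".  ``testable`` is False when either group has fewer than
    two non-missing values; ``t_stat``/``p_value`` are NaN in that case.
    """

    metabolite: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    t_stat: float
    df: int
    p_value: float
    pattern: str  # "Up" | "Down"
    testable: bool = True


def group_ttest(
    matrix: AbundanceMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
) -> list[MetaboliteTestResult]:
    """Pooled-variance two-sample t-test per metabolite between two groups.

    ``group1``/``group2`` are disjoint lists of sample ids (columns of the
    log2-area matrix).  Missing values are dropped per metabolite; a
    metabolite with fewer than two values in either group is returned
    flagged untestable rather than silently skipped.
    """
    if matrix.semantics is not Semantics.LOG2_AREA:
        raise DataError(
            f"group_ttest expects log2_area semantics, got {matrix.semantics.value}"
        )
    overlap = set(group1) & set(group2)
    if overlap:
        raise DataError(f"groups overlap: {sorted(overlap)}")
    sub1 = matrix.values[list(group1)].to_numpy()
    sub2 = matrix.values[list(group2)].to_numpy()
    # vectorized pooled t over all metabolites at once (missing dropped per
    # metabolite through nan-aware sums); agrees with scipy's equal-variance
    # two-sample test to machine precision
    n1 = (~np.isnan(sub1)).sum(axis=1)
    n2 = (~np.isnan(sub2)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nansum(sub1, axis=1) / n1
        m2 = np.nansum(sub2, axis=1) / n2
        ss1 = np.nansum((sub1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((sub2 - m2[:, None]) ** 2, axis=1)
        df = n1 + n2 - 2
        sp2 = (ss1 + ss2) / np.maximum(df, 1)
        t_arr = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p_arr = 2.0 * stats.t.sf(np.abs(t_arr), np.maximum(df, 1))
    results: list[MetaboliteTestResult] = []
    for i, met in enumerate(matrix.feature_ids):
        testable = bool(n1[i] >= 2 and n2[i] >= 2)
        results.append(
            MetaboliteTestResult(
                met,
                int(n1[i]),
                int(n2[i]),
                float(m1[i]),
                float(m2[i]),
                float(t_arr[i]) if testable else float("nan"),
                int(max(df[i], 0)),
                float(p_arr[i]) if testable else float("nan"),
                "Up" if m2[i] > m1[i] else "Down",
                testable=testable,
            )
        )
    return results


def significant_set(
    results: Sequence[MetaboliteTestResult], alpha: float = 0.05
) -> list[str]:
    """Metabolites whose test p-value is at most ``alpha`` (inclusive)."""
    return [r.metabolite for r in results if r.testable and r.p_value <= alpha]


def results_frame(results: Sequence[MetaboliteTestResult]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in results],
            "n1": [r.n1 for r in results],
            "n2": [r.n2 for r in results],
            "mean1": [r.mean1 for r in results],
            "mean2": [r.mean2 for r in results],
            "t_stat": [r.t_stat for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "pattern": [r.pattern for r in results],
            "testable": [r.testable for r in results],
        }
    )
    return frame.sort_values("p_value", kind="stable").reset_index(drop=True)


def normalize_to_baseline(
    raw: AbundanceMatrix, meta: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Express raw volatile areas as percent of each patient's baseline.

    Returns a frame indexed by metabolite with one column per
    (patient, timepoint) pair, values = 100 * area / baseline area.  A zero
    baseline with a later non-zero area yields a missing value (with a
    warning); 0/0 yields 0.  The baseline column itself is 100 wherever the
    baseline was measured and non-zero.
    """
    if raw.semantics is not Semantics.RAW_AREA:
        raise DataError(
            f"normalize_to_baseline expects raw_area semantics, got {raw.semantics.value}"
        )
    patients: list[str] = []
    for m in meta:
        if m.patient_id not in patients and m.sample_id in raw.sample_ids:
            patients.append(m.patient_id)
    columns: dict[tuple[str, str], np.ndarray] = {}
    for pid in patients:
        base = sample_for(meta, pid, Timepoint.BASELINE)
        if base is None or base.sample_id not in raw.sample_ids:
            raise DataError(f"patient {pid!r} has no baseline sample")
        b = raw.column(base.sample_id).to_numpy()
        for t in Timepoint:
            sm = sample_for(meta, pid, t)
            if sm is None or sm.sample_id not in raw.sample_ids:
                continue
            a = raw.column(sm.sample_id).to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = 100.0 * a / b
            zero_base = (b == 0) & (a == 0)
            pct[zero_base] = 0.0
            bad = (b == 0) & (a > 0)
            if bad.any():
                names = [raw.feature_ids[i] for i in np.flatnonzero(bad)]
                log.warning(
                    "patient %s %s: zero baseline with non-zero area for %s; "
                    "recorded as missing", pid, t.value, names,
                )
                pct[bad] = np.nan
            columns[(pid, t.value)] = pct
    frame = pd.DataFrame(columns, index=raw.feature_ids)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["patient", "timepoint"])
    return frame


def trend_classify(
    profile: pd.DataFrame, from_t: Timepoint, to_t: Timepoint
) -> dict[str, str]:
    """Label each metabolite's direction of change between two timepoints.

    ``profile`` is the percent-of-baseline frame from
    :func:`normalize_to_baseline`.  A metabolite is a ``decrease`` when the
    later value is strictly below the earlier one in a strict majority of
    patients having both measurements (``increase`` symmetric, ``none``
    otherwise).
    """
    from_t, to_t = Timepoint(from_t), Timepoint(to_t)
    out: dict[str, str] = {}
    patients = profile.columns.get_level_values("patient").unique()
    for met in profile.index:
        ups = downs = n = 0
        for pid in patients:
            try:
                a = profile.loc[met, (pid, from_t.value)]
                b = profile.loc[met, (pid, to_t.value)]
            except KeyError:
                continue
            if pd.isna(a) or pd.isna(b):
                continue
            n += 1
            if b > a:
                ups += 1
            elif b < a:
                downs += 1
        if n and ups > n / 2:
            out[met] = "increase"
        elif n and downs > n / 2:
            out[met] = "decrease"
        else:
            out[met] = "none"
    return out


def paired_baseline_test(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    metabolite: str,
    t: Timepoint,
) -> tuple[float, bool]:
    """Paired two-sided t-test of per-patient change from baseline.

    Returns ``(p_value, degenerate)``.  With fewer than two complete
    patient pairs the metabolite is untestable (p = NaN).  A non-zero
    change that is exactly constant across patients has zero variance; the
    p-value is then reported as 0.0 with the degenerate flag set (all-zero
    changes give p = 1).
    """
    t = Timepoint(t)
    if metabolite not in matrix.feature_ids:
        raise DataError(f"unknown metabolite {metabolite!r}")
    row = matrix.values.loc[metabolite]
    pairs: list[tuple[float, float]] = []
    patients = {m.patient_id for m in meta if m.sample_id in matrix.sample_ids}
    for pid in sorted(patients):
        base = sample_for(meta, pid, Timepoint.BASELINE)
        later = sample_for(meta, pid, t)
        if base is None or later is None:
            continue
        if base.sample_id not in row.index or later.sample_id not in row.index:
            continue
        a, b = row[base.sample_id], row[later.sample_id]
        if pd.isna(a) or pd.isna(b):
            continue
        pairs.append((float(a), float(b)))
    if len(pairs) < 2:
        return float("nan"), False
    diffs = np.array([b - a for a, b in pairs])
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs.mean(), 0.0):
            return 1.0, False
        return 0.0, True
    _, p = stats.ttest_rel([a for a, _ in pairs], [b for _, b in pairs])
    return float(p), False
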