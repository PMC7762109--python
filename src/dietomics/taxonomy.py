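"""Species-level taxonomic filtering, richness and inverse Simpson diversity.

The filtering rule mirrors a common shotgun-metagenomics convention: only
species-rank classifications are kept, human reads are excluded, and a
taxon must average at least ``min_mean_reads`` reads per sample across the
whole run (a single global filter, so every sample sees the same retained
taxon set).  Diversity is the inverse Simpson index, 1 / sum(p_i^2) — the
effective number of equally abundant species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    AbundanceMatrix,
    DataError,
    Rank,
    Semantics,
    TaxonCount,
    get_logger,
)

log = get_logger("taxonomy")

__all__ = [
    "DiversityResult",
    "filter_taxa",
    "inverse_simpson",
    "diversity_table",
    "to_relative",
]


@dataclass(frozen=True)
class DiversityResult:
    """Richness and diversity of one sample after filtering.

    ``richness`` counts retained taxa with a positive count in the sample;
    ``retained_taxa`` is the global count of taxa passing the filter, which
    is shared by all samples and is the bound ``inv_simpson <= richness``
    refers to.
    """

    sample_id: str
    richness: int
    inv_simpson: float
    retained_taxa: int


def filter_taxa(
    counts: Iterable[TaxonCount], min_mean_reads: float = 100.0
) -> AbundanceMatrix:
    """Build the read-count matrix of retained species.

    Keeps taxa with rank ``species``, not flagged human, whose mean read
    count over all samples in the run is at least ``min_mean_reads``
    (inclusive boundary).  Retained taxa absent from a sample get an
    explicit 0.  Sample column order follows first appearance in the input.
    """
    counts = list(counts)
    if not counts:
        raise DataError("empty taxon count input")
    sample_ids: list[str] = []
    for c in counts:
        if c.sample_id not in sample_ids:
            sample_ids.append(c.sample_id)
    species = [c for c in counts if c.rank is Rank.SPECIES and not c.is_human]
    table: dict[str, dict[str, int]] = {}
    taxa_order: list[str] = []
    for c in species:
        if c.taxon_name not in table:
            table[c.taxon_name] = {}
            taxa_order.append(c.taxon_name)
        table[c.taxon_name][c.sample_id] = c.read_count
    n = len(sample_ids)
    retained = [
        t for t in taxa_order if sum(table[t].values()) / n >= min_mean_reads
    ]
    arr = np.array(
        [[table[t].get(s, 0) for s in sample_ids] for t in retained], dtype=float
    ).reshape(len(retained), n)
    log.info(
        "filter_taxa: %d species -> %d retained (mean >= %g reads), %d samples",
        len(taxa_order), len(retained), min_mean_reads, n,
    )
    return AbundanceMatrix.from_arrays(retained, sample_ids, arr, Semantics.READ_COUNT)


def inverse_simpson(column: Sequence[float] | np.ndarray) -> float:
    """Inverse Simpson index of one abundance column.

    Computes 1 / sum(p_i^2) with p_i the proportions of the column; zeros
    contribute nothing, so the result is invariant to sequencing depth and
    bounded by the number of positive entries.
    """
    x = np.asarray(column, dtype=float)
    x = x[~np.isnan(x)]
    if np.any(x < 0):
        raise DataError("inverse_simpson: negative abundances")
    total = x.sum()
    if total <= 0:
        raise DataError("inverse_simpson: column has no positive values")
    p = x / total
    return float(1.0 / np.sum(p * p))


def diversity_table(matrix: AbundanceMatrix) -> list[DiversityResult]:
    """Per-sample richness and inverse Simpson over a filtered count matrix.

    Emits both the per-sample positive-taxon richness and the global
    retained-taxon count (the filter is global, so the latter is the same
    for every sample and is typically the near-constant figure a run-level
    report shows).
    """
    results = []
    retained = len(matrix.feature_ids)
    for sid in matrix.sample_ids:
        col = matrix.column(sid).to_numpy()
        if np.nansum(col) <= 0:
            raise DataError(f"sample {sid!r}: empty column, diversity undefined")
        results.append(
            DiversityResult(
                sample_id=sid,
                richness=int((col > 0).sum()),
                inv_simpson=inverse_simpson(col),
                retained_taxa=retained,
            )
        )
    return results


def diversity_frame(results: Sequence[DiversityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "richness": [r.richness for r in results],
            "inv_simpson": [r.inv_simpson for r in results],
            "retained_taxa": [r.retained_taxa for r in results],
        }
    )


def to_relative(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Convert a read-count matrix to per-sample relative abundances."""
    arr = matrix.values.to_numpy(dtype=float)
    sums = np.nansum(arr, axis=0)
    if np.any(sums <= 0):
        bad = [s for s, t in zip(matrix.sample_ids, sums) if t <= 0]
        raise DataError(f"cannot normalize zero-total columns: {bad}")
    return AbundanceMatrix.from_arrays(
        matrix.feature_ids, matrix.sample_ids, arr / sums, Semantics.RELATIVE_ABUNDANCE
    )
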