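"""Spectral-count metaproteomics: FDR filtering, two-search merging, parsimony
protein grouping, and EC-level relative abundance.

The quantification model is label-free spectral counting: every peptide-
spectrum match (PSM) retained after target-decoy FDR filtering contributes
one observation to the protein group its peptide is assigned to.  Because
gut-community peptides are frequently shared between homologous proteins,
peptides are assigned to a single representative protein by greedy
maximum-coverage parsimony, and the surviving groups are rolled up to
Enzyme Classification (EC) numbers, where spectral counts are summed and
normalized to per-sample relative abundances.
"""

from __future__ import annotations

import heapq
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    AbundanceMatrix,
    DataError,
    PsmRecord,
    Semantics,
    Source,
    get_logger,
)
from .taxonomy import inverse_simpson

log = get_logger("proteomics")

__all__ = [
    "MergedIdentification",
    "ProteinGroup",
    "EcProfileSummary",
    "filter_fdr",
    "merge_searches",
    "infer_protein_groups",
    "ec_abundance",
    "summarize_profile",
]


@dataclass(frozen=True)
class MergedIdentification:
    """The single identification retained for one MS2 spectrum after the
    sample-specific metagenome and human-reference searches are merged."""

    spectrum_id: str
    sample_id: str
    peptide: str
    protein_refs: tuple[str, ...]
    chosen_source: Source
    score: float


@dataclass
class ProteinGroup:
    """A representative protein standing for all proteins that share its
    peptides, with spectral-count quantification.

    ``psm_count`` counts every merged identification whose peptide belongs
    to the group, so ``psm_count >= len(unique_peptides)`` always holds.
    """

    representative: str
    members: set[str]
    unique_peptides: set[str]
    psm_count: int
    ec_ids: frozenset[str] = frozenset()
    source: Source = Source.METAGENOME

    @property
    def is_human(self) -> bool:
        return self.source is Source.HUMAN

    @property
    def is_contaminant(self) -> bool:
        return self.source is Source.CONTAMINANT


@dataclass(frozen=True)
class EcProfileSummary:
    """Per-sample annotation summary of the EC-level profile.

    ``proteins_identified`` counts all inferred groups; ``proteins_min2``
    counts only groups supported by at least two distinct peptides (the set
    actually quantified).  Contaminant groups are excluded from every count.
    """

    sample_id: str
    proteins_identified: int
    proteins_min2: int
    human_proteins: int
    pct_nonhuman_with_ec: float
    ec_families: int
    ec_inv_simpson: float


def filter_fdr(psms: Sequence[PsmRecord], q_threshold: float = 0.01) -> list[PsmRecord]:
    """Keep PSMs identified below the FDR threshold (``q_value`` strictly
    less than ``q_threshold``), preserving input order."""
    if not (0.0 < q_threshold <= 1.0):
        raise ValueError(f"q_threshold {q_threshold} outside (0, 1]")
    return [p for p in psms if p.q_value < q_threshold]


def merge_searches(
    metagenome_psms: Sequence[PsmRecord], human_psms: Sequence[PsmRecord]
) -> list[MergedIdentification]:
    """Combine the two FDR-filtered searches at the MS2 spectrum level.

    When the same spectrum was identified in both searches the higher match
    score wins; an exact tie is resolved in favour of the sample-specific
    metagenome search, the primary reference.  Spectra seen in only one
    search pass through unchanged.  Output is ordered by (sample, spectrum).
    """
    by_key: dict[tuple[str, str], PsmRecord] = {}
    for records, label in ((metagenome_psms, "metagenome"), (human_psms, "human")):
        seen: set[tuple[str, str]] = set()
        for rec in records:
            key = (rec.sample_id, rec.spectrum_id)
            if key in seen:
                raise DataError(
                    f"duplicate spectrum {rec.spectrum_id!r} in sample "
                    f"{rec.sample_id!r} within the {label} search"
                )
            seen.add(key)
            incumbent = by_key.get(key)
            # metagenome records are inserted first, so strict '>' gives the
            # metagenome identification the tie.
            if incumbent is None or rec.score > incumbent.score:
                by_key[key] = rec
    merged = [
        MergedIdentification(
            spectrum_id=rec.spectrum_id,
            sample_id=rec.sample_id,
            peptide=rec.peptide,
            protein_refs=rec.protein_refs,
            chosen_source=rec.source,
            score=rec.score,
        )
        for rec in by_key.values()
    ]
    merged.sort(key=lambda m: (m.sample_id, m.spectrum_id))
    return merged


def infer_protein_groups(
    ids: Sequence[MergedIdentification],
    ec_map: Mapping[str, Iterable[str]],
    min_peptides: int = 2,
) -> list[ProteinGroup]:
    """Assign peptides to representative proteins and build quantified groups.

    Greedy maximum-coverage parsimony: repeatedly pick the protein covering
    the most not-yet-assigned peptides (ties broken lexicographically by
    accession) and assign those peptides to it.  Groups with fewer than
    ``min_peptides`` distinct peptides are then discarded.  ``ec_map`` gives
    the EC annotation of the representative; proteins absent from the map
    simply yield groups with no EC ids.
    """
    if not ids:
        return []
    pep_proteins: dict[str, set[str]] = defaultdict(set)
    pep_psms: Counter[str] = Counter()
    pep_source: dict[str, Counter] = defaultdict(Counter)
    for ident in ids:
        pep_proteins[ident.peptide].update(ident.protein_refs)
        pep_psms[ident.peptide] += 1
        pep_source[ident.peptide][ident.chosen_source] += 1

    protein_peps: dict[str, set[str]] = defaultdict(set)
    for pep, prots in pep_proteins.items():
        for prot in prots:
            protein_peps[prot].add(pep)

    # lazy-greedy max coverage with a stale-entry heap
    unassigned: set[str] = set(pep_proteins)
    heap = [(-len(peps), prot) for prot, peps in protein_peps.items()]
    heapq.heapify(heap)
    assignment: dict[str, list[str]] = {}
    while unassigned and heap:
        neg_cov, prot = heapq.heappop(heap)
        cover = protein_peps[prot] & unassigned
        if not cover:
            continue
        if len(cover) < -neg_cov:
            heapq.heappush(heap, (-len(cover), prot))
            continue
        # tie-break: the heap orders (-coverage, accession), so among equal
        # coverage the lexicographically smallest accession pops first.
        assignment[prot] = sorted(cover)
        unassigned -= cover

    groups: list[ProteinGroup] = []
    for rep in sorted(assignment):
        peps = assignment[rep]
        members: set[str] = set()
        sources: Counter = Counter()
        psm_count = 0
        for pep in peps:
            members.update(pep_proteins[pep])
            psm_count += pep_psms[pep]
            sources.update(pep_source[pep])
        # modal source of the group's PSMs; ties resolved by enum order
        order = [Source.METAGENOME, Source.HUMAN, Source.CONTAMINANT]
        src = max(order, key=lambda s: (sources.get(s, 0), -order.index(s)))
        groups.append(
            ProteinGroup(
                representative=rep,
                members=members,
                unique_peptides=set(peps),
                psm_count=psm_count,
                ec_ids=frozenset(ec_map.get(rep, ())),
                source=src,
            )
        )
    return [g for g in groups if len(g.unique_peptides) >= min_peptides]


def ec_abundance(groups_by_sample: Mapping[str, Sequence[ProteinGroup]]) -> AbundanceMatrix:
    """Roll protein-group spectral counts up to EC classes and normalize.

    Per sample, the raw abundance of EC ``e`` is the sum of ``psm_count``
    over groups annotated with ``e``; a group carrying several EC numbers
    contributes its full count to each (counts stay integral, no
    splitting).  Columns are then normalized to sum to 1 over EC-assigned
    counts only, so the profile is insensitive to each sample's unannotated
    fraction.  Contaminant groups are excluded.  An EC observed in any
    sample appears in every column, with 0 (not missing) where absent.
    """
    raw: dict[str, Counter[str]] = {}
    for sample_id, groups in groups_by_sample.items():
        counts: Counter[str] = Counter()
        for g in groups:
            if g.is_contaminant:
                continue
            for ec in g.ec_ids:
                counts[ec] += g.psm_count
        if not counts:
            raise DataError(f"sample {sample_id!r} has zero EC-assigned PSMs")
        raw[sample_id] = counts

    ec_ids = sorted(set().union(*[set(c) for c in raw.values()]))
    sample_ids = list(groups_by_sample)
    arr = np.zeros((len(ec_ids), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        counts = raw[sid]
        col = np.array([counts.get(ec, 0) for ec in ec_ids], dtype=float)
        arr[:, j] = col / col.sum()
    return AbundanceMatrix.from_arrays(ec_ids, sample_ids, arr, Semantics.RELATIVE_ABUNDANCE)


def summarize_profile(
    ids: Sequence[MergedIdentification],
    groups: Sequence[ProteinGroup],
    ec_matrix: AbundanceMatrix,
    sample_id: str,
    min_peptides: int = 2,
) -> EcProfileSummary:
    """Build the per-sample annotation summary (protein counts, human
    proteins, EC coverage of the non-human fraction, EC family count and EC
    inverse Simpson diversity).

    ``groups`` should be the unfiltered inference output (``min_peptides=1``)
    so that both the total and the two-peptide-supported counts can be
    reported; percentages are computed on the two-peptide set, the set the
    analysis actually uses.
    """
    if sample_id not in ec_matrix.sample_ids:
        raise DataError(f"unknown sample {sample_id!r}")
    groups = [g for g in groups if not g.is_contaminant]
    filtered = [g for g in groups if len(g.unique_peptides) >= min_peptides]
    nonhuman = [g for g in filtered if not g.is_human]
    with_ec = [g for g in nonhuman if g.ec_ids]
    pct = 100.0 * len(with_ec) / len(nonhuman) if nonhuman else float("nan")
    col = ec_matrix.column(sample_id)
    positive = col[col > 0]
    return EcProfileSummary(
        sample_id=sample_id,
        proteins_identified=len(groups),
        proteins_min2=len(filtered),
        human_proteins=sum(1 for g in groups if g.is_human),
        pct_nonhuman_with_ec=pct,
        ec_families=int((col > 0).sum()),
        ec_inv_simpson=inverse_simpson(positive.to_numpy()),
    )


def summary_table(summaries: Sequence[EcProfileSummary]) -> pd.DataFrame:
    """Tabulate per-sample summaries, one row per sample."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "proteins_identified": [s.proteins_identified for s in summaries],
            "proteins_min2": [s.proteins_min2 for s in summaries],
            "human_proteins": [s.human_proteins for s in summaries],
            "pct_nonhuman_with_ec": [s.pct_nonhuman_with_ec for s in summaries],
            "ec_families": [s.ec_families for s in summaries],
            "ec_inv_simpson": [s.ec_inv_simpson for s in summaries],
        }
    )
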