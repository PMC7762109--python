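"""Seeded generators for every input kind, with planted effects.

The generators emulate the statistical structure of a small longitudinal
diet-intervention stool study: five patients sampled at baseline, week 2
and week 12, with strongly patient-specific baselines, shared-peptide
ambiguity in the metaproteome, zero-inflated taxon counts and occasional
missing metabolite measurements.  Effects are *planted* — EC-level
spectral-count shifts per diet arm, large fold changes for chosen taxa in
a chosen number of patients, and mean log2 shifts for chosen metabolites —
and every generator returns the ground truth alongside the data, so each
pipeline stage has an exact recovery target.

Determinism: one global seed fans out to per-table substreams by stable
CRC32 hashing of the table name, so adding a new table never perturbs the
draws of an existing one; the same seed always reproduces byte-identical
tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_core import (
    AbundanceMatrix,
    Arm,
    PsmRecord,
    Rank,
    SampleMeta,
    Semantics,
    Source,
    TaxonCount,
    Timepoint,
)

__all__ = [
    "SynthConfig",
    "PlantedTaxon",
    "make_meta",
    "generate_psm_tables",
    "generate_taxa_counts",
    "generate_metabolite_tables",
]

DEFAULT_ARMS = {
    "P001": Arm.WF,
    "P005": Arm.MSCD,
    "P007": Arm.MSCD,
    "P010": Arm.MSCD,
    "P015": Arm.WF,
}


@dataclass(frozen=True)
class PlantedTaxon:
    """A taxon planted to change ``fold``-fold (ratio scale) between
    baseline and week 12 in the first ``n_patients_affected`` patients."""

    fold: float
    n_patients_affected: int
    direction: str  # "increase" | "decrease"


@dataclass
class SynthConfig:
    """Study-shaped generator settings.

    Defaults mirror the emulated study design: five patients (two on the
    whole-foods arm, three on the modified specific-carbohydrate-diet arm),
    three timepoints, roughly 700 EC families per sample, ~400 species at
    a desk-scale read depth of 1e5, and ~170 identified metabolites with
    log2 areas in the 17–28 range.  ``noise_sd`` is the log2-scale
    measurement noise shared by the proteomic and metabolite generators;
    ``patient_sd`` is the per-patient baseline offset (small, emulating
    residual intensity differences that survive normalization).
    """

    seed: int = 0
    arms: dict[str, Arm] = field(default_factory=lambda: dict(DEFAULT_ARMS))
    n_ecs: int = 700
    n_taxa: int = 400
    n_metabolites: int = 170
    planted_ec_shifts: dict[str, dict[Arm, float]] = field(default_factory=dict)
    planted_ec_patient_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_taxon_folds: dict[str, PlantedTaxon] = field(default_factory=dict)
    planted_metabolite_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    patient_sd: float = 0.15
    shared_peptide_rate: float = 0.2
    human_fraction: float = 0.03
    unclassified_fraction: float = 0.30
    missing_rate: float = 0.01
    read_depth: int = 100_000

    def __post_init__(self) -> None:
        for name in ("shared_peptide_rate", "human_fraction",
                     "unclassified_fraction", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.arms = {p: Arm(a) for p, a in self.arms.items()}

    @property
    def patients(self) -> list[str]:
        return sorted(self.arms)


def _rng(config: SynthConfig, table: str, index: int = 0) -> np.random.Generator:
    """Substream for one table: stable under addition of other tables."""
    return np.random.default_rng(
        [int(config.seed), zlib.crc32(table.encode()) & 0x7FFFFFFF, index]
    )


def make_meta(config: SynthConfig) -> list[SampleMeta]:
    """Sample metadata for the full design (every patient, every timepoint)."""
    rows = []
    for pid in config.patients:
        for t in Timepoint:
            rows.append(
                SampleMeta(
                    sample_id=f"{pid}_{t.value}",
                    patient_id=pid,
                    timepoint=t,
                    arm=config.arms[pid],
                )
            )
    return rows


def _ec_names(n: int) -> list[str]:
    """Synthetic EC-style identifiers (four dotted integer fields)."""
    names = []
    i = 0
    while len(names) < n:
        a, b, c, d = (i // 343) % 7 + 1, (i // 49) % 7 + 1, (i // 7) % 7 + 1, i % 7 + 1
        names.append(f"{a}.{b}.{c}.{d * 10 + (i // 2401)}")
        i += 1
    return names


# ---------------------------------------------------------------------------
# metaproteomics


def _planted_shift(config: SynthConfig, ec: str, patient: str, t: Timepoint) -> float:
    """Planted log2 shift of EC abundance for one patient at one timepoint.

    Arm-level shifts (and per-patient overrides) switch on at week 2 and
    persist through week 12, modelling a sustained dietary response.
    """
    if t is Timepoint.BASELINE:
        return 0.0
    override = config.planted_ec_patient_overrides.get(patient, {})
    if ec in override:
        return override[ec]
    per_arm = config.planted_ec_shifts.get(ec, {})
    return per_arm.get(config.arms[patient], 0.0)


def generate_psm_tables(config: SynthConfig):
    """Per-sample PSM tables for both searches, plus ground truth.

    Returns ``(tables, truth_matrix, ec_map)`` where ``tables`` maps
    sample_id to ``(metagenome_records, human_records)``, ``truth_matrix``
    is the realized EC relative-abundance matrix implied by the true
    records (exactly what a lossless merge/group/normalize should
    recover), and ``ec_map`` maps protein accessions to EC-id sets.

    Structure: each EC class is carried by two homologous proteins whose
    spectral counts follow a patient-specific log-normal baseline times the
    planted effect, with log2-scale noise ``noise_sd``.  A
    ``shared_peptide_rate`` fraction of peptides map to both homologs.
    Unannotated microbial proteins (no EC) and human proteins are added at
    realistic proportions, a handful of spectra are identified in both
    searches (the correct, higher-scoring search wins), a few contaminant
    identifications are included, and ~1% junk records straddle the FDR
    boundary with q-values at or above 0.01 so the FDR filter removes
    exactly them.
    """
    ecs = _ec_names(config.n_ecs)
    planted = set(config.planted_ec_shifts) | {
        ec for ov in config.planted_ec_patient_overrides.values() for ec in ov
    }
    rng_global = _rng(config, "psm/global")
    # abundance floor: planted ECs sit in the upper abundance range so a
    # 2.5-fold decrease stays comfortably above the integer counting floor
    offsets = {}
    for ec in ecs:
        lo, hi = (5.5, 7.0) if ec in planted else (3.0, 5.5)
        offsets[ec] = rng_global.uniform(lo, hi)

    ec_map = {}
    for i, ec in enumerate(ecs):
        ec_map[f"MGP{i:04d}a"] = {ec}
        ec_map[f"MGP{i:04d}b"] = {ec}

    n_unannot = 2 * config.n_ecs  # roughly half of microbial groups end up without an EC
    n_human = max(3, config.n_ecs // 7)

    patient_effect = {
        pid: _rng(config, "psm/patient", i).normal(0.0, config.patient_sd, config.n_ecs)
        for i, pid in enumerate(config.patients)
    }

    tables: dict[str, tuple[list[PsmRecord], list[PsmRecord]]] = {}
    truth_counts: dict[str, np.ndarray] = {}
    sample_ids: list[str] = []

    for p_idx, pid in enumerate(config.patients):
        for t in Timepoint:
            sid = f"{pid}_{t.value}"
            sample_ids.append(sid)
            rng = _rng(config, "psm/sample", p_idx * 10 + list(Timepoint).index(t))
            meta_records: list[PsmRecord] = []
            human_records: list[PsmRecord] = []
            counter = 0

            def spectrum() -> str:
                nonlocal counter
                counter += 1
                return f"sp{counter:06d}"

            ec_count = np.zeros(config.n_ecs)
            for e_idx, ec in enumerate(ecs):
                log2c = (
                    offsets[ec]
                    + patient_effect[pid][e_idx]
                    + _planted_shift(config, ec, pid, t)
                    + rng.normal(0.0, config.noise_sd)
                )
                count = max(4, int(round(2.0 ** log2c)))
                ec_count[e_idx] = count
                prot_a, prot_b = f"MGP{e_idx:04d}a", f"MGP{e_idx:04d}b"
                for k, (prot, c) in enumerate(
                    ((prot_a, (count + 1) // 2), (prot_b, count // 2))
                ):
                    n_pep = max(2, min(5, c // 3))
                    for j in range(c):
                        pep_idx = j % n_pep
                        # the first two PSMs pin two protein-specific
                        # peptides, so every true protein survives the
                        # two-peptide support filter and no spectral count
                        # is lost to parsimony
                        shared = j >= 2 and rng.random() < config.shared_peptide_rate
                        if shared:
                            peptide = f"SHPEP{e_idx:04d}_{pep_idx}"
                            refs = (prot_a, prot_b)
                        else:
                            peptide = f"PEP{e_idx:04d}{'ab'[k]}_{pep_idx}"
                            refs = (prot,)
                        meta_records.append(
                            PsmRecord(
                                spectrum_id=spectrum(),
                                sample_id=sid,
                                peptide=peptide,
                                protein_refs=refs,
                                source=Source.METAGENOME,
                                score=float(rng.uniform(30, 100)),
                                q_value=float(rng.uniform(0.0, 0.009)),
                            )
                        )
            truth_counts[sid] = ec_count

            # unannotated microbial proteins: real identifications, no EC
            for u in range(n_unannot):
                c = int(rng.integers(4, 9))
                for j in range(c):
                    meta_records.append(
                        PsmRecord(
                            spectrum_id=spectrum(),
                            sample_id=sid,
                            peptide=f"UPEP{u:04d}_{j % 2}",
                            protein_refs=(f"MGU{u:04d}",),
                            source=Source.METAGENOME,
                            score=float(rng.uniform(30, 100)),
                            q_value=float(rng.uniform(0.0, 0.009)),
                        )
                    )

            # contaminants (trypsin, keratin): retained through merging but
            # excluded downstream
            for cname in ("CONT_TRYP", "CONT_KER1"):
                for j in range(3):
                    meta_records.append(
                        PsmRecord(
                            spectrum_id=spectrum(),
                            sample_id=sid,
                            peptide=f"CPEP_{cname}_{j % 2}",
                            protein_refs=(cname,),
                            source=Source.CONTAMINANT,
                            score=float(rng.uniform(30, 100)),
                            q_value=float(rng.uniform(0.0, 0.009)),
                        )
                    )

            # human-search records: singleton spectra plus competitors for a
            # few metagenome spectra (losing on score, as the correct
            # identification scores higher)
            for h in range(n_human):
                c = int(rng.integers(4, 9))
                for j in range(c):
                    human_records.append(
                        PsmRecord(
                            spectrum_id=spectrum(),
                            sample_id=sid,
                            peptide=f"HPEP{h:04d}_{j % 2}",
                            protein_refs=(f"HUM{h:04d}",),
                            source=Source.HUMAN,
                            score=float(rng.uniform(30, 100)),
                            q_value=float(rng.uniform(0.0, 0.009)),
                        )
                    )
            n_compete = min(len(meta_records), 50)
            for idx in rng.choice(len(meta_records), size=n_compete, replace=False):
                rec = meta_records[int(idx)]
                human_records.append(
                    PsmRecord(
                        spectrum_id=rec.spectrum_id,
                        sample_id=sid,
                        peptide=f"HXPEP_{rec.spectrum_id}",
                        protein_refs=("HUM_ALT",),
                        source=Source.HUMAN,
                        score=rec.score - float(rng.uniform(1.0, 10.0)),
                        q_value=float(rng.uniform(0.0, 0.009)),
                    )
                )

            # ~1% junk straddling the FDR boundary (q >= 0.01): the strict
            # below-threshold filter removes exactly these
            n_junk = max(1, len(meta_records) // 100)
            for j in range(n_junk):
                q = 0.01 if j == 0 else float(rng.uniform(0.01, 0.05))
                meta_records.append(
                    PsmRecord(
                        spectrum_id=spectrum(),
                        sample_id=sid,
                        peptide=f"JUNKPEP{j:05d}",
                        protein_refs=(f"DECOYJ{j:05d}",),
                        source=Source.METAGENOME,
                        score=float(rng.uniform(10, 40)),
                        q_value=q,
                    )
                )
            tables[sid] = (meta_records, human_records)

    arr = np.column_stack([truth_counts[s] for s in sample_ids])
    truth_matrix = AbundanceMatrix.from_arrays(
        ecs, sample_ids, arr / arr.sum(axis=0), Semantics.RELATIVE_ABUNDANCE
    )
    return tables, truth_matrix, ec_map


# ---------------------------------------------------------------------------
# taxonomy


#: relative safety margin on planted taxon folds; the planted change is
#: "at least" the stated fold, so that integer rounding and the screening
#: pseudocount (both of which attenuate an observed ratio) cannot pull a
#: genuinely planted change back under the screen's own threshold
_PLANT_MARGIN = 1.05


def generate_taxa_counts(config: SynthConfig):
    """Per-sample taxon count tables (baseline and week 12) plus truth.

    Each patient gets its own Dirichlet baseline over the species pool
    (strongly individual microbiomes); baseline counts are multinomial at
    ``read_depth``, with a human species at ``human_fraction``, an
    unclassified bin, and one genus-rank row to exercise rank filtering.

    Planted taxa start at a detectable baseline proportion (0.2% for
    increases, 2% for decreases) and change *at least* ``fold``-fold —
    deterministically in count space, with a 5% margin — in the first
    ``n_patients_affected`` patients at week 12, mirroring organisms whose
    abundance moves by the stated fold or more.  Unaffected patients keep
    their baseline composition up to resampling noise.
    """
    taxa = [f"Taxon_{i:04d}" for i in range(config.n_taxa)]
    for name in config.planted_taxon_folds:
        if name not in taxa:
            raise ValueError(f"planted taxon {name!r} not among generated taxa")
    planted_idx = {name: taxa.index(name) for name in config.planted_taxon_folds}
    species_mass = 1.0 - config.human_fraction - config.unclassified_fraction
    counts: list[TaxonCount] = []
    truth = dict(config.planted_taxon_folds)
    for p_idx, pid in enumerate(config.patients):
        rng = _rng(config, "taxa/patient", p_idx)
        base = rng.dirichlet(np.full(config.n_taxa, 0.7))
        for name, pt in config.planted_taxon_folds.items():
            base[planted_idx[name]] = 0.002 if pt.direction == "increase" else 0.02
        base /= base.sum()
        full = np.concatenate(
            [base * species_mass, [config.human_fraction, config.unclassified_fraction]]
        )
        drawn_b = rng.multinomial(config.read_depth, full)

        # week 12: planted counts are a deterministic function of the same
        # patient's baseline counts; everything else is resampled
        fixed = np.full(len(full), -1, dtype=np.int64)
        for name, pt in config.planted_taxon_folds.items():
            if p_idx >= pt.n_patients_affected:
                continue
            i = planted_idx[name]
            c_b = int(drawn_b[i]) or max(1, int(round(full[i] * config.read_depth)))
            if pt.direction == "increase":
                fixed[i] = int(np.ceil(pt.fold * _PLANT_MARGIN * c_b))
            else:
                fixed[i] = int(np.floor(c_b / (pt.fold * _PLANT_MARGIN)))
        free = fixed < 0
        remaining = config.read_depth - int(fixed[~free].sum())
        if remaining < 0:
            raise ValueError("planted taxa exceed the read depth; lower their folds")
        drawn_w = np.zeros_like(drawn_b)
        drawn_w[~free] = fixed[~free]
        drawn_w[free] = rng.multinomial(remaining, full[free] / full[free].sum())

        for t, drawn in ((Timepoint.BASELINE, drawn_b), (Timepoint.WEEK12, drawn_w)):
            sid = f"{pid}_{t.value}"
            for name, c in zip(taxa, drawn[:-2]):
                counts.append(TaxonCount(sid, name, Rank.SPECIES, int(c)))
            counts.append(
                TaxonCount(sid, "Homo sapiens", Rank.SPECIES, int(drawn[-2]), is_human=True)
            )
            counts.append(TaxonCount(sid, "unclassified", Rank.UNCLASSIFIED, int(drawn[-1])))
            counts.append(TaxonCount(sid, "GenusOnlyBin", Rank.GENUS, 500))
    return counts, truth


# ---------------------------------------------------------------------------
# metabolomics


def generate_metabolite_tables(config: SynthConfig):
    """Global (log2 area) and volatile (raw area) matrices plus truth.

    Global values follow ``patient baseline + metabolite offset + planted
    week-2 shift + N(0, noise_sd)`` with log2 areas in the study's 17–28
    range; cells go missing at ``missing_rate``.  Volatile raw areas are
    log-normal and strictly positive, with every patient's baseline
    defined.  Planted mean shifts switch on at week 2 and persist through
    week 12.  Returns ``(global_matrix, volatile_matrix, truth)``.
    """
    mets = [f"met_{i:03d}" for i in range(config.n_metabolites)]
    for name in config.planted_metabolite_effects:
        if name not in mets:
            raise ValueError(f"planted metabolite {name!r} not among generated ones")
    rng = _rng(config, "metab/global")
    offsets = np.clip(rng.normal(22.5, 2.5, config.n_metabolites), 17.0, 28.0)
    pats = config.patients
    patient_base = {p: _rng(config, "metab/patient", i).normal(0.0, config.patient_sd)
                    for i, p in enumerate(pats)}
    sample_ids = [f"{p}_{t.value}" for p in pats for t in Timepoint]
    glob = np.zeros((config.n_metabolites, len(sample_ids)))
    rng_noise = _rng(config, "metab/noise")
    for j, sid in enumerate(sample_ids):
        pid, tval = sid.rsplit("_", 1)
        t = Timepoint(tval)
        shift = np.array(
            [
                config.planted_metabolite_effects.get(m, 0.0)
                if t is not Timepoint.BASELINE
                else 0.0
                for m in mets
            ]
        )
        glob[:, j] = (
            offsets + patient_base[pid] + shift
            + rng_noise.normal(0.0, config.noise_sd, config.n_metabolites)
        )
    if config.missing_rate > 0:
        mask = _rng(config, "metab/missing").random(glob.shape) < config.missing_rate
        glob[mask] = np.nan
    global_matrix = AbundanceMatrix.from_arrays(mets, sample_ids, glob, Semantics.LOG2_AREA)

    n_vol = max(5, config.n_metabolites // 7)
    vol_names = [f"vol_{i:03d}" for i in range(n_vol)]
    rng_v = _rng(config, "metab/volatile")
    vol = np.zeros((n_vol, len(sample_ids)))
    scale = rng_v.uniform(4.0, 6.0, n_vol)  # log10 area scale
    for j, sid in enumerate(sample_ids):
        vol[:, j] = 10.0 ** (scale + rng_v.normal(0.0, 0.3, n_vol))
    volatile_matrix = AbundanceMatrix.from_arrays(
        vol_names, sample_ids, vol, Semantics.RAW_AREA
    )
    truth = dict(config.planted_metabolite_effects)
    return global_matrix, volatile_matrix, truth
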