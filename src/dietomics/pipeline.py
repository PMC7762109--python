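"""End-to-end orchestration: inputs (synthetic or on-disk) through the
proteomic, taxonomic and metabolomic stages to screen tables and a single
human-readable report.

Comparisons follow the emulated study design: every patient follows the
strict specific-carbohydrate diet for the first two weeks, so the
baseline-to-week-2 EC screen pools all patients; from week 2 to week 12
patients are on their randomized arm, so that screen runs within arm.
Taxonomic data exist at baseline and week 12 only, so the large-fold
k-of-n taxon screen compares those.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from . import __version__
from .io_core import (
    AbundanceMatrix,
    Arm,
    ConfigurationError,
    DataError,
    SampleMeta,
    Source,
    Timepoint,
    get_logger,
    load_config,
    meta_index,
    read_matrix,
    read_psm_table,
    read_sample_meta,
    read_taxon_counts,
    write_matrix,
    write_psm_table,
    write_sample_meta,
    write_taxon_counts,
)
from . import metabolomics, proteomics, screening, taxonomy
from .synth import SynthConfig, generate_metabolite_tables, generate_psm_tables, \
    generate_taxa_counts, make_meta

log = get_logger("pipeline")

__all__ = ["RunReport", "run_pipeline", "process_psm_sample"]


@dataclass
class RunReport:
    """Paths and tables produced by one pipeline run."""

    out_dir: str
    seed: int
    version: str
    config_echo: dict
    output_paths: dict[str, str] = field(default_factory=dict)
    diversity: list = field(default_factory=list)
    screens: dict[str, list] = field(default_factory=dict)
    metabolite_results: list = field(default_factory=list)

    def summary_text(self) -> str:
        lines = [
            f"dietomics run (version {self.version}, seed {self.seed})",
            "",
            "outputs:",
        ]
        for name in sorted(self.output_paths):
            lines.append(f"  {name}: {os.path.relpath(self.output_paths[name], self.out_dir)}")
        lines.append("")
        lines.append(f"diversity: {len(self.diversity)} samples")
        for name, verdicts in self.screens.items():
            n_hit = sum(1 for v in verdicts if v.direction != "none")
            lines.append(f"screen {name}: {n_hit} of {len(verdicts)} features reported")
        n_sig = sum(
            1 for r in self.metabolite_results if r.testable and r.p_value <= 0.05
        )
        n_loose = sum(
            1 for r in self.metabolite_results if r.testable and r.p_value <= 0.1
        )
        lines.append(
            f"metabolites: {n_sig} significant at alpha=0.05 "
            f"({n_loose} at alpha=0.1) of {len(self.metabolite_results)} tested"
        )
        return "\n".join(lines) + "\n"


def process_psm_sample(
    metagenome_psms,
    human_psms,
    ec_map: Mapping[str, set],
    q_threshold: float = 0.01,
    min_peptides: int = 2,
):
    """One sample's PSM stage: FDR filter, merge, group.

    Returns ``(merged_ids, groups_all, groups_filtered)`` where
    ``groups_all`` is the inference output before the minimum-peptide
    filter (used for total protein counts) and ``groups_filtered`` the
    quantified set.
    """
    meta_f = proteomics.filter_fdr(metagenome_psms, q_threshold)
    human_f = proteomics.filter_fdr(human_psms, q_threshold)
    merged = proteomics.merge_searches(meta_f, human_f)
    groups_all = proteomics.infer_protein_groups(merged, ec_map, min_peptides=1)
    groups = [g for g in groups_all if len(g.unique_peptides) >= min_peptides]
    return merged, groups_all, groups


def _comparison_patients(meta: Sequence[SampleMeta], spec) -> list[str]:
    patients = sorted({m.patient_id for m in meta})
    if spec in (None, "all"):
        return patients
    if isinstance(spec, str):
        arm = Arm(spec)
        return sorted({m.patient_id for m in meta if m.arm is arm})
    return list(spec)


def run_pipeline(config, out_dir: str | None = None) -> RunReport:
    """Run every stage described by ``config`` and write all outputs.

    ``config`` is a YAML path or an equivalent dict.  With a ``synth``
    section the inputs are generated in memory (and written alongside the
    outputs); otherwise the ``inputs`` section must name the PSM directory,
    EC map, taxon-count directory, metabolite tables and sample metadata.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = dict(config)
    out_dir = out_dir or cfg.get("out_dir")
    if not out_dir:
        raise ConfigurationError("no output directory given (out_dir)")
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    thresholds = {
        "q_value": 0.01,
        "min_peptides": 2,
        "fold": 2.0,
        "taxon_fold": 10.0,
        "min_patients": 4,
        "alpha": 0.05,
        "min_mean_reads": 100.0,
    }
    thresholds.update(cfg.get("thresholds", {}))

    report = RunReport(out_dir=out_dir, seed=seed, version=__version__, config_echo=cfg)

    # ------------------------------------------------------------------ inputs
    if "synth" in cfg:
        synth_kwargs = dict(cfg["synth"] or {})
        synth_kwargs.setdefault("seed", seed)
        scfg = SynthConfig(**synth_kwargs)
        meta = make_meta(scfg)
        psm_tables, _, ec_map = generate_psm_tables(scfg)
        taxa_counts, _ = generate_taxa_counts(scfg)
        global_matrix, volatile_matrix, _ = generate_metabolite_tables(scfg)
        log.info("synthesized inputs: %d samples, %d ECs, %d taxa, %d metabolites",
                 len(meta), scfg.n_ecs, scfg.n_taxa, scfg.n_metabolites)
    else:
        inputs = cfg.get("inputs")
        if not inputs:
            raise ConfigurationError("config needs either a 'synth' or an 'inputs' section")
        meta = read_sample_meta(inputs["meta"])
        ec_map = _read_ec_map(inputs["ec_map"])
        psm_tables = {}
        for m in meta:
            psm_tables[m.sample_id] = (
                read_psm_table(
                    os.path.join(inputs["psm_dir"], f"{m.sample_id}.metagenome.tsv"),
                    Source.METAGENOME, sample_id=m.sample_id,
                ),
                read_psm_table(
                    os.path.join(inputs["psm_dir"], f"{m.sample_id}.human.tsv"),
                    Source.HUMAN, sample_id=m.sample_id,
                ),
            )
        taxa_counts = []
        for fname in sorted(os.listdir(inputs["taxa_dir"])):
            taxa_counts.extend(read_taxon_counts(os.path.join(inputs["taxa_dir"], fname)))
        global_matrix = read_matrix(inputs["global"])
        volatile_matrix = read_matrix(inputs["volatile"])

    for label in _comparison_labels(cfg):
        try:
            Timepoint(label)
        except ValueError:
            raise ConfigurationError(f"unknown timepoint label {label!r}")

    write_sample_meta(meta, os.path.join(out_dir, "meta.tsv"))
    report.output_paths["meta"] = os.path.join(out_dir, "meta.tsv")

    # -------------------------------------------------------------- proteomics
    groups_by_sample = {}
    groups_all_by_sample = {}
    ids_by_sample = {}
    for sid, (mg, hu) in psm_tables.items():
        ids, groups_all, groups = process_psm_sample(
            mg, hu, ec_map, thresholds["q_value"], thresholds["min_peptides"]
        )
        ids_by_sample[sid] = ids
        groups_all_by_sample[sid] = groups_all
        groups_by_sample[sid] = groups
        log.info("sample %s: %d merged ids, %d groups (>=%d peptides)",
                 sid, len(ids), len(groups), thresholds["min_peptides"])
    ec_matrix = proteomics.ec_abundance(groups_by_sample)
    summaries = [
        proteomics.summarize_profile(
            ids_by_sample[sid], groups_all_by_sample[sid], ec_matrix, sid,
            min_peptides=thresholds["min_peptides"],
        )
        for sid in ec_matrix.sample_ids
    ]
    path = os.path.join(out_dir, "ec_matrix.tsv")
    write_matrix(ec_matrix, path)
    report.output_paths["ec_matrix"] = path
    path = os.path.join(out_dir, "proteomics_summary.tsv")
    proteomics.summary_table(summaries).to_csv(path, sep="\t", index=False)
    report.output_paths["proteomics_summary"] = path

    # ---------------------------------------------------------------- taxonomy
    taxa_matrix = taxonomy.filter_taxa(taxa_counts, thresholds["min_mean_reads"])
    diversity = taxonomy.diversity_table(taxa_matrix)
    report.diversity = diversity
    taxa_rel = taxonomy.to_relative(taxa_matrix)
    path = os.path.join(out_dir, "diversity.tsv")
    taxonomy.diversity_frame(diversity).to_csv(path, sep="\t", index=False)
    report.output_paths["diversity"] = path
    path = os.path.join(out_dir, "taxa_rel.tsv")
    write_matrix(taxa_rel, path)
    report.output_paths["taxa_rel"] = path

    # ------------------------------------------------------------------ screens
    comparisons = cfg.get("comparisons") or [
        {"name": "ec_baseline_week2_all", "t1": "baseline", "t2": "week2",
         "patients": "all", "mode": "three-criteria"},
        {"name": "ec_week2_week12_MSCD", "t1": "week2", "t2": "week12",
         "patients": "MSCD", "mode": "three-criteria"},
        {"name": "ec_week2_week12_WF", "t1": "week2", "t2": "week12",
         "patients": "WF", "mode": "three-criteria"},
    ]
    for comp in comparisons:
        name = comp.get("name") or f"ec_{comp['t1']}_{comp['t2']}"
        patients = _comparison_patients(meta, comp.get("patients"))
        fcs = screening.fold_changes(
            ec_matrix, meta, Timepoint(comp["t1"]), Timepoint(comp["t2"]), patients
        )
        if comp.get("mode", "three-criteria") == "k-of-n":
            verdicts = screening.kofn_screen(
                fcs, thresholds["taxon_fold"], thresholds["min_patients"]
            )
        else:
            verdicts = screening.consistency_screen(fcs, thresholds["fold"])
        report.screens[name] = verdicts
        path = os.path.join(out_dir, f"screen_{name}.tsv")
        screening.verdict_frame(verdicts).to_csv(path, sep="\t", index=False)
        report.output_paths[f"screen_{name}"] = path

    taxa_patients = sorted(
        {m.patient_id for m in meta if m.sample_id in taxa_rel.sample_ids}
    )
    fcs = screening.fold_changes(
        taxa_rel, meta, Timepoint.BASELINE, Timepoint.WEEK12, taxa_patients
    )
    verdicts = screening.kofn_screen(
        fcs, thresholds["taxon_fold"], thresholds["min_patients"]
    )
    report.screens["taxa_baseline_week12_kofn"] = verdicts
    path = os.path.join(out_dir, "screen_taxa_baseline_week12_kofn.tsv")
    screening.verdict_frame(verdicts).to_csv(path, sep="\t", index=False)
    report.output_paths["screen_taxa_baseline_week12_kofn"] = path

    # -------------------------------------------------------------- metabolites
    by_sample = meta_index(meta)
    g1 = [s for s in global_matrix.sample_ids
          if by_sample[s].timepoint is Timepoint.BASELINE]
    g2 = [s for s in global_matrix.sample_ids
          if by_sample[s].timepoint is Timepoint.WEEK2]
    results = metabolomics.group_ttest(global_matrix, g1, g2)
    report.metabolite_results = results
    path = os.path.join(out_dir, "metabolites_baseline_week2.tsv")
    metabolomics.results_frame(results).to_csv(path, sep="\t", index=False)
    report.output_paths["metabolites"] = path

    profile = metabolomics.normalize_to_baseline(volatile_matrix, meta)
    path = os.path.join(out_dir, "volatile_percent_of_baseline.tsv")
    profile.to_csv(path, sep="\t")
    report.output_paths["volatile_profile"] = path

    # -------------------------------------------------------------- report body
    path = os.path.join(out_dir, "report.txt")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(report.summary_text())
        fh.write("\nconfig:\n")
        fh.write(yaml.safe_dump(cfg, sort_keys=True))
    report.output_paths["report"] = path
    return report


def _comparison_labels(cfg) -> list[str]:
    labels = []
    for comp in cfg.get("comparisons") or []:
        labels.extend([comp.get("t1"), comp.get("t2")])
    return [l for l in labels if l is not None]


def _read_ec_map(path) -> dict[str, set[str]]:
    """Two-column accession-to-EC TSV, one row per (accession, EC) pair."""
    import csv

    out: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for row in reader:
            if len(row) < 2:
                raise DataError(f"EC map {path}: short row {row!r}")
            out.setdefault(row[0], set()).add(row[1])
    return out


def write_ec_map(ec_map: Mapping[str, set], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tec\n")
        for acc in sorted(ec_map):
            for ec in sorted(ec_map[acc]):
                fh.write(f"{acc}\t{ec}\n")
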