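"""Shared domain types, tabular readers/writers, configuration and logging.

All on-disk tables are tab-separated UTF-8 with a single header line.
Abundance matrices additionally carry a ``#semantics=`` comment line so a
matrix round-trips together with the meaning of its values.  Missing values
are written as empty fields and read back from any of ``""``, ``NA`` or
``N/A``; missing is always distinct from zero.
"""

from __future__ import annotations

import enum
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Timepoint",
    "Arm",
    "Source",
    "Rank",
    "Semantics",
    "SampleMeta",
    "PsmRecord",
    "TaxonCount",
    "AbundanceMatrix",
    "DietomicsError",
    "ConfigurationError",
    "DataError",
    "ValidationError",
    "get_logger",
    "load_config",
    "read_sample_meta",
    "read_psm_table",
    "read_taxon_counts",
    "read_matrix",
    "write_matrix",
    "DEFAULT_PSM_COLUMNS",
    "DEFAULT_HUMAN_NAMES",
]

MISSING_TOKENS = {"", "NA", "N/A", "na", "n/a"}


class DietomicsError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(DietomicsError):
    """A required column, key or option is missing or malformed."""


class DataError(DietomicsError):
    """Input data violates a contract (bad value, duplicate, missing sample)."""


class ValidationError(DietomicsError):
    """An in-memory object violates its own invariants."""


def get_logger(name: str) -> logging.Logger:
    """Return a module-tagged logger writing structured lines to stderr."""
    logger = logging.getLogger(f"dietomics.{name}")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(levelname)s [%(name)s] %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    WEEK2 = "week2"
    WEEK12 = "week12"


class Arm(str, enum.Enum):
    SCD = "SCD"
    MSCD = "MSCD"
    WF = "WF"


class Source(str, enum.Enum):
    METAGENOME = "metagenome"
    HUMAN = "human"
    CONTAMINANT = "contaminant"


class Rank(str, enum.Enum):
    SPECIES = "species"
    GENUS = "genus"
    FAMILY = "family"
    ORDER = "order"
    CLASS = "class"
    PHYLUM = "phylum"
    KINGDOM = "kingdom"
    DOMAIN = "domain"
    UNCLASSIFIED = "unclassified"


class Semantics(str, enum.Enum):
    PSM_COUNT = "psm_count"
    RELATIVE_ABUNDANCE = "relative_abundance"
    READ_COUNT = "read_count"
    LOG2_AREA = "log2_area"
    RAW_AREA = "raw_area"
    PERCENT_OF_BASELINE = "percent_of_baseline"


@dataclass(frozen=True)
class SampleMeta:
    """One row of the sample-metadata table.

    ``sample_id`` keys every column of every data matrix; ``patient_id`` and
    ``timepoint`` together identify a collection visit, so the pair must be
    unique across the table.
    """

    sample_id: str
    patient_id: str
    timepoint: Timepoint
    arm: Arm


@dataclass(frozen=True)
class PsmRecord:
    """A single scored peptide-spectrum match.

    ``score`` is the search-engine match score (higher is a better match);
    ``q_value`` is the target-decoy FDR estimate at which this match is
    accepted.  ``protein_refs`` lists every protein the peptide maps to.
    """

    spectrum_id: str
    sample_id: str
    peptide: str
    protein_refs: tuple[str, ...]
    source: Source
    score: float
    q_value: float

    def __post_init__(self) -> None:
        if not self.protein_refs:
            raise ValidationError(
                f"PSM {self.spectrum_id!r}: protein_refs must be non-empty"
            )
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(
                f"PSM {self.spectrum_id!r}: q_value {self.q_value} outside [0, 1]"
            )


@dataclass(frozen=True)
class TaxonCount:
    """Read count assigned to one taxon in one sample."""

    sample_id: str
    taxon_name: str
    rank: Rank
    read_count: int
    is_human: bool = False

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValidationError(
                f"taxon {self.taxon_name!r}: negative read count {self.read_count}"
            )


class AbundanceMatrix:
    """Feature-by-sample matrix with explicit value semantics.

    Values are non-negative reals; NaN marks a missing measurement and is
    never conflated with zero.  When ``semantics`` is ``relative_abundance``
    each sample column must sum to 1 (over non-missing entries) within 1e-9.
    """

    COLUMN_SUM_TOL = 1e-9

    def __init__(self, values: pd.DataFrame, semantics: Semantics) -> None:
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.semantics = Semantics(semantics)
        self.validate()

    @classmethod
    def from_arrays(
        cls,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
        semantics: Semantics,
    ) -> "AbundanceMatrix":
        frame = pd.DataFrame(
            np.asarray(values, dtype=float), index=list(feature_ids), columns=list(sample_ids)
        )
        return cls(frame, semantics)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise DataError(f"unknown sample {sample_id!r}")
        return self.values[sample_id]

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        arr = self.values.to_numpy()
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValidationError("negative abundance values")
        if self.semantics is Semantics.RELATIVE_ABUNDANCE and arr.size:
            sums = np.nansum(arr, axis=0)
            # all-NaN columns have nothing to normalize
            has_data = (~np.isnan(arr)).any(axis=0)
            bad = has_data & (np.abs(sums - 1.0) > self.COLUMN_SUM_TOL)
            if bad.any():
                names = [c for c, b in zip(self.values.columns, bad) if b]
                raise ValidationError(
                    f"relative_abundance columns do not sum to 1: {names}"
                )

    def equals(self, other: "AbundanceMatrix") -> bool:
        if self.semantics is not other.semantics:
            return False
        if self.feature_ids != other.feature_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        return bool(np.all(both_nan | np.isclose(a, b, rtol=0, atol=1e-12, equal_nan=False)))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AbundanceMatrix({len(self.feature_ids)} features x "
            f"{len(self.sample_ids)} samples, semantics={self.semantics.value})"
        )


# ---------------------------------------------------------------------------
# configuration

def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path}: top level must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# readers / writers

DEFAULT_PSM_COLUMNS = {
    "spectrum": "spectrum",
    "peptide": "peptide",
    "proteins": "proteins",
    "score": "score",
    "q_value": "q_value",
}

DEFAULT_HUMAN_NAMES = ("Homo sapiens",)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment=None, encoding="utf-8"
    )


def read_sample_meta(path) -> list[SampleMeta]:
    """Read the sample-metadata table (sample_id, patient_id, timepoint, arm)."""
    table = _read_tsv(path)
    required = ["sample_id", "patient_id", "timepoint", "arm"]
    for col in required:
        if col not in table.columns:
            raise ConfigurationError(f"sample metadata {path}: missing column {col!r}")
    rows: list[SampleMeta] = []
    for i, row in table.iterrows():
        try:
            rows.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    patient_id=row["patient_id"],
                    timepoint=Timepoint(row["timepoint"]),
                    arm=Arm(row["arm"]),
                )
            )
        except ValueError as exc:
            raise DataError(f"sample metadata line {i + 2}: {exc}") from exc
    validate_sample_meta(rows)
    return rows


def validate_sample_meta(rows: Iterable[SampleMeta]) -> None:
    seen_samples: set[str] = set()
    seen_visits: set[tuple[str, Timepoint]] = set()
    for row in rows:
        if row.sample_id in seen_samples:
            raise DataError(f"duplicate sample_id {row.sample_id!r}")
        seen_samples.add(row.sample_id)
        visit = (row.patient_id, row.timepoint)
        if visit in seen_visits:
            raise DataError(
                f"duplicate (patient, timepoint) pair {row.patient_id!r}/{row.timepoint.value}"
            )
        seen_visits.add(visit)


def write_sample_meta(rows: Sequence[SampleMeta], path) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "patient_id": [r.patient_id for r in rows],
            "timepoint": [r.timepoint.value for r in rows],
            "arm": [r.arm.value for r in rows],
        }
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def meta_index(rows: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    return {r.sample_id: r for r in rows}


def sample_for(
    rows: Iterable[SampleMeta], patient_id: str, timepoint: Timepoint
) -> SampleMeta | None:
    for r in rows:
        if r.patient_id == patient_id and r.timepoint is Timepoint(timepoint):
            return r
    return None


def read_psm_table(
    path,
    source: Source,
    sample_id: str | None = None,
    columns: Mapping[str, str] | None = None,
    protein_delimiter: str = ";",
    contaminant_prefix: str | None = "CONT_",
) -> list[PsmRecord]:
    """Parse a delimited PSM identification table into :class:`PsmRecord` rows.

    ``columns`` maps the logical names (spectrum, peptide, proteins, score,
    q_value, and optionally sample) to the header names actually present.
    ``source`` stamps which search database produced the table, except that
    a row whose protein references all start with ``contaminant_prefix``
    (the convention for spiked contaminant entries such as trypsin and
    keratins) is stamped as contaminant.  Row order is preserved.
    """
    source = Source(source)
    colmap = dict(DEFAULT_PSM_COLUMNS)
    if columns:
        colmap.update(columns)
    table = _read_tsv(path)
    for logical in ("spectrum", "peptide", "proteins", "score", "q_value"):
        if colmap[logical] not in table.columns:
            raise ConfigurationError(
                f"PSM table {path}: missing required column "
                f"{colmap[logical]!r} (for {logical!r})"
            )
    sample_col = colmap.get("sample", "sample")
    records: list[PsmRecord] = []
    for i, row in table.iterrows():
        line_no = i + 2  # header is line 1
        try:
            score = float(row[colmap["score"]])
            q_value = float(row[colmap["q_value"]])
        except ValueError as exc:
            raise DataError(f"PSM table {path} line {line_no}: unparsable numeric ({exc})")
        refs = tuple(p for p in row[colmap["proteins"]].split(protein_delimiter) if p)
        sid = sample_id
        if sid is None:
            if sample_col not in table.columns:
                raise ConfigurationError(
                    f"PSM table {path}: no sample_id given and no {sample_col!r} column"
                )
            sid = row[sample_col]
        row_source = source
        if contaminant_prefix and refs and all(
            r.startswith(contaminant_prefix) for r in refs
        ):
            row_source = Source.CONTAMINANT
        try:
            records.append(
                PsmRecord(
                    spectrum_id=row[colmap["spectrum"]],
                    sample_id=sid,
                    peptide=row[colmap["peptide"]],
                    protein_refs=refs,
                    source=row_source,
                    score=score,
                    q_value=q_value,
                )
            )
        except ValidationError as exc:
            raise DataError(f"PSM table {path} line {line_no}: {exc}") from exc
    return records


def write_psm_table(records: Sequence[PsmRecord], path, protein_delimiter: str = ";") -> None:
    frame = pd.DataFrame(
        {
            "spectrum": [r.spectrum_id for r in records],
            "sample": [r.sample_id for r in records],
            "peptide": [r.peptide for r in records],
            "proteins": [protein_delimiter.join(r.protein_refs) for r in records],
            "score": [r.score for r in records],
            "q_value": [r.q_value for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_taxon_counts(
    path,
    sample_id: str | None = None,
    human_names: Sequence[str] = DEFAULT_HUMAN_NAMES,
) -> list[TaxonCount]:
    """Parse a taxon/rank/count table (the shape of a read-classifier report).

    A taxon is flagged human when its name contains any entry of
    ``human_names`` (default: names containing "Homo sapiens"); the set is
    configurable for inputs that carry taxids or other labels.
    """
    table = _read_tsv(path)
    for col in ("taxon", "rank", "count"):
        if col not in table.columns:
            raise ConfigurationError(f"taxon table {path}: missing column {col!r}")
    rows: list[TaxonCount] = []
    seen: set[tuple[str, str]] = set()
    for i, row in table.iterrows():
        line_no = i + 2
        try:
            count = int(row["count"])
        except ValueError as exc:
            raise DataError(f"taxon table {path} line {line_no}: unparsable count ({exc})")
        if count < 0:
            raise DataError(f"taxon table {path} line {line_no}: negative count {count}")
        try:
            rank = Rank(row["rank"].strip().lower())
        except ValueError:
            raise DataError(
                f"taxon table {path} line {line_no}: unknown rank {row['rank']!r}"
            )
        sid = sample_id
        if sid is None:
            if "sample" not in table.columns:
                raise ConfigurationError(
                    f"taxon table {path}: no sample_id given and no 'sample' column"
                )
            sid = row["sample"]
        key = (sid, row["taxon"])
        if key in seen:
            raise DataError(
                f"taxon table {path} line {line_no}: duplicate taxon {row['taxon']!r}"
            )
        seen.add(key)
        rows.append(
            TaxonCount(
                sample_id=sid,
                taxon_name=row["taxon"],
                rank=rank,
                read_count=count,
                is_human=any(h in row["taxon"] for h in human_names),
            )
        )
    return rows


def write_taxon_counts(rows: Sequence[TaxonCount], path) -> None:
    frame = pd.DataFrame(
        {
            "sample": [r.sample_id for r in rows],
            "taxon": [r.taxon_name for r in rows],
            "rank": [r.rank.value for r in rows],
            "count": [r.read_count for r in rows],
        }
    )
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_matrix(matrix: AbundanceMatrix, path) -> None:
    """Serialize a matrix as TSV with a ``#semantics=`` header comment.

    Missing cells are written as empty fields.  The matrix is validated
    first; an invalid matrix (e.g. a relative-abundance column not summing
    to 1) is refused.
    """
    matrix.validate()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#semantics={matrix.semantics.value}\n")
        fh.write("feature\t" + "\t".join(matrix.sample_ids) + "\n")
        arr = matrix.values.to_numpy()
        for fid, row in zip(matrix.feature_ids, arr):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def read_matrix(path) -> AbundanceMatrix:
    """Read a matrix written by :func:`write_matrix` (exact round-trip)."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#semantics="):
            raise DataError(f"matrix {path}: missing '#semantics=' header line")
        semantics = Semantics(first.split("=", 1)[1])
        header = fh.readline().rstrip("\n")
        if not header:
            raise DataError(f"matrix {path}: missing column header line")
        sample_ids = header.split("\t")[1:]
        feature_ids: list[str] = []
        data: list[list[float]] = []
        for line_no, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise DataError(f"matrix {path} line {line_no}: wrong field count")
            feature_ids.append(cells[0])
            row = []
            for cell in cells[1:]:
                if cell in MISSING_TOKENS:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError as exc:
                        raise DataError(
                            f"matrix {path} line {line_no}: unparsable value ({exc})"
                        )
            data.append(row)
    values = np.array(data, dtype=float).reshape(len(feature_ids), len(sample_ids))
    return AbundanceMatrix.from_arrays(feature_ids, sample_ids, values, semantics)
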