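"""Reading and writing of expression tables, miRNA annotation, and score tables.

Expression data are held as pandas DataFrames with features (mature miRNAs or
precursors) on the rows and samples on the columns; :func:`validate_expression_matrix`
enforces the invariants every downstream operation assumes (unique identifiers,
finite numeric values). Annotation comes from the miRBase two-file dialect
(aliases.txt plus a precursor-to-mature mapping) or, as a convenience, from a
miRBase-style GFF3.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

MIMAT_PATTERN = re.compile(r"^MIMAT(\d+)$")

#: tokens recognized as missing cells in expression tables
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")


class AnnotationError(ValueError):
    """Raised for malformed or empty annotation inputs."""


def parse_mimat_number(accession: str) -> int:
    """Return the integer suffix of a mature miRNA MIMAT accession.

    MIMAT numbers are chronological: ``MIMAT0000062`` (hsa-let-7a-5p) was
    deposited far earlier than ``MIMAT0031893``, and early accessions are, on
    average, better validated. Precursor accessions (``MI0...``) are rejected.

    >>> parse_mimat_number("MIMAT0000062")
    62
    """
    match = MIMAT_PATTERN.match(accession.strip())
    if match is None:
        raise AnnotationError(
            f"not a mature miRNA MIMAT accession: {accession!r}"
        )
    value = int(match.group(1))
    if value < 1:
        raise AnnotationError(f"MIMAT number must be >= 1, got {accession!r}")
    return value


def format_mimat(number: int, width: int = 7) -> str:
    """Zero-padded inverse of :func:`parse_mimat_number`."""
    if number < 1:
        raise ValueError("MIMAT number must be >= 1")
    return f"MIMAT{number:0{width}d}"


@dataclass(frozen=True)
class MirnaAnnotation:
    """Annotation record for one mature miRNA."""

    mature_name: str
    mimat_number: int
    precursor_names: tuple[str, ...] = ()
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.mimat_number < 1:
            raise AnnotationError(
                f"{self.mature_name}: MIMAT number must be >= 1"
            )
        if self.sequence is not None:
            seq = self.sequence.upper().replace("U", "T")
            if len(seq) < 16:
                raise AnnotationError(
                    f"{self.mature_name}: mature sequence shorter than 16 nt"
                )
            if not set(seq) <= set("ACGTN"):
                raise AnnotationError(
                    f"{self.mature_name}: invalid characters in sequence"
                )
            object.__setattr__(self, "sequence", seq)
        object.__setattr__(
            self, "precursor_names", tuple(self.precursor_names)
        )


@dataclass
class AnnotationSet:
    """A set of mature miRNA annotations plus the scaling constant N_max.

    ``n_max`` defaults to the largest MIMAT number in the set; an override may
    enlarge it (e.g. to whole-miRBase semantics) but never shrink it, since
    the B component 1 - N/N_max must stay within [0, 1].
    """

    records: dict[str, MirnaAnnotation]
    n_max: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise AnnotationError("annotation set is empty")
        observed = max(r.mimat_number for r in self.records.values())
        if self.n_max == 0:
            self.n_max = observed
        elif self.n_max < observed:
            raise AnnotationError(
                f"n_max override {self.n_max} is smaller than the largest "
                f"MIMAT number in the set ({observed})"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __getitem__(self, name: str) -> MirnaAnnotation:
        return self.records[name]

    def with_n_max(self, n_max: int) -> "AnnotationSet":
        return AnnotationSet(records=dict(self.records), n_max=n_max)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def validate_expression_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Check ExpressionMatrix invariants; return the frame unchanged."""
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature identifiers: {dupes[:5]}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression table contains non-numeric cells")
    if not np.isfinite(values).all():
        raise ValueError("expression table contains non-finite values")
    return frame


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    orientation: str = "rows-are-features",
    sep: str | None = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Read a delimited expression table into a features x samples DataFrame.

    Parameters
    ----------
    orientation
        ``"rows-are-features"`` (default) or ``"rows-are-samples"``; the
        returned frame is always features on rows.
    on_missing
        ``"error"`` rejects tables with missing cells (the scoring math
        assumes complete rows); ``"drop"`` removes features containing any
        missing cell, with a logged warning.
    """
    path = Path(path)
    if orientation not in ("rows-are-features", "rows-are-samples"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if on_missing not in ("error", "drop"):
        raise ValueError(f"unknown missing-value policy: {on_missing!r}")
    frame = pd.read_csv(
        path,
        sep=_sep_for(path, sep),
        index_col=0,
        na_values=list(missing_tokens),
        keep_default_na=False,
    )
    if orientation == "rows-are-samples":
        frame = frame.T
    for col in frame.columns:
        if frame[col].dtype == object:
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = converted.isna() & frame[col].notna()
            if bad.any():
                offender = frame.loc[bad, col].iloc[0]
                raise ValueError(
                    f"non-numeric cell {offender!r} in column {col!r} of {path}"
                )
            frame[col] = converted
    if frame.isna().any().any():
        if on_missing == "error":
            raise ValueError(
                f"{path}: missing values present; pass on_missing='drop' to "
                "remove affected features"
            )
        n_before = len(frame)
        frame = frame.dropna(axis=0)
        logger.warning(
            "%s: dropped %d features with missing cells",
            path,
            n_before - len(frame),
        )
    frame = frame.astype(float)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return validate_expression_matrix(frame)


def write_expression_table(
    frame: pd.DataFrame, path: str | Path, sep: str | None = None
) -> None:
    path = Path(path)
    validate_expression_matrix(frame)
    frame.to_csv(path, sep=_sep_for(path, sep))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _read_mature_sequences(fasta_path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[record.id] = str(record.seq).upper().replace("U", "T")
    return seqs


def read_annotation(
    aliases_path: str | Path,
    mapping_path: str | Path,
    fasta_path: str | Path | None = None,
    n_max_override: int | None = None,
) -> AnnotationSet:
    """Build an :class:`AnnotationSet` from miRBase-dialect files.

    ``aliases_path`` follows the miRBase aliases.txt layout: an accession,
    a tab, then semicolon-separated names. Only ``MIMAT`` (mature) lines are
    used; precursor ``MI0...`` lines are ignored here. ``mapping_path`` is a
    two-column (precursor TAB mature) text file; a mature produced from
    several genomic loci accumulates all its precursors. Mature names present
    in the mapping but lacking a MIMAT accession are skipped with a warning.
    """
    mimat_by_name: dict[str, int] = {}
    with open(aliases_path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            accession = parts[0].strip()
            if not accession.startswith("MIMAT"):
                continue
            number = parse_mimat_number(accession)
            for name in parts[1].split(";"):
                name = name.strip()
                if name:
                    mimat_by_name[name] = number

    precursors: dict[str, list[str]] = {}
    with open(mapping_path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[\t,]", line)
            if len(parts) < 2:
                raise AnnotationError(
                    f"{mapping_path}: expected two columns, got {line!r}"
                )
            precursor, mature = parts[0].strip(), parts[1].strip()
            bucket = precursors.setdefault(mature, [])
            if precursor not in bucket:
                bucket.append(precursor)

    sequences = _read_mature_sequences(fasta_path) if fasta_path else {}

    records: dict[str, MirnaAnnotation] = {}
    names = set(mimat_by_name) | set(precursors)
    for name in sorted(names):
        if name not in mimat_by_name:
            logger.warning("mature %s has no MIMAT accession; skipped", name)
            continue
        records[name] = MirnaAnnotation(
            mature_name=name,
            mimat_number=mimat_by_name[name],
            precursor_names=tuple(precursors.get(name, ())),
            sequence=sequences.get(name),
        )
    if not records:
        raise AnnotationError(
            f"no mature records with MIMAT accessions in {aliases_path}"
        )
    return AnnotationSet(records=records, n_max=n_max_override or 0)


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def read_annotation_gff3(
    gff_path: str | Path,
    fasta_path: str | Path | None = None,
    n_max_override: int | None = None,
) -> AnnotationSet:
    """Read a miRBase-style GFF3 into an :class:`AnnotationSet`.

    Mature entries carry ``Alias=MIMAT...`` and ``Derives_from=<precursor ID>``;
    precursor entries (``miRNA_primary_transcript``) provide the ID-to-name
    resolution for the precursor column.
    """
    precursor_name_by_id: dict[str, str] = {}
    matures: list[dict[str, str]] = []
    with open(gff_path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            feature_type, attr_text = fields[2], fields[8]
            attrs = dict(_GFF_ATTR.findall(attr_text))
            if feature_type == "miRNA_primary_transcript":
                if "ID" in attrs:
                    precursor_name_by_id[attrs["ID"]] = attrs.get(
                        "Name", attrs["ID"]
                    )
            elif feature_type == "miRNA":
                matures.append(attrs)

    sequences = _read_mature_sequences(fasta_path) if fasta_path else {}
    grouped: dict[str, dict] = {}
    for attrs in matures:
        name = attrs.get("Name")
        alias = attrs.get("Alias", "")
        if not name or not alias.startswith("MIMAT"):
            logger.warning("mature GFF3 record without MIMAT alias skipped: %s", attrs)
            continue
        number = parse_mimat_number(alias)
        entry = grouped.setdefault(name, {"mimat": number, "precursors": []})
        derives = attrs.get("Derives_from")
        if derives:
            pname = precursor_name_by_id.get(derives, derives)
            if pname not in entry["precursors"]:
                entry["precursors"].append(pname)
    records = {
        name: MirnaAnnotation(
            mature_name=name,
            mimat_number=entry["mimat"],
            precursor_names=tuple(entry["precursors"]),
            sequence=sequences.get(name),
        )
        for name, entry in grouped.items()
    }
    if not records:
        raise AnnotationError(f"no mature miRNA records in {gff_path}")
    return AnnotationSet(records=records, n_max=n_max_override or 0)


def write_annotation(
    annotation: AnnotationSet,
    aliases_path: str | Path,
    mapping_path: str | Path,
    fasta_path: str | Path | None = None,
) -> None:
    """Serialize an AnnotationSet back to the two-file dialect (plus FASTA).

    Re-reading the written files with :func:`read_annotation` reproduces the
    set (idempotence), provided n_max was not overridden.
    """
    with open(aliases_path, "w") as handle:
        for name in sorted(annotation.records):
            rec = annotation.records[name]
            handle.write(f"{format_mimat(rec.mimat_number)}\t{name};\n")
    with open(mapping_path, "w") as handle:
        for name in sorted(annotation.records):
            for precursor in annotation.records[name].precursor_names:
                handle.write(f"{precursor}\t{name}\n")
    if fasta_path is not None:
        with open(fasta_path, "w") as handle:
            for name in sorted(annotation.records):
                seq = annotation.records[name].sequence
                if seq:
                    handle.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# reference profiles and score tables
# ---------------------------------------------------------------------------

def read_reference_profile(path: str | Path, sep: str | None = None) -> pd.Series:
    """Read a per-miRNA median-RPM reference profile.

    The canonical layout is two columns (name, median_rpm); extra columns
    (e.g. a planted-truth flag in synthetic fixtures) are tolerated — the
    column named ``median_rpm`` is used, else the second column.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    column = "median_rpm" if "median_rpm" in frame.columns else frame.columns[0]
    series = frame[column].astype(float)
    series.index = series.index.astype(str)
    if series.index.has_duplicates:
        raise ValueError(f"{path}: duplicate miRNA names in reference profile")
    if not np.isfinite(series.to_numpy()).all() or (series < 0).any():
        raise ValueError(f"{path}: RPM values must be finite and non-negative")
    series.name = "median_rpm"
    series.index.name = "name"
    return series


def write_reference_profile(series: pd.Series, path: str | Path) -> None:
    out = series.rename("median_rpm").rename_axis("name")
    out.to_csv(Path(path), sep="\t")


SCORE_COLUMNS = ["name", "median", "mimat", "correlation", "A", "B", "C", "score"]


def write_score_table(table, path: str | Path) -> None:
    """Write a ScoreTable as TSV, score-descending with MIMAT-ascending ties.

    The header carries the scaling constants and weights as ``#`` comments so
    a written table is self-describing.
    """
    from .scoring import ScoreTable  # local import to avoid a cycle

    if not isinstance(table, ScoreTable):
        raise TypeError("write_score_table expects a ScoreTable")
    path = Path(path)
    frame = table.frame.sort_values(
        ["score", "mimat"], ascending=[False, True], kind="mergesort"
    )
    with open(path, "w") as handle:
        handle.write(
            f"# m_max={table.m_max!r}\tn_max={table.n_max}\t"
            f"w_a={table.weights.w_a!r}\tw_b={table.weights.w_b!r}\t"
            f"w_c={table.weights.w_c!r}\n"
        )
        frame.reset_index().to_csv(
            handle, sep="\t", index=False, float_format="%.6f"
        )


def read_score_table(path: str | Path):
    from .scoring import ScoreTable, ScoreWeights

    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as handle:
        first = handle.readline()
        if first.startswith("#"):
            for item in first[1:].strip().split("\t"):
                key, _, value = item.partition("=")
                meta[key] = float(value)
            frame = pd.read_csv(handle, sep="\t", index_col=0)
        else:
            handle.seek(0)
            frame = pd.read_csv(handle, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    weights = ScoreWeights(
        meta.get("w_a", 0.5), meta.get("w_b", 0.3), meta.get("w_c", 0.2)
    )
    return ScoreTable(
        frame=frame,
        weights=weights,
        m_max=meta.get("m_max", float(frame["median"].max())),
        n_max=int(meta.get("n_max", frame["mimat"].max())),
    )
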