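"""Readers and writers for the pipeline's tabular interchange formats.

Four formats, all UTF-8 tab-delimited with '.' decimals:

* BLAST tabular search results (outfmt-6 column order, optionally extended
  with query/subject length columns 13-14);
* subject annotation maps tying each database protein to its CAZyme family
  and a four-rank taxonomic lineage (phylum, class, family, genus);
* per-sample metadata (metagenome size in bp, geography, cohort, age, BMI,
  age group);
* samples x families numeric matrices (abundance, normalized profiles).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Catalytic CAZyme classes retained by the analysis.  Non-catalytic
#: carbohydrate-binding modules (CBM) and auxiliary activities (AA) are
#: deliberately not accepted by the annotation reader.
CATALYTIC_CLASSES = ("GH", "GT", "PL", "CE")

#: Lineage ranks carried by a subject annotation, coarse to fine.
LINEAGE_RANKS = ("phylum", "class", "family", "genus")

_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE)(\d+)$")


class ParseError(ValueError):
    """Malformed input row; the message names the file and line number."""


@dataclass(frozen=True, slots=True)
class BlastHit:
    """One tabular alignment record (one row of BLAST outfmt 6)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float
    query_length: int | None = None
    subject_length: int | None = None

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length must be >= 1, got {self.alignment_length}")
        if self.evalue < 0:
            raise ValueError(f"E-value must be non-negative, got {self.evalue}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity outside [0, 100]: {self.percent_identity}")
        for name in ("query_length", "subject_length"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")


@dataclass(frozen=True, slots=True)
class SubjectAnnotation:
    """Family and taxonomic lineage of one database protein."""

    subject_id: str
    family: str
    lineage: tuple[str, str, str, str]  # phylum, class, family, genus

    @property
    def cazy_class(self) -> str:
        m = _FAMILY_RE.match(self.family)
        assert m is not None
        return m.group(1)

    def lineage_at(self, rank: str) -> str:
        return self.lineage[LINEAGE_RANKS.index(rank)]


@dataclass(frozen=True, slots=True)
class SampleRecord:
    """Per-sample metadata for one gut metagenome."""

    sample_id: str
    metagenome_size_bp: int
    geography: str = ""
    cohort: str = "other"
    age_years: float | None = None
    bmi: float | None = None
    age_group: str | None = None

    def __post_init__(self) -> None:
        if self.metagenome_size_bp <= 0:
            raise ValueError(
                f"metagenome size must be positive, got {self.metagenome_size_bp}"
            )
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"age must be non-negative, got {self.age_years}")
        if self.bmi is not None and self.bmi <= 0:
            raise ValueError(f"BMI must be positive, got {self.bmi}")


def validate_family_label(label: str) -> str:
    """Check a CAZyme family label (catalytic class prefix + number).

    Returns the label; raises ``ValueError`` for CBM/AA or anything else
    outside the four catalytic classes.
    """
    if not _FAMILY_RE.match(label):
        raise ValueError(
            f"family label {label!r} is not a catalytic CAZyme family "
            f"(expected one of {CATALYTIC_CLASSES} followed by a number; "
            "CBM and AA classes are excluded from the analysis)"
        )
    return label


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tab(
    path: str | Path,
    has_lengths: bool = False,
    lengths: Mapping[str, int] | None = None,
) -> list[BlastHit]:
    """Read BLAST outfmt-6 tabular results into :class:`BlastHit` records.

    The standard 12 columns are ``qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore``; with ``has_lengths``
    two extra columns ``qlen slen`` are required.  When lengths are absent
    they may be supplied through ``lengths`` (query_id -> query length in
    nucleotides), or later via a side table, before coverage filtering.

    Row order is preserved.  Malformed rows raise :class:`ParseError`
    naming the line.
    """
    path = Path(path)
    want = 14 if has_lengths else 12
    hits: list[BlastHit] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < want:
                raise ParseError(
                    f"{path}:{lineno}: expected at least {want} tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                qlen = int(fields[12]) if has_lengths else None
                slen = int(fields[13]) if has_lengths else None
                if qlen is None and lengths is not None:
                    qlen = int(lengths[fields[0]]) if fields[0] in lengths else None
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                    query_length=qlen,
                    subject_length=slen,
                )
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Write hits as 14-column extended outfmt-6 (qlen/slen appended).

    Positional columns not tracked by :class:`BlastHit` (mismatches, gap
    opens, coordinates) are written as zeros / 1-based spans so that the
    row shape round-trips through :func:`read_blast_tab`.
    """
    with Path(path).open("w", encoding="utf-8") as fh:
        for h in hits:
            qlen = h.query_length if h.query_length is not None else 0
            slen = h.subject_length if h.subject_length is not None else 0
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t0\t0\t1\t{qlen or h.alignment_length}\t1\t"
                f"{h.alignment_length}\t{h.evalue:.6g}\t{h.bit_score:.6g}\t"
                f"{qlen}\t{slen}\n"
            )


# ---------------------------------------------------------------------------
# Annotation map
# ---------------------------------------------------------------------------

def read_annotation_map(path: str | Path) -> dict[str, SubjectAnnotation]:
    """Read a subject annotation TSV into a subject_id -> annotation map.

    Columns: subject_id, family, phylum, class, family_taxon, genus.
    Duplicate subject ids and non-catalytic family classes are errors;
    lineage entries may be the literal string ``unknown``.
    """
    path = Path(path)
    out: dict[str, SubjectAnnotation] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["subject_id", "family"]:
            raise ParseError(
                f"{path}:1: expected header starting 'subject_id\\tfamily', got {header[:2]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields, found {len(fields)}")
            sid, family = fields[0], fields[1]
            try:
                validate_family_label(family)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if sid in out:
                raise ParseError(f"{path}:{lineno}: duplicate subject_id {sid!r}")
            out[sid] = SubjectAnnotation(
                subject_id=sid, family=family, lineage=tuple(fields[2:6])
            )
    return out


def write_annotation_map(
    annotations: Mapping[str, SubjectAnnotation] | Iterable[SubjectAnnotation],
    path: str | Path,
) -> None:
    if isinstance(annotations, Mapping):
        annotations = annotations.values()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("subject_id\tfamily\tphylum\tclass\tfamily_taxon\tgenus\n")
        for a in annotations:
            fh.write(f"{a.subject_id}\t{a.family}\t" + "\t".join(a.lineage) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "sample_id", "metagenome_size_bp", "geography", "cohort",
    "age_years", "bmi", "age_group",
]


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the per-sample metadata TSV; blank age/BMI cells become None."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id", "metagenome_size_bp") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample_id(s) {dups}")
    records = []
    for _, row in df.iterrows():
        size = row["metagenome_size_bp"]
        try:
            size = int(size)
        except (ValueError, TypeError) as exc:
            raise ParseError(
                f"{path}: non-numeric metagenome size {size!r} for sample "
                f"{row['sample_id']!r}"
            ) from exc

        def _opt(name, cast=float):
            if name not in row or pd.isna(row[name]):
                return None
            return cast(row[name])

        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                metagenome_size_bp=size,
                geography=str(row.get("geography", "") or ""),
                cohort=str(row.get("cohort", "other") or "other"),
                age_years=_opt("age_years"),
                bmi=_opt("bmi"),
                age_group=_opt("age_group", str),
            )
        )
    return records


def write_sample_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "metagenome_size_bp": r.metagenome_size_bp,
            "geography": r.geography,
            "cohort": r.cohort,
            "age_years": "" if r.age_years is None else repr(float(r.age_years)),
            "bmi": "" if r.bmi is None else repr(float(r.bmi)),
            "age_group": r.age_group or "",
        })
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def metadata_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id (NaN for missing)."""
    df = pd.DataFrame(
        {
            "metagenome_size_bp": [r.metagenome_size_bp for r in records],
            "geography": [r.geography for r in records],
            "cohort": [r.cohort for r in records],
            "age_years": [math.nan if r.age_years is None else r.age_years for r in records],
            "bmi": [math.nan if r.bmi is None else r.bmi for r in records],
            "age_group": [r.age_group for r in records],
        },
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
    )
    return df


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x families matrix as TSV (12 significant digits)."""
    matrix.to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
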