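"""Clonotype table ingestion, CDR3 translation and clonotype collapsing.

A T-cell clone is defined by its exact TCR nucleotide sequence (V gene label,
CDR3 nucleotide sequence, J gene label); distinct nucleotide clones can encode
the same amino-acid clonotype, which is identified by the triple
(V label, CDR3 amino-acid sequence, J label).  This module reads and writes
clonotype tables in two tab-separated dialects (a 5-column ``simple_tsv`` and
the AIRR Rearrangement subset), translates CDR3 nucleotide sequences, applies
the productive-CDR3 exclusion rules, and collapses nucleotide-defined clones
into amino-acid-defined repertoires.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple, Union

from Bio.Seq import Seq

__all__ = [
    "CloneRecord",
    "AAKey",
    "NTKey",
    "Repertoire",
    "MouseMetadata",
    "ClonotypeTableError",
    "translate_cdr3",
    "read_clonotype_table",
    "write_clonotype_table",
    "read_repertoire",
    "apply_record_filters",
    "collapse_to_aa",
    "repertoire_from_records",
    "read_metadata",
    "write_metadata",
]

SUBSETS = ("CD4", "CD8")
CHAINS = ("alpha", "beta")
#: Receptor types in the fixed reporting order used throughout.
RECEPTOR_TYPES = ("CD4_alpha", "CD4_beta", "CD8_alpha", "CD8_beta")

_NT_ALPHABET = frozenset("ACGT")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

AIRR_COLUMNS = ("v_call", "j_call", "junction", "junction_aa", "duplicate_count")
SIMPLE_COLUMNS = ("v", "j", "cdr3_nt", "cdr3_aa", "count")
DIALECTS = ("airr", "simple_tsv")


class ClonotypeTableError(ValueError):
    """Malformed clonotype table (carries the offending line number)."""


class AAKey(NamedTuple):
    """Amino-acid clonotype identity: (V label, CDR3 aa, J label)."""

    v_label: str
    cdr3_aa: str
    j_label: str


class NTKey(NamedTuple):
    """Nucleotide clone identity: (V label, CDR3 nt, J label)."""

    v_label: str
    cdr3_nt: str
    j_label: str


@dataclass(frozen=True)
class CloneRecord:
    """One nucleotide-defined clone as read from a clonotype table.

    ``cdr3_nt`` may be empty when the upstream annotation found no CDR3; such
    records are kept but flagged so that the exclusion report can count them.
    ``count`` is the number of molecules (UMI-corrected upstream).
    """

    v_label: str
    j_label: str
    cdr3_nt: str
    count: int
    cdr3_aa: Optional[str] = None

    @property
    def has_cdr3(self) -> bool:
        return bool(self.cdr3_nt)

    @property
    def nt_key(self) -> NTKey:
        return NTKey(self.v_label, self.cdr3_nt, self.j_label)


@dataclass
class MouseMetadata:
    """Per-mouse covariates driving the GLM stage and the simulator."""

    mouse_id: str
    sex: str  # "M" or "F"
    age: float  # weeks
    site: str
    cohort: str = "wild"  # "wild" or "lab"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")


@dataclass
class Repertoire:
    """A keyed multiset of clones for one (mouse, subset, chain).

    ``clones`` maps a clone key — an :class:`NTKey` at nucleotide level or an
    :class:`AAKey` at amino-acid level — to a positive molecule count.
    """

    mouse_id: str
    subset: str
    chain: str
    clones: Dict[Union[NTKey, AAKey], int] = field(default_factory=dict)
    level: str = "amino_acid"  # or "nucleotide"

    def __post_init__(self) -> None:
        if self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}, got {self.subset!r}")
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if self.level not in ("nucleotide", "amino_acid"):
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def receptor_type(self) -> str:
        return f"{self.subset}_{self.chain}"

    @property
    def size(self) -> int:
        """Repertoire size: total number of molecules (sum of clone counts)."""
        return sum(self.clones.values())

    @property
    def unique_count(self) -> int:
        """Number of unique clone keys."""
        return len(self.clones)


def translate_cdr3(cdr3_nt: str) -> Optional[str]:
    """Translate a CDR3 nucleotide sequence in frame 0.

    Returns the amino-acid sequence, or ``None`` (failure marker) when the
    length is not a multiple of 3 or the translation contains a stop codon.
    Characters outside {A,C,G,T} raise ``ValueError``.
    """
    bad = set(cdr3_nt) - _NT_ALPHABET
    if bad:
        raise ValueError(f"non-ACGT characters in CDR3: {sorted(bad)}")
    if len(cdr3_nt) == 0 or len(cdr3_nt) % 3 != 0:
        return None
    aa = str(Seq(cdr3_nt).translate())
    if "*" in aa:
        return None
    return aa


def _parse_row(
    fields: Dict[str, str], line_no: int, path: str
) -> CloneRecord:
    cdr3_nt = (fields["cdr3_nt"] or "").strip().upper()
    if cdr3_nt and (set(cdr3_nt) - _NT_ALPHABET):
        raise ClonotypeTableError(
            f"{path}:{line_no}: bad characters in nucleotide CDR3 {cdr3_nt!r}"
        )
    cdr3_aa = (fields.get("cdr3_aa") or "").strip().upper() or None
    if cdr3_aa and (set(cdr3_aa) - _AA_ALPHABET):
        raise ClonotypeTableError(
            f"{path}:{line_no}: bad characters in amino-acid CDR3 {cdr3_aa!r}"
        )
    raw_count = (fields["count"] or "").strip()
    try:
        count = int(raw_count)
    except ValueError:
        raise ClonotypeTableError(
            f"{path}:{line_no}: count {raw_count!r} is not an integer"
        ) from None
    if count < 1:
        raise ClonotypeTableError(f"{path}:{line_no}: count must be >= 1, got {count}")
    return CloneRecord(
        v_label=fields["v"].strip(),
        j_label=fields["j"].strip(),
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        count=count,
    )


def _column_map(dialect: str) -> Dict[str, str]:
    if dialect == "airr":
        return {"v": "v_call", "j": "j_call", "cdr3_nt": "junction",
                "cdr3_aa": "junction_aa", "count": "duplicate_count"}
    if dialect == "simple_tsv":
        return {"v": "v", "j": "j", "cdr3_nt": "cdr3_nt",
                "cdr3_aa": "cdr3_aa", "count": "count"}
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_clonotype_table(path, dialect: str = "airr") -> List[CloneRecord]:
    """Read one clonotype table into a list of :class:`CloneRecord`.

    Rows with an empty CDR3 nucleotide field are returned flagged (empty
    ``cdr3_nt``), not dropped; :func:`apply_record_filters` excludes them.
    Malformed rows raise :class:`ClonotypeTableError` naming the line number.
    """
    colmap = _column_map(dialect)
    path = Path(path)
    records: List[CloneRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ClonotypeTableError(f"{path}: empty file (no header)")
        missing = [c for c in colmap.values() if c != "junction_aa"
                   and c != "cdr3_aa" and c not in reader.fieldnames]
        if missing:
            raise ClonotypeTableError(f"{path}: missing columns {missing}")
        has_aa = colmap["cdr3_aa"] in reader.fieldnames
        for line_no, row in enumerate(reader, start=2):
            fields = {
                "v": row.get(colmap["v"], "") or "",
                "j": row.get(colmap["j"], "") or "",
                "cdr3_nt": row.get(colmap["cdr3_nt"], "") or "",
                "cdr3_aa": (row.get(colmap["cdr3_aa"], "") or "") if has_aa else "",
                "count": row.get(colmap["count"], "") or "",
            }
            records.append(_parse_row(fields, line_no, str(path)))
    return records


def write_clonotype_table(repertoire: Repertoire, path, dialect: str = "airr") -> None:
    """Write a repertoire as a clonotype table (round-trips through read)."""
    colmap = _column_map(dialect)
    header = AIRR_COLUMNS if dialect == "airr" else SIMPLE_COLUMNS
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for key in sorted(repertoire.clones):
            count = repertoire.clones[key]
            if repertoire.level == "nucleotide":
                v, cdr3_nt, j = key
                cdr3_aa = translate_cdr3(cdr3_nt) or ""
            else:
                v, cdr3_aa, j = key
                cdr3_nt = ""
            row = {"v": v, "j": j, "cdr3_nt": cdr3_nt,
                   "cdr3_aa": cdr3_aa, "count": str(count)}
            writer.writerow([row[k] for k, _ in zip(
                ("v", "j", "cdr3_nt", "cdr3_aa", "count"), header)])


def read_repertoire(
    path,
    mouse_id: str,
    subset: str,
    chain: str,
    dialect: str = "airr",
    level: str = "amino_acid",
) -> Repertoire:
    """Read a clonotype table directly into a :class:`Repertoire`.

    At ``amino_acid`` level the amino-acid CDR3 column is used as the key (the
    nucleotide column may be empty, as written for collapsed repertoires); at
    ``nucleotide`` level the nucleotide CDR3 is required.
    """
    records = read_clonotype_table(path, dialect=dialect)
    clones: Dict[Union[NTKey, AAKey], int] = {}
    for rec in records:
        if level == "nucleotide":
            if not rec.has_cdr3:
                continue
            key: Union[NTKey, AAKey] = rec.nt_key
        else:
            aa = rec.cdr3_aa or (translate_cdr3(rec.cdr3_nt) if rec.has_cdr3 else None)
            if aa is None:
                continue
            key = AAKey(rec.v_label, aa, rec.j_label)
        clones[key] = clones.get(key, 0) + rec.count
    return Repertoire(mouse_id=mouse_id, subset=subset, chain=chain,
                      clones=clones, level=level)


def apply_record_filters(
    records: Iterable[CloneRecord],
) -> Tuple[List[CloneRecord], Counter]:
    """Exclude records without a productive CDR3.

    Exclusion reasons: ``missing_cdr3`` (empty CDR3 nt field), ``frame``
    (length not a multiple of 3) and ``stop_codon``.  Kept records have their
    ``cdr3_aa`` filled from the translation.  The partition is exact:
    ``len(kept) + sum(report.values()) == len(records)``.
    """
    kept: List[CloneRecord] = []
    report: Counter = Counter()
    for rec in records:
        if not rec.has_cdr3:
            report["missing_cdr3"] += 1
            continue
        if len(rec.cdr3_nt) % 3 != 0:
            report["frame"] += 1
            continue
        aa = str(Seq(rec.cdr3_nt).translate())
        if "*" in aa:
            report["stop_codon"] += 1
            continue
        if rec.cdr3_aa != aa:
            rec = CloneRecord(rec.v_label, rec.j_label, rec.cdr3_nt,
                              rec.count, cdr3_aa=aa)
        kept.append(rec)
    return kept, report


def repertoire_from_records(
    records: Iterable[CloneRecord], mouse_id: str, subset: str, chain: str
) -> Repertoire:
    """Assemble filtered records into a nucleotide-level repertoire."""
    clones: Dict[Union[NTKey, AAKey], int] = {}
    for rec in records:
        clones[rec.nt_key] = clones.get(rec.nt_key, 0) + rec.count
    return Repertoire(mouse_id=mouse_id, subset=subset, chain=chain,
                      clones=clones, level="nucleotide")


def collapse_to_aa(
    records: Iterable[CloneRecord], mouse_id: str, subset: str, chain: str
) -> Repertoire:
    """Collapse filtered nucleotide records to an amino-acid repertoire.

    Synonymous nucleotide clones (same V label, same translated CDR3, same J
    label) merge into a single amino-acid clonotype whose count is the sum of
    theirs, so total repertoire size is conserved.
    """
    clones: Dict[Union[NTKey, AAKey], int] = {}
    for rec in records:
        aa = rec.cdr3_aa if rec.cdr3_aa is not None else translate_cdr3(rec.cdr3_nt)
        if aa is None:
            raise ValueError(
                f"record {rec.nt_key} has no productive CDR3; filter records first"
            )
        key = AAKey(rec.v_label, aa, rec.j_label)
        clones[key] = clones.get(key, 0) + rec.count
    return Repertoire(mouse_id=mouse_id, subset=subset, chain=chain,
                      clones=clones, level="amino_acid")


METADATA_COLUMNS = ("mouse_id", "sex", "age_weeks", "site", "cohort")


def read_metadata(path) -> List[MouseMetadata]:
    """Read a mouse metadata TSV (mouse_id, sex, age_weeks, site, cohort)."""
    path = Path(path)
    out: List[MouseMetadata] = []
    seen = set()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = [c for c in METADATA_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ClonotypeTableError(f"{path}: missing metadata columns {missing}")
        for line_no, row in enumerate(reader, start=2):
            mid = row["mouse_id"].strip()
            if mid in seen:
                raise ClonotypeTableError(f"{path}:{line_no}: duplicate mouse_id {mid!r}")
            seen.add(mid)
            try:
                age = float(row["age_weeks"])
            except ValueError:
                raise ClonotypeTableError(
                    f"{path}:{line_no}: age_weeks {row['age_weeks']!r} not numeric"
                ) from None
            out.append(MouseMetadata(mouse_id=mid, sex=row["sex"].strip(),
                                     age=age, site=row["site"].strip(),
                                     cohort=row["cohort"].strip()))
    return out


def write_metadata(metadata: Iterable[MouseMetadata], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for m in metadata:
            writer.writerow([m.mouse_id, m.sex, repr(m.age), m.site, m.cohort])
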