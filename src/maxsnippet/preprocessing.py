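"""Reading and cleaning per-patient CDR3 repertoires.

A *repertoire* is one patient's bag of CDR3 sequences together with a binary
diagnosis label (1 = case, 0 = control).  This module reads tabular
rearrangement files (a plain CSV dialect or an AIRR-style TSV), applies the
read-level and sequence-level filters used upstream of the classifier, and
produces a clean :class:`Cohort`.

Filters implemented here:

* raw-read filtering by length and mean Phred quality (strict removal rules:
  length == ``min_length`` and mean quality == ``min_avg_quality`` are kept);
* duplicate collapsing within a patient (counts summed);
* removal of CDR3s with ambiguous symbols (non-ACGT bases, nonstandard
  residues such as ``X`` or ``*``);
* removal of any CDR3 observed in more than one patient (carry-over
  contamination control) — removed from *all* patients carrying it.

Germline V/D/J assignment and CDR3 boundary calling are upstream
responsibilities: the reader trusts the ``cdr3_aa``/``junction_aa`` column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .atchley import AMINO_ACIDS

__all__ = [
    "RawRead",
    "Repertoire",
    "Cohort",
    "FormatError",
    "ValidationError",
    "read_rearrangement_table",
    "read_fastq",
    "filter_reads",
    "collapse_duplicates",
    "drop_ambiguous",
    "remove_shared_sequences",
    "write_cohort_csv",
    "filter_report",
]

_AA_SET = frozenset(AMINO_ACIDS)
_NT_SET = frozenset("ACGT")

#: Column synonyms for the AIRR Rearrangement dialect.
_AIRR_COLUMNS = {
    "repertoire_id": "patient_id",
    "junction_aa": "cdr3_aa",
    "junction": "cdr3_nt",
    "duplicate_count": "count",
}


class FormatError(ValueError):
    """Input file malformed (missing column, empty file, bad dialect)."""


class ValidationError(ValueError):
    """Input parsed but violates a contract (e.g. non-binary labels)."""


@dataclass
class RawRead:
    """One sequencing read with per-base Phred quality scores."""

    read_id: str
    sequence: str
    quality: Sequence[int]

    def mean_quality(self) -> float:
        if len(self.quality) != len(self.sequence):
            raise ValidationError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )
        return float(sum(self.quality)) / len(self.quality) if self.quality else 0.0


@dataclass
class Repertoire:
    """One patient's labeled bag of CDR3 sequences.

    ``cdr3_nt`` and ``counts``, when present, are parallel to ``cdr3_aa``.
    """

    patient_id: str
    label: int
    cdr3_aa: list[str]
    cdr3_nt: list[str] | None = None
    counts: list[int] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id}: label must be 0 or 1, got {self.label!r}"
            )
        if self.cdr3_nt is not None and len(self.cdr3_nt) != len(self.cdr3_aa):
            raise ValidationError(f"patient {self.patient_id}: cdr3_nt not parallel")
        if self.counts is not None and len(self.counts) != len(self.cdr3_aa):
            raise ValidationError(f"patient {self.patient_id}: counts not parallel")

    def __len__(self) -> int:
        return len(self.cdr3_aa)


@dataclass
class Cohort:
    """A list of repertoires plus free-text provenance."""

    repertoires: list[Repertoire]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.repertoires)

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.repertoires]

    def validate_for_fitting(self) -> None:
        labels = set(self.labels)
        if labels != {0, 1}:
            raise ValidationError(
                f"cohort must contain both labels for fitting, found {sorted(labels)}"
            )


def read_rearrangement_table(path: str | Path, dialect: str = "csv") -> Cohort:
    """Read a tabular rearrangement file into a :class:`Cohort`.

    ``dialect='csv'`` expects columns ``patient_id,label,cdr3_aa`` with optional
    ``cdr3_nt`` and ``count``; ``dialect='airr'`` expects a TSV with AIRR
    column names (``repertoire_id``, ``junction_aa``, ...) plus a ``label``
    column.  Rows with an empty CDR3 are dropped and counted in provenance.
    """
    path = Path(path)
    if dialect not in ("csv", "airr"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "airr" else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if dialect == "airr":
        df = df.rename(columns=_AIRR_COLUMNS)
    for col in ("patient_id", "label", "cdr3_aa"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    n_raw = len(df)
    df = df[df["cdr3_aa"].notna() & (df["cdr3_aa"].str.strip() != "")]
    n_dropped = n_raw - len(df)

    bad = set(df["label"].unique()) - {"0", "1"}
    if bad:
        raise ValidationError(f"{path}: non-binary labels {sorted(bad)}")

    have_nt = "cdr3_nt" in df.columns and df["cdr3_nt"].notna().all()
    have_count = "count" in df.columns and df["count"].notna().all()

    repertoires = []
    for pid, grp in df.groupby("patient_id", sort=True):
        labels = grp["label"].unique()
        if len(labels) != 1:
            raise ValidationError(f"{path}: patient {pid} has conflicting labels")
        repertoires.append(
            Repertoire(
                patient_id=str(pid),
                label=int(labels[0]),
                cdr3_aa=[s.strip().upper() for s in grp["cdr3_aa"]],
                cdr3_nt=[s.strip().upper() for s in grp["cdr3_nt"]] if have_nt else None,
                counts=[int(c) for c in grp["count"]] if have_count else None,
            )
        )
    return Cohort(
        repertoires,
        provenance={"source": str(path), "dialect": dialect, "rows_dropped_empty_cdr3": n_dropped},
    )


def read_fastq(path: str | Path) -> list[RawRead]:
    """Read Sanger (Phred+33) FASTQ into :class:`RawRead` records."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            RawRead(rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
        )
    return reads


def filter_reads(
    reads: Iterable[RawRead], min_length: int = 300, min_avg_quality: float = 35.0
) -> list[RawRead]:
    """Keep reads with length >= ``min_length`` and mean Phred >= ``min_avg_quality``.

    The removal rules are strict inequalities (shorter *than* 300, quality
    lower *than* 35), so reads exactly at the thresholds are retained.  Order
    is preserved and the filter is idempotent.
    """
    return [
        r
        for r in reads
        if len(r.sequence) >= min_length and r.mean_quality() >= min_avg_quality
    ]


def collapse_duplicates(repertoire: Repertoire) -> Repertoire:
    """Merge identical CDR3s within one patient, summing duplicate counts.

    Collapsing keys on the nucleotide sequence when present, else on the
    amino-acid sequence.  First occurrence order is preserved.
    """
    keys = repertoire.cdr3_nt if repertoire.cdr3_nt is not None else repertoire.cdr3_aa
    counts = repertoire.counts or [1] * len(repertoire)
    merged: dict[str, int] = {}
    first_idx: dict[str, int] = {}
    for i, (key, c) in enumerate(zip(keys, counts)):
        if key in merged:
            merged[key] += c
        else:
            merged[key] = c
            first_idx[key] = i
    order = sorted(first_idx, key=first_idx.get)
    idx = [first_idx[k] for k in order]
    return Repertoire(
        patient_id=repertoire.patient_id,
        label=repertoire.label,
        cdr3_aa=[repertoire.cdr3_aa[i] for i in idx],
        cdr3_nt=[repertoire.cdr3_nt[i] for i in idx] if repertoire.cdr3_nt else None,
        counts=[merged[k] for k in order],
        flags=list(repertoire.flags),
    )


def drop_ambiguous(repertoire: Repertoire) -> Repertoire:
    """Remove CDR3s containing ambiguous bases or nonstandard residues."""
    keep = []
    for i, aa in enumerate(repertoire.cdr3_aa):
        if not set(aa) <= _AA_SET:
            continue
        if repertoire.cdr3_nt is not None and not set(repertoire.cdr3_nt[i]) <= _NT_SET:
            continue
        keep.append(i)
    return Repertoire(
        patient_id=repertoire.patient_id,
        label=repertoire.label,
        cdr3_aa=[repertoire.cdr3_aa[i] for i in keep],
        cdr3_nt=[repertoire.cdr3_nt[i] for i in keep] if repertoire.cdr3_nt else None,
        counts=[repertoire.counts[i] for i in keep] if repertoire.counts else None,
        flags=list(repertoire.flags),
    )


def remove_shared_sequences(cohort: Cohort) -> Cohort:
    """Remove any CDR3 observed in two or more patients, from all of them.

    Comparison is on the amino-acid string, case-insensitive.  A repertoire
    emptied by the filter is retained but flagged (and a warning issued); it
    cannot be scored downstream.
    """
    if len(cohort) < 2:
        raise ValidationError("shared-sequence removal needs at least 2 repertoires")
    carriers: dict[str, set[str]] = {}
    for rep in cohort.repertoires:
        for aa in set(s.upper() for s in rep.cdr3_aa):
            carriers.setdefault(aa, set()).add(rep.patient_id)
    shared = {aa for aa, pids in carriers.items() if len(pids) >= 2}

    out_reps = []
    removed_per_patient = {}
    for rep in cohort.repertoires:
        keep = [i for i, aa in enumerate(rep.cdr3_aa) if aa.upper() not in shared]
        removed_per_patient[rep.patient_id] = len(rep) - len(keep)
        flags = list(rep.flags)
        if not keep:
            warnings.warn(
                f"patient {rep.patient_id}: repertoire emptied by shared-sequence removal"
            )
            flags.append("emptied_by_shared_sequence_removal")
        out_reps.append(
            Repertoire(
                patient_id=rep.patient_id,
                label=rep.label,
                cdr3_aa=[rep.cdr3_aa[i] for i in keep],
                cdr3_nt=[rep.cdr3_nt[i] for i in keep] if rep.cdr3_nt else None,
                counts=[rep.counts[i] for i in keep] if rep.counts else None,
                flags=flags,
            )
        )
    prov = dict(cohort.provenance)
    prov["shared_sequences_removed"] = removed_per_patient
    return Cohort(out_reps, provenance=prov)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Re-emit a cohort in the plain CSV dialect."""
    rows = []
    for rep in cohort.repertoires:
        for i, aa in enumerate(rep.cdr3_aa):
            row = {"patient_id": rep.patient_id, "label": rep.label, "cdr3_aa": aa}
            if rep.cdr3_nt is not None:
                row["cdr3_nt"] = rep.cdr3_nt[i]
            if rep.counts is not None:
                row["count"] = rep.counts[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_report(stages: dict[str, Cohort]) -> pd.DataFrame:
    """Tabulate per-patient CDR3 counts after each named filter stage."""
    ids: list[str] = []
    for cohort in stages.values():
        for rep in cohort.repertoires:
            if rep.patient_id not in ids:
                ids.append(rep.patient_id)
    data = {"patient_id": ids}
    for name, cohort in stages.items():
        counts = {r.patient_id: len(r) for r in cohort.repertoires}
        data[f"n_{name}"] = [counts.get(pid, 0) for pid in ids]
    return pd.DataFrame(data)
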