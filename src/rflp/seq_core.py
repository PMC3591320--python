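"""Sequence data model: records, gapped alignments, primers, FASTA I/O.

Residues are uppercase IUPAC nucleotide codes. Coordinates are 0-based,
half-open throughout the library; 1-based inclusive conversion happens only
at the reporting layer (CLI output).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import DataError

#: IUPAC nucleotide ambiguity codes mapped to the sets of bases they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

ALPHABET = frozenset(IUPAC_SETS)

#: Watson-Crick complement, extended over the ambiguity codes.
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

GAP = "-"


def _check_alphabet(residues: str, record_id: str, allow_gap: bool = False) -> None:
    allowed = ALPHABET | {GAP} if allow_gap else ALPHABET
    for offset, base in enumerate(residues):
        if base not in allowed:
            raise DataError(
                f"record {record_id!r}: illegal character {base!r} at offset {offset}"
            )


@dataclass(frozen=True)
class SeqRecord:
    """An identified nucleotide sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier token.
    residues : str
        Uppercase residues over the IUPAC nucleotide alphabet.
    description : str
        Free-text description (may be empty).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence record id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        _check_alphabet(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3'. Minimum length 10 bp; no gaps."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise DataError("primer name must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        _check_alphabet(self.sequence, self.name)
        if len(self.sequence) < 10:
            raise DataError(
                f"primer {self.name!r}: length {len(self.sequence)} < 10 bp"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# The assay's primer pair, targeting the mitochondrial putative control
# region of Pocillopora (the segment between atp8 and cox1).
PDAM_F = Primer("Pdam-F", "AAGAAGATTCGGGCTCGTTT")
PDAM_R = Primer("Pdam-R", "CGCCTCCTCTACCAAGACAG")


@dataclass(frozen=True)
class AlignmentRow:
    """One row of a gapped alignment, optionally carrying a lineage label."""

    id: str
    residues: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("alignment row id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        if "." in self.residues:
            raise DataError(
                f"record {self.id!r}: gap character '.' is not accepted; use '-'"
            )
        _check_alphabet(self.residues, self.id, allow_gap=True)

    def degapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class GappedAlignment:
    """A multiple alignment as parallel gapped rows of identical length."""

    rows: tuple[AlignmentRow, ...]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise DataError("alignment must contain at least one row")
        widths = {len(r.residues) for r in self.rows}
        if len(widths) != 1:
            raise DataError(f"alignment rows have unequal lengths: {sorted(widths)}")
        object.__setattr__(self, "n_columns", widths.pop())

    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.rows]


def reverse_complement(residues: str) -> str:
    """Return the reverse complement, mapping IUPAC codes to their complements."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(residues.upper()))
    except KeyError as exc:
        raise DataError(f"illegal character {exc.args[0]!r} in sequence") from None


def bases_match(a: str, b: str) -> bool:
    """True iff the IUPAC base sets of ``a`` and ``b`` intersect (N matches all)."""
    try:
        return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])
    except KeyError:
        bad = a if a not in IUPAC_SETS else b
        raise DataError(f"illegal residue {bad!r}") from None


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a plain FASTA file into a list of :class:`SeqRecord`.

    Residues are uppercased; entry order is preserved. Illegal characters
    raise :class:`~rflp.errors.DataError` naming the record and offset.
    """
    records: list[SeqRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(
            SeqRecord(id=entry.id, residues=str(entry.seq), description=entry.description)
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records to ``path`` in FASTA format, ``width`` residues per line."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                if desc:
                    header = f"{rec.id} {desc}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>label`` sidecar file into a mapping."""
    labels: dict[str, str] = {}
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise DataError(f"labels file {path}: malformed line {lineno}: {row}")
            labels[row[0].strip()] = row[1].strip()
    return labels


def _split_label_suffix(raw_id: str) -> tuple[str, Optional[str]]:
    if "|" in raw_id:
        base, _, label = raw_id.rpartition("|")
        if base and label:
            return base, label
    return raw_id, None


def read_alignment(path: str | Path, labels_path: str | Path | None = None) -> GappedAlignment:
    """Read a gapped FASTA alignment, attaching lineage labels.

    Labels come from a ``"|label"`` suffix on the FASTA id or from a sidecar
    TSV (``id<TAB>label``). The sidecar wins when both are present.
    """
    sidecar = read_labels(labels_path) if labels_path is not None else {}
    rows = []
    for entry in SeqIO.parse(str(path), "fasta"):
        base_id, suffix_label = _split_label_suffix(entry.id)
        label = sidecar.get(base_id, sidecar.get(entry.id, suffix_label))
        rows.append(AlignmentRow(id=base_id, residues=str(entry.seq), label=label))
    return GappedAlignment(rows=tuple(rows))


def write_alignment(alignment: GappedAlignment, path: str | Path) -> None:
    """Write a gapped alignment as FASTA with ``|label`` header suffixes."""
    with open(path, "w") as handle:
        for row in alignment.rows:
            header = row.id if row.label is None else f"{row.id}|{row.label}"
            handle.write(f">{header}\n{row.residues}\n")


def as_biopython(record: SeqRecord) -> _BioSeqRecord:
    """Convert to a Biopython SeqRecord (interoperability helper)."""
    return _BioSeqRecord(Seq(record.residues), id=record.id, description=record.description)
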