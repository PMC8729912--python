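"""Sequence and alignment I/O.

Reads and writes protein FASTA and aligned FASTA (MSA) files and
translates nucleotide input in all six frames, so the annotator accepts
either DNA or amino-acid sequences.  All coordinates emitted by the
downstream modules are 1-based and inclusive, on the protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .errors import SequenceError

log = logging.getLogger(__name__)

#: The 20 standard amino acids, in alphabetical one-letter order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_VALID_PROTEIN = frozenset(AA_ALPHABET) | {"X", "*"}
_VALID_NUC = frozenset("ACGTN")
GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: the unit of annotation.

    ``sequence`` is uppercase over the 20 amino-acid letters plus X
    (unknown); ``*`` is tolerated only transiently after translation.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"invalid record id {self.id!r}")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_PROTEIN
        if bad:
            raise SequenceError(
                f"record {self.id!r} contains characters outside the protein "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: ordered (id, aligned row) pairs.

    All rows have equal length; the gap character is ``-``. Ungapping any
    row must yield a valid :class:`ProteinRecord` sequence.
    """

    rows: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SequenceError(f"an MSA needs at least 2 rows, got {len(self.rows)}")
        widths = {len(s) for _, s in self.rows}
        if len(widths) > 1:
            detail = ", ".join(f"{i}:{len(s)}" for i, s in self.rows)
            raise SequenceError(f"unequal MSA row lengths ({detail})")
        for rid, row in self.rows:
            ProteinRecord(id=rid, sequence=row.replace(GAP, "") or "X")
            if not row.replace(GAP, ""):
                raise SequenceError(f"MSA row {rid!r} is all gaps")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def __len__(self) -> int:
        return len(self.rows)

    def ungapped(self, index: int) -> ProteinRecord:
        """The index-th row with gaps removed, as a ProteinRecord."""
        rid, row = self.rows[index]
        return ProteinRecord(id=rid, sequence=row.replace(GAP, ""))

    def ungapped_records(self) -> List[ProteinRecord]:
        return [self.ungapped(i) for i in range(len(self.rows))]


def read_fasta(path: str | Path) -> List[ProteinRecord]:
    """Read a protein FASTA file, preserving record order.

    Sequences are uppercased and CR/LF normalized (Biopython does both
    implicitly).  Duplicate ids and out-of-alphabet characters are
    rejected with a message naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"no such file: {path}")
    records: List[ProteinRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), description=desc)
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA with sequence lines wrapped at ``wrap`` columns."""
    if wrap < 1:
        raise SequenceError(f"wrap must be positive, got {wrap}")
    records = list(records)
    if not records:
        log.warning("write_fasta: writing an empty record collection to %s", path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file as an :class:`Msa` (invariants enforced)."""
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"no such file: {path}")
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append((rec.id, str(rec.seq).upper()))
    if len(rows) < 2:
        raise SequenceError(f"MSA {path} has fewer than 2 rows")
    return Msa(rows=tuple(rows))


def write_msa(msa: Msa, path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), wrap):
                fh.write(row[i : i + wrap] + "\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _translate(nuc: str) -> str:
    """Standard-code translation; any codon containing N becomes X."""
    out = []
    table = standard_dna_table
    for i in range(0, len(nuc) - 2, 3):
        codon = nuc[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table[codon])
    return "".join(out)


def translate_frames(nucleotide: str, id_prefix: str = "seq") -> List[ProteinRecord]:
    """Translate a nucleotide sequence in all six frames.

    Returns six records named ``{id_prefix}_frame{+1,+2,+3,-1,-2,-3}``;
    frames too short to yield a codon get the placeholder sequence 'X'
    with a logged warning (a ProteinRecord cannot be empty).
    """
    nuc = nucleotide.upper()
    bad = set(nuc) - _VALID_NUC
    if bad:
        raise SequenceError(f"non-nucleotide characters in input: {sorted(bad)}")
    rc = nuc.translate(_COMPLEMENT)[::-1]
    out: List[ProteinRecord] = []
    for strand, seq in (("+", nuc), ("-", rc)):
        for off in range(3):
            aa = _translate(seq[off:])
            if not aa:
                log.warning("frame %s%d of %s is empty", strand, off + 1, id_prefix)
                aa = "X"
            out.append(
                ProteinRecord(id=f"{id_prefix}_frame{strand}{off + 1}", sequence=aa)
            )
    return out


def is_nucleotide(sequence: str) -> bool:
    """Heuristic: a sequence over ACGTN only is treated as DNA."""
    return bool(sequence) and set(sequence.upper()) <= _VALID_NUC


def protein_products(record: ProteinRecord, min_len: int = 30) -> List[ProteinRecord]:
    """Split a translated frame at stop codons into scannable products.

    Segments between stops shorter than ``min_len`` residues are skipped
    (they are almost always translational nonsense).
    """
    out = []
    for k, seg in enumerate(record.sequence.split("*")):
        if len(seg) >= min_len:
            out.append(ProteinRecord(id=f"{record.id}_seg{k + 1}", sequence=seg))
    return out
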