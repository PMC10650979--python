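"""FASTA input/output, taxon labelling, and alignment validation.

Reference alignments arrive as taxon-labelled multiple sequence alignments in
FASTA with ``-`` as the gap character; queries arrive as unaligned FASTA.
Coordinates throughout the package are 1-based alignment columns, so that a
statement like "an A at position 82" can be checked directly against the file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

# IUPAC nucleotide codes -> constituent bases.  'U' is normalized to 'T' on
# input; '.' is NOT accepted as a gap (deposited alignments use '-').
IUPAC_CODES: Mapping[str, frozenset[str]] = {
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

GAP = "-"
BASES = ("A", "C", "G", "T")
AMBIGUITY_CODES = frozenset(IUPAC_CODES) - frozenset(BASES)
ALPHABET = frozenset(IUPAC_CODES) | {GAP}

#: roles a sequence row can play
ROLE_QUERY = "query"
ROLE_REFERENCE = "reference_voucher"
ROLE_DATABASE = "database"
ROLES = (ROLE_QUERY, ROLE_REFERENCE, ROLE_DATABASE)


class SeqIOError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named nucleotide sequence (possibly gapped)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record has an empty id")
        if not self.residues:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in ALPHABET:
                raise SeqIOError(
                    f"record {self.id!r}: illegal character {ch!r} "
                    f"at position {pos}"
                )

    @property
    def degapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class AlignedRecord:
    """A sequence row of an alignment carrying a taxon label and a role."""

    record: SequenceRecord
    taxon: str = ""
    role: str = ROLE_DATABASE

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SeqIOError(f"unknown role {self.role!r}")
        if self.role != ROLE_QUERY and not self.taxon:
            raise SeqIOError(
                f"record {self.record.id!r}: non-query records need a taxon"
            )

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def residues(self) -> str:
        return self.record.residues

    @property
    def genus(self) -> str:
        return self.taxon.split()[0] if self.taxon else ""


@dataclass(frozen=True)
class Alignment:
    """An ordered, width-consistent collection of aligned records.

    Columns are numbered ``1..width`` inclusive.  All-gap columns are
    retained so printed column numbers stay comparable to the source file.
    """

    records: tuple[AlignedRecord, ...]
    width: int
    all_gap_columns: tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.records)

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, one character per record."""
        if not 1 <= col <= self.width:
            raise IndexError(f"column {col} outside 1..{self.width}")
        return "".join(r.residues[col - 1] for r in self.records)

    @property
    def taxa(self) -> tuple[str, ...]:
        """Distinct non-query taxa in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            if r.role != ROLE_QUERY and r.taxon not in seen:
                seen[r.taxon] = None
        return tuple(seen)

    def records_of(self, taxon: str) -> tuple[AlignedRecord, ...]:
        return tuple(
            r for r in self.records
            if r.role != ROLE_QUERY and r.taxon == taxon
        )

    def without(self, record_id: str) -> "Alignment":
        """Copy of the alignment with one record removed (leave-one-out)."""
        kept = tuple(r for r in self.records if r.id != record_id)
        if len(kept) == len(self.records):
            raise KeyError(record_id)
        return validate_alignment(kept)


def _normalize(raw: str, rec_id: str) -> str:
    residues = raw.upper().replace("U", "T")
    for pos, ch in enumerate(residues, start=1):
        if ch not in ALPHABET:
            raise SeqIOError(
                f"record {rec_id!r}: illegal character "
                f"{raw[pos - 1]!r} at position {pos}"
            )
    return residues


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and RNA ``U`` is normalized to ``T``; record
    order is preserved.  Duplicate ids, illegal characters and empty files
    raise :class:`SeqIOError`.
    """
    path = Path(path)
    if not path.exists():
        raise SeqIOError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise SeqIOError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        residues = _normalize(str(bio.seq), bio.id)
        records.append(
            SequenceRecord(id=bio.id, residues=residues,
                           description=bio.description)
        )
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord | AlignedRecord],
                path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns.

    ``read_fasta(write_fasta(x))`` reproduces ids, descriptions and residues
    exactly.
    """
    if not records:
        raise SeqIOError("refusing to write an empty FASTA file")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            sr = rec.record if isinstance(rec, AlignedRecord) else rec
            header = sr.description if sr.description else sr.id
            if not header.startswith(sr.id):
                header = f"{sr.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(sr.residues), wrap):
                fh.write(sr.residues[i:i + wrap] + "\n")


# --- taxon labelling ---------------------------------------------------

_BINOMIAL = re.compile(r"^[A-Z][A-Za-z.\-]*$")


def parse_binomial(description: str) -> str | None:
    """Extract a ``Genus species`` binomial from a GenBank-style header.

    Default rule: the first two whitespace-separated alphabetic tokens after
    the accession form the binomial (e.g. ``ON722358 Nerium oleander ycf1b``
    -> ``Nerium oleander``).  Returns ``None`` when no binomial is found.
    """
    tokens = description.split()
    for i in range(1, len(tokens) - 1):
        genus, species = tokens[i], tokens[i + 1]
        if (_BINOMIAL.match(genus) and genus[0].isupper()
                and species.isalpha() and species.islower()):
            return f"{genus} {species}"
    return None


def read_taxon_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a TSV taxon map with columns ``id, taxon[, role]``."""
    entries: dict[str, tuple[str, str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("id", "record_id") and lineno == 1:
                continue
            if len(parts) < 2:
                raise SeqIOError(
                    f"taxon map line {lineno}: expected id<TAB>taxon")
            rec_id, taxon = parts[0], parts[1]
            role = parts[2] if len(parts) > 2 and parts[2] else ROLE_DATABASE
            if role != ROLE_QUERY and not taxon:
                raise SeqIOError(
                    f"taxon map line {lineno}: empty taxon for {rec_id!r}")
            entries[rec_id] = (taxon, role)
    return entries


def label_records(
    records: Iterable[SequenceRecord],
    taxon_map: Mapping[str, tuple[str, str]] | None = None,
    query_ids: Iterable[str] = (),
) -> list[AlignedRecord]:
    """Attach taxon labels to records.

    Precedence: an id present in ``taxon_map`` wins over header parsing;
    ids listed in ``query_ids`` get the query role and need no taxon.
    Non-query records that resolve to no taxon raise, listing every
    unresolved id.
    """
    taxon_map = dict(taxon_map or {})
    query_ids = set(query_ids)
    out: list[AlignedRecord] = []
    unresolved: list[str] = []
    for rec in records:
        if rec.id in taxon_map:
            taxon, role = taxon_map[rec.id]
            out.append(AlignedRecord(record=rec, taxon=taxon, role=role))
            continue
        if rec.id in query_ids:
            out.append(AlignedRecord(record=rec, taxon="", role=ROLE_QUERY))
            continue
        taxon = parse_binomial(rec.description)
        if taxon is None:
            unresolved.append(rec.id)
        else:
            out.append(AlignedRecord(record=rec, taxon=taxon,
                                     role=ROLE_DATABASE))
    if unresolved:
        raise SeqIOError(
            "could not resolve a taxon for record(s): "
            + ", ".join(repr(i) for i in unresolved)
        )
    return out


def validate_alignment(records: Sequence[AlignedRecord]) -> Alignment:
    """Check width consistency and build an :class:`Alignment`.

    Ragged inputs raise an error naming the shortest and longest record ids;
    all-gap columns are allowed but listed on the returned object.
    """
    if len(records) < 2:
        raise SeqIOError("alignment needs at least two records")
    lengths = {len(r.residues) for r in records}
    if len(lengths) > 1:
        shortest = min(records, key=lambda r: len(r.residues))
        longest = max(records, key=lambda r: len(r.residues))
        raise SeqIOError(
            f"ragged alignment: record {shortest.id!r} has length "
            f"{len(shortest.residues)} but {longest.id!r} has "
            f"{len(longest.residues)}"
        )
    width = lengths.pop()
    for r in records:
        if set(r.residues) == {GAP}:
            raise SeqIOError(f"record {r.id!r} is all gaps")
    all_gap = tuple(
        c for c in range(1, width + 1)
        if all(r.residues[c - 1] == GAP for r in records)
    )
    return Alignment(records=tuple(records), width=width,
                     all_gap_columns=all_gap)


def read_alignment(
    path: str | Path,
    taxon_map_path: str | Path | None = None,
    query_ids: Iterable[str] = (),
) -> Alignment:
    """Convenience: read + label + validate a reference alignment file."""
    records = read_fasta(path)
    tmap = read_taxon_map(taxon_map_path) if taxon_map_path else None
    return validate_alignment(label_records(records, tmap, query_ids))
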