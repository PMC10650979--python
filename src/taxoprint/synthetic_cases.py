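"""Synthetic stand-in reference sets for the three published case studies.

The original deposited alignments live in an external archive; these
builders construct *synthetic* alignments that reproduce the published
taxon compositions and diagnostic-character coordinates exactly, so the
full pipeline (counting, indel coding, discovery, fingerprint assembly,
classification) can be exercised end to end without any download:

* Camellia, trnH-psbA: 7 *C. japonica* with A at column 82 and a 7-nt gap
  at 232; 22 *C. sinensis* with G and no gap; 76 other-*Camellia* records
  of which 75 carry G (one A exception) and 16 carry the gap (60 do not).
* Nerium, ycf1b: 5 *N. oleander* with C at 545 and T at 587; 11 other
  Apocynaceae with T and C respectively.
* Prunus, trnH-psbA: *P. laurocerasus* with a 10-bp deletion at column
  114, absent from all 57 other-*Prunus* records.

Background columns are a shared consensus plus a few species-private
substitutions, drawn from a fixed seed: every builder is deterministic.
The gut-content query of each case is returned degapped, as it would
arrive from the sequencer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import (
    BASES,
    GAP,
    AlignedRecord,
    Alignment,
    SequenceRecord,
    ROLE_REFERENCE,
    validate_alignment,
)


@dataclass(frozen=True)
class CaseStudy:
    """A synthetic case: reference alignment, gut query, expected answer."""

    name: str
    marker: str
    alignment: Alignment
    query: SequenceRecord
    target_taxon: str


def _consensus(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(BASES), size=length))


def _mutate(seq: list[str], col: int, rng: np.random.Generator) -> None:
    seq[col - 1] = rng.choice([b for b in BASES if b != seq[col - 1]])


def _private_snps(consensus: list[str], columns: list[int],
                  rng: np.random.Generator) -> list[str]:
    seq = list(consensus)
    for col in columns:
        _mutate(seq, col, rng)
    return seq


def _pick_columns(rng: np.random.Generator, length: int,
                  forbidden: set[int], k: int) -> list[int]:
    free = [c for c in range(20, length - 20) if c not in forbidden]
    cols = sorted(rng.choice(free, size=k, replace=False).tolist())
    forbidden.update(cols)
    return cols


def camellia_case() -> CaseStudy:
    """Synthetic Camellia trnH-psbA set: 7 + 22 + 76 records.

    *C. japonica* is separated by the A at column 82 (one A exception in
    another species) combined with the 7-nt gap at columns 232-238
    (present in 16 of the 76 other-Camellia records).
    """
    rng = np.random.default_rng(20230821)
    width = 320
    gap_span = set(range(232, 239))
    # keep species-private variation away from the diagnostic loci and the
    # indel breakpoints (flank polymorphism blurs exact gap placement)
    forbidden = set(range(77, 88)) | set(range(227, 244))
    consensus = _consensus(rng, width)

    species = {
        "Camellia sinensis": 22,
        "Camellia oleifera": 20,
        "Camellia reticulata": 16,
        "Camellia sasanqua": 20,
        "Camellia chekiangoleosa": 20,
    }
    private = {sp: _pick_columns(rng, width, forbidden, 3)
               for sp in species}

    records: list[AlignedRecord] = []

    def add(sp: str, idx: int, seq: list[str], role: str = "database"
            ) -> None:
        rid = f"syn_{sp.split()[1]}_{idx}"
        records.append(AlignedRecord(
            record=SequenceRecord(id=rid, residues="".join(seq),
                                  description=f"{rid} {sp} trnH-psbA "
                                              "synthetic"),
            taxon=sp, role=role))

    japonica = list(consensus)
    japonica[82 - 1] = "A"       # diagnostic state; all others carry G
    for col in gap_span:
        japonica[col - 1] = GAP
    for i in range(7):
        add("Camellia japonica", i, japonica,
            role=ROLE_REFERENCE if i == 0 else "database")

    for sp, n in species.items():
        base_seq = _private_snps(consensus, private[sp], rng)
        base_seq[82 - 1] = "G"
        for i in range(n):
            seq = list(base_seq)
            if sp == "Camellia oleifera" and i == 0:
                seq[82 - 1] = "A"        # the published 75-of-76 exception
            if sp == "Camellia reticulata":
                for col in gap_span:     # the 16 gap-carrying records
                    seq[col - 1] = GAP
            add(sp, i, seq)

    alignment = validate_alignment(records)
    query = SequenceRecord(
        id="gut_alpaca_trnH",
        residues="".join(japonica).replace(GAP, ""),
        description="gut_alpaca_trnH synthetic gut-content amplicon")
    return CaseStudy(name="camellia", marker="trnH-psbA",
                     alignment=alignment, query=query,
                     target_taxon="Camellia japonica")


def nerium_case() -> CaseStudy:
    """Synthetic Apocynaceae ycf1b set: 5 N. oleander + 11 relatives.

    Two zero-exception SNPs separate *N. oleander*: C at column 545
    (all 11 others T) and T at column 587 (all others C).
    """
    rng = np.random.default_rng(20230822)
    width = 650
    forbidden = set(range(540, 551)) | set(range(582, 593))
    consensus = _consensus(rng, width)
    consensus[545 - 1] = "T"
    consensus[587 - 1] = "C"

    species = {
        "Vinca minor": 3,
        "Trachomitum venetum": 3,
        "Apocynum cannabinum": 3,
        "Asclepias syriaca": 2,
    }
    private = {sp: _pick_columns(rng, width, forbidden, 4)
               for sp in species}

    records: list[AlignedRecord] = []
    oleander = list(consensus)
    oleander[545 - 1] = "C"
    oleander[587 - 1] = "T"
    for i in range(5):
        rid = f"syn_oleander_{i}"
        records.append(AlignedRecord(
            record=SequenceRecord(
                id=rid, residues="".join(oleander),
                description=f"{rid} Nerium oleander ycf1b synthetic"),
            taxon="Nerium oleander",
            role=ROLE_REFERENCE if i < 2 else "database"))
    for sp, n in species.items():
        base_seq = _private_snps(consensus, private[sp], rng)
        for i in range(n):
            rid = f"syn_{sp.split()[0].lower()}_{i}"
            records.append(AlignedRecord(
                record=SequenceRecord(
                    id=rid, residues="".join(base_seq),
                    description=f"{rid} {sp} ycf1b synthetic"),
                taxon=sp))

    alignment = validate_alignment(records)
    query = SequenceRecord(
        id="gut_alpaca_ycf1b", residues="".join(oleander),
        description="gut_alpaca_ycf1b synthetic gut-content amplicon")
    return CaseStudy(name="nerium", marker="ycf1b", alignment=alignment,
                     query=query, target_taxon="Nerium oleander")


def prunus_case() -> CaseStudy:
    """Synthetic Prunus trnH-psbA set: P. laurocerasus vs 57 congeners.

    A 10-bp deletion at columns 114-123 is present in every
    *P. laurocerasus* record and absent from all 57 other-*Prunus*
    records.
    """
    rng = np.random.default_rng(20230823)
    width = 350
    gap_span = set(range(114, 124))
    # flank margin keeps private variation off the indel breakpoints
    forbidden = set(range(109, 129))
    consensus = _consensus(rng, width)

    species = {
        "Prunus avium": 15,
        "Prunus padus": 14,
        "Prunus serotina": 14,
        "Prunus spinosa": 14,
    }
    private = {sp: _pick_columns(rng, width, forbidden, 3)
               for sp in species}

    records: list[AlignedRecord] = []
    lauro = list(consensus)
    for col in gap_span:
        lauro[col - 1] = GAP
    for i in range(6):
        rid = f"syn_laurocerasus_{i}"
        records.append(AlignedRecord(
            record=SequenceRecord(
                id=rid, residues="".join(lauro),
                description=f"{rid} Prunus laurocerasus trnH-psbA "
                            "synthetic"),
            taxon="Prunus laurocerasus",
            role=ROLE_REFERENCE if i == 0 else "database"))
    for sp, n in species.items():
        base_seq = _private_snps(consensus, private[sp], rng)
        for i in range(n):
            rid = f"syn_{sp.split()[1]}_{i}"
            records.append(AlignedRecord(
                record=SequenceRecord(
                    id=rid, residues="".join(base_seq),
                    description=f"{rid} {sp} trnH-psbA synthetic"),
                taxon=sp))

    alignment = validate_alignment(records)
    query = SequenceRecord(
        id="gut_goat_trnH", residues="".join(lauro).replace(GAP, ""),
        description="gut_goat_trnH synthetic gut-content amplicon")
    return CaseStudy(name="prunus", marker="trnH-psbA",
                     alignment=alignment, query=query,
                     target_taxon="Prunus laurocerasus")


ALL_CASES = (camellia_case, nerium_case, prunus_case)
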