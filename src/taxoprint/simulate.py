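"""Synthetic taxon-labelled alignments with planted diagnostic characters.

The generator emulates the statistical structure of a barcoding reference
set: K taxa whose members are identical up to intra-taxon substitution
noise, each taxon fixed for a small number of taxon-specific SNPs and for
taxon-specific deletions with shared breakpoints, plus occasional IUPAC
ambiguity calls.  Inter-taxon divergence is represented by the planted
characters themselves rather than by a model of sequence evolution: what is
under test is the counting and discovery logic, which only sees column
states.  Ground truth (the planted characters) is returned alongside, so
discovery precision/recall and leave-one-out classification accuracy can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .characters import (
    DiagnosticCharacter,
    code_indels,
    find_diagnostics,
    assemble_fingerprint,
)
from .classify import DECISION_ASSIGNED, evaluate_query
from .profile_align import map_query
from .seqio import (
    BASES,
    GAP,
    AlignedRecord,
    Alignment,
    SequenceRecord,
    validate_alignment,
    write_fasta,
)

# ambiguity code that contains the true base (Sanger-style soft call)
_COMPATIBLE = {
    "A": ("R", "M", "W"),
    "C": ("Y", "M", "S"),
    "G": ("R", "K", "S"),
    "T": ("Y", "K", "W"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic reference set.

    ``theta`` is the per-site, per-sequence intra-taxon substitution
    probability; planted SNPs are fixed within their taxon and differ from
    the background consensus; planted indels are shared-breakpoint
    deletions ``(taxon_index, start_column, length)``.
    """

    n_taxa: int = 3
    seqs_per_taxon: int | Sequence[int] = 5
    length: int = 120
    theta: float = 0.0
    planted_snps_per_taxon: int = 1
    planted_indels: tuple[tuple[int, int, int], ...] = ()
    ambiguity_rate: float = 0.0
    seed: int = 0

    def per_taxon_counts(self) -> list[int]:
        if isinstance(self.seqs_per_taxon, int):
            return [self.seqs_per_taxon] * self.n_taxa
        counts = list(self.seqs_per_taxon)
        if len(counts) != self.n_taxa:
            raise ValueError("seqs_per_taxon vector length != n_taxa")
        return counts

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1]")
        for t, start, length in self.planted_indels:
            if not 0 <= t < self.n_taxa:
                raise ValueError(f"planted indel names unknown taxon {t}")
            if start < 2 or start + length - 1 > self.length - 1:
                raise ValueError(
                    f"planted indel ({t},{start},{length}) touches a "
                    "terminus or exceeds the sequence length")


@dataclass(frozen=True)
class GroundTruth:
    """Planted characters, per-record taxa, and the consensus sequence."""

    characters: tuple[DiagnosticCharacter, ...]
    record_taxa: dict[str, str]
    consensus: str


def taxon_name(index: int) -> str:
    return f"Simulatus taxon{chr(ord('a') + index)}"


def simulate_alignment(config: SimulationConfig
                       ) -> tuple[Alignment, GroundTruth]:
    """Draw one synthetic alignment plus its ground truth.

    Fully reproducible from ``config.seed``.  Planted loci must not
    overlap; planted SNP columns and indel spans are chosen by the
    generator away from each other and from sequence termini.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.length
    consensus = "".join(rng.choice(list(BASES), size=L))

    # reserve loci: planted indel spans first, then SNP columns
    reserved: set[int] = set()
    for t, start, length in config.planted_indels:
        span = set(range(start, start + length))
        if span & reserved:
            raise ValueError("overlapping planted indel spans")
        reserved |= span
    snp_columns: list[tuple[int, int]] = []  # (taxon, column)
    free = [c for c in range(2, L) if c not in reserved]
    rng.shuffle(free)
    need = config.n_taxa * config.planted_snps_per_taxon
    if len(free) < need:
        raise ValueError("sequence too short for the requested planted SNPs")
    pos = 0
    planted_chars: list[DiagnosticCharacter] = []
    counts = config.per_taxon_counts()
    snp_state: dict[tuple[int, int], str] = {}
    for t in range(config.n_taxa):
        for _ in range(config.planted_snps_per_taxon):
            col = free[pos]
            pos += 1
            reserved.add(col)
            base = consensus[col - 1]
            alt = rng.choice([b for b in BASES if b != base])
            snp_columns.append((t, col))
            snp_state[(t, col)] = alt
            planted_chars.append(DiagnosticCharacter(
                kind="snp", target_taxon=taxon_name(t), state=alt,
                column=col, support=(counts[t], counts[t])))
    for t, start, length in config.planted_indels:
        planted_chars.append(DiagnosticCharacter(
            kind="indel", target_taxon=taxon_name(t), state="present",
            span=(start, start + length - 1),
            support=(counts[t], counts[t])))

    records: list[AlignedRecord] = []
    record_taxa: dict[str, str] = {}
    for t in range(config.n_taxa):
        taxon = taxon_name(t)
        taxon_indels = [(s, l) for (tt, s, l) in config.planted_indels
                        if tt == t]
        taxon_snps = {col: snp_state[(t, col)]
                      for (tt, col) in snp_columns if tt == t}
        # a taxon's own planted loci are fixed by construction; other
        # taxa's planted loci remain ordinary mutable sites for it
        own_reserved = set(taxon_snps)
        for start, length in taxon_indels:
            own_reserved |= set(range(start, start + length))
        for k in range(counts[t]):
            # per-record substream: the uniform fields are drawn the same
            # way for every theta, so the mutated site sets are nested as
            # theta grows (recall is then monotone under a shared seed)
            rec_rng = np.random.default_rng([config.seed, t, k])
            noise_u = rec_rng.random(L)
            noise_pick = rec_rng.integers(0, 3, size=L)
            amb_u = rec_rng.random(L)
            amb_pick = rec_rng.integers(0, 3, size=L)

            seq = list(consensus)
            for col, alt in taxon_snps.items():
                seq[col - 1] = alt
            for col in np.flatnonzero(noise_u < config.theta) + 1:
                if col in own_reserved:
                    continue
                cur = seq[col - 1]
                seq[col - 1] = [b for b in BASES
                                if b != cur][noise_pick[col - 1]]
            # ambiguity calls compatible with the true base
            for col in np.flatnonzero(amb_u < config.ambiguity_rate) + 1:
                if col in own_reserved:
                    continue
                cur = seq[col - 1]
                seq[col - 1] = _COMPATIBLE[cur][amb_pick[col - 1]]
            for start, length in taxon_indels:
                for col in range(start, start + length):
                    seq[col - 1] = GAP
            rec_id = f"sim_t{t}_{k}"
            record_taxa[rec_id] = taxon
            records.append(AlignedRecord(
                record=SequenceRecord(
                    id=rec_id, residues="".join(seq),
                    description=f"{rec_id} {taxon} synthetic"),
                taxon=taxon))
    alignment = validate_alignment(records)
    truth = GroundTruth(characters=tuple(planted_chars),
                        record_taxa=record_taxa, consensus=consensus)
    return alignment, truth


def export(alignment: Alignment, truth: GroundTruth, outdir: str | Path
           ) -> dict[str, Path]:
    """Write FASTA + taxon-map TSV + ground-truth TSV to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "alignment.fasta"
    write_fasta([r.record for r in alignment.records], fasta)
    tmap = outdir / "taxa.tsv"
    with tmap.open("w") as fh:
        fh.write("id\ttaxon\trole\n")
        for r in alignment.records:
            fh.write(f"{r.id}\t{r.taxon}\t{r.role}\n")
    gt = outdir / "ground_truth.tsv"
    with gt.open("w") as fh:
        fh.write("taxon\tkind\tlocus\tstate\n")
        for ch in truth.characters:
            locus = (str(ch.column) if ch.kind == "snp"
                     else f"{ch.span[0]}-{ch.span[1]}")
            fh.write(f"{ch.target_taxon}\t{ch.kind}\t{locus}\t{ch.state}\n")
    return {"fasta": fasta, "taxa": tmap, "ground_truth": gt}


def _character_key(ch: DiagnosticCharacter) -> tuple:
    return (ch.kind, ch.target_taxon, ch.locus, ch.state)


def discovery_metrics(alignment: Alignment, truth: GroundTruth
                      ) -> tuple[float, float]:
    """Precision and recall of strict diagnostic discovery vs the truth.

    Only planted-style states are scored: SNP base states and indel
    *present* states (the complementary *absent* states that planting a
    deletion necessarily creates for the other taxa are ignored).
    """
    found: set[tuple] = set()
    for taxon in alignment.taxa:
        for ch in find_diagnostics(alignment, taxon):
            if ch.kind == "indel" and ch.state != "present":
                continue
            found.add(_character_key(ch))
    planted = {_character_key(ch) for ch in truth.characters}
    tp = len(found & planted)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(planted) if planted else 1.0
    return precision, recall


def leave_one_out_accuracy(alignment: Alignment, truth: GroundTruth,
                           allow_near: bool = True,
                           max_records: int | None = None) -> float:
    """Hold out each record, re-discover fingerprints, classify it back.

    The held-out sequence is degapped and profile-aligned like a field
    query; accuracy is the fraction of records assigned to their true
    taxon.
    """
    ids = [r.id for r in alignment.records]
    if max_records is not None:
        ids = ids[:max_records]
    correct = 0
    for rec_id in ids:
        rest = alignment.without(rec_id)
        fingerprints = []
        for taxon in rest.taxa:
            cands = find_diagnostics(rest, taxon)
            if cands:
                fingerprints.append(
                    assemble_fingerprint(rest, taxon, cands, allow_near))
        held = next(r for r in alignment.records if r.id == rec_id)
        query = SequenceRecord(id=held.id, residues=held.record.degapped,
                               description=held.record.description)
        aq = map_query(query, rest)
        result = evaluate_query(aq, fingerprints)
        if (result.decision == DECISION_ASSIGNED
                and result.decision_taxa[0] == truth.record_taxa[rec_id]):
            correct += 1
    return correct / len(ids)


@dataclass(frozen=True)
class BenchmarkSummary:
    """Per-replicate and mean recovery metrics."""

    precision: tuple[float, ...]
    recall: tuple[float, ...]
    accuracy: tuple[float, ...]

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recall))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))


def benchmark_recovery(config: SimulationConfig, replicates: int = 10,
                       loo_max_records: int | None = None
                       ) -> BenchmarkSummary:
    """Replicate simulate -> discover -> classify and summarize.

    Per-replicate seeds are ``config.seed + replicate_index``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    prec, rec, acc = [], [], []
    for r in range(replicates):
        cfg = SimulationConfig(
            n_taxa=config.n_taxa, seqs_per_taxon=config.seqs_per_taxon,
            length=config.length, theta=config.theta,
            planted_snps_per_taxon=config.planted_snps_per_taxon,
            planted_indels=config.planted_indels,
            ambiguity_rate=config.ambiguity_rate,
            seed=config.seed + r)
        alignment, truth = simulate_alignment(cfg)
        p, r_ = discovery_metrics(alignment, truth)
        a = leave_one_out_accuracy(alignment, truth,
                                   max_records=loo_max_records)
        prec.append(p)
        rec.append(r_)
        acc.append(a)
    return BenchmarkSummary(precision=tuple(prec), recall=tuple(rec),
                            accuracy=tuple(acc))
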