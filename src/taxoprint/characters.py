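"""Diagnostic character discovery and combination fingerprints.

The identification unit is a *diagnostic character*: an alignment column
state (SNP) or a coded indel that is fixed (or nearly fixed) within a target
taxon and absent (or nearly absent) from every comparison taxon, together
with explicit support counts -- "A at column 82 in 7 of 7 Camellia japonica
records, G in 75 of 76 other-genus records".  Where no single character
separates the target, a *combination fingerprint* conjoins several so that
every non-target taxon is excluded by at least one of them.

Indels are coded by the simple-indel-coding convention: every maximal
internal gap run is one presence/absence character keyed by its exact
(start, end) span; a record whose gap run overlaps a character's span
without matching it exactly scores *missing*; terminal gap runs are treated
as missing data (ragged Sanger ends, not deletions).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import (
    GAP,
    BASES,
    AMBIGUITY_CODES,
    IUPAC_CODES,
    Alignment,
    AlignedRecord,
    ROLE_QUERY,
)

STATE_GAP = "gap"
STATE_AMBIGUOUS = "ambiguous"
COLUMN_STATES = BASES + (STATE_GAP, STATE_AMBIGUOUS)

PRESENT = "present"
ABSENT = "absent"
MISSING = "missing"


def classify_residue(ch: str) -> str:
    """Map one alignment character to a column state."""
    if ch in BASES:
        return ch
    if ch == GAP:
        return STATE_GAP
    if ch in AMBIGUITY_CODES:
        return STATE_AMBIGUOUS
    raise ValueError(f"unexpected residue {ch!r}")


@dataclass(frozen=True)
class ColumnCounts:
    """Per-taxon state counts at one 1-based alignment column."""

    column: int
    counts: Mapping[str, Mapping[str, int]]

    def taxon_total(self, taxon: str) -> int:
        return sum(self.counts[taxon].values())


def column_counts(alignment: Alignment, column: int) -> ColumnCounts:
    """Count, per taxon, how many records carry each state at ``column``.

    Query-role records are excluded; within each taxon the state counts
    partition the taxon's records (conservation).
    """
    if not 1 <= column <= alignment.width:
        raise IndexError(
            f"column {column} outside alignment width 1..{alignment.width}")
    counts: dict[str, dict[str, int]] = {}
    for rec in alignment.records:
        if rec.role == ROLE_QUERY:
            continue
        state = classify_residue(rec.residues[column - 1])
        bucket = counts.setdefault(rec.taxon, {})
        bucket[state] = bucket.get(state, 0) + 1
    return ColumnCounts(column=column, counts=counts)


# --- indel coding ------------------------------------------------------


def gap_runs(residues: str, include_terminal: bool = False
             ) -> list[tuple[int, int]]:
    """Maximal gap runs of one row as 1-based inclusive (start, end) spans."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, ch in enumerate(residues, start=1):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(residues)))
    if not include_terminal:
        n = len(residues)
        runs = [(s, e) for s, e in runs if s > 1 and e < n]
    return runs


@dataclass(frozen=True)
class IndelCharacter:
    """One simple-indel-coded gap character.

    ``states`` maps record id -> present / absent / missing.  *present*
    means the record has a maximal gap run at exactly ``start..end``;
    *missing* means a different gap run of that record overlaps the span.
    """

    start: int
    end: int
    states: Mapping[str, str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def code_indels(alignment: Alignment) -> list[IndelCharacter]:
    """Simple indel coding of all internal gap runs in the alignment.

    One character per distinct (start, end) span observed in at least one
    record; spans are returned sorted.  Terminal runs are excluded (missing
    data).  Every internal run of every record maps to exactly one character
    (the one with its own span).
    """
    internal: dict[str, set[tuple[int, int]]] = {}
    all_runs: dict[str, list[tuple[int, int]]] = {}
    spans: set[tuple[int, int]] = set()
    for rec in alignment.records:
        runs = gap_runs(rec.residues)
        internal[rec.id] = set(runs)
        all_runs[rec.id] = gap_runs(rec.residues, include_terminal=True)
        spans.update(runs)

    out = []
    for start, end in sorted(spans):
        states: dict[str, str] = {}
        for rec in alignment.records:
            if (start, end) in internal[rec.id]:
                states[rec.id] = PRESENT
            elif any(s <= end and e >= start for s, e in all_runs[rec.id]):
                # a different (or terminal) gap overlaps the span
                states[rec.id] = MISSING
            else:
                states[rec.id] = ABSENT
        out.append(IndelCharacter(start=start, end=end, states=states))
    return out


# --- diagnostic discovery ----------------------------------------------


@dataclass(frozen=True)
class DiagnosticCharacter:
    """A taxon-diagnostic column state or indel state with support counts.

    ``support`` is (records of the target carrying the state, countable
    target records); ``exceptions`` lists non-target taxa with at least one
    record carrying the state, as (taxon, n_with_state, n_total).
    """

    kind: str                      # "snp" | "indel"
    target_taxon: str
    state: str                     # base for snp, present/absent for indel
    column: int | None = None      # snp locus
    span: tuple[int, int] | None = None  # indel locus
    support: tuple[int, int] = (0, 0)
    exceptions: tuple[tuple[str, int, int], ...] = ()

    @property
    def locus(self) -> tuple[int, int]:
        return (self.column, self.column) if self.kind == "snp" else self.span

    @property
    def n_exception_records(self) -> int:
        return sum(n for _, n, _ in self.exceptions)

    @property
    def is_strict(self) -> bool:
        return self.n_exception_records == 0

    def describe(self) -> str:
        if self.kind == "snp":
            locus = f"col {self.column}"
        else:
            locus = f"cols {self.span[0]}-{self.span[1]}"
        k, n = self.support
        txt = (f"{self.kind} {locus}: {self.target_taxon} state "
               f"{self.state} ({k}/{n})")
        if self.exceptions:
            exc = "; ".join(f"{t} {k_}/{n_}" for t, k_, n_ in self.exceptions)
            txt += f", exceptions: {exc}"
        return txt


def _record_state_at(rec: AlignedRecord, column: int) -> str:
    return classify_residue(rec.residues[column - 1])


def find_diagnostics(
    alignment: Alignment,
    target: str,
    min_target_fraction: float = 1.0,
    max_other_exceptions: int = 0,
    strict_ambiguity: bool = False,
) -> list[DiagnosticCharacter]:
    """Discover SNP and indel characters diagnostic for ``target``.

    A column state qualifies when at least ``min_target_fraction`` of the
    target's countable records carry it and at most ``max_other_exceptions``
    non-target records (totalled over taxa) carry it.  By default ambiguity
    codes carry no state -- an R neither supports an A diagnosis nor counts
    as an exception to it -- and are dropped from the target denominator;
    ``strict_ambiguity`` instead counts a compatible ambiguous non-target
    record as an exception.  SNP states are the four bases only; a column
    where any target record has a gap is left to the indel characters.
    """
    taxa = alignment.taxa
    if target not in taxa:
        raise KeyError(f"unknown taxon {target!r}; alignment has "
                       + ", ".join(repr(t) for t in taxa))
    refs = [r for r in alignment.records if r.role != ROLE_QUERY]
    target_recs = [r for r in refs if r.taxon == target]
    other_recs = [r for r in refs if r.taxon != target]

    out: list[DiagnosticCharacter] = []

    for col in range(1, alignment.width + 1):
        tgt_states = [_record_state_at(r, col) for r in target_recs]
        if STATE_GAP in tgt_states:
            continue  # indel territory
        countable = [s for s in tgt_states if s != STATE_AMBIGUOUS]
        if not countable:
            continue
        for base in BASES:
            k = sum(1 for s in countable if s == base)
            if k / len(countable) < min_target_fraction or k == 0:
                continue
            exceptions: list[tuple[str, int, int]] = []
            n_exc = 0
            for taxon in taxa:
                if taxon == target:
                    continue
                n_with = 0
                n_total = 0
                for r in other_recs:
                    if r.taxon != taxon:
                        continue
                    n_total += 1
                    ch = r.residues[col - 1]
                    if ch == base:
                        n_with += 1
                    elif (strict_ambiguity and ch in AMBIGUITY_CODES
                          and base in IUPAC_CODES[ch]):
                        n_with += 1
                if n_with:
                    exceptions.append((taxon, n_with, n_total))
                    n_exc += n_with
            if n_exc <= max_other_exceptions:
                out.append(DiagnosticCharacter(
                    kind="snp", target_taxon=target, state=base,
                    column=col, support=(k, len(countable)),
                    exceptions=tuple(exceptions)))

    for indel in code_indels(alignment):
        by_id = indel.states
        for state in (PRESENT, ABSENT):
            tgt = [by_id[r.id] for r in target_recs]
            countable_i = [s for s in tgt if s != MISSING]
            if not countable_i:
                continue
            k = sum(1 for s in countable_i if s == state)
            if k / len(countable_i) < min_target_fraction or k == 0:
                continue
            exceptions = []
            n_exc = 0
            for taxon in taxa:
                if taxon == target:
                    continue
                tax_states = [by_id[r.id] for r in other_recs
                              if r.taxon == taxon]
                n_total = sum(1 for s in tax_states if s != MISSING)
                n_with = sum(1 for s in tax_states if s == state)
                if n_with:
                    exceptions.append((taxon, n_with, n_total))
                    n_exc += n_with
            if n_exc <= max_other_exceptions:
                out.append(DiagnosticCharacter(
                    kind="indel", target_taxon=target, state=state,
                    span=indel.span, support=(k, len(countable_i)),
                    exceptions=tuple(exceptions)))
    return out


# --- combination fingerprints ------------------------------------------


@dataclass(frozen=True)
class Fingerprint:
    """A minimal conjunction of diagnostic characters for one taxon.

    ``complete`` is true iff every non-target taxon in the alignment is
    excluded by at least one member character.
    """

    target_taxon: str
    characters: tuple[DiagnosticCharacter, ...]
    excluded_taxa: tuple[str, ...]
    residual_taxa: tuple[str, ...]
    complete: bool


def _taxa_excluded_by(char: DiagnosticCharacter, taxa: Sequence[str],
                      allow_near: bool) -> set[str]:
    """Non-target taxa ruled out by one character.

    A taxon is excluded when none of its records carry the diagnostic state;
    with ``allow_near`` a taxon whose carriers are declared exceptions is
    also treated as excluded (with the caveat carried on the character).
    """
    carriers = {t for t, n, _ in char.exceptions if n > 0}
    excluded = {t for t in taxa if t != char.target_taxon
                and t not in carriers}
    if allow_near:
        excluded |= {t for t in carriers}
    return excluded


def assemble_fingerprint(
    alignment: Alignment,
    target: str,
    candidates: Sequence[DiagnosticCharacter],
    allow_near: bool = False,
) -> Fingerprint:
    """Greedy minimal conjunction of candidates excluding all other taxa.

    At each step the candidate excluding the most not-yet-excluded taxa is
    added; ties prefer zero-exception characters over near-diagnostics, then
    the lower column.  Stops when every non-target taxon is excluded
    (``complete``) or no candidate helps (residual taxa listed).
    """
    if not candidates:
        raise ValueError("empty candidate set")
    others = [t for t in alignment.taxa if t != target]
    remaining = set(others)
    chosen: list[DiagnosticCharacter] = []
    pool = list(candidates)
    while remaining and pool:
        def gain(c: DiagnosticCharacter) -> int:
            return len(_taxa_excluded_by(c, others, allow_near) & remaining)

        best = max(
            pool,
            key=lambda c: (gain(c), c.is_strict, -c.locus[0],
                           c.kind == "snp"),
        )
        if gain(best) == 0:
            break
        chosen.append(best)
        remaining -= _taxa_excluded_by(best, others, allow_near)
        pool.remove(best)
    excluded = tuple(t for t in others if t not in remaining)
    return Fingerprint(
        target_taxon=target,
        characters=tuple(chosen),
        excluded_taxa=excluded,
        residual_taxa=tuple(sorted(remaining)),
        complete=not remaining,
    )


def assemble_fingerprint_exact(
    alignment: Alignment,
    target: str,
    candidates: Sequence[DiagnosticCharacter],
    allow_near: bool = False,
    max_candidates: int = 20,
) -> Fingerprint:
    """Exact minimum set cover over at most ``max_candidates`` characters.

    Enumerates subsets by increasing size; falls back to the greedy result
    when no complete conjunction exists.
    """
    if len(candidates) > max_candidates:
        raise ValueError(
            f"exact search limited to {max_candidates} candidates")
    others = [t for t in alignment.taxa if t != target]
    need = set(others)
    cover = {c: _taxa_excluded_by(c, others, allow_near) for c in candidates}
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            if set().union(*(cover[c] for c in combo)) >= need:
                return Fingerprint(
                    target_taxon=target, characters=tuple(combo),
                    excluded_taxa=tuple(others), residual_taxa=(),
                    complete=True)
    return assemble_fingerprint(alignment, target, candidates, allow_near)


# --- fingerprint JSON --------------------------------------------------

FINGERPRINT_FORMAT_VERSION = 1


def _character_to_dict(c: DiagnosticCharacter) -> dict:
    return {
        "kind": c.kind,
        "target_taxon": c.target_taxon,
        "state": c.state,
        "column": c.column,
        "span": list(c.span) if c.span else None,
        "support": list(c.support),
        "exceptions": [list(x) for x in c.exceptions],
    }


def _character_from_dict(d: dict) -> DiagnosticCharacter:
    return DiagnosticCharacter(
        kind=d["kind"], target_taxon=d["target_taxon"], state=d["state"],
        column=d["column"],
        span=tuple(d["span"]) if d["span"] else None,
        support=tuple(d["support"]),
        exceptions=tuple((t, int(k), int(n))
                         for t, k, n in d["exceptions"]),
    )


def fingerprints_to_json(
    fingerprints: Sequence[Fingerprint],
    marker: str = "marker",
    alignment_width: int | None = None,
    alignment_sha256: str = "",
) -> dict:
    """Versioned JSON document for a set of fingerprints.

    Carries the marker name, source-alignment width and hash, and the
    coordinate convention, so a classifier can refuse coordinates that do
    not belong to the alignment in hand.
    """
    return {
        "format_version": FINGERPRINT_FORMAT_VERSION,
        "marker": marker,
        "coordinate_convention": "1-based alignment columns, inclusive",
        "alignment_width": alignment_width,
        "alignment_sha256": alignment_sha256,
        "fingerprints": [
            {
                "target_taxon": fp.target_taxon,
                "complete": fp.complete,
                "excluded_taxa": list(fp.excluded_taxa),
                "residual_taxa": list(fp.residual_taxa),
                "characters": [_character_to_dict(c)
                               for c in fp.characters],
            }
            for fp in fingerprints
        ],
    }


def fingerprints_from_json(doc: dict) -> list[Fingerprint]:
    """Inverse of :func:`fingerprints_to_json` (lossless round-trip)."""
    if doc.get("format_version") != FINGERPRINT_FORMAT_VERSION:
        raise ValueError(
            f"unsupported fingerprint format version "
            f"{doc.get('format_version')!r}")
    out = []
    for fp in doc["fingerprints"]:
        out.append(Fingerprint(
            target_taxon=fp["target_taxon"],
            characters=tuple(_character_from_dict(c)
                             for c in fp["characters"]),
            excluded_taxa=tuple(fp["excluded_taxa"]),
            residual_taxa=tuple(fp["residual_taxa"]),
            complete=fp["complete"],
        ))
    return out


def support_table(
    alignment: Alignment,
    diagnostics: Iterable[DiagnosticCharacter],
    marker: str = "marker",
) -> pd.DataFrame:
    """Per-locus support table: one row per (character, taxon) count.

    Machine-readable companion of the character reports, with columns
    (marker, locus, kind, state, taxon, n_with_state, n_total, is_target).
    """
    rows = []
    for d in diagnostics:
        locus = (str(d.column) if d.kind == "snp"
                 else f"{d.span[0]}-{d.span[1]}")
        rows.append({
            "marker": marker, "locus": locus, "kind": d.kind,
            "state": d.state, "taxon": d.target_taxon,
            "n_with_state": d.support[0], "n_total": d.support[1],
            "is_target": True,
        })
        for taxon, n_with, n_total in d.exceptions:
            rows.append({
                "marker": marker, "locus": locus, "kind": d.kind,
                "state": d.state, "taxon": taxon,
                "n_with_state": n_with, "n_total": n_total,
                "is_target": False,
            })
    return pd.DataFrame(
        rows, columns=["marker", "locus", "kind", "state", "taxon",
                       "n_with_state", "n_total", "is_target"])
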