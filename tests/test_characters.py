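"""Column counting, indel coding, diagnostic discovery, fingerprints."""

import numpy as np
import pytest

from taxoprint.characters import (
    ABSENT,
    MISSING,
    PRESENT,
    assemble_fingerprint,
    assemble_fingerprint_exact,
    code_indels,
    column_counts,
    find_diagnostics,
    fingerprints_from_json,
    fingerprints_to_json,
    gap_runs,
    support_table,
)
from taxoprint.seqio import AMBIGUITY_CODES, BASES, GAP

from conftest import make_alignment, random_alignment


# --- independent oracles ------------------------------------------------

def oracle_snp_diagnostics(aln, target, min_frac=1.0, max_exc=0):
    """Brute-force re-derivation of SNP diagnostics from raw residues."""
    found = set()
    tgt = [r for r in aln.records if r.taxon == target and r.role != "query"]
    oth = [r for r in aln.records if r.taxon != target and r.role != "query"]
    for col in range(1, aln.width + 1):
        tgt_res = [r.residues[col - 1] for r in tgt]
        if GAP in tgt_res:
            continue
        countable = [c for c in tgt_res if c in BASES]
        if not countable:
            continue
        for base in "ACGT":
            k = countable.count(base)
            if k == 0 or k / len(countable) < min_frac:
                continue
            n_exc = sum(1 for r in oth if r.residues[col - 1] == base)
            if n_exc <= max_exc:
                found.add((col, base))
    return found


def oracle_indel_runs(residues):
    """Independent maximal-internal-gap-run scan."""
    runs, n = [], len(residues)
    i = 0
    while i < n:
        if residues[i] == GAP:
            j = i
            while j < n and residues[j] == GAP:
                j += 1
            if i > 0 and j < n:
                runs.append((i + 1, j))
            i = j
        else:
            i += 1
    return runs


# --- column counts ------------------------------------------------------

def test_column_counts_hand_count():
    aln = make_alignment(
        ["ACGT", "ACGA", "AC-T", "GCRT", "GCGT", "GCGT"],
        taxa=["Taxon x"] * 3 + ["Taxon y"] * 3)
    cc = column_counts(aln, 3)
    assert cc.counts["Taxon x"] == {"G": 2, "gap": 1}
    assert cc.counts["Taxon y"] == {"ambiguous": 1, "G": 2}
    cc1 = column_counts(aln, 1)
    assert cc1.counts == {"Taxon x": {"A": 3}, "Taxon y": {"G": 3}}


def test_column_counts_conservation(rng):
    aln = random_alignment(rng, n_records=9, width=25)
    for col in range(1, aln.width + 1):
        cc = column_counts(aln, col)
        for taxon in aln.taxa:
            assert cc.taxon_total(taxon) == len(aln.records_of(taxon))


def test_column_counts_out_of_range():
    aln = make_alignment(["ACGT", "ACGT"])
    with pytest.raises(IndexError):
        column_counts(aln, 5)
    with pytest.raises(IndexError):
        column_counts(aln, 0)


def test_queries_excluded_from_counts():
    aln = make_alignment(["ACGT", "AGGT", "ATGT"],
                         taxa=["Taxon x", "Taxon x", ""],
                         roles=["database", "database", "query"])
    cc = column_counts(aln, 2)
    assert cc.counts == {"Taxon x": {"C": 1, "G": 1}}


# --- indel coding -------------------------------------------------------

def test_code_indels_definition():
    aln = make_alignment(["AC---T", "ACGGGT"])
    chars = code_indels(aln)
    assert len(chars) == 1
    ch = chars[0]
    assert (ch.start, ch.end, ch.length) == (3, 5, 3)
    assert ch.states == {"r0": PRESENT, "r1": ABSENT}


def test_code_indels_overlap_scores_missing():
    aln = make_alignment(["AC---TTT", "AC----TT", "ACGGGTTT"])
    chars = {(c.start, c.end): c for c in code_indels(aln)}
    assert set(chars) == {(3, 5), (3, 6)}
    assert chars[(3, 5)].states["r1"] == MISSING
    assert chars[(3, 6)].states["r0"] == MISSING
    assert chars[(3, 5)].states["r2"] == ABSENT


def test_terminal_gaps_are_missing_data():
    aln = make_alignment(["--GTACGT", "ACGTACGT", "ACGT--GT"])
    chars = code_indels(aln)
    assert [(c.start, c.end) for c in chars] == [(5, 6)]
    # the ragged-start record is absent for the internal character
    assert chars[0].states["r0"] == ABSENT


def test_indel_coding_completeness(rng):
    """Every maximal internal gap run maps to exactly one character."""
    for _ in range(20):
        aln = random_alignment(rng, n_records=6, width=25, gap_prob=0.2)
        chars = {(c.start, c.end): c for c in code_indels(aln)}
        for rec in aln.records:
            for run in oracle_indel_runs(rec.residues):
                assert run in chars
                assert chars[run].states[rec.id] == PRESENT


# --- diagnostic discovery -----------------------------------------------

def test_find_diagnostics_unknown_taxon():
    aln = make_alignment(["ACGT", "ACGT"])
    with pytest.raises(KeyError):
        find_diagnostics(aln, "Taxon nope")


def test_shared_state_never_diagnostic():
    aln = make_alignment(["AAAA", "AAAA", "AAAA"],
                         taxa=["Taxon x", "Taxon y", "Taxon z"])
    for taxon in aln.taxa:
        assert find_diagnostics(aln, taxon) == []


def test_find_diagnostics_matches_bruteforce(rng):
    """Strict discovery equals exhaustive enumeration on random data."""
    for _ in range(50):
        aln = random_alignment(rng, n_records=8, width=30)
        for taxon in aln.taxa:
            got = {(d.column, d.state)
                   for d in find_diagnostics(aln, taxon)
                   if d.kind == "snp"}
            assert got == oracle_snp_diagnostics(aln, taxon)


def test_monotonicity_in_thresholds(rng):
    """Loosening either threshold never removes a diagnostic."""
    for _ in range(10):
        aln = random_alignment(rng, n_records=8, width=30)
        taxon = aln.taxa[0]
        def keyset(min_frac, max_exc):
            return {(d.kind, d.locus, d.state) for d in find_diagnostics(
                aln, taxon, min_target_fraction=min_frac,
                max_other_exceptions=max_exc)}
        strict = keyset(1.0, 0)
        assert strict <= keyset(1.0, 2)
        assert strict <= keyset(0.6, 0)


def test_ambiguity_carries_no_state():
    # two Taxon-y records carry R (A/G): neither supports nor excepts A
    aln = make_alignment(["AAAA", "AAAA", "RAAA", "CAAA"],
                         taxa=["Taxon x", "Taxon x", "Taxon y", "Taxon y"])
    diags = find_diagnostics(aln, "Taxon x")
    assert ("snp", (1, 1), "A") in {(d.kind, d.locus, d.state)
                                    for d in diags}
    strict = find_diagnostics(aln, "Taxon x", strict_ambiguity=True)
    assert all(d.locus != (1, 1) for d in strict if d.kind == "snp")


def test_target_gap_column_left_to_indels():
    aln = make_alignment(["A-GT", "AAGT", "ACGT"],
                         taxa=["Taxon x", "Taxon y", "Taxon z"])
    diags = find_diagnostics(aln, "Taxon x")
    assert all(d.kind == "indel" or d.column != 2 for d in diags)


# --- fingerprints -------------------------------------------------------

def _camellia_like():
    """3 taxa where only a conjunction separates Taxon x."""
    rows = (["A" + "C" * 9 + "---" + "G" * 8] * 2          # x: SNP + gap
            + ["G" + "C" * 9 + "GGG" + "G" * 8] * 2        # y
            + ["A" + "C" * 9 + "GGG" + "G" * 8] * 1        # z shares SNP
            + ["G" + "C" * 9 + "---" + "G" * 8] * 1)       # z' shares gap
    taxa = (["Taxon x"] * 2 + ["Taxon y"] * 2
            + ["Taxon z"] + ["Taxon w"])
    return make_alignment(rows, taxa)


def test_single_character_fingerprint_complete():
    aln = make_alignment(["AAAA", "AAAA", "CAAA", "GAAA"],
                         taxa=["Taxon x", "Taxon x", "Taxon y", "Taxon z"])
    cands = find_diagnostics(aln, "Taxon x")
    fp = assemble_fingerprint(aln, "Taxon x", cands)
    assert fp.complete and len(fp.characters) == 1


def test_combination_fingerprint_needed():
    aln = _camellia_like()
    cands = find_diagnostics(aln, "Taxon x", max_other_exceptions=2)
    fp = assemble_fingerprint(aln, "Taxon x", cands)
    assert fp.complete
    kinds = sorted(c.kind for c in fp.characters)
    assert kinds == ["indel", "snp"]


def test_identical_taxa_cannot_be_separated():
    aln = make_alignment(["ACGT", "ACGT", "AGGT"],
                         taxa=["Taxon x", "Taxon y", "Taxon z"])
    cands = find_diagnostics(aln, "Taxon x", min_target_fraction=0.0,
                             max_other_exceptions=10)
    fp = assemble_fingerprint(aln, "Taxon x", cands)
    assert not fp.complete
    assert "Taxon y" in fp.residual_taxa


def test_empty_candidates_rejected():
    aln = make_alignment(["ACGT", "ACGT"])
    with pytest.raises(ValueError):
        assemble_fingerprint(aln, aln.taxa[0], [])


def test_fingerprint_soundness(rng):
    """Every excluded taxon fails at least one member character."""
    for _ in range(10):
        aln = random_alignment(rng, n_records=8, width=30)
        for taxon in aln.taxa:
            cands = find_diagnostics(aln, taxon, max_other_exceptions=1)
            if not cands:
                continue
            fp = assemble_fingerprint(aln, taxon, cands)
            for other in fp.excluded_taxa:
                assert any(
                    all(exc_t != other for exc_t, n, _ in ch.exceptions
                        if n > 0)
                    for ch in fp.characters)


def test_exact_cover_not_larger_than_greedy():
    aln = _camellia_like()
    cands = find_diagnostics(aln, "Taxon x", max_other_exceptions=2)
    greedy = assemble_fingerprint(aln, "Taxon x", cands)
    exact = assemble_fingerprint_exact(aln, "Taxon x", cands)
    assert exact.complete
    assert len(exact.characters) <= len(greedy.characters)


def test_fingerprint_json_round_trip():
    aln = _camellia_like()
    cands = find_diagnostics(aln, "Taxon x", max_other_exceptions=2)
    fp = assemble_fingerprint(aln, "Taxon x", cands)
    doc = fingerprints_to_json([fp], marker="trnH-psbA",
                               alignment_width=aln.width)
    back = fingerprints_from_json(doc)
    assert back == [fp]


def test_support_table_columns():
    aln = _camellia_like()
    cands = find_diagnostics(aln, "Taxon x", max_other_exceptions=2)
    df = support_table(aln, cands, marker="m1")
    assert list(df.columns) == ["marker", "locus", "kind", "state", "taxon",
                                "n_with_state", "n_total", "is_target"]
    assert (df[df.is_target].n_with_state <= df[df.is_target].n_total).all()
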