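"""Query-to-profile alignment.

Diagnostic fingerprints are defined in the column coordinates of a fixed
reference alignment, so a query (e.g. a Sanger amplicon from gut content)
must be mapped onto those columns without re-aligning the references --
re-running a multiple aligner would renumber every published position.
The reference alignment is condensed into a per-column base/gap frequency
profile and the degapped query is aligned to it by semi-global affine-gap
dynamic programming.

Scoring: matching base ``b`` at column ``c`` scores
``match_reward * freq(b, c) - mismatch_penalty * (1 - freq(b, c) - freq(gap, c))``;
skipping a column (a query-relative deletion) costs affine penalties scaled
by the column's non-gap frequency, so that columns that are mostly gap in
the references are nearly free to skip -- a query identical to a gapped
reference row then reproduces that row's gap structure exactly.  End gaps
are free on both sides (partial amplicons are not penalised at termini).
Traceback ties prefer diagonal, then vertical (query consumption), then
horizontal, making the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import (
    GAP,
    BASES,
    AMBIGUITY_CODES,
    IUPAC_CODES,
    Alignment,
    SequenceRecord,
    ROLE_QUERY,
)

STATE_UNALIGNED = "unaligned"
STATE_GAP = "gap"

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_GAP_ROW = len(BASES)  # row 4 of the frequency matrix


@dataclass(frozen=True)
class AlignScoring:
    """Alignment parameters (rewards and penalties are positive numbers)."""

    match_reward: float = 2.0
    mismatch_penalty: float = 2.0
    gap_open: float = 5.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class Profile:
    """Per-column {A, C, G, T, gap} frequencies of a reference alignment."""

    width: int
    frequencies: np.ndarray  # shape (5, width), columns sum to 1

    def freq(self, base: str, column: int) -> float:
        """Frequency of ``base`` (or "gap") at 1-based ``column``."""
        row = _GAP_ROW if base == STATE_GAP else _BASE_INDEX[base]
        return float(self.frequencies[row, column - 1])


def build_profile(alignment: Alignment) -> Profile:
    """Column frequency profile over the non-query records.

    Ambiguity codes are distributed fractionally and uniformly over their
    constituent bases (an R adds 1/2 to A and 1/2 to G).
    """
    refs = [r for r in alignment.records if r.role != ROLE_QUERY]
    if not refs:
        raise ValueError("profile needs at least one non-query record")
    freqs = np.zeros((5, alignment.width))
    for rec in refs:
        for j, ch in enumerate(rec.residues):
            if ch == GAP:
                freqs[_GAP_ROW, j] += 1.0
            elif ch in _BASE_INDEX:
                freqs[_BASE_INDEX[ch], j] += 1.0
            else:
                bases = IUPAC_CODES[ch]
                w = 1.0 / len(bases)
                for b in bases:
                    freqs[_BASE_INDEX[b], j] += w
    freqs /= len(refs)
    return Profile(width=alignment.width, frequencies=freqs)


@dataclass(frozen=True)
class AlignedQuery:
    """A query mapped onto reference alignment coordinates.

    Every query residue is either assigned to exactly one column (via
    ``column_state``) or to exactly one insertion.  ``identity_to_nearest``
    is the best per-site identity against any reference row over the
    aligned span; ``aligned_fraction`` is the share of query residues that
    landed in columns.
    """

    query_id: str
    column_state: tuple[str, ...]          # one state per column, 1-based
    insertions: tuple[tuple[int, str], ...]  # (anchor column, residues)
    identity_to_nearest: float
    aligned_fraction: float
    nearest_reference: str = ""
    score: float = 0.0

    def state_at(self, column: int) -> str:
        return self.column_state[column - 1]

    def gap_runs(self) -> list[tuple[int, int]]:
        """Internal gap runs of the query row, like a reference row's."""
        runs: list[tuple[int, int]] = []
        start = None
        w = len(self.column_state)
        for col in range(1, w + 1):
            if self.column_state[col - 1] == STATE_GAP:
                if start is None:
                    start = col
            elif start is not None:
                runs.append((start, col - 1))
                start = None
        if start is not None:
            runs.append((start, w))
        return runs


@dataclass(frozen=True)
class AlignmentQualityFlag:
    """ok / warn / fail verdict on a query-to-profile alignment."""

    level: str
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.level not in ("ok", "warn", "fail"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.level == "fail" and not self.reasons:
            raise ValueError("fail flag needs at least one reason")


def _column_score(profile: Profile, scoring: AlignScoring) -> np.ndarray:
    """(4, width) matrix of per-base per-column match scores."""
    f = profile.frequencies
    base_f = f[:4, :]
    gap_f = f[_GAP_ROW, :]
    return (scoring.match_reward * base_f
            - scoring.mismatch_penalty * (1.0 - base_f - gap_f))


def align_query(
    query: SequenceRecord,
    profile: Profile,
    scoring: AlignScoring | None = None,
) -> AlignedQuery:
    """Semi-global affine-gap alignment of a (degapped) query to a profile.

    Returns the query's state at every profile column, its insertions
    relative to the profile, and summary identity statistics.  The query is
    degapped before alignment; an empty query raises ``ValueError``.
    """
    scoring = scoring or AlignScoring()
    seq = query.degapped
    if not seq:
        raise ValueError(f"query {query.id!r} is empty after degapping")
    w = profile.width
    m = len(seq)
    col_score = _column_score(profile, scoring)
    # occupancy weight: skipping a mostly-gap column is cheap
    occ = 1.0 - profile.frequencies[_GAP_ROW, :]

    # query residue score rows: ambiguity codes score as the mean over
    # their constituent bases
    qscore = np.zeros((m, w))
    for i, ch in enumerate(seq):
        if ch in _BASE_INDEX:
            qscore[i] = col_score[_BASE_INDEX[ch]]
        else:
            rows = [_BASE_INDEX[b] for b in IUPAC_CODES[ch]]
            qscore[i] = col_score[rows].mean(axis=0)

    NEG = -1e18
    go, ge = scoring.gap_open, scoring.gap_extend
    # M: residue i aligned to column j; X: column j skipped (deletion);
    # Y: residue i inserted after column j.  1-based i, j.
    M = np.full((m + 1, w + 1), NEG)
    X = np.full((m + 1, w + 1), NEG)
    Y = np.full((m + 1, w + 1), NEG)
    M[0, 0] = 0.0
    X[0, 1:] = 0.0          # free leading deletions (semi-global)
    Y[1:, 0] = 0.0          # free leading insertions (query overhang)
    # traceback: 0=M, 1=X, 2=Y; plus per-state predecessor choice
    ptrM = np.zeros((m + 1, w + 1), dtype=np.int8)
    ptrX = np.zeros((m + 1, w + 1), dtype=np.int8)
    ptrY = np.zeros((m + 1, w + 1), dtype=np.int8)

    for i in range(0, m + 1):
        for j in range(0, w + 1):
            if i > 0 and j > 0:
                prev = (M[i - 1, j - 1], Y[i - 1, j - 1], X[i - 1, j - 1])
                k = int(np.argmax(prev))  # ties: M, then Y, then X
                M[i, j] = prev[k] + qscore[i - 1, j - 1]
                ptrM[i, j] = (0, 2, 1)[k]
            if j > 0 and i > 0:
                open_x = M[i, j - 1] - (go + ge) * occ[j - 1]
                ext_x = X[i, j - 1] - ge * occ[j - 1]
                if open_x >= ext_x:
                    X[i, j], ptrX[i, j] = open_x, 0
                else:
                    X[i, j], ptrX[i, j] = ext_x, 1
            elif j > 0:  # i == 0: leading deletions stay free
                X[i, j], ptrX[i, j] = 0.0, 1
            if i > 0 and j > 0:
                open_y = M[i - 1, j] - (go + ge)
                ext_y = Y[i - 1, j] - ge
                if open_y >= ext_y:
                    Y[i, j], ptrY[i, j] = open_y, 0
                else:
                    Y[i, j], ptrY[i, j] = ext_y, 2
            elif i > 0:  # j == 0: query overhang before the profile
                Y[i, j], ptrY[i, j] = 0.0, 2

    # free trailing gaps: the alignment may end at any cell of the last row
    # (remaining columns skipped free) or the last column (remaining query
    # residues become a trailing insertion).  Ties prefer the fullest
    # alignment (largest j, then largest i) for determinism.
    best = (M[m, w], 0, m, w)
    for sc, st in ((X[m, w], 1), (Y[m, w], 2)):
        if sc > best[0]:
            best = (sc, st, m, w)
    for j in range(w - 1, -1, -1):  # end with free trailing deletion
        for sc, st in ((M[m, j], 0), (X[m, j], 1), (Y[m, j], 2)):
            if sc > best[0]:
                best = (sc, st, m, j)
    for i in range(m - 1, -1, -1):  # end with free trailing insertion
        for sc, st in ((M[i, w], 0), (X[i, w], 1), (Y[i, w], 2)):
            if sc > best[0]:
                best = (sc, st, i, w)
    best_score, state, i, j = best
    end_i, end_j = i, j

    states = [STATE_UNALIGNED] * w
    insertions: dict[int, list[str]] = {}
    trailing_ins = seq[end_i:]
    for col in range(end_j + 1, w + 1):
        states[col - 1] = STATE_UNALIGNED
    while i > 0 or j > 0:
        if state == 0:  # M
            if i == 0 or j == 0:
                break
            states[j - 1] = seq[i - 1]
            nxt = ptrM[i, j]
            i, j, state = i - 1, j - 1, int(nxt)
        elif state == 1:  # X: column j skipped
            if j == 0:
                break
            if i == 0:
                j -= 1          # leading free deletion: column unaligned
                continue
            states[j - 1] = STATE_GAP
            nxt = ptrX[i, j]
            j, state = j - 1, int(nxt)
        else:  # Y: residue i inserted after column j
            if i == 0:
                break
            insertions.setdefault(j, []).insert(0, seq[i - 1])
            nxt = ptrY[i, j]
            i, state = i - 1, int(nxt)

    # residues before the aligned start are a leading insertion at anchor 0
    if i > 0:
        insertions.setdefault(0, [])
        insertions[0] = list(seq[:i]) + insertions[0]
    if trailing_ins:
        insertions.setdefault(end_j, [])
        insertions[end_j] = insertions[end_j] + list(trailing_ins)

    ins = tuple(sorted((anchor, "".join(chars))
                       for anchor, chars in insertions.items()))
    n_in_columns = sum(1 for s in states
                       if s not in (STATE_UNALIGNED, STATE_GAP))
    aligned_fraction = n_in_columns / m

    return AlignedQuery(
        query_id=query.id,
        column_state=tuple(states),
        insertions=ins,
        identity_to_nearest=0.0,  # filled by identity_to_references
        aligned_fraction=aligned_fraction,
        score=float(best_score),
    )


def identity_to_references(aq: AlignedQuery, alignment: Alignment
                           ) -> AlignedQuery:
    """Attach the best per-site identity against any reference row.

    Identity is computed over columns where both the query and the
    reference carry a base (pairwise deletion); a query ambiguity code
    counts as a match when the reference base is among its constituents.
    """
    best_id, best_ref = 0.0, ""
    for rec in alignment.records:
        if rec.role == ROLE_QUERY:
            continue
        same = comparable = 0
        for col in range(1, alignment.width + 1):
            q = aq.state_at(col)
            r = rec.residues[col - 1]
            if q in (STATE_UNALIGNED, STATE_GAP) or r == GAP:
                continue
            if r not in BASES:
                continue
            comparable += 1
            if q == r or (q in AMBIGUITY_CODES and r in IUPAC_CODES[q]):
                same += 1
        ident = same / comparable if comparable else 0.0
        if ident > best_id:
            best_id, best_ref = ident, rec.id
    return AlignedQuery(
        query_id=aq.query_id, column_state=aq.column_state,
        insertions=aq.insertions, identity_to_nearest=best_id,
        aligned_fraction=aq.aligned_fraction, nearest_reference=best_ref,
        score=aq.score)


def map_query(query: SequenceRecord, alignment: Alignment,
              scoring: AlignScoring | None = None) -> AlignedQuery:
    """Profile-align ``query`` to ``alignment`` and fill identity stats."""
    profile = build_profile(alignment)
    aq = align_query(query, profile, scoring)
    return identity_to_references(aq, alignment)


def assess_quality(
    aq: AlignedQuery,
    min_identity: float = 0.7,
    min_aligned_fraction: float = 0.8,
) -> AlignmentQualityFlag:
    """Flag a mapped query as ok / warn / fail.

    ok requires ``aligned_fraction >= min_aligned_fraction`` and
    ``identity_to_nearest >= min_identity``; values below half the scale
    (0.5) fail outright, anything between warns.
    """
    reasons: list[str] = []
    level = "ok"
    if aq.aligned_fraction < min_aligned_fraction:
        reasons.append(
            f"low aligned fraction ({aq.aligned_fraction:.2f} < "
            f"{min_aligned_fraction:.2f})")
        level = "fail" if aq.aligned_fraction < 0.5 else "warn"
    if aq.identity_to_nearest < min_identity:
        reasons.append(
            f"low identity ({aq.identity_to_nearest:.2f} < "
            f"{min_identity:.2f})")
        if aq.identity_to_nearest < 0.5:
            level = "fail"
        elif level != "fail":
            level = "warn"
    return AlignmentQualityFlag(level=level, reasons=tuple(reasons))
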