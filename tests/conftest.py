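import numpy as np
import pytest

from taxoprint.seqio import (
    AlignedRecord,
    SequenceRecord,
    validate_alignment,
)

BASES = "ACGT"


def make_alignment(rows, taxa=None, roles=None):
    """Build an Alignment from plain residue strings."""
    taxa = taxa or [f"Taxon sp{i}" for i in range(len(rows))]
    roles = roles or ["database"] * len(rows)
    records = [
        AlignedRecord(
            record=SequenceRecord(id=f"r{i}", residues=row,
                                  description=f"r{i} {t} test"),
            taxon=t if role != "query" else "",
            role=role,
        )
        for i, (row, t, role) in enumerate(zip(rows, taxa, roles))
    ]
    return validate_alignment(records)


def random_alignment(rng, n_records=8, width=30, n_taxa=3,
                     gap_prob=0.08, amb_prob=0.03):
    """Random labelled alignment; every record keeps >= 1 base."""
    alphabet = list(BASES) + ["-", "R", "Y", "N"]
    probs = [(1 - gap_prob - amb_prob) / 4] * 4 + [gap_prob] + \
        [amb_prob / 3] * 3
    rows = []
    for _ in range(n_records):
        while True:
            row = "".join(rng.choice(alphabet, size=width, p=probs))
            if any(ch in BASES for ch in row):
                break
        rows.append(row)
    taxa = [f"Taxon sp{rng.integers(n_taxa)}" for _ in range(n_records)]
    # make sure every named taxon really occurs
    return make_alignment(rows, taxa)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
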