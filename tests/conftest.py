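"""Shared fixtures: the synthetic repeat-locus reference and pedigree builders."""

import pytest

from chng3.formats_io import Individual, Pedigree, VariantRecord
from chng3.linkage_lod import MarkerData
from chng3.synthetic_data import make_repeat_locus_reference


@pytest.fixture(scope="session")
def repeat_reference():
    """(sequence, locus, seq_start): (TTTG)4 at chr15:88,569,434-88,569,449."""
    return make_repeat_locus_reference(flank_length=200, n_units=4, seed=42)


@pytest.fixture(scope="session")
def printed_deletion(repeat_reference):
    """The 4-bp one-unit deletion, VCF-anchored one base before the tract."""
    seq, locus, seq_start = repeat_reference
    pos = locus.tract.start - 1
    off = pos - seq_start
    return VariantRecord(locus.chrom, pos, seq[off: off + 5], seq[off])


@pytest.fixture(scope="session")
def repeat_internal_snv(repeat_reference):
    """T>C at chr15:88,569,448, inside the last repeat unit."""
    _, locus, _ = repeat_reference
    return VariantRecord(locus.chrom, 88_569_448, "T", "C")


def build_phase_known_pedigree(n_children: int):
    """Three-generation family with n non-recombinant phase-known meioses.

    Grandfather (affected, 1/2) x grandmother (3/3, phenotype unknown) fix
    the affected father's phase (disease with allele 1); the mother is 4/4,
    so each of the n affected 1/4 children is one informative
    non-recombinant meiosis.
    """
    inds = {
        "gf": Individual("F", "gf", None, None, 1, "affected", [(1, 2)]),
        "gm": Individual("F", "gm", None, None, 2, "unknown", [(3, 3)]),
        "fa": Individual("F", "fa", "gf", "gm", 1, "affected", [(1, 3)]),
        "mo": Individual("F", "mo", None, None, 2, "unknown", [(4, 4)]),
    }
    for i in range(n_children):
        inds[f"c{i}"] = Individual(
            "F", f"c{i}", "fa", "mo", 1, "affected", [(1, 4)]
        )
    ped = Pedigree(inds)
    marker = MarkerData.from_pedigree(ped, [0.25] * 4)
    return ped, marker
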