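"""Mass arithmetic, mass-block alignment, and ppm utilities."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from pabseq import chem

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- peptide mass

def brute_force_mass(seq):
    return sum(chem.DEFAULT_TABLE.mono[r] for r in seq) + chem.DEFAULT_TABLE.water_mono


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("", 18.010565),
        ("G", 57.02146372 + 18.01056468),
    ],
)
def test_peptide_mass_examples(seq, expected):
    assert chem.peptide_mass(seq) == pytest.approx(expected, abs=1e-5)


def test_peptide_mass_matches_summation_oracle():
    rng = random.Random(0)
    for _ in range(50):
        seq = "".join(rng.choices(RESIDUES, k=rng.randint(1, 25)))
        assert chem.peptide_mass(seq) == pytest.approx(brute_force_mass(seq), abs=1e-9)


def test_peptide_mass_with_modifications():
    base = chem.peptide_mass("QCK")
    assert chem.peptide_mass("Q(pyroGlu)CK") == pytest.approx(base - 17.02654910, abs=1e-6)
    assert chem.peptide_mass("QC(+57.02146)K") == pytest.approx(base + 57.02146, abs=1e-6)


def test_unknown_tokens_raise_typed_errors():
    with pytest.raises(chem.UnknownResidueError) as e:
        chem.peptide_mass("PEPTIDEZ")
    assert e.value.token == "Z"
    with pytest.raises(chem.UnknownModificationError) as e:
        chem.peptide_mass("C(nosuchmod)")
    assert e.value.token == "nosuchmod"


# -------------------------------------------------------- mass-block alignment

def test_worked_overlap_example():
    """The isobaric overlap of SEQVENCE and EGGECPEP is [E][N/GG][CE/EC]."""
    al = chem.align_mass_blocks("SEQVENCE", "EGGECPEP", min_blocks=3)
    assert al is not None
    assert al.block_count == 3
    assert [(b.a_str(), b.b_str()) for b in al.blocks] == [
        ("E", "E"),
        ("N", "GG"),
        ("CE", "EC"),
    ]
    assert al.offset == 4


def test_identity_overlap_is_all_single_blocks():
    al = chem.align_mass_blocks("PEPTIDE", "PEPTIDE")
    assert al.block_count == 7
    assert all(len(b.a) == 1 and len(b.b) == 1 for b in al.blocks)


def test_no_overlap_returns_none():
    assert chem.align_mass_blocks("DDDD", "WWWW", min_blocks=1) is None


def _oracle_decompositions(sa, sb, table):
    """All block segmentations (<=2 per side) of two segments, by recursion."""
    masses = table.mono

    def seg_mass(s):
        return sum(masses[c] for c in s)

    def rec(a, b):
        if not a and not b:
            return [0]
        best = []
        for da in (1, 2):
            for db in (1, 2):
                if da <= len(a) and db <= len(b) and abs(
                    seg_mass(a[:da]) - seg_mass(b[:db])
                ) < 1e-6:
                    best.extend(n + 1 for n in rec(a[da:], b[db:]))
        return best

    return rec(sa, sb)


def _oracle_best_alignment(a, b, min_blocks, table):
    """Exhaustive suffix/prefix enumeration with recursive segmentation."""
    best = None
    for la in range(1, len(a) + 1):
        for lb in range(1, len(b) + 1):
            sa, sb = a[len(a) - la:], b[:lb]
            if abs(
                sum(table.mono[c] for c in sa) - sum(table.mono[c] for c in sb)
            ) > 1e-6:
                continue
            counts = _oracle_decompositions(sa, sb, table)
            counts = [c for c in counts if c >= min_blocks]
            if not counts:
                continue
            key = (sum(table.mono[c] for c in sa), max(counts))
            if best is None or key > best:
                best = key
    return best


def test_alignment_agrees_with_exhaustive_oracle():
    """Random peptide pairs up to length 8: same overlap mass and block count."""
    rng = random.Random(42)
    alphabet = "GASNVQTLE"  # isobaric-rich alphabet
    checked = 0
    for _ in range(1000):
        a = "".join(rng.choices(alphabet, k=rng.randint(3, 8)))
        b = "".join(rng.choices(alphabet, k=rng.randint(3, 8)))
        got = chem.align_mass_blocks(a, b, min_blocks=2)
        want = _oracle_best_alignment(a, b, 2, chem.DEFAULT_TABLE)
        if want is None:
            assert got is None
        else:
            checked += 1
            suffix_mass = sum(
                chem.DEFAULT_TABLE.mono[c] for c in a[len(a) - got.len_a:]
            )
            assert suffix_mass == pytest.approx(want[0], abs=1e-6)
            assert got.block_count == want[1]
    assert checked > 10  # the alphabet must actually produce overlaps


def test_alignment_block_masses_balance():
    al = chem.align_mass_blocks("SEQVENCE", "EGGECPEP", min_blocks=3)
    for blk in al.blocks:
        ma = sum(chem.DEFAULT_TABLE.mono[r] for r, _ in blk.a)
        mb = sum(chem.DEFAULT_TABLE.mono[r] for r, _ in blk.b)
        assert ma == pytest.approx(mb, abs=1e-6)


def test_alignment_symmetric_under_reversal():
    """Reversing both peptides and swapping roles mirrors the decomposition."""
    a, b = "SEQVENCE", "EGGECPEP"
    fwd = chem.align_mass_blocks(a, b, min_blocks=3)
    rev = chem.align_mass_blocks(b[::-1], a[::-1], min_blocks=3)
    assert rev is not None
    assert rev.block_count == fwd.block_count
    assert [(b_.b_str()[::-1], b_.a_str()[::-1]) for b_ in reversed(rev.blocks)] == [
        (b_.a_str(), b_.b_str()) for b_ in fwd.blocks
    ]


@given(st.text(alphabet="GANQSTVL", min_size=2, max_size=10))
@settings(max_examples=50, deadline=None)
def test_self_alignment_is_full_identity(seq):
    al = chem.align_mass_blocks(seq, seq)
    assert al is not None
    assert al.offset == 0
    assert al.len_a == len(seq)


# ------------------------------------------------------------------------ ppm

def test_ppm_worked_examples():
    assert chem.ppm_delta(25383.27 + 23791.52 - 18.011, 49156.70) == pytest.approx(
        1.6, abs=0.05
    )
    assert chem.ppm_delta(23411.85, 23410.93) == pytest.approx(39.3, abs=0.05)
    assert chem.ppm_delta(100.0, 100.0) == 0.0


def test_ppm_rejects_nonpositive_observed():
    with pytest.raises(chem.ChemError):
        chem.ppm_delta(100.0, 0.0)


# -------------------------------------------------------------- residue table

def test_residue_table_invariants():
    t = chem.DEFAULT_TABLE
    assert len(t.mono) == 20
    assert t.mono["I"] == t.mono["L"]
    assert t.water_avg == 18.011
    assert t.averagine_residue_mass > 0


def test_residue_table_from_config(tmp_path):
    p = tmp_path / "table.tsv"
    p.write_text("# override\nX\t100.0\nmyMod\t-1.5\n")
    t = chem.ResidueTable.from_config(p)
    assert t.residue_mass("X") == 100.0
    assert t.mod_mass("myMod") == -1.5
    assert t.mono["G"] == chem.DEFAULT_TABLE.mono["G"]
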