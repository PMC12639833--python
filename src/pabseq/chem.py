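"""Mass arithmetic, residue tables, isobaric mass blocks, and ppm utilities.

Every other stage of the pipeline leans on three primitives defined here:

* a residue/modification mass table (monoisotopic and average),
* suffix/prefix *mass-block* alignment between two peptides — the overlap
  notion used to build the peptide overlap graph.  A mass block is a pair of
  equal-mass residue segments, each at most two residues long, so that
  isobaric differences such as ``N`` vs ``GG`` or swapped adjacent residues
  still align,
* signed parts-per-million mass deltas, with the sign convention
  ``(expected - observed) / observed * 1e6``.

Peptide strings may carry modification annotations in parentheses directly
after the modified residue, either as a signed delta (``"Q(-17.03)"``) or as
a name registered in the table (``"C(cam)"``).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "ResidueTable",
    "MassBlock",
    "MassBlockAlignment",
    "ChemError",
    "UnknownResidueError",
    "UnknownModificationError",
    "DEFAULT_TABLE",
    "parse_peptide",
    "peptide_mass",
    "token_masses",
    "prefix_masses",
    "suffix_masses",
    "align_mass_blocks",
    "decompose_mass_blocks",
    "ppm_delta",
]

# Monoisotopic residue masses (Da).  Full precision matters: isobaric
# identities (N = GG, Q = GA, SL = TV) must hold exactly for mass-block
# arithmetic.
_MONO = {
    "G": 57.02146372, "A": 71.03711379, "S": 87.03202841, "P": 97.05276385,
    "V": 99.06841392, "T": 101.04767847, "C": 103.00918448, "L": 113.08406398,
    "I": 113.08406398, "N": 114.04292744, "D": 115.02694302, "Q": 128.05857751,
    "K": 128.09496302, "E": 129.04259309, "M": 131.04048509, "H": 137.05891186,
    "F": 147.06841391, "R": 156.10111102, "Y": 163.06332853, "W": 186.07931295,
}

# Average residue masses (Da)
_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# Closed modification set; extensible via ResidueTable.modifications.
_MODS = {
    "cam": 57.02146372,        # carbamidomethyl (fixed on C)
    "pyroGlu": -17.02654910,   # pyroglutamate from Gln, N-terminal
    "deamidation": 0.98401558,
    "lysLoss": -128.09496302,  # C-terminal lysine truncation (chain level)
}


class ChemError(ValueError):
    """Base error for mass-arithmetic problems."""


class UnknownResidueError(ChemError):
    def __init__(self, token: str):
        self.token = token
        super().__init__(f"unknown residue: {token!r}")


class UnknownModificationError(ChemError):
    def __init__(self, token: str):
        self.token = token
        super().__init__(f"unknown modification: {token!r}")


@dataclass(frozen=True)
class ResidueTable:
    """Residue and modification masses plus the shared physical constants."""

    mono: dict = field(default_factory=lambda: dict(_MONO))
    average: dict = field(default_factory=lambda: dict(_AVG))
    modifications: dict = field(default_factory=lambda: dict(_MODS))
    water_mono: float = 18.01056468
    # Average water as printed in antibody pairing arithmetic (18.011 Da).
    water_avg: float = 18.011
    proton: float = 1.00727646
    averagine_residue_mass: float = 111.1254
    disulfide_loss_mono: float = 2.01565   # 2 x monoisotopic H per bond
    disulfide_loss_avg: float = 2.0159     # 2 x average H per bond

    def residue_mass(self, residue: str, average: bool = False) -> float:
        table = self.average if average else self.mono
        try:
            return table[residue]
        except KeyError:
            raise UnknownResidueError(residue) from None

    def mod_mass(self, name: str) -> float:
        try:
            return self.modifications[name]
        except KeyError:
            raise UnknownModificationError(name) from None

    def disulfide_loss(self, average: bool = False) -> float:
        return self.disulfide_loss_avg if average else self.disulfide_loss_mono

    @classmethod
    def from_config(cls, path) -> "ResidueTable":
        """Load residue/modification overrides from a ``name<TAB>mass`` file.

        Single-letter names override residue masses (monoisotopic column);
        longer names are registered as modifications.
        """
        mono = dict(_MONO)
        mods = dict(_MODS)
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, value = line.split("\t")[:2]
                if len(name) == 1 and name.isalpha():
                    mono[name] = float(value)
                else:
                    mods[name] = float(value)
        return cls(mono=mono, modifications=mods)


DEFAULT_TABLE = ResidueTable()


def parse_peptide(sequence: str, table: ResidueTable = DEFAULT_TABLE):
    """Parse ``"SEQ(+57.02)VENCE"`` into ``((residue, mod_delta), ...)``.

    The parenthesized annotation applies to the residue immediately before it
    and may be a signed float or a registered modification name.
    """
    tokens = []
    i = 0
    n = len(sequence)
    while i < n:
        ch = sequence[i]
        if ch == "(":
            raise ChemError(f"modification with no preceding residue at {i} in {sequence!r}")
        if ch not in table.mono:
            raise UnknownResidueError(ch)
        delta = 0.0
        i += 1
        if i < n and sequence[i] == "(":
            j = sequence.index(")", i)
            body = sequence[i + 1 : j]
            try:
                delta = float(body)
            except ValueError:
                delta = table.mod_mass(body)
            i = j + 1
        tokens.append((ch, delta))
    return tuple(tokens)


def token_masses(tokens, table: ResidueTable = DEFAULT_TABLE, average: bool = False):
    """Per-token masses (residue + modification delta) for parsed tokens."""
    return [table.residue_mass(r, average) + d for r, d in tokens]


def peptide_mass(sequence, table: ResidueTable = DEFAULT_TABLE, average: bool = False) -> float:
    """Neutral peptide mass: residue masses + modification deltas + water.

    An empty chain is water.
    """
    tokens = sequence if isinstance(sequence, tuple) else parse_peptide(sequence, table)
    water = table.water_avg if average else table.water_mono
    return sum(token_masses(tokens, table, average)) + water


def prefix_masses(tokens, table: ResidueTable = DEFAULT_TABLE):
    """Cumulative residue masses after 1..n residues (no water)."""
    out = []
    acc = 0.0
    for m in token_masses(tokens, table):
        acc += m
        out.append(acc)
    return out


def suffix_masses(tokens, table: ResidueTable = DEFAULT_TABLE):
    """Cumulative residue masses of the last 1..n residues (no water)."""
    out = []
    acc = 0.0
    for m in reversed(token_masses(tokens, table)):
        acc += m
        out.append(acc)
    return out


@dataclass(frozen=True)
class MassBlock:
    a: tuple  # token segment from peptide A (suffix side)
    b: tuple  # token segment from peptide B (prefix side)

    def a_str(self) -> str:
        return "".join(r for r, _ in self.a)

    def b_str(self) -> str:
        return "".join(r for r, _ in self.b)


@dataclass(frozen=True)
class MassBlockAlignment:
    """Suffix(A)/prefix(B) overlap decomposed into equal-mass blocks."""

    offset: int        # residues of A preceding the overlap
    len_a: int         # overlapped suffix length of A (residues)
    len_b: int         # overlapped prefix length of B (residues)
    blocks: tuple      # ordered MassBlock pairs

    @property
    def block_count(self) -> int:
        return len(self.blocks)


_BLOCK_TOL = 1e-6  # Da; block equality is symbolic/exact, not instrumental


def decompose_mass_blocks(seg_a, seg_b, masses_a, masses_b, tol: float = _BLOCK_TOL):
    """Finest decomposition of two equal-mass segments into mass blocks.

    Dynamic program over (consumed-from-A, consumed-from-B) states; each
    block takes 1 or 2 residues from either side with equal block mass.
    Among all valid decompositions the one with the most blocks is
    returned, as a tuple of :class:`MassBlock`; ``None`` if none exists.
    """
    na, nb = len(seg_a), len(seg_b)
    # best[ia][ib]: max blocks decomposing seg_a[ia:], seg_b[ib:]; -1 = impossible
    best = [[-1] * (nb + 1) for _ in range(na + 1)]
    choice = [[None] * (nb + 1) for _ in range(na + 1)]
    best[na][nb] = 0
    for ia in range(na - 1, -1, -1):
        for ib in range(nb - 1, -1, -1):
            for da in (1, 2):
                if ia + da > na:
                    continue
                ma = masses_a[ia] if da == 1 else masses_a[ia] + masses_a[ia + 1]
                for db in (1, 2):
                    if ib + db > nb:
                        continue
                    mb = masses_b[ib] if db == 1 else masses_b[ib] + masses_b[ib + 1]
                    if abs(ma - mb) > tol:
                        continue
                    sub = best[ia + da][ib + db]
                    if sub >= 0 and sub + 1 > best[ia][ib]:
                        best[ia][ib] = sub + 1
                        choice[ia][ib] = (da, db)
    if best[0][0] < 0:
        return None
    blocks = []
    ia = ib = 0
    while ia < na or ib < nb:
        da, db = choice[ia][ib]
        blocks.append(MassBlock(tuple(seg_a[ia : ia + da]), tuple(seg_b[ib : ib + db])))
        ia += da
        ib += db
    return tuple(blocks)


def align_mass_blocks(
    peptide_a,
    peptide_b,
    min_blocks: int = 1,
    table: ResidueTable = DEFAULT_TABLE,
) -> Optional[MassBlockAlignment]:
    """Maximal suffix(A)/prefix(B) overlap decomposable into mass blocks.

    All (suffix length, prefix length) pairs with equal total mass are
    candidate overlaps; the decomposable one with the largest overlap mass
    wins, ties broken toward more blocks (finest granularity).  Returns
    ``None`` when no decomposition reaches ``min_blocks`` blocks.
    """
    if min_blocks < 1:
        raise ValueError("min_blocks must be >= 1")
    tok_a = peptide_a if isinstance(peptide_a, tuple) else parse_peptide(peptide_a, table)
    tok_b = peptide_b if isinstance(peptide_b, tuple) else parse_peptide(peptide_b, table)
    if not tok_a or not tok_b:
        raise ChemError("peptides must be non-empty")
    ma = token_masses(tok_a, table)
    mb = token_masses(tok_b, table)
    suf = suffix_masses(tok_a, table)   # suf[k-1] = mass of last k residues of A
    pre = prefix_masses(tok_b, table)   # pre[k-1] = mass of first k residues of B

    best = None
    best_key = None
    for la in range(1, len(tok_a) + 1):
        target = suf[la - 1]
        lo = bisect.bisect_left(pre, target - _BLOCK_TOL)
        hi = bisect.bisect_right(pre, target + _BLOCK_TOL)
        for idx in range(lo, hi):
            lb = idx + 1
            seg_a = tok_a[len(tok_a) - la :]
            seg_b = tok_b[:lb]
            blocks = decompose_mass_blocks(
                seg_a, seg_b, ma[len(tok_a) - la :], mb[:lb]
            )
            if blocks is None or len(blocks) < min_blocks:
                continue
            key = (target, len(blocks))
            if best_key is None or key > best_key:
                best_key = key
                best = MassBlockAlignment(
                    offset=len(tok_a) - la, len_a=la, len_b=lb, blocks=blocks
                )
    return best


def ppm_delta(expected: float, observed: float) -> float:
    """Signed mass difference in parts per million.

    ``(expected - observed) / observed * 1e6`` — the convention used in the
    pairing report where the expected mass is computed from a pairing and
    the observed mass comes from intact deconvolution.
    """
    if observed <= 0 or not math.isfinite(observed):
        raise ChemError(f"observed mass must be positive, got {observed}")
    return (expected - observed) / observed * 1e6
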