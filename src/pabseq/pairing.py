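"""Grouping sequenced subunits into whole antibodies with intact masses.

Three intact samples constrain the grouping:

* subunit sample — LC, Fd, Fc/2 masses (monoisotopic);
* reduced sample — LC and full heavy-chain masses; an HC is a sequenced Fd
  joined to a sequenced Fc/2, and its mass is ``Fd + Fc/2 - water`` (one
  peptide bond);
* whole sample — deglycosylated antibody masses (average-mass mode); the
  expected whole mass of an (LC, HC) pairing is
  ``2 x (HC + LC) - n_disulfide x disulfide_loss``.

An Fd/Fc2 junction must also satisfy the hinge protease's cleavage motif
(IdeS cuts after ``...LLG | G...``) and be spanned by at least one
bottom-up peptide.  Gates: 4 Da on the reduced HC mass, 100 ppm on the
whole mass (lenient because partially reformed disulfides shift reduced
and whole species).  All pairings passing both gates are reported — an
ambiguous mass can legitimately yield an extra (mispaired) group, which is
left to the reader of the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

from . import chem

__all__ = [
    "ENZYME_RULES",
    "HCPairing",
    "AntibodyGroup",
    "pair_hc",
    "pair_antibody",
    "annotate_terminal_mods",
]

# (Fd C-terminal motif, Fc/2 N-terminal motif) per hinge protease
ENZYME_RULES = {
    "IdeS": ("LLG", "G"),
    "SpeB": ("", ""),   # flexible hinge: motif check disabled by default
}

TABLE = chem.DEFAULT_TABLE

# closed terminal-modification set for mass reconciliation
TERMINAL_MODS = {
    "lysLoss": -128.09496,
    "pyroGlu": -17.02655,
}


@dataclass
class HCPairing:
    fd_sequence: str
    fc_sequence: str
    fd_mass: float
    fc_mass: float
    combined_mass: float            # Fd + Fc/2 - water
    observed_reduced: float
    ppm: float


@dataclass
class AntibodyGroup:
    lc_sequence: str
    lc_mass: float
    lc_observed_reduced: float
    lc_ppm: float
    hc: HCPairing
    expected_whole: float
    observed_whole: float
    whole_ppm: float
    disulfide_count: int
    annotations: List[str] = field(default_factory=list)


def _junction_ok(fd_seq: str, fc_seq: str, rule: Tuple[str, str]) -> bool:
    left, right = rule
    return fd_seq.endswith(left) and fc_seq.startswith(right)


def _junction_spanned(fd_seq: str, fc_seq: str, peptides, flank: int = 4) -> bool:
    """True when a bottom-up peptide covers residues on both sides of the joint."""
    probe = fd_seq[-flank:] + fc_seq[:flank]
    probe = probe.replace("I", "L")
    for p in peptides:
        seq = (p.sequence if hasattr(p, "sequence") else str(p)).replace("I", "L")
        if probe in seq:
            return True
    return False


def pair_hc(
    fd_list: Sequence[Tuple[str, float]],
    fc_list: Sequence[Tuple[str, float]],
    reduced_masses: Sequence[float],
    enzyme: str = "IdeS",
    peptides: Sequence = (),
    mass_tol: float = 4.0,
    water: float = None,
    require_junction_peptide: bool = True,
) -> List[HCPairing]:
    """All Fd x Fc/2 combinations consistent with a reduced HC mass.

    ``fd_list`` / ``fc_list`` hold (sequence, subunit mass) pairs.  A
    pairing is kept when the junction satisfies the enzyme motif, at least
    one bottom-up peptide spans the joint (unless disabled), and
    ``Fd + Fc/2 - water`` is within ``mass_tol`` of an observed reduced
    mass.  An empty result is valid.
    """
    rule = ENZYME_RULES[enzyme]
    if water is None:
        water = TABLE.water_avg
    out = []
    for fd_seq, fd_mass in fd_list:
        for fc_seq, fc_mass in fc_list:
            if not _junction_ok(fd_seq, fc_seq, rule):
                continue
            if require_junction_peptide and not _junction_spanned(fd_seq, fc_seq, peptides):
                continue
            combined = fd_mass + fc_mass - water
            for obs in reduced_masses:
                if abs(combined - obs) <= mass_tol:
                    out.append(
                        HCPairing(
                            fd_sequence=fd_seq,
                            fc_sequence=fc_seq,
                            fd_mass=fd_mass,
                            fc_mass=fc_mass,
                            combined_mass=combined,
                            observed_reduced=obs,
                            ppm=chem.ppm_delta(combined, obs),
                        )
                    )
    return out


def pair_antibody(
    lc_list: Sequence[Tuple[str, float]],
    hc_pairings: Sequence[HCPairing],
    whole_masses: Sequence[float],
    disulfide_count: int = 16,
    whole_tol_ppm: float = 100.0,
    disulfide_loss: float = None,
) -> List[AntibodyGroup]:
    """LC + HC pairings whose expected whole mass matches an observed one.

    ``lc_list`` holds (sequence, observed reduced LC mass) pairs; the
    expected whole mass uses the observed reduced HC and LC masses —
    ``2 x (HC + LC) - disulfide_count x disulfide_loss`` — compared at
    ``whole_tol_ppm``.  All passing pairings are reported, including
    ambiguous extras.
    """
    if disulfide_loss is None:
        disulfide_loss = TABLE.disulfide_loss_avg
    out = []
    for lc_seq, lc_obs in lc_list:
        for hc in hc_pairings:
            expected = 2 * (hc.observed_reduced + lc_obs) - disulfide_count * disulfide_loss
            for obs in whole_masses:
                ppm = chem.ppm_delta(expected, obs)
                if abs(ppm) <= whole_tol_ppm:
                    out.append(
                        AntibodyGroup(
                            lc_sequence=lc_seq,
                            lc_mass=lc_obs,
                            lc_observed_reduced=lc_obs,
                            lc_ppm=0.0,
                            hc=hc,
                            expected_whole=expected,
                            observed_whole=obs,
                            whole_ppm=ppm,
                            disulfide_count=disulfide_count,
                        )
                    )
    return out


def annotate_terminal_mods(
    sequence: str,
    observed_mass: float,
    tol: float = 2.0,
    average: bool = False,
    mods: Dict[str, float] = None,
) -> Optional[List[str]]:
    """Smallest terminal-modification set reconciling sequence and mass.

    Tries the closed set (lysine truncation, pyroglutamate from Gln) in
    combinations of increasing size; pyroGlu requires an N-terminal Q and
    Lys loss a C-terminal K.  Returns the list of modification names
    (empty when the unmodified mass already matches) or ``None`` with no
    combination within ``tol`` Da.
    """
    if mods is None:
        mods = TERMINAL_MODS
    base = chem.peptide_mass(sequence, average=average)
    applicable = []
    for name, delta in mods.items():
        if name == "pyroGlu" and not sequence.startswith("Q"):
            continue
        if name == "lysLoss" and not sequence.endswith("K"):
            continue
        applicable.append((name, delta))
    for size in range(0, len(applicable) + 1):
        for combo in combinations(applicable, size):
            mass = base + sum(d for _, d in combo)
            if abs(mass - observed_mass) <= tol:
                return [name for name, _ in combo]
    return None
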