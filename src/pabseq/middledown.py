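"""Middle-down fragment mass handling.

Targeted middle-down runs of the subunit sample yield, per selected
precursor, a deconvoluted list of neutral c/z fragment masses (electron
transfer dissociation).  This module aggregates the per-run lists that
belong to the same subunit mass, derives the two working mass lists —

* PRMs (prefix residue masses): every fragment interpreted as a c ion,
* SRMs (suffix residue masses): every fragment interpreted as a z ion,

and provides the fragment-match count ``T`` and middle-down coverage used
throughout assembly and evaluation.  Converting SRMs to PRMs through the
(imperfect) precursor mass would inflate their error, so the two lists are
kept separate: PRMs guide left-to-right sequencing, SRMs right-to-left.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from . import chem

__all__ = [
    "C_ION_OFFSET",
    "Z_ION_OFFSET",
    "FragmentMassSet",
    "aggregate_precursors",
    "count_matches",
    "count_matched_sites",
    "md_coverage",
    "srm_to_prm_error_demo",
]

logger = logging.getLogger(__name__)

# Neutral c ion = prefix residue masses + NH3.
C_ION_OFFSET = 17.02655
# Neutral z(dot) ion relative to the suffix residue mass sum; which z species
# the upstream deconvolution reports is instrument-pipeline dependent, so this
# is a configuration default rather than a fixed constant.
Z_ION_OFFSET = 2.00549


@dataclass
class FragmentMassSet:
    """Aggregated neutral fragment masses for one subunit precursor."""

    precursor_mass: float
    fragments: list            # sorted neutral fragment masses (Da)
    intensities: list
    tol_ppm: float = 50.0
    c_ion_offset: float = C_ION_OFFSET
    z_ion_offset: float = Z_ION_OFFSET
    prm_list: list = field(init=False)
    srm_list: list = field(init=False)

    def __post_init__(self):
        order = sorted(range(len(self.fragments)), key=lambda i: self.fragments[i])
        self.fragments = [self.fragments[i] for i in order]
        self.intensities = [self.intensities[i] for i in order]
        if any(f <= 0 for f in self.fragments):
            raise ValueError("fragment masses must be positive")
        self.prm_list = sorted(
            f - self.c_ion_offset for f in self.fragments if f > self.c_ion_offset
        )
        self.srm_list = sorted(
            f - self.z_ion_offset for f in self.fragments if f > self.z_ion_offset
        )

    @classmethod
    def empty(cls, precursor_mass: float, tol_ppm: float = 50.0) -> "FragmentMassSet":
        return cls(precursor_mass, [], [], tol_ppm=tol_ppm)


def _merge_duplicates(masses, intensities, tol_ppm):
    """Cluster near-identical masses; intensity-weighted mean, summed intensity."""
    order = sorted(range(len(masses)), key=lambda i: masses[i])
    out_m, out_i = [], []
    for idx in order:
        m, inten = masses[idx], intensities[idx]
        if out_m and abs(m - out_m[-1]) <= out_m[-1] * tol_ppm * 1e-6:
            tot = out_i[-1] + inten
            out_m[-1] = (out_m[-1] * out_i[-1] + m * inten) / tot if tot > 0 else out_m[-1]
            out_i[-1] = tot
        else:
            out_m.append(m)
            out_i.append(inten)
    return out_m, out_i


def aggregate_precursors(
    runs,
    subunit_masses,
    tol_ppm: float = 50.0,
    match_tol_ppm: float = 50.0,
):
    """Pool per-run precursor fragment lists by subunit mass.

    Parameters
    ----------
    runs
        Iterable of per-run mappings ``{precursor_mass: [(mass, intensity), ...]}``
        (the targeted experiment acquires the same precursors in several runs).
    subunit_masses
        Deconvoluted subunit monoisotopic masses from the intact stage.
    tol_ppm
        Tolerance for matching a precursor mass to a subunit mass; precursors
        matching none are logged and skipped.
    match_tol_ppm
        Fragment-match tolerance recorded on the resulting sets.

    Returns
    -------
    dict mapping subunit mass -> :class:`FragmentMassSet`.
    """
    pooled = {m: ([], []) for m in subunit_masses}
    for run in runs:
        for pmass, frags in run.items():
            best = None
            for sm in subunit_masses:
                err = abs(pmass - sm) / sm * 1e6
                if err <= tol_ppm and (best is None or err < best[1]):
                    best = (sm, err)
            if best is None:
                logger.warning(
                    "precursor %.3f Da matches no subunit mass; skipped", pmass
                )
                continue
            masses, intens = pooled[best[0]]
            for f, i in frags:
                masses.append(f)
                intens.append(i)
    out = {}
    for sm, (masses, intens) in pooled.items():
        masses, intens = _merge_duplicates(masses, intens, tol_ppm)
        out[sm] = FragmentMassSet(sm, masses, intens, tol_ppm=match_tol_ppm)
    return out


def count_matches(site_masses, observed, tol_ppm: float) -> int:
    """Number of observed masses within tolerance of any theoretical site.

    Each observed mass counts at most once even if two adjacent windows
    overlap; both inputs must be sorted ascending.
    """
    count = 0
    prev_hi = -1.0
    for m in site_masses:
        tol = m * tol_ppm * 1e-6
        lo = max(m - tol, prev_hi)
        hi = m + tol
        if hi <= lo:
            continue
        count += bisect.bisect_right(observed, hi) - bisect.bisect_right(observed, lo)
        prev_hi = hi
    return count


def count_matched_sites(site_masses, observed, tol_ppm: float) -> int:
    """Number of theoretical sites with at least one observed mass in window."""
    count = 0
    for m in site_masses:
        tol = m * tol_ppm * 1e-6
        lo = bisect.bisect_left(observed, m - tol)
        hi = bisect.bisect_right(observed, m + tol)
        if hi > lo:
            count += 1
    return count


def match_count_for_sequence(sequence, fms: FragmentMassSet, direction: str,
                             table: chem.ResidueTable = chem.DEFAULT_TABLE) -> int:
    """Match count T for a candidate sequence against one direction's list.

    ``forward`` matches theoretical prefix masses against the PRM list;
    ``reverse`` matches suffix masses against the SRM list.
    """
    tokens = sequence if isinstance(sequence, tuple) else chem.parse_peptide(sequence, table)
    if direction == "forward":
        sites = chem.prefix_masses(tokens, table)[:-1]
        return count_matches(sites, fms.prm_list, fms.tol_ppm)
    if direction == "reverse":
        sites = chem.suffix_masses(tokens, table)[:-1]
        return count_matches(sites, fms.srm_list, fms.tol_ppm)
    raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")


def md_coverage(sequence, fms: FragmentMassSet,
                table: chem.ResidueTable = chem.DEFAULT_TABLE) -> float:
    """Middle-down coverage of a sequence.

    Matched c sites plus matched z sites over the ``2 * (length - 1)``
    possible (c, z) fragments, within the set's ppm tolerance.
    """
    tokens = sequence if isinstance(sequence, tuple) else chem.parse_peptide(sequence, table)
    if len(tokens) < 2:
        raise ValueError("sequence must have at least 2 residues")
    c_sites = chem.prefix_masses(tokens, table)[:-1]
    z_sites = chem.suffix_masses(tokens, table)[:-1]
    matched = count_matched_sites(c_sites, fms.prm_list, fms.tol_ppm) + count_matched_sites(
        z_sites, fms.srm_list, fms.tol_ppm
    )
    return matched / (2 * (len(tokens) - 1))


def srm_to_prm_error_demo(precursor_obs, precursor_true, srm_obs, suffix_true):
    """Error inflation when converting an SRM to a PRM via the precursor mass.

    Returns ``(srm error, converted prm error)`` in Da: the direct suffix
    mass error versus the error after subtracting the observed SRM from the
    observed precursor mass, which stacks the precursor's own error on top.
    """
    if min(precursor_obs, precursor_true, srm_obs, suffix_true) <= 0:
        raise ValueError("all masses must be positive")
    srm_err = abs(srm_obs - suffix_true)
    prm_err = abs((precursor_obs - srm_obs) - (precursor_true - suffix_true))
    return srm_err, prm_err
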