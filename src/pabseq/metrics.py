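"""Evaluation utilities: residue accuracy and coverage reporting."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

from . import chem, middledown, refine

__all__ = ["residue_accuracy", "coverage_report", "CoverageReport"]


def _aligner():
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -1
    a.extend_gap_score = -1
    return a


def residue_accuracy(candidate: str, truth: str) -> float:
    """Correctly identified residues over the candidate length.

    The two sequences are globally aligned (unit mismatch/gap costs) and
    identically aligned positions are counted; Ile and Leu are distinct.
    """
    if not candidate:
        raise ValueError("candidate sequence is empty")
    if not truth:
        raise ValueError("truth sequence is empty")
    if candidate == truth:
        return 1.0
    aln = _aligner().align(candidate, truth)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        matches += sum(
            1 for x, y in zip(candidate[a0:a1], truth[b0:b1]) if x == y
        )
    return matches / len(candidate)


@dataclass
class CoverageReport:
    depth: List[int]                  # bottom-up read depth per residue
    tiers: List[str]                  # ">95%" | ">85%" | "<=85%" per residue
    confidence: List[float]
    matched_c_sites: List[int]
    matched_z_sites: List[int]

    @property
    def fully_covered(self) -> bool:
        return all(d > 0 for d in self.depth)


def coverage_report(
    candidate: str,
    peptides: Sequence,
    fms: Optional[middledown.FragmentMassSet] = None,
    table: chem.ResidueTable = chem.DEFAULT_TABLE,
) -> CoverageReport:
    """Per-residue bottom-up depth and confidence tiers plus MD site map.

    Depth counts mapped reads covering each residue; the confidence tier is
    the best local confidence among reads agreeing at that position.  When
    a fragment mass set is given the matched c and z cleavage sites (1-based
    site index) are listed.
    """
    tokens = chem.parse_peptide(candidate, table)
    n = len(tokens)
    depth = [0] * n
    conf = [0.0] * n
    for m in refine.map_reads(peptides, tokens, table):
        for i in range(m.start, m.end):
            depth[i] += 1
        for seq_pos, read_pos, same in m.iter_positions():
            if same:
                conf[seq_pos] = max(conf[seq_pos], m.peptide.confidence[read_pos])
    tiers = [">95%" if c > 0.95 else (">85%" if c > 0.85 else "<=85%") for c in conf]
    matched_c: List[int] = []
    matched_z: List[int] = []
    if fms is not None:
        pre = chem.prefix_masses(tokens, table)
        suf = chem.suffix_masses(tokens, table)
        for i in range(1, n):
            m = pre[i - 1]
            tol = m * fms.tol_ppm * 1e-6
            if middledown.count_matches([m], fms.prm_list, fms.tol_ppm):
                matched_c.append(i)
            m = suf[n - i - 1]
            if middledown.count_matches([m], fms.srm_list, fms.tol_ppm):
                matched_z.append(i)
    return CoverageReport(depth, tiers, conf, matched_c, matched_z)
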