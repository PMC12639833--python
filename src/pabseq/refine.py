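"""Post-assembly refinement: isobaric-error correction and Ile/Leu calls.

Assembly can realize a region from a single misread spectrum — classic de
novo isobarics such as N vs GG, SL vs TV, or swapped adjacent residues
leave the total mass unchanged and survive mass-based scoring.  The
corrector re-aligns every de novo read (PSM) onto the assembled sequence
with mass-block decomposition; wherever a read disagrees through an
equal-mass block, that block is a candidate rewrite.  A rewrite is applied
only on consensus: enough reads support the replacement, more than support
the current residues, and the supporters' local confidence beats the
incumbents'.  Every accepted rewrite is isobaric by construction, so the
sequence mass is preserved exactly.

Ile and Leu share a residue mass, so assembly works in Leu-space; w-ion
evidence from EThcD spectra votes each Leu position back to Ile where a
strict majority of mapped reads support it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import chem

__all__ = [
    "ReadMapping",
    "CorrectionCandidate",
    "CorrectionLogEntry",
    "RefinementResult",
    "map_read",
    "spider_correct",
    "resolve_ile_leu",
]

_SEED_K = 5


@dataclass
class ReadMapping:
    """Placement of one de novo read on an assembled sequence."""

    peptide: object                 # DeNovoPeptide
    start: int                      # residue index on the sequence
    end: int                        # exclusive
    blocks: Tuple                   # MassBlock decomposition (read side = a)
    identity: int                   # matching single-residue block count

    def iter_positions(self):
        """Yield (seq_pos, read_pos, is_identity) per single-residue block."""
        pa = 0
        pb = self.start
        for blk in self.blocks:
            if len(blk.a) == 1 and len(blk.b) == 1:
                yield pb, pa, blk.a[0] == blk.b[0]
            pa += len(blk.a)
            pb += len(blk.b)


def _kmer_index(seq_letters: str, k: int = _SEED_K):
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq_letters) - k + 1):
        index[seq_letters[i : i + k]].append(i)
    return index


def map_read(
    peptide,
    seq_tokens,
    seq_cum,
    seq_index,
    table: chem.ResidueTable = chem.DEFAULT_TABLE,
) -> Optional[ReadMapping]:
    """Best mass-consistent placement of a read on the sequence.

    Seeded by exact 5-mers, anchored by exact cumulative-mass equality
    (isobaric errors preserve segment masses), verified by mass-block
    decomposition.  Returns the placement with the most identity positions,
    or ``None``.
    """
    toks = peptide.tokens
    letters = "".join(r for r, _ in toks)
    n = len(toks)
    if n < _SEED_K:
        return None
    read_masses = chem.token_masses(toks, table)
    read_mass = sum(read_masses)
    starts = set()
    for off in (0, n // 2, n - _SEED_K):
        kmer = letters[off : off + _SEED_K]
        for pos in seq_index.get(kmer, ()):
            base = pos - off
            for d in (-2, -1, 0, 1, 2):
                s = base + d
                if 0 <= s < len(seq_tokens):
                    starts.add(s)
    best = None
    for s in starts:
        target = seq_cum[s] + read_mass  # cumulative mass at placement end
        # find e with seq_cum[e] == target (exact isobaric arithmetic)
        lo, hi = s + 1, len(seq_tokens)
        e = None
        while lo <= hi:
            mid = (lo + hi) // 2
            v = seq_cum[mid]
            if abs(v - target) <= 1e-6:
                e = mid
                break
            if v < target:
                lo = mid + 1
            else:
                hi = mid - 1
        if e is None:
            continue
        seg = seq_tokens[s:e]
        seg_masses = [seq_cum[i + 1] - seq_cum[i] for i in range(s, e)]
        blocks = chem.decompose_mass_blocks(toks, seg, read_masses, seg_masses)
        if blocks is None:
            continue
        identity = sum(
            1 for b in blocks if len(b.a) == 1 and len(b.b) == 1 and b.a[0] == b.b[0]
        )
        if best is None or identity > best.identity:
            best = ReadMapping(peptide, s, e, blocks, identity)
    return best


def map_reads(peptides, seq_tokens, table: chem.ResidueTable = chem.DEFAULT_TABLE):
    """Map a collection of reads onto the sequence; unmappable reads are dropped."""
    letters = "".join(r for r, _ in seq_tokens).replace("I", "L")
    seq_cum = [0.0]
    for m in chem.token_masses(seq_tokens, table):
        seq_cum.append(seq_cum[-1] + m)
    index = _kmer_index(letters)
    out = []
    for p in peptides:
        m = map_read(p, seq_tokens, seq_cum, index, table)
        if m is not None:
            out.append(m)
    return out


@dataclass
class CorrectionCandidate:
    start: int
    end: int                    # exclusive, on the assembled sequence
    original: Tuple
    replacement: Tuple
    support: int
    incumbent_support: int
    support_conf: float
    incumbent_conf: float
    accepted: bool = False
    reason: str = ""


@dataclass
class CorrectionLogEntry:
    position: int
    original: str
    replacement: str
    support: int
    decision: str


@dataclass
class RefinementResult:
    sequences: List[Tuple]          # top candidates, best first (token tuples)
    corrections: List[CorrectionCandidate]
    log: List[CorrectionLogEntry]
    flagged_positions: List[int] = field(default_factory=list)

    @property
    def best(self) -> Tuple:
        return self.sequences[0]


def spider_correct(
    seq_tokens,
    psms,
    low_conf_threshold: float = 0.5,
    min_support: int = 2,
    top_k: int = 5,
    table: chem.ResidueTable = chem.DEFAULT_TABLE,
) -> RefinementResult:
    """Consensus isobaric-error correction of an assembled sequence.

    Every mapped read votes: single-residue identity blocks support the
    current sequence, any other block proposes an equal-mass rewrite of its
    span.  A rewrite is accepted when (a) its span touches low-agreement
    residues, (b) at least ``min_support`` reads propose the identical
    replacement, (c) more reads propose it than support the incumbent
    residues, and (d) the supporters' mean local confidence beats the
    incumbents'.  Conflicting equal-support rewrites cancel and are flagged.
    """
    mappings = map_reads(psms, seq_tokens, table)
    n = len(seq_tokens)

    # agreement-based per-position confidence: best local confidence among
    # reads that *agree* with the current residue at that position
    agree_conf = [0.0] * n
    for m in mappings:
        for seq_pos, read_pos, same in m.iter_positions():
            if same:
                agree_conf[seq_pos] = max(
                    agree_conf[seq_pos], m.peptide.confidence[read_pos]
                )

    # collect rewrite proposals keyed by (span, replacement)
    proposals: Dict[Tuple[int, int, Tuple], List[ReadMapping]] = defaultdict(list)
    prop_conf: Dict[Tuple[int, int, Tuple], List[float]] = defaultdict(list)
    incumbents: Dict[Tuple[int, int], List[float]] = defaultdict(list)
    for m in mappings:
        pa = 0
        pb = m.start
        for blk in m.blocks:
            la, lb = len(blk.a), len(blk.b)
            span = (pb, pb + lb)
            a_str = tuple(blk.a)
            b_str = tuple(blk.b)
            if a_str != b_str:
                key = (span[0], span[1], a_str)
                proposals[key].append(m)
                confs = [m.peptide.confidence[pa + k] for k in range(la)]
                prop_conf[key].append(sum(confs) / len(confs))
            else:
                confs = [m.peptide.confidence[pa + k] for k in range(la)]
                incumbents[span].append(sum(confs) / len(confs))
            pa += la
            pb += lb

    candidates: List[CorrectionCandidate] = []
    for (s, e, repl), supporters in proposals.items():
        inc = incumbents.get((s, e), [])
        span_len = e - s
        low_needed = min(2, span_len)
        n_low = sum(1 for i in range(s, e) if agree_conf[i] < low_conf_threshold)
        cand = CorrectionCandidate(
            start=s,
            end=e,
            original=tuple(seq_tokens[s:e]),
            replacement=repl,
            support=len(supporters),
            incumbent_support=len(inc),
            support_conf=sum(prop_conf[(s, e, repl)]) / len(supporters),
            incumbent_conf=sum(inc) / len(inc) if inc else 0.0,
        )
        if n_low < low_needed:
            cand.reason = "span not low-confidence"
        elif cand.support < min_support:
            cand.reason = "insufficient support"
        elif cand.support <= cand.incumbent_support:
            cand.reason = "no consensus over incumbent"
        elif cand.support_conf <= cand.incumbent_conf:
            cand.reason = "no confidence gain"
        else:
            cand.accepted = True
        candidates.append(cand)

    # conflicting rewrites of the same span with equal support cancel
    by_span = defaultdict(list)
    for c in candidates:
        if c.accepted:
            by_span[(c.start, c.end)].append(c)
    flagged = []
    for span, group in by_span.items():
        if len(group) > 1:
            group.sort(key=lambda c: -c.support)
            if group[0].support == group[1].support:
                for c in group:
                    c.accepted = False
                    c.reason = "ambiguous: conflicting equal-support rewrites"
                flagged.extend(range(span[0], span[1]))
            else:
                for c in group[1:]:
                    c.accepted = False
                    c.reason = "outvoted by stronger rewrite"

    # apply non-overlapping accepted rewrites, strongest first
    accepted = sorted(
        (c for c in candidates if c.accepted), key=lambda c: (-c.support, c.start)
    )
    applied: List[CorrectionCandidate] = []
    taken = set()
    for c in accepted:
        span = set(range(c.start, c.end))
        if span & taken:
            c.accepted = False
            c.reason = "overlaps a stronger accepted rewrite"
            continue
        taken |= span
        applied.append(c)

    def realize(subset):
        out = []
        i = 0
        edits = sorted(subset, key=lambda c: c.start)
        for c in edits:
            out.extend(seq_tokens[i : c.start])
            out.extend(c.replacement)
            i = c.end
        out.extend(seq_tokens[i:])
        return tuple(out)

    sequences = [realize(applied)]
    # alternates: drop the weakest edits one at a time
    for k in range(len(applied) - 1, -1, -1):
        if len(sequences) >= top_k:
            break
        alt = realize(applied[:k] + applied[k + 1 :])
        if alt not in sequences:
            sequences.append(alt)
    if tuple(seq_tokens) not in sequences and len(sequences) < top_k:
        sequences.append(tuple(seq_tokens))

    log = [
        CorrectionLogEntry(
            position=c.start,
            original="".join(r for r, _ in c.original),
            replacement="".join(r for r, _ in c.replacement),
            support=c.support,
            decision="accepted" if c in applied else (c.reason or "rejected"),
        )
        for c in candidates
    ]
    return RefinementResult(sequences, candidates, log, flagged)


def resolve_ile_leu(
    seq_tokens,
    psms,
    table: chem.ResidueTable = chem.DEFAULT_TABLE,
):
    """Assign Ile vs Leu at every Leu position from EThcD w-ion evidence.

    Mapped EThcD reads vote per position; a strict majority of Ile votes
    flips the residue to Ile, otherwise it stays Leu (ties and positions
    with no evidence are flagged low-confidence).  Returns
    ``(tokens, flagged_positions)``.
    """
    ethcd = [p for p in psms if p.mode.upper() == "ETHCD" and p.w_evidence]
    votes: Dict[int, List[str]] = defaultdict(list)
    for m in map_reads(ethcd, seq_tokens, table):
        for seq_pos, read_pos, same in m.iter_positions():
            if not same:
                continue
            ev = m.peptide.w_evidence[read_pos]
            if ev in ("I", "L"):
                votes[seq_pos].append(ev)
    out = list(seq_tokens)
    flagged = []
    for i, (r, d) in enumerate(seq_tokens):
        if r != "L":
            continue
        v = votes.get(i, [])
        n_i = v.count("I")
        n_l = v.count("L")
        if n_i > n_l:
            out[i] = ("I", d)
        elif n_i == n_l:
            flagged.append(i)   # no evidence or tie: Leu by default, flagged
    return tuple(out), flagged
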