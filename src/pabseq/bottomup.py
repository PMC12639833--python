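"""Bottom-up de novo peptide processing.

The input is a table of de novo peptide reads (a PEAKS-style export): a
residue string with modifications, a per-residue local confidence, the
average local confidence (ALC), the fragmentation mode, and — for EThcD
spectra — per-residue w-ion evidence distinguishing Ile from Leu.  Reads
use Leu at every I/L position; Ile is restored only after assembly.

Processing steps:

* :func:`filter_peptides` — ALC and longest-low-confidence-run filter.
* :func:`build_overlap_graph` — bidirectional overlap graph whose edges are
  mass-block alignments of at least three blocks, so isobaric read errors
  (N vs GG, swapped residues) still overlap.  Identical reads collapse into
  one graph node that remembers its member spectra.
* :func:`accumulate_confidence` — each node's positional confidence is
  boosted by the overlapping regions of its neighbors, so a residue that is
  poorly fragmented in one spectrum but well covered in another ends up
  confident.
* :class:`MotifTerminusClassifier` — labels peptides as chain starts/ends
  (LC, Fd, Fc/2) from shipped consensus terminal motifs; the classifier is
  a pluggable contract (any callable mapping a peptide to one of the seven
  classes can be substituted).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from . import chem

__all__ = [
    "DeNovoPeptide",
    "GraphNode",
    "Edge",
    "OverlapGraph",
    "TerminusSets",
    "TERMINUS_CLASSES",
    "filter_peptides",
    "build_overlap_graph",
    "accumulate_confidence",
    "MotifTerminusClassifier",
    "build_terminus_sets",
]

TERMINUS_CLASSES = (
    "LC-START", "LC-END", "Fd-START", "Fd-END", "Fc/2-START", "Fc/2-END", "OTHER",
)

SUBUNIT_TYPES = ("LC", "Fd", "Fc/2")


@dataclass(frozen=True)
class DeNovoPeptide:
    """One bottom-up de novo read."""

    sequence: str
    confidence: Tuple[float, ...]
    alc: float
    mode: str = "HCD"
    spectrum_id: str = ""
    w_evidence: Optional[Tuple[Optional[str], ...]] = None
    tokens: Tuple = field(default=None)

    def __post_init__(self):
        if self.tokens is None:
            object.__setattr__(self, "tokens", chem.parse_peptide(self.sequence))
        if len(self.confidence) != len(self.tokens):
            raise ValueError(
                f"confidence length {len(self.confidence)} != residue count "
                f"{len(self.tokens)} for {self.sequence!r}"
            )

    def __len__(self):
        return len(self.tokens)


def filter_peptides(
    peptides: Sequence[DeNovoPeptide],
    min_alc: float = 0.7,
    max_low_conf_run: int = 4,
    low_conf_threshold: float = 0.5,
) -> List[DeNovoPeptide]:
    """Keep reads with ALC above ``min_alc`` and no long unconfident run.

    A read is dropped when its longest run of residues with local confidence
    below ``low_conf_threshold`` exceeds ``max_low_conf_run``.
    """
    kept = []
    for p in peptides:
        if p.alc <= min_alc:
            continue
        run = worst = 0
        for c in p.confidence:
            run = run + 1 if c < low_conf_threshold else 0
            worst = max(worst, run)
        if worst <= max_low_conf_run:
            kept.append(p)
    return kept


@dataclass
class GraphNode:
    tokens: Tuple
    sequence: str
    members: List[DeNovoPeptide]
    confidence: List[float]          # base: element-wise max over members
    acc_confidence: List[float]      # after accumulation (>= confidence)
    alc: float


@dataclass(frozen=True)
class Edge:
    u: int
    v: int
    alignment: chem.MassBlockAlignment


class OverlapGraph:
    """Peptide overlap graph over deduplicated reads."""

    def __init__(self, nodes: List[GraphNode]):
        self.nodes = nodes
        self.out_edges: Dict[int, List[Edge]] = {i: [] for i in range(len(nodes))}
        self.in_edges: Dict[int, List[Edge]] = {i: [] for i in range(len(nodes))}

    def add_edge(self, edge: Edge):
        self.out_edges[edge.u].append(edge)
        self.in_edges[edge.v].append(edge)

    @property
    def n_edges(self):
        return sum(len(v) for v in self.out_edges.values())


def build_overlap_graph(
    peptides: Sequence[DeNovoPeptide],
    min_blocks: int = 3,
    table: chem.ResidueTable = chem.DEFAULT_TABLE,
) -> OverlapGraph:
    """Build the bidirectional mass-block overlap graph.

    An edge u -> v exists when the maximal suffix(u)/prefix(v) overlap
    decomposes into at least ``min_blocks`` mass blocks and v extends u to
    the right (the overlap does not swallow all of v).  Candidate (u, v)
    pairs are pre-screened by exact suffix/prefix cumulative-mass equality,
    which is a necessary condition for any overlap, so the resulting edge
    set equals the all-pairs computation.
    """
    # deduplicate identical token strings into nodes
    index: Dict[Tuple, int] = {}
    nodes: List[GraphNode] = []
    for p in peptides:
        i = index.get(p.tokens)
        if i is None:
            i = len(nodes)
            index[p.tokens] = i
            nodes.append(
                GraphNode(
                    tokens=p.tokens,
                    sequence=p.sequence,
                    members=[p],
                    confidence=list(p.confidence),
                    acc_confidence=list(p.confidence),
                    alc=p.alc,
                )
            )
        else:
            node = nodes[i]
            node.members.append(p)
            node.confidence = [max(a, b) for a, b in zip(node.confidence, p.confidence)]
            node.acc_confidence = list(node.confidence)
            node.alc = max(node.alc, p.alc)

    graph = OverlapGraph(nodes)
    if not nodes:
        return graph

    prefix = [chem.prefix_masses(n.tokens, table) for n in nodes]
    suffix = [chem.suffix_masses(n.tokens, table) for n in nodes]

    # flat sorted list of (prefix mass, node, prefix length) for screening
    pref_entries = []
    for vi, pm in enumerate(prefix):
        for lb in range(min_blocks, len(pm) + 1):
            pref_entries.append((pm[lb - 1], vi, lb))
    pref_entries.sort()
    pref_vals = [e[0] for e in pref_entries]

    tol = 1e-5
    candidates: Set[Tuple[int, int]] = set()
    for ui, sm in enumerate(suffix):
        for la in range(min_blocks, len(sm) + 1):
            val = sm[la - 1]
            lo = bisect.bisect_left(pref_vals, val - tol)
            hi = bisect.bisect_right(pref_vals, val + tol)
            for k in range(lo, hi):
                vi = pref_entries[k][1]
                if vi != ui:
                    candidates.add((ui, vi))

    for ui, vi in sorted(candidates):
        al = _best_extension_alignment(
            nodes[ui].tokens, nodes[vi].tokens, min_blocks, table
        )
        if al is not None:
            graph.add_edge(Edge(ui, vi, al))
    return graph


def _best_extension_alignment(tok_a, tok_b, min_blocks, table):
    """Like chem.align_mass_blocks but requiring that B extend past the overlap."""
    ma = chem.token_masses(tok_a, table)
    mb = chem.token_masses(tok_b, table)
    suf = chem.suffix_masses(tok_a, table)
    pre = chem.prefix_masses(tok_b, table)
    best = None
    best_key = None
    for la in range(min_blocks, len(tok_a) + 1):
        target = suf[la - 1]
        lo = bisect.bisect_left(pre, target - 1e-6)
        hi = bisect.bisect_right(pre, target + 1e-6)
        for idx in range(lo, hi):
            lb = idx + 1
            if lb >= len(tok_b) or lb < min_blocks:
                continue
            blocks = chem.decompose_mass_blocks(
                tok_a[len(tok_a) - la :], tok_b[:lb], ma[len(tok_a) - la :], mb[:lb]
            )
            if blocks is None or len(blocks) < min_blocks:
                continue
            key = (target, len(blocks))
            if best_key is None or key > best_key:
                best_key = key
                best = chem.MassBlockAlignment(
                    offset=len(tok_a) - la, len_a=la, len_b=lb, blocks=blocks
                )
    return best


def _block_contributions(alignment, a_len, giver_conf, giver_alc, to_a_side: bool):
    """Per-position contributions one neighbor gives across an alignment.

    For single-residue blocks the giver's positional confidence maps over;
    for any block involving a two-residue segment the giver's ALC is used
    (positions no longer correspond one-to-one inside such a block).
    Returns a list of (position-on-receiver, value).
    """
    out = []
    pa = a_len - alignment.len_a  # position in A coords
    pb = 0                        # position in B coords
    for blk in alignment.blocks:
        la, lb = len(blk.a), len(blk.b)
        if la == 1 and lb == 1:
            if to_a_side:
                out.append((pa, giver_conf[pb]))
            else:
                out.append((pb, giver_conf[pa]))
        else:
            if to_a_side:
                for k in range(la):
                    out.append((pa + k, giver_alc))
            else:
                for k in range(lb):
                    out.append((pb + k, giver_alc))
        pa += la
        pb += lb
    return out


def accumulate_confidence(graph: OverlapGraph) -> OverlapGraph:
    """Boost each node's positional confidence from its overlap neighbors.

    For node P, every right-extender Q (edge P -> Q) contributes Q's local
    confidence over the overlapped suffix of P, and every left-extender R
    (edge R -> P) contributes over the overlapped prefix of P; inside
    two-residue mass blocks the contributing node's ALC substitutes for
    positional scores.  Contributions use neighbors' *original* scores, so
    the update is order-independent.  Per residue the updated score is
    ``min(1, original + mean(contributions))`` — never below the original.
    """
    contribs: List[List[List[float]]] = [
        [[] for _ in node.tokens] for node in graph.nodes
    ]
    for i, node in enumerate(graph.nodes):
        for e in graph.out_edges[i]:
            q = graph.nodes[e.v]
            for pos, val in _block_contributions(
                e.alignment, len(node.tokens), q.confidence, q.alc, to_a_side=True
            ):
                contribs[i][pos].append(val)
        for e in graph.in_edges[i]:
            r = graph.nodes[e.u]
            for pos, val in _block_contributions(
                e.alignment, len(r.tokens), r.confidence, r.alc, to_a_side=False
            ):
                contribs[i][pos].append(val)
    for i, node in enumerate(graph.nodes):
        node.acc_confidence = [
            min(1.0, c + (sum(vals) / len(vals) if vals else 0.0))
            for c, vals in zip(node.confidence, contribs[i])
        ]
    # invalidate assembly caches derived from accumulated confidence
    for k in [k for k in graph.__dict__ if k.startswith("_assembly")]:
        del graph.__dict__[k]
    return graph


class MotifTerminusClassifier:
    """Default terminus classifier from consensus terminal motifs.

    START classes compare the peptide's N-terminal residues against each
    motif, END classes its C-terminal residues; the best identity fraction
    wins if it reaches ``score_floor``, else OTHER.  Comparison is done in
    Leu-space (I folded into L).  Profiles ship as a plain-text fixture and
    can be overridden with any ``class<TAB>motif`` file.
    """

    def __init__(self, profiles=None, score_floor: float = 0.75, min_len: int = 5):
        if profiles is None:
            profiles = _load_default_profiles()
        self.profiles = [(cls, motif.replace("I", "L")) for cls, motif in profiles]
        self.score_floor = score_floor
        self.min_len = min_len

    def __call__(self, peptide) -> str:
        seq = peptide.sequence if hasattr(peptide, "sequence") else str(peptide)
        seq = "".join(ch for ch in seq if ch.isalpha()).replace("I", "L")
        if len(seq) < self.min_len:
            return "OTHER"
        best_cls, best_score = "OTHER", -1.0
        for cls, motif in self.profiles:
            n = min(len(motif), len(seq))
            if n < self.min_len:
                continue
            if cls.endswith("START"):
                matches = sum(a == b for a, b in zip(seq[:n], motif[:n]))
            else:
                matches = sum(a == b for a, b in zip(seq[-n:], motif[-n:]))
            score = matches / n
            if score > best_score:
                best_cls, best_score = cls, score
        return best_cls if best_score >= self.score_floor else "OTHER"


def _load_default_profiles():
    profiles = []
    text = (
        resources.files("pabseq").joinpath("data/terminus_motifs.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, motif = line.split("\t")
        profiles.append((cls, motif))
    return profiles


@dataclass
class TerminusSets:
    """Start/end node sets per subunit type; the seven classes partition nodes."""

    by_class: Dict[str, Set[int]]

    def starts(self, subunit_type: str) -> Set[int]:
        return self.by_class.get(f"{subunit_type}-START", set())

    def ends(self, subunit_type: str) -> Set[int]:
        return self.by_class.get(f"{subunit_type}-END", set())


def build_terminus_sets(
    graph: OverlapGraph,
    classifier: Optional[Callable] = None,
) -> TerminusSets:
    """Classify every graph node into one of the seven terminus classes."""
    if classifier is None:
        classifier = MotifTerminusClassifier()
    by_class: Dict[str, Set[int]] = {c: set() for c in TERMINUS_CLASSES}
    for i, node in enumerate(graph.nodes):
        by_class[classifier(node)].add(i)
    return TerminusSets(by_class)
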