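"""Independent exhaustive oracle for the assembly DP, used by tests.

Enumerates every path through the overlap graph from a seed set by DFS,
recomputes s(p) = T + (NA - NU) from scratch on the realized string, and
reports the best terminal score.  Entirely separate from the incremental
bookkeeping inside the DP.
"""

import random

from pabseq import bottomup, chem, middledown

WATER = chem.DEFAULT_TABLE.water_mono
AVERAGINE = chem.DEFAULT_TABLE.averagine_residue_mass


def make_reads(truth, rng, min_len=8, max_len=14, min_olap=4, max_olap=7, conf=None):
    """Overlapping tiling reads of a truth string."""
    reads = []
    start = 0
    while True:
        end = min(start + rng.randint(min_len, max_len), len(truth))
        if len(truth) - end < min_len and end < len(truth):
            end = len(truth)
        seq = truth[start:end]
        c = tuple(conf if conf is not None else [0.9] * len(seq))[: len(seq)]
        c = tuple(c) + (0.9,) * (len(seq) - len(c))
        reads.append(
            bottomup.DeNovoPeptide(sequence=seq, confidence=c, alc=0.9)
        )
        if end == len(truth):
            return reads
        start = end - rng.randint(min_olap, max_olap)


def realize_paths(graph, seeds, reverse=False):
    """All simple realizations (tokens, flags, chain) by DFS over edges."""
    out = []

    def rec(tokens, flags, chain, node, depth):
        out.append((tokens, flags, chain))
        if depth > 15:
            return
        edges = graph.out_edges[node] if not reverse else graph.in_edges[node]
        for e in edges:
            if not reverse:
                k = e.alignment.len_b
                other = graph.nodes[e.v]
                ext = other.tokens[k:]
                ext_flags = bytes(
                    1 if c < 0.5 else 0 for c in other.acc_confidence[k:]
                )
                if not ext:
                    continue
                rec(tokens + ext, flags + ext_flags, chain + (e.v,), e.v, depth + 1)
            else:
                off = e.alignment.offset
                other = graph.nodes[e.u]
                ext = other.tokens[:off]
                ext_flags = bytes(
                    1 if c < 0.5 else 0 for c in other.acc_confidence[:off]
                )
                if not ext:
                    continue
                rec(ext + tokens, ext_flags + flags, (e.u,) + chain, e.u, depth + 1)

    for s in seeds:
        node = graph.nodes[s]
        flags = bytes(1 if c < 0.5 else 0 for c in node.acc_confidence)
        rec(node.tokens, flags, (s,), s, 0)
    return out


def score_from_scratch(tokens, flags, observed, tol_ppm, direction="forward"):
    """s(p) recomputed on the realized string with the canonical matcher."""
    masses = chem.token_masses(tokens)
    total = sum(masses)
    if direction == "forward":
        sites = []
        acc = 0.0
        for m in masses[:-1]:
            acc += m
            sites.append(acc)
    else:
        sites = []
        acc = 0.0
        for m in reversed(masses[1:]):
            acc += m
            sites.append(acc)
    T = middledown.count_matches(sites, sorted(observed), tol_ppm)
    NU = sum(flags)
    return T + total / AVERAGINE - NU, T


def best_terminal_score(
    graph, seeds, terminals, observed, subunit_mass,
    mass_tol=4.0, tol_ppm=50.0, end_penalty=5.0, reverse=False,
):
    """Maximum adjusted s(p) over every exhaustively enumerated path."""
    best = None
    for tokens, flags, chain in realize_paths(graph, seeds, reverse):
        mass = sum(chem.token_masses(tokens)) + WATER
        if abs(mass - subunit_mass) > mass_tol:
            continue
        score, _ = score_from_scratch(
            tokens, flags, observed, tol_ppm,
            "forward" if not reverse else "reverse",
        )
        endpoint = chain[-1] if not reverse else chain[0]
        if endpoint not in terminals:
            score -= end_penalty
        if best is None or score > best:
            best = score
    return best
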