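"""Discretized-mass dynamic-programming assembly of one antibody subunit.

A subunit sequence is assembled from the peptide overlap graph three ways —
once per hypothesized type (LC, Fd, Fc/2), each with its own start/end
peptide sets — and the attempt with the most middle-down fragment matches
wins.  One attempt runs:

* a forward pass: start peptides seed a DP table indexed by discretized
  path mass (default width 0.1 Da, so 111.2 Da -> index 1112); each index
  holds a bounded priority queue (capacity 10) of partial paths ranked by

      s(p) = T + (NA - NU)

  where ``T`` counts matched middle-down prefix residue masses (PRMs),
  ``NA = path residue mass / averagine residue mass`` is the expected
  residue count for that mass, and ``NU`` counts residues whose accumulated
  bottom-up confidence is below threshold;
* a reverse pass, seeded by end peptides and extending leftward against the
  suffix residue mass (SRM) list;
* a merge: a forward and a reverse full-mass candidate are spliced at a
  shared peptide, and merged candidates are ranked by their total
  middle-down matches (c-side plus z-side, recomputed on the merged
  sequence).

Paths whose total mass misses the intact subunit mass by more than 4 Da are
never terminal; full-mass paths ending outside the predefined end-peptide
set take a score penalty.
"""

from __future__ import annotations

import bisect
import heapq
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import chem, middledown
from .bottomup import OverlapGraph, TerminusSets, SUBUNIT_TYPES

__all__ = [
    "AssemblyError",
    "NoStartPeptidesError",
    "NoMergeError",
    "AssemblyPath",
    "DPTable",
    "TypeAttempt",
    "SubunitReport",
    "discretize",
    "forward_pass",
    "reverse_pass",
    "merge_directions",
    "apply_end_penalty",
    "sequence_subunit",
]

WATER = chem.DEFAULT_TABLE.water_mono
AVERAGINE = chem.DEFAULT_TABLE.averagine_residue_mass


class AssemblyError(RuntimeError):
    pass


class NoStartPeptidesError(AssemblyError):
    """The attempted subunit type has no labeled seed peptides."""


class NoMergeError(AssemblyError):
    """Forward and reverse candidates share no junction peptide."""


def discretize(mass: float, width: float = 0.1) -> int:
    """Nearest-integer index of ``mass / width``."""
    if mass < 0:
        raise ValueError(f"mass must be non-negative, got {mass}")
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    return round(mass / width)


def tokens_to_str(tokens) -> str:
    parts = []
    for r, d in tokens:
        parts.append(r if d == 0.0 else f"{r}({d:+.5f})")
    return "".join(parts)


class _Path:
    """A partial assembly path (immutable once created)."""

    __slots__ = (
        "mass", "T", "NU", "tokens", "flags", "chain", "end_node",
        "prev_hi", "alive", "score", "key",
    )

    def __init__(self, mass, T, NU, tokens, flags, chain, end_node, prev_hi):
        self.mass = mass        # residue mass sum, no water
        self.T = T
        self.NU = NU
        self.tokens = tokens    # realized residue tokens
        self.flags = flags      # bytes: 1 = low-confidence residue
        self.chain = chain      # ((node_id, boundary), ...) see pass docs
        self.end_node = end_node
        self.prev_hi = prev_hi  # upper edge of last counted match window
        self.alive = True
        self.score = T + mass / AVERAGINE - NU
        # queue order: score desc, T desc, fewer peptides, lexicographic
        self.key = (-self.score, -T, len(chain), tokens)

    def rank_key(self):
        return self.key


@dataclass
class AssemblyPath:
    """A finished candidate: realized sequence plus its score bookkeeping."""

    sequence: str
    tokens: Tuple
    mass: float                 # total neutral mass (residues + water)
    T: int
    NA: float
    NU: int
    score: float                # s(p) = T + (NA - NU), after any end penalty
    penalized: bool
    chain: Tuple
    flags: bytes = b""
    T_forward: int = 0
    T_reverse: int = 0


@dataclass
class DPTable:
    width: float
    capacity: int
    queues: Dict[int, List] = field(default_factory=dict)

    def push(self, path: "_Path") -> bool:
        idx = round(path.mass / self.width)
        q = self.queues.get(idx)
        if q is None:
            self.queues[idx] = [path]
            return True
        if len(q) >= self.capacity:
            worst = q[0]
            for p in q:
                if p.key > worst.key:
                    worst = p
            if path.key >= worst.key:
                path.alive = False
                return False
            worst.alive = False
            q.remove(worst)
        q.append(path)
        return True


def _count_new(sites, observed, prev_hi):
    """Count observed masses in the union of new site windows.

    ``sites`` must be increasing and all above any previously counted site;
    ``prev_hi`` is the upper bound of the last counted window so that an
    observed mass is never counted twice.  Returns (count, new_prev_hi).
    """
    count = 0
    for m, tol in sites:
        lo = max(m - tol, prev_hi)
        hi = m + tol
        if hi > lo:
            count += bisect.bisect_right(observed, hi) - bisect.bisect_right(observed, lo)
            prev_hi = hi
    return count, prev_hi


def _node_data(graph: OverlapGraph, low_conf_threshold: float, table):
    key = (low_conf_threshold, id(table))
    cached = graph.__dict__.get("_assembly_node_data")
    if cached is not None and cached[0] == key:
        return cached[1]
    data = []
    for node in graph.nodes:
        masses = chem.token_masses(node.tokens, table)
        cums = []
        acc = 0.0
        for m in masses:
            acc += m
            cums.append(acc)
        flags = bytes(
            1 if c < low_conf_threshold else 0 for c in node.acc_confidence
        )
        data.append({"masses": masses, "cums": cums, "flags": flags, "total": acc})
    graph.__dict__["_assembly_node_data"] = (key, data)
    return data


def _node_masses(graph: OverlapGraph, table):
    cached = graph.__dict__.get("_assembly_masses")
    if cached is not None:
        return cached
    data = []
    for node in graph.nodes:
        cums = []
        acc = 0.0
        for m in chem.token_masses(node.tokens, table):
            acc += m
            cums.append(acc)
        data.append((cums, acc))
    graph.__dict__["_assembly_masses"] = data
    return data


# Reachability exploration bounds: coincidental short overlaps (the minimum
# three mass blocks can be a mere 3-residue composition match) compound
# multiplicatively in large graphs, so the unscored reachability pass closes
# exhaustively over *strong* edges (overlap >= _STRONG_MIN residues, where
# genuine read overlaps live) and admits weak-edge deviations in bounded
# tiers under a global state budget.
_STRONG_MIN = 5
# Weak tiers are off by default: a weak-edge deviation into a foreign
# lineage drags that lineage's whole strong closure along, exploding the
# state set, while the scored DP can still traverse weak edges *within*
# marked registers (error variants overlap their neighbors strongly).
_P1_MAX_WEAK_TIERS = 0
_P1_STATE_BUDGET = 150_000
# Coincidental back-edges form loops that pump path mass indefinitely,
# spawning a register at every index.  Reachability therefore refuses to
# extend a state into a node already visited on its (first-arrival) path —
# a peptide read maps to one position, so node reuse is never meaningful —
# and a wide per-node register cap remains as a safety net.
_P1_NODE_REGISTERS = 24


def _phase1_edges(graph: OverlapGraph, reverse: bool, table):
    """Per-node [(next node, appended mass, strong)] for reachability only."""
    key = f"_assembly_p1edges_{'r' if reverse else 'f'}"
    cached = graph.__dict__.get(key)
    if cached is not None:
        return cached
    nm = _node_masses(graph, table)
    out = [[] for _ in graph.nodes]
    for i in range(len(graph.nodes)):
        edges = graph.out_edges[i] if not reverse else graph.in_edges[i]
        for e in edges:
            # strong: a long overlap, or an exact sequence overlap of >= 4
            # residues (all single-residue identity blocks) — coincidental
            # exact 4-mers are far rarer than composition matches
            min_len = min(e.alignment.len_a, e.alignment.len_b)
            strong = min_len >= _STRONG_MIN or (
                min_len >= 4
                and all(len(b.a) == 1 and b.a == b.b for b in e.alignment.blocks)
            )
            if not reverse:
                cums, total = nm[e.v]
                ext = total - cums[e.alignment.len_b - 1]
                nxt = e.v
            else:
                cums, _ = nm[e.u]
                off = e.alignment.offset
                if off == 0:
                    continue
                ext = cums[off - 1]
                nxt = e.u
            if ext > 0:
                out[i].append((nxt, ext, strong))
    graph.__dict__[key] = out
    return out


def _reachable_states(graph, seeds, reverse, limit, width, table):
    """(node, mass index) states reachable from the seeds up to ``limit``.

    Exhaustive over strong edges; weak edges explored in at most
    ``_P1_MAX_WEAK_TIERS`` deviation tiers under a global state budget.
    Returns (key -> state id, masses, predecessor lists).
    """
    cache_key = ("p1", reverse, frozenset(seeds), width)
    cached = graph.__dict__.get("_assembly_reach", {}).get(cache_key)
    if cached is not None and cached[0] >= limit:
        return cached[1]
    nm = _node_masses(graph, table)
    p1 = _phase1_edges(graph, reverse, table)
    ids: Dict[Tuple[int, int], int] = {}
    masses: List[float] = []
    nodes_of: List[int] = []
    preds: List[List[int]] = []
    visited: List[int] = []          # bitmask of nodes on the first-arrival path
    weak_done: List[bool] = []
    node_registers: Dict[int, int] = {}
    heap: List[Tuple[float, int]] = []

    def admit(node, mass, mask):
        k = (node, round(mass / width))
        sid = ids.get(k)
        if sid is None:
            if (
                len(masses) >= _P1_STATE_BUDGET
                or node_registers.get(node, 0) >= _P1_NODE_REGISTERS
            ):
                return None
            sid = len(masses)
            ids[k] = sid
            masses.append(mass)
            nodes_of.append(node)
            preds.append([])
            visited.append(mask)
            weak_done.append(False)
            node_registers[node] = node_registers.get(node, 0) + 1
            heapq.heappush(heap, (mass, sid))
        return sid

    for s in seeds:
        total = nm[s][1]
        if total <= limit:
            admit(s, total, 1 << s)

    def expand(sid, mass, want_strong):
        vmask = visited[sid]
        for nxt, ext, strong in p1[nodes_of[sid]]:
            if strong is not want_strong:
                continue
            if (vmask >> nxt) & 1:
                continue  # node reuse: a read maps to one position
            new_mass = mass + ext
            if new_mass > limit:
                continue
            bit = 1 << nxt
            tid = admit(nxt, new_mass, vmask | bit)
            if tid is not None:
                preds[tid].append(sid)

    for _tier in range(_P1_MAX_WEAK_TIERS + 1):
        # strong closure in ascending mass order
        while heap:
            mass, sid = heapq.heappop(heap)
            expand(sid, mass, True)
        if _tier == _P1_MAX_WEAK_TIERS or len(masses) >= _P1_STATE_BUDGET:
            break
        # one tier of weak-edge deviations
        for sid in range(len(masses)):
            if weak_done[sid]:
                continue
            weak_done[sid] = True
            expand(sid, masses[sid], False)

    data = (ids, masses, preds)
    graph.__dict__.setdefault("_assembly_reach", {})[cache_key] = (limit, data)
    return data


def _marked_states(graph, seeds, reverse, target_res, mass_tol, width, table):
    """States lying on some path that terminates within the mass window.

    Back-propagates from terminal states over the reachability DAG; the
    scored DP only ever extends into marked states.  Removing states that
    cannot terminate never changes the terminal top-1 (it only frees queue
    slots), so the bounded-queue contract is preserved.
    """
    ids, masses, preds = _reachable_states(
        graph, seeds, reverse, target_res + mass_tol, width, table
    )
    slack = 0.3  # representative-mass drift inside a shared index bin
    frontier = [
        sid for sid, m in enumerate(masses) if abs(m - target_res) <= mass_tol + slack
    ]
    marked_ids = set(frontier)
    while frontier:
        sid = frontier.pop()
        for p in preds[sid]:
            if p not in marked_ids:
                marked_ids.add(p)
                frontier.append(p)
    return {k for k, sid in ids.items() if sid in marked_ids}


def _run_pass(
    graph: OverlapGraph,
    seeds: Set[int],
    terminals: Set[int],
    observed: Sequence[float],
    subunit_mass: float,
    *,
    reverse: bool,
    width: float,
    capacity: int,
    mass_tol: float,
    tol_ppm: float,
    low_conf_threshold: float,
    end_penalty: float,
    top_k: int,
    table,
    beam_margin: Optional[float],
    beam_window: float,
) -> List[AssemblyPath]:
    if not seeds:
        raise NoStartPeptidesError(
            f"no {'end' if reverse else 'start'} peptides for this subunit type"
        )
    nd = _node_data(graph, low_conf_threshold, table)
    target_res = subunit_mass - WATER
    ppm = tol_ppm * 1e-6

    # Pre-compute per-edge extension payloads.
    # forward edge u->v: appended tokens v[len_b:], new sites start at old mass.
    # reverse edge u->v (v is current head): prepended tokens u[:offset],
    #   new suffix sites start at old suffix mass.
    ext_cache: Dict[Tuple[int, int, int], tuple] = graph.__dict__.setdefault(
        f"_assembly_ext_{'r' if reverse else 'f'}_{low_conf_threshold}", {}
    )

    def edge_ext(e):
        key = (e.u, e.v, e.alignment.offset)
        hit = ext_cache.get(key)
        if hit is not None:
            return hit
        if not reverse:
            node = graph.nodes[e.v]
            k = e.alignment.len_b
            toks = node.tokens[k:]
            masses = nd[e.v]["masses"][k:]
            flags = nd[e.v]["flags"][k:]
        else:
            node = graph.nodes[e.u]
            k = e.alignment.offset
            toks = node.tokens[:k]
            masses = list(reversed(nd[e.u]["masses"][:k]))
            flags = nd[e.u]["flags"][:k]
        cums = []
        acc = 0.0
        for m in masses:
            acc += m
            cums.append(acc)
        # site offsets created by the extension: the junction cut (0.0) plus
        # each interior cut of the appended run
        site_offsets = (0.0,) + tuple(cums[:-1])
        hit = (toks, site_offsets, sum(flags), flags, acc)
        ext_cache[key] = hit
        return hit

    marked = _marked_states(
        graph, seeds, reverse, target_res, mass_tol, width, table
    )
    dp = DPTable(width, capacity)
    heap: List[Tuple[float, int, _Path]] = []
    counter = 0
    candidates: List[_Path] = []
    window_best: Dict[int, float] = {}

    def push(path):
        nonlocal counter
        if beam_margin is not None:
            w = int(path.mass // beam_window)
            best = window_best.get(w)
            if best is not None and path.score < best - beam_margin:
                return
            if best is None or path.score > best:
                window_best[w] = path.score
        if dp.push(path):
            heapq.heappush(heap, (path.mass, counter, path))
            counter += 1

    for s in sorted(seeds):
        total = nd[s]["total"]
        if total > target_res + mass_tol:
            continue
        si = round(total / width)
        if (s, si) not in marked and (s, si - 1) not in marked and (s, si + 1) not in marked:
            continue
        if not reverse:
            cums = nd[s]["cums"]
            toks = graph.nodes[s].tokens
            flags = nd[s]["flags"]
        else:
            masses = list(reversed(nd[s]["masses"]))
            cums = []
            acc = 0.0
            for m in masses:
                acc += m
                cums.append(acc)
            toks = graph.nodes[s].tokens
            flags = nd[s]["flags"]
        sites = [(m, m * ppm) for m in cums[:-1]]
        T, prev_hi = _count_new(sites, observed, -1.0)
        path = _Path(
            mass=total,
            T=T,
            NU=sum(flags),
            tokens=toks,
            flags=flags,
            chain=((s, len(toks) if not reverse else 0),),
            end_node=s,
            prev_hi=prev_hi,
        )
        push(path)

    # dominance: paths sharing (end node, mass index) have identical
    # futures — extending more than the best is pure duplication, and the
    # score difference is a constant offset, so top-1 exactness holds
    extended: Dict[Tuple[int, int], tuple] = {}

    while heap:
        _, _, path = heapq.heappop(heap)
        if not path.alive:
            continue
        if abs(path.mass + WATER - subunit_mass) <= mass_tol:
            candidates.append(path)
        state = (path.end_node, discretize(path.mass, width))
        prev = extended.get(state)
        if prev is not None and prev <= path.key:
            continue
        extended[state] = path.key
        edges = (
            graph.out_edges[path.end_node]
            if not reverse
            else graph.in_edges[path.end_node]
        )
        pm = path.mass
        base_hi = path.prev_hi
        br = bisect.bisect_right
        for e in edges:
            toks, site_offsets, n_low, flags, ext_total = edge_ext(e)
            if not toks:
                continue
            new_mass = pm + ext_total
            if new_mass > target_res + mass_tol:
                continue
            nxt_node = e.v if not reverse else e.u
            ni = round(new_mass / width)
            if (
                (nxt_node, ni) not in marked
                and (nxt_node, ni - 1) not in marked
                and (nxt_node, ni + 1) not in marked
            ):
                continue
            dT = 0
            prev_hi = base_hi
            for c in site_offsets:
                m = pm + c
                tol = m * ppm
                lo = m - tol
                if lo < prev_hi:
                    lo = prev_hi
                hi = m + tol
                if hi > lo:
                    dT += br(observed, hi) - br(observed, lo)
                    prev_hi = hi
            if not reverse:
                new_tokens = path.tokens + toks
                new_flags = path.flags + flags
                nxt = e.v
                boundary = len(new_tokens)
                chain = path.chain + ((nxt, boundary),)
            else:
                new_tokens = toks + path.tokens
                new_flags = flags + path.flags
                nxt = e.u
                # boundary: length of realized strictly after this node's span
                boundary = len(path.tokens) - e.alignment.len_b
                chain = path.chain + ((nxt, boundary),)
            push(
                _Path(
                    mass=new_mass,
                    T=path.T + dT,
                    NU=path.NU + n_low,
                    tokens=new_tokens,
                    flags=new_flags,
                    chain=chain,
                    end_node=nxt,
                    prev_hi=prev_hi,
                )
            )

    out = []
    for p in candidates:
        penalized = p.end_node not in terminals
        score = p.score - (end_penalty if penalized else 0.0)
        out.append(
            AssemblyPath(
                sequence=tokens_to_str(p.tokens),
                tokens=p.tokens,
                mass=p.mass + WATER,
                T=p.T,
                NA=p.mass / AVERAGINE,
                NU=p.NU,
                score=score,
                penalized=penalized,
                chain=p.chain,
                flags=p.flags,
            )
        )
    out.sort(key=lambda a: (-a.score, -a.T, len(a.chain), a.tokens))
    # deduplicate identical realized sequences
    seen = set()
    uniq = []
    for a in out:
        if a.tokens not in seen:
            seen.add(a.tokens)
            uniq.append(a)
    return uniq[:top_k]


def forward_pass(
    graph, starts, ends, prm_list, subunit_mass,
    width=0.1, capacity=10, mass_tol=4.0, tol_ppm=50.0,
    low_conf_threshold=0.5, end_penalty=5.0, top_k=10,
    table=chem.DEFAULT_TABLE, beam_margin=30.0, beam_window=50.0,
):
    """Left-to-right DP against the PRM list; seeds are start peptides.

    In the returned paths ``chain`` holds ``(node, end position)`` pairs in
    realized-residue coordinates.  ``beam_margin`` additionally drops paths
    scoring far below the best path of similar mass (``None`` disables,
    leaving the pure bounded-queue DP).
    """
    return _run_pass(
        graph, set(starts), set(ends), list(prm_list), subunit_mass,
        reverse=False, width=width, capacity=capacity, mass_tol=mass_tol,
        tol_ppm=tol_ppm, low_conf_threshold=low_conf_threshold,
        end_penalty=end_penalty, top_k=top_k, table=table,
        beam_margin=beam_margin, beam_window=beam_window,
    )


def reverse_pass(
    graph, starts, ends, srm_list, subunit_mass,
    width=0.1, capacity=10, mass_tol=4.0, tol_ppm=50.0,
    low_conf_threshold=0.5, end_penalty=5.0, top_k=10,
    table=chem.DEFAULT_TABLE, beam_margin=30.0, beam_window=50.0,
):
    """Right-to-left DP against the SRM list; seeds are end peptides.

    ``chain`` holds ``(node, residues-after-span)`` pairs: the number of
    realized residues strictly to the right of the node's span at the time
    it was prepended (0 for the seed).
    """
    return _run_pass(
        graph, set(ends), set(starts), list(srm_list), subunit_mass,
        reverse=True, width=width, capacity=capacity, mass_tol=mass_tol,
        tol_ppm=tol_ppm, low_conf_threshold=low_conf_threshold,
        end_penalty=end_penalty, top_k=top_k, table=table,
        beam_margin=beam_margin, beam_window=beam_window,
    )


def apply_end_penalty(path: AssemblyPath, ends: Set[int], penalty: float = 5.0) -> float:
    """Score after the end-peptide penalty (already folded in by the passes)."""
    last = path.chain[-1][0]
    base = path.T + (path.NA - path.NU)
    return base if last in ends else base - penalty


def merge_directions(
    forward_cands: List[AssemblyPath],
    reverse_cands: List[AssemblyPath],
    subunit_mass: float,
    fms: middledown.FragmentMassSet,
    mass_tol: float = 4.0,
    top_k: int = 10,
    junctions_per_pair: int = 3,
    table=chem.DEFAULT_TABLE,
) -> List[AssemblyPath]:
    """Splice forward and reverse candidates at a shared peptide.

    The merged sequence takes the forward realization up to the end of the
    shared peptide and the reverse realization after it; it must match the
    subunit mass within ``mass_tol``.  Candidates are ranked by total
    middle-down matches (c-side + z-side recomputed on the merged
    sequence), ties by NA - NU, then lexicographically.
    """
    if not forward_cands or not reverse_cands:
        raise NoMergeError("both directions need at least one candidate")
    results = {}
    target_res = subunit_mass - WATER
    agree_w = 4  # residues of forward/reverse agreement flanking the junction
    for f in forward_cands:
        f_pre = [0.0]
        for m in chem.token_masses(f.tokens, table):
            f_pre.append(f_pre[-1] + m)
        for r in reverse_cands:
            r_suf = [0.0]
            for m in reversed(chem.token_masses(r.tokens, table)):
                r_suf.append(r_suf[-1] + m)
            # candidate junctions: forward prefix + reverse suffix matching the
            # subunit mass, with the two realizations agreeing around the
            # joint (so the reverse path's covering peptide spans the site)
            junctions = []
            nr = len(r.tokens)
            for jf in range(agree_w, len(f.tokens) - 1):
                needed = target_res - f_pre[jf]
                jr = bisect.bisect_left(r_suf, needed - mass_tol)
                while jr < len(r_suf) and r_suf[jr] <= needed + mass_tol:
                    pos = nr - jr  # junction position in r.tokens
                    if (
                        agree_w <= pos <= nr - 1
                        and f.tokens[jf - agree_w : jf] == r.tokens[pos - agree_w : pos]
                        and f.tokens[jf : jf + 2] == r.tokens[pos : pos + 2]
                    ):
                        junctions.append((jf, jr))
                    jr += 1
            junctions.sort(key=lambda j: abs(j[0] / max(len(f.tokens), 1) - 0.5))
            for jf, jr in junctions[:junctions_per_pair]:
                left = f.tokens[:jf]
                right = r.tokens[len(r.tokens) - jr :]
                merged = left + right
                if merged in results:
                    continue
                mass = sum(chem.token_masses(merged, table))
                if abs(mass - target_res) > mass_tol:
                    continue
                cums = []
                acc = 0.0
                for m in chem.token_masses(merged, table):
                    acc += m
                    cums.append(acc)
                t_c = middledown.count_matches(cums[:-1], fms.prm_list, fms.tol_ppm)
                suffix = sorted(acc - c for c in cums[:-1])
                t_z = middledown.count_matches(suffix, fms.srm_list, fms.tol_ppm)
                flags = f.flags[:jf] + r.flags[len(r.tokens) - jr :]
                nu = sum(flags)
                results[merged] = AssemblyPath(
                    sequence=tokens_to_str(merged),
                    tokens=merged,
                    mass=mass + WATER,
                    T=t_c + t_z,
                    NA=mass / AVERAGINE,
                    NU=nu,
                    score=(t_c + t_z) + mass / AVERAGINE - nu,
                    penalized=False,
                    chain=f.chain + r.chain,
                    flags=flags,
                    T_forward=t_c,
                    T_reverse=t_z,
                )
    if not results:
        raise NoMergeError("no forward/reverse pair shares a junction peptide "
                           "within the mass tolerance")
    out = sorted(
        results.values(), key=lambda a: (-a.T, -(a.NA - a.NU), a.tokens)
    )
    return out[:top_k]


@dataclass
class TypeAttempt:
    subunit_type: str
    candidates: List[AssemblyPath] = field(default_factory=list)
    forward: List[AssemblyPath] = field(default_factory=list)
    reverse: List[AssemblyPath] = field(default_factory=list)
    error: Optional[str] = None

    @property
    def best(self) -> Optional[AssemblyPath]:
        return self.candidates[0] if self.candidates else None


@dataclass
class SubunitReport:
    subunit_mass: float
    attempts: Dict[str, TypeAttempt]
    winner_type: Optional[str]
    low_confidence: bool = False

    @property
    def best(self) -> Optional[AssemblyPath]:
        if self.winner_type is None:
            return None
        return self.attempts[self.winner_type].best


def sequence_subunit(
    graph: OverlapGraph,
    term_sets: TerminusSets,
    fms: middledown.FragmentMassSet,
    subunit_mass: float,
    **kwargs,
) -> SubunitReport:
    """Assemble one subunit three times (LC, Fd, Fc/2) and pick the winner.

    The winning type is the one whose best merged candidate has the most
    middle-down matches (ties: NA - NU, then type order).  When every
    fragment list is empty the ranking degenerates to NA - NU and the
    report is flagged low-confidence.
    """
    kwargs.setdefault("tol_ppm", fms.tol_ppm)
    attempts: Dict[str, TypeAttempt] = {}
    for stype in SUBUNIT_TYPES:
        attempt = TypeAttempt(stype)
        starts = term_sets.starts(stype)
        ends = term_sets.ends(stype)
        try:
            attempt.forward = forward_pass(
                graph, starts, ends, fms.prm_list, subunit_mass, **kwargs
            )
            if not attempt.forward:
                raise NoMergeError("no forward candidates reach the subunit mass")
            attempt.reverse = reverse_pass(
                graph, starts, ends, fms.srm_list, subunit_mass, **kwargs
            )
            attempt.candidates = merge_directions(
                forward_cands=attempt.forward,
                reverse_cands=attempt.reverse,
                subunit_mass=subunit_mass,
                fms=fms,
                mass_tol=kwargs.get("mass_tol", 4.0),
                top_k=kwargs.get("top_k", 10),
            )
        except AssemblyError as exc:
            attempt.error = str(exc)
        attempts[stype] = attempt

    winner = None
    winner_key = None
    for stype in SUBUNIT_TYPES:
        best = attempts[stype].best
        if best is None:
            continue
        key = (best.T, best.NA - best.NU)
        if winner_key is None or key > winner_key:
            winner, winner_key = stype, key
    low_conf = not fms.prm_list and not fms.srm_list
    return SubunitReport(subunit_mass, attempts, winner, low_confidence=low_conf)
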