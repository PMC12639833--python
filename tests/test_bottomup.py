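"""Peptide filtering, overlap graph, confidence accumulation, terminus labels."""

import random

import pytest

from pabseq import bottomup, simulate
from pabseq.bottomup import DeNovoPeptide, MotifTerminusClassifier


def pep(seq, conf=None, alc=None, **kw):
    conf = tuple(conf if conf is not None else [0.9] * len(seq))
    if alc is None:
        alc = sum(conf) / len(conf)
    return DeNovoPeptide(sequence=seq, confidence=conf, alc=alc, **kw)


# -------------------------------------------------------------------- filter

def test_alc_threshold_is_strict():
    lo = pep("PEPTIDES", alc=0.69)
    hi = pep("PEPTIDES", alc=0.71)
    kept = bottomup.filter_peptides([lo, hi], min_alc=0.7)
    assert kept == [hi]


def test_low_confidence_run_filter():
    ok = pep("PEPTIDESK", conf=[0.9, 0.4, 0.4, 0.4, 0.4, 0.9, 0.9, 0.9, 0.9], alc=0.8)
    bad = pep("PEPTIDESK", conf=[0.9, 0.4, 0.4, 0.4, 0.4, 0.4, 0.9, 0.9, 0.9], alc=0.8)
    kept = bottomup.filter_peptides([ok, bad], min_alc=0.7, max_low_conf_run=4)
    assert kept == [ok]


def test_perfect_confidence_kept():
    p = pep("PEPTIDE")
    assert bottomup.filter_peptides([p]) == [p]


def test_filter_matches_brute_force_oracle():
    rng = random.Random(9)
    peps = []
    for _ in range(200):
        n = rng.randint(6, 20)
        conf = [rng.random() for _ in range(n)]
        peps.append(pep("".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=n)), conf))

    def oracle(p):
        if p.alc <= 0.7:
            return False
        best = run = 0
        for c in p.confidence:
            run = run + 1 if c < 0.5 else 0
            best = max(best, run)
        return best <= 4

    got = bottomup.filter_peptides(peps)
    assert got == [p for p in peps if oracle(p)]


# ------------------------------------------------------------- overlap graph

def test_worked_example_edge():
    """SEQVENCE -> EGGECPEP via the 3-block isobaric overlap."""
    g = bottomup.build_overlap_graph([pep("SEQVENCE"), pep("EGGECPEP")])
    edges = [(e.u, e.v) for i in g.out_edges for e in g.out_edges[i]]
    assert (0, 1) in edges
    e = g.out_edges[0][0]
    assert e.alignment.block_count >= 3


def test_disjoint_sequences_share_no_edge():
    g = bottomup.build_overlap_graph([pep("DDDDDDDD"), pep("WWWWWWWW")])
    assert g.n_edges == 0


def test_duplicate_reads_collapse_to_one_node():
    g = bottomup.build_overlap_graph([pep("PEPTIDES"), pep("PEPTIDES")])
    assert len(g.nodes) == 1
    assert len(g.nodes[0].members) == 2


def test_tiling_reads_chain_the_truth_and_match_allpairs_oracle():
    """30 tiling reads of a 120-mer: truth reachable; edges equal all-pairs."""
    rng = random.Random(1)
    truth = "".join(rng.choices("ACDEFGHKMNPQRSTVWY", k=120))
    reads = []
    start = 0
    while start < len(truth) - 10:
        end = min(start + rng.randint(14, 20), len(truth))
        reads.append(pep(truth[start:end]))
        if end == len(truth):
            break
        start = end - rng.randint(5, 8)
    g = bottomup.build_overlap_graph(reads)
    # all-pairs oracle over unique sequences
    from pabseq.bottomup import _best_extension_alignment
    from pabseq import chem
    expected = set()
    for i, a in enumerate(g.nodes):
        for j, b in enumerate(g.nodes):
            if i != j and _best_extension_alignment(
                a.tokens, b.tokens, 3, chem.DEFAULT_TABLE
            ):
                expected.add((i, j))
    got = {(e.u, e.v) for i in g.out_edges for e in g.out_edges[i]}
    assert got == expected
    # consecutive tiling reads are chained
    order = {tuple(r.tokens): k for k, r in enumerate(reads)}
    node_order = sorted(range(len(g.nodes)), key=lambda i: order[g.nodes[i].tokens])
    for a, b in zip(node_order, node_order[1:]):
        assert (a, b) in got


# ---------------------------------------------------- confidence accumulation

def test_isolated_node_scores_unchanged():
    g = bottomup.build_overlap_graph([pep("DDDDDDDD")])
    bottomup.accumulate_confidence(g)
    assert g.nodes[0].acc_confidence == g.nodes[0].confidence


def test_overlap_boosts_poorly_fragmented_terminus():
    """A perfect right-extender lifts the weak C-terminal scores of P."""
    p = pep("GASPVTCLND", conf=[0.9] * 7 + [0.2, 0.2, 0.2])
    q = pep("CLNDQKEMHF", conf=[1.0] * 10)
    g = bottomup.build_overlap_graph([p, q])
    assert g.n_edges > 0
    before = list(g.nodes[0].confidence)
    bottomup.accumulate_confidence(g)
    after = g.nodes[0].acc_confidence
    assert after[7] > before[7] and after[8] > before[8]
    # hand computation: min(1, 0.2 + 1.0) = 1.0 for the overlapped tail
    assert after[7] == pytest.approx(1.0)


def test_accumulated_never_below_original():
    bundle = simulate.simulate_scenario(simulate.SimScenario(n_antibodies=1, seed=5))
    peps = bottomup.filter_peptides(bundle.peptides)[:150]
    g = bottomup.build_overlap_graph(peps)
    bottomup.accumulate_confidence(g)
    for node in g.nodes:
        for orig, acc in zip(node.confidence, node.acc_confidence):
            assert acc >= orig - 1e-12
            assert acc <= 1.0 + 1e-12


def test_symmetric_pair_updated_identically():
    p = pep("GASPVTCLND", conf=[0.5] * 10)
    q = pep("CLNDGASPVT", conf=[0.5] * 10)
    g = bottomup.build_overlap_graph([p, q])
    bottomup.accumulate_confidence(g)
    assert g.nodes[0].acc_confidence == g.nodes[1].acc_confidence


# ----------------------------------------------------------------- classifier

def test_classifier_on_simulator_labels():
    """Motif classifier reaches >= 95% on labeled terminal/middle reads."""
    bundle = simulate.simulate_scenario(simulate.SimScenario(n_antibodies=2, seed=8))
    clf = MotifTerminusClassifier()
    correct = sum(
        clf(p) == label for p, label in zip(bundle.peptides, bundle.peptide_labels)
    )
    assert correct / len(bundle.peptides) >= 0.95


def test_reversed_decoy_is_other():
    clf = MotifTerminusClassifier()
    assert clf(pep("PSQTLVLE")) == "OTHER"  # reversed LC-start motif
    assert clf(pep("GASNDQKW")) == "OTHER"


def test_short_peptide_is_other():
    clf = MotifTerminusClassifier()
    assert clf(pep("DIQM")) == "OTHER"


def test_terminus_sets_partition_nodes(bundle_one):
    peps = bottomup.filter_peptides(bundle_one.peptides)
    g = bottomup.build_overlap_graph(peps)
    ts = bottomup.build_terminus_sets(g)
    total = sum(len(v) for v in ts.by_class.values())
    assert total == len(g.nodes)
    all_ids = set()
    for v in ts.by_class.values():
        assert not (all_ids & v)
        all_ids |= v
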