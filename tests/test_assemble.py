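"""Discretized-mass DP assembly: passes, merging, scoring, oracle checks."""

import random

import pytest

import dp_oracle
from pabseq import assemble, bottomup, chem, middledown
from pabseq.assemble import AssemblyPath, discretize
from pabseq.middledown import C_ION_OFFSET, Z_ION_OFFSET, FragmentMassSet

WATER = chem.DEFAULT_TABLE.water_mono
ALPHABET = "ADEFGHKMNPQRSTVWY"


# ----------------------------------------------------------------- discretize

@pytest.mark.parametrize(
    "mass,width,index",
    [(111.2, 0.1, 1112), (0.0, 0.1, 0), (1234.567, 0.1, 12346)],
)
def test_discretize_examples(mass, width, index):
    assert discretize(mass, width) == index


def test_discretize_rejects_negative_mass():
    with pytest.raises(ValueError):
        discretize(-1.0)


# -------------------------------------------------------------- toy fixtures

def toy(seed=0, n=40, conf=None):
    rng = random.Random(seed)
    truth = "".join(rng.choices(ALPHABET, k=n))
    reads = dp_oracle.make_reads(truth, rng, conf=conf)
    graph = bottomup.build_overlap_graph(reads)
    order = {tuple(r.tokens): k for k, r in enumerate(reads)}
    nodes = sorted(range(len(graph.nodes)), key=lambda i: order[graph.nodes[i].tokens])
    starts, ends = {nodes[0]}, {nodes[-1]}
    return truth, graph, starts, ends


def full_prm(truth):
    toks = chem.parse_peptide(truth)
    return chem.prefix_masses(toks)[:-1]


def full_srm(truth):
    toks = chem.parse_peptide(truth)
    return chem.suffix_masses(toks)[:-1]


def test_forward_pass_recovers_truth_with_full_ladder():
    """5-ish tiling reads, complete noiseless PRMs: unique top path is truth."""
    truth, graph, starts, ends = toy(seed=2)
    mass = chem.peptide_mass(truth)
    cands = assemble.forward_pass(
        graph, starts, ends, full_prm(truth), mass, beam_margin=None
    )
    assert cands
    assert cands[0].sequence == truth
    assert cands[0].T == len(truth) - 1
    assert not cands[0].penalized


def test_no_candidates_when_target_unreachable():
    truth, graph, starts, ends = toy(seed=3)
    cands = assemble.forward_pass(
        graph, starts, ends, full_prm(truth), chem.peptide_mass(truth) + 500.0,
        beam_margin=None,
    )
    assert cands == []


def test_reverse_pass_mirrors_forward():
    truth, graph, starts, ends = toy(seed=4)
    mass = chem.peptide_mass(truth)
    cands = assemble.reverse_pass(
        graph, starts, ends, full_srm(truth), mass, beam_margin=None
    )
    assert cands and cands[0].sequence == truth
    assert cands[0].T == len(truth) - 1


def test_empty_srm_list_ranks_by_residue_count_minus_unconfident():
    truth, graph, starts, ends = toy(seed=5)
    mass = chem.peptide_mass(truth)
    cands = assemble.reverse_pass(graph, starts, ends, [], mass, beam_margin=None)
    assert cands
    assert cands[0].T == 0
    assert cands[0].score == pytest.approx(cands[0].NA - cands[0].NU)


def test_capacity_ten_at_least_as_good_as_capacity_one():
    """Wider queues never hurt on a branchy isobaric toy graph."""
    rng = random.Random(6)
    truth = "GASNVT" * 6 + "QKEMHF"
    reads = dp_oracle.make_reads(truth, rng)
    # isobaric variant reads (N -> GG) create branching
    variants = []
    for r in reads:
        if "N" in r.sequence[2:-2]:
            i = r.sequence.index("N", 2)
            variants.append(
                bottomup.DeNovoPeptide(
                    sequence=r.sequence[:i] + "GG" + r.sequence[i + 1:],
                    confidence=r.confidence[:i] + (0.3, 0.3) + r.confidence[i + 1:],
                    alc=0.8,
                )
            )
    allreads = reads + variants
    graph = bottomup.build_overlap_graph(allreads)
    order = {tuple(r.tokens): k for k, r in enumerate(reads)}
    nodes = [i for i in range(len(graph.nodes)) if graph.nodes[i].tokens in order]
    nodes.sort(key=lambda i: order[graph.nodes[i].tokens])
    starts, ends = {nodes[0]}, {nodes[-1]}
    mass = chem.peptide_mass(truth)
    top1 = assemble.forward_pass(
        graph, starts, ends, full_prm(truth), mass, capacity=1, beam_margin=None
    )
    top10 = assemble.forward_pass(
        graph, starts, ends, full_prm(truth), mass, capacity=10, beam_margin=None
    )
    assert top10 and top1
    assert top10[0].score >= top1[0].score - 1e-9


def test_end_penalty_applied_to_unlabeled_terminus():
    truth, graph, starts, ends = toy(seed=7)
    mass = chem.peptide_mass(truth)
    with_ends = assemble.forward_pass(
        graph, starts, ends, full_prm(truth), mass, beam_margin=None
    )
    without = assemble.forward_pass(
        graph, starts, set(), full_prm(truth), mass, beam_margin=None
    )
    assert with_ends[0].sequence == without[0].sequence
    assert without[0].penalized
    assert without[0].score == pytest.approx(with_ends[0].score - 5.0)


def test_apply_end_penalty_on_finished_path():
    truth, graph, starts, ends = toy(seed=8)
    mass = chem.peptide_mass(truth)
    cand = assemble.forward_pass(
        graph, starts, ends, full_prm(truth), mass, beam_margin=None
    )[0]
    base = assemble.apply_end_penalty(cand, ends)
    assert base == pytest.approx(cand.T + cand.NA - cand.NU)
    assert assemble.apply_end_penalty(cand, set()) == pytest.approx(base - 5.0)


# -------------------------------------------------------------------- merging

def make_fms(truth, tol=50.0):
    frags = [m + C_ION_OFFSET for m in full_prm(truth)] + [
        m + Z_ION_OFFSET for m in full_srm(truth)
    ]
    return FragmentMassSet(chem.peptide_mass(truth), frags, [1.0] * len(frags), tol_ppm=tol)


def test_merge_reconstructs_truth_rank_one():
    truth, graph, starts, ends = toy(seed=9, n=50)
    mass = chem.peptide_mass(truth)
    fms = make_fms(truth)
    fwd = assemble.forward_pass(graph, starts, ends, fms.prm_list, mass, beam_margin=None)
    rev = assemble.reverse_pass(graph, starts, ends, fms.srm_list, mass, beam_margin=None)
    merged = assemble.merge_directions(fwd, rev, mass, fms)
    assert merged[0].sequence == truth
    # every cleavage site matches on both the c and z side; the combined
    # list can add a few coincidental cross-series matches on top
    assert merged[0].T >= 2 * (len(truth) - 1)


def test_merge_rejects_mass_mismatch():
    truth, graph, starts, ends = toy(seed=10)
    mass = chem.peptide_mass(truth)
    fms = make_fms(truth)
    fwd = assemble.forward_pass(graph, starts, ends, fms.prm_list, mass, beam_margin=None)
    rev = assemble.reverse_pass(graph, starts, ends, fms.srm_list, mass, beam_margin=None)
    with pytest.raises(assemble.NoMergeError):
        assemble.merge_directions(fwd, rev, mass + 10.0, fms)


def test_merge_rejects_disagreeing_candidates():
    """No junction where forward and reverse realizations agree -> no merge."""
    a = chem.parse_peptide("GASPVTMNDQKEHFRW")
    b = chem.parse_peptide("WRFHEKQDNMTVPSAG")  # same composition, reversed
    mass = chem.peptide_mass("GASPVTMNDQKEHFRW")
    fms = FragmentMassSet(mass, [500.0], [1.0])
    f = AssemblyPath("f", a, mass, 0, 1.0, 0, 1.0, False, ((0, len(a)),), bytes(len(a)))
    r = AssemblyPath("r", b, mass, 0, 1.0, 0, 1.0, False, ((1, 0),), bytes(len(b)))
    with pytest.raises(assemble.NoMergeError):
        assemble.merge_directions([f], [r], mass, fms)


# ---------------------------------------------------------- score bookkeeping

def test_incremental_score_equals_from_scratch():
    """DP-maintained (T, NU, mass) equals recomputation on realized strings."""
    rng = random.Random(12)
    for trial in range(10):
        truth = "".join(rng.choices(ALPHABET, k=rng.randint(25, 45)))
        reads = dp_oracle.make_reads(truth, rng)
        graph = bottomup.build_overlap_graph(reads)
        order = {tuple(r.tokens): k for k, r in enumerate(reads)}
        nodes = sorted(
            range(len(graph.nodes)), key=lambda i: order[graph.nodes[i].tokens]
        )
        observed = [m for i, m in enumerate(full_prm(truth)) if i % 2 == 0]
        mass = chem.peptide_mass(truth)
        cands = assemble.forward_pass(
            graph, {nodes[0]}, {nodes[-1]}, observed, mass, beam_margin=None
        )
        for c in cands:
            score, T = dp_oracle.score_from_scratch(
                c.tokens, c.flags, observed, 50.0
            )
            assert c.T == T
            assert c.T + c.NA - c.NU == pytest.approx(score, abs=1e-9)


def test_dp_top1_matches_exhaustive_oracle_small():
    """Spot check of DP-vs-enumeration equality on small random graphs."""
    rng = random.Random(13)
    agreements = 0
    for trial in range(20):
        truth = "".join(rng.choices(ALPHABET, k=rng.randint(20, 40)))
        reads = dp_oracle.make_reads(truth, rng)
        if len(reads) > 12:
            continue
        graph = bottomup.build_overlap_graph(reads)
        order = {tuple(r.tokens): k for k, r in enumerate(reads)}
        nodes = sorted(
            range(len(graph.nodes)), key=lambda i: order[graph.nodes[i].tokens]
        )
        observed = sorted(
            m for m in full_prm(truth) if rng.random() < 0.7
        )
        mass = chem.peptide_mass(truth)
        starts, ends = {nodes[0]}, {nodes[-1]}
        cands = assemble.forward_pass(
            graph, starts, ends, observed, mass, capacity=64, beam_margin=None
        )
        best = dp_oracle.best_terminal_score(graph, starts, ends, observed, mass)
        if best is None:
            assert cands == []
        else:
            assert cands
            assert cands[0].score == pytest.approx(best, abs=1e-9)
        agreements += 1
    assert agreements >= 10


# ----------------------------------------------------------- sequence_subunit

def test_sequence_subunit_picks_type_with_most_matches(bundle_one):
    from pabseq import pipeline as pl

    inputs = pl.InputBundle.from_simulation(bundle_one)
    peps = bottomup.filter_peptides(inputs.peptides)
    graph = bottomup.build_overlap_graph(peps)
    bottomup.accumulate_confidence(graph)
    ts = bottomup.build_terminus_sets(graph)
    lc = next(c for c in bundle_one.chain_set.chains if c.subunit_type == "LC")
    subs = [m for m, _ in inputs.subunit]
    target = min(subs, key=lambda m: abs(m - lc.mono_mass))
    fs = middledown.aggregate_precursors(inputs.md_runs, subs)
    rep = assemble.sequence_subunit(graph, ts, fs[target], target)
    assert rep.winner_type == "LC"
    assert rep.best is not None
    assert rep.best.T > 0


def test_sequence_subunit_degenerate_no_fragments(bundle_one):
    from pabseq import pipeline as pl

    inputs = pl.InputBundle.from_simulation(bundle_one)
    peps = bottomup.filter_peptides(inputs.peptides)
    graph = bottomup.build_overlap_graph(peps)
    bottomup.accumulate_confidence(graph)
    ts = bottomup.build_terminus_sets(graph)
    lc = next(c for c in bundle_one.chain_set.chains if c.subunit_type == "LC")
    subs = [m for m, _ in inputs.subunit]
    target = min(subs, key=lambda m: abs(m - lc.mono_mass))
    rep = assemble.sequence_subunit(
        graph, ts, FragmentMassSet.empty(target), target
    )
    assert rep.low_confidence
    if rep.best is not None:
        assert rep.best.T == 0
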