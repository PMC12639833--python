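"""Feature-based intact deconvolution and inclusion-list generation."""

import math

import numpy as np
import pytest

from pabseq import intact, simulate
from pabseq.intact import CentroidScan, Feature, PROTON


def scan(rt, peaks):
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    return CentroidScan(rt, mz, inten)


# ----------------------------------------------------------------- merge_scans

def test_merge_identical_peaks_sums_intensity():
    scans = [scan(10.00, [(1000.0, 5.0)]), scan(10.05, [(1000.0, 7.0)])]
    merged = intact.merge_scans(scans, window=0.1)
    assert len(merged) == 1
    assert merged[0].intensity[0] == pytest.approx(12.0)


def test_distant_scans_stay_separate():
    scans = [scan(10.0, [(1000.0, 1.0)]), scan(10.5, [(1000.0, 1.0)])]
    assert len(intact.merge_scans(scans, window=0.1)) == 2


def test_merge_matches_grouping_oracle():
    """Merged peak count equals brute-force (window bin, m/z bin) grouping."""
    rng = np.random.default_rng(4)
    scans = []
    for k in range(50):
        rt = 10.0 + 0.01 * k
        mzs = np.sort(rng.choice(np.arange(900.0, 1100.0, 0.5), 20, replace=False))
        scans.append(CentroidScan(rt, mzs, rng.uniform(1, 10, 20)))
    window, tol = 0.1, 0.01
    merged = intact.merge_scans(scans, window=window, mz_tol=tol)
    # oracle: peaks grouped by (floor(rt/window), m/z chained within tol)
    n_oracle = 0
    from collections import defaultdict
    groups = defaultdict(list)
    for s in scans:
        for mz in s.mz:
            groups[math.floor(s.rt / window)].append(mz)
    for vals in groups.values():
        vals.sort()
        n_oracle += 1 + sum(1 for a, b in zip(vals, vals[1:]) if b - a > tol)
    assert sum(len(s.mz) for s in merged) == n_oracle


def test_merge_empty_input():
    assert intact.merge_scans([]) == []


# ------------------------------------------------------------ deconvolute_scan

def envelope(mass, charges, intensity=100.0):
    return sorted(
        ((mass + z * PROTON) / z, intensity) for z in charges
    )


def test_single_species_recovered_within_tolerance():
    truth = 23440.0
    s = scan(10.0, envelope(truth, range(20, 31)))
    out = intact.deconvolute_scan(s, charge_range=(10, 40))
    assert len(out) == 1
    mass = out[0][0]
    assert abs(mass - truth) / truth * 1e6 < 20


def test_single_isolated_peak_reports_nothing():
    s = scan(10.0, [(1173.0, 50.0)])
    assert intact.deconvolute_scan(s) == []


def test_two_coeluting_species_recovered_in_abundance_order():
    peaks = envelope(23440.0, range(20, 31), 100.0) + envelope(
        25380.0, range(20, 31), 60.0
    )
    peaks.sort()
    mz = [p[0] for p in peaks]
    inten = [p[1] for p in peaks]
    out = intact.deconvolute_scan(CentroidScan(10.0, np.array(mz), np.array(inten)))
    masses = [m for m, _, _ in out[:2]]
    assert min(abs(m - 23440.0) for m in masses) < 1.0
    assert min(abs(m - 25380.0) for m in masses) < 1.0
    assert abs(out[0][0] - 23440.0) < 1.0  # higher-abundance species first


# --------------------------------------------------------------- link_features

def _decon_series(mass, charges, scans_idx, rts):
    merged, per_scan = [], []
    for i, rt in zip(scans_idx, rts):
        peaks = envelope(mass, charges)
        merged.append(scan(rt, peaks))
        per_scan.append(
            [(mass, {z: ((mass + z * PROTON) / z, 10.0) for z in charges}, 10.0)]
        )
    return merged, per_scan


def test_continuous_species_reported_with_features_per_charge():
    charges = range(18, 26)
    merged, per_scan = _decon_series(23440.0, charges, range(10), np.arange(10) * 0.1)
    out = intact.link_features(merged, per_scan)
    assert len(out) == 1
    assert len(out[0].features) == 8


def test_single_scan_species_dropped():
    merged, per_scan = _decon_series(23440.0, range(18, 26), [0], [10.0])
    assert intact.link_features(merged, per_scan, min_consecutive_scans=3) == []


def test_nonconsecutive_charges_dropped():
    merged, per_scan = _decon_series(23440.0, [5, 9], range(10), np.arange(10) * 0.1)
    assert intact.link_features(merged, per_scan, min_consecutive_charges=3) == []


# ------------------------------------------------------------- inclusion list

def feat(mz, rt, z, inten):
    return Feature(mz - 0.5, mz + 0.5, rt - 0.1, rt + 0.1, z, inten, mz, rt)


def test_top_four_features_selected():
    p = intact.ProteoformMass(
        23440.0, "monoisotopic", 1.0,
        [feat(900 + 10 * k, 10.0 + k, 20 + k, 100 - k) for k in range(6)],
    )
    incl = intact.build_inclusion_list([p], per_mass=4)
    assert len(incl.entries) == 4
    assert [e.feature.intensity for e in incl.entries] == [100, 99, 98, 97]


def test_conflicting_feature_skipped_for_next_best():
    shared = feat(950.0, 10.0, 25, 90)
    p1 = intact.ProteoformMass(23440.0, "monoisotopic", 0.6, [feat(900, 10, 20, 100)])
    p2 = intact.ProteoformMass(
        25380.0, "monoisotopic", 0.4,
        [feat(900.3, 10.05, 21, 95), feat(1100, 12, 23, 50)],
    )
    incl = intact.build_inclusion_list([p1, p2], per_mass=4)
    # p2's first feature overlaps p1's in both m/z and RT; its second is taken
    mzs = [e.mz for e in incl.entries]
    assert 900 in mzs and 1100 in mzs and 900.3 not in mzs


def test_fewer_features_than_per_mass_no_padding():
    p = intact.ProteoformMass(
        23440.0, "monoisotopic", 1.0, [feat(900, 10, 20, 10), feat(1000, 11, 21, 9)]
    )
    assert len(intact.build_inclusion_list([p], per_mass=4).entries) == 2


def test_inclusion_list_never_overlaps_pairwise():
    rng = np.random.default_rng(0)
    feats = [
        feat(float(rng.uniform(900, 1100)), float(rng.uniform(9, 13)),
             int(rng.integers(18, 30)), float(rng.uniform(1, 100)))
        for _ in range(40)
    ]
    p = intact.ProteoformMass(23440.0, "monoisotopic", 1.0, feats)
    incl = intact.build_inclusion_list([p], per_mass=40)
    for i, a in enumerate(incl.entries):
        for b in incl.entries[i + 1:]:
            assert not a.feature.overlaps(b.feature)


# ----------------------------------------------------------------- round trip

def test_simulated_envelopes_round_trip():
    """Recovered masses within 2x the simulated ppm noise; order preserved."""
    species = [(23440.0, 0.5), (25380.0, 0.3), (23791.0, 0.2)]
    noise = 3.0
    scans = simulate.emit_scans(species, seed=7, ppm_noise=noise)
    out = intact.deconvolute(scans)
    assert len(out) >= 3
    recovered = []
    for truth, _ in species:
        best = min(out, key=lambda p: abs(p.mass - truth))
        assert abs(best.mass - truth) / truth * 1e6 <= 2 * noise
        recovered.append(best)
    abundances = [p.abundance for p in recovered]
    assert abundances == sorted(abundances, reverse=True)
    # relative abundances over the result sum to <= 1
    assert sum(p.abundance for p in out) <= 1.0 + 1e-9


def test_apex_to_monoisotopic_magnitude():
    # at 25 kDa the apex sits ~16 Da above the monoisotopic mass
    mono = intact.apex_to_monoisotopic(25000.0)
    assert 25000 - 20 < mono < 25000 - 12
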