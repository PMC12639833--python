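"""Feature-based intact mass deconvolution and inclusion-list generation.

Whole, reduced, and subunit samples are profiled by LC-MS1 only; species in
the 23-150 kDa range appear as multi-charge envelopes.  Deconvolution here
is a deterministic three-step procedure:

1. :func:`merge_scans` — a sliding retention-time window accumulates
   neighboring centroid spectra, merging peaks of (nearly) the same m/z.
2. :func:`deconvolute_scan` — greedy highest-intensity-first charge
   assignment: a neutral mass is reported only when supported by peaks at
   two or more distinct charges.
3. :func:`link_features` — masses that persist across consecutive merged
   scans are linked into proteoforms; each (charge, m/z window, RT window)
   becomes a *feature*, and proteoforms must be supported by a run of
   consecutive charges.

:func:`build_inclusion_list` then picks, per proteoform, the most intense
non-overlapping features as targets for the middle-down acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .chem import DEFAULT_TABLE

__all__ = [
    "CentroidScan",
    "Feature",
    "ProteoformMass",
    "InclusionEntry",
    "InclusionList",
    "merge_scans",
    "deconvolute_scan",
    "link_features",
    "build_inclusion_list",
    "deconvolute",
    "apex_to_monoisotopic",
]

PROTON = DEFAULT_TABLE.proton


@dataclass
class CentroidScan:
    rt: float                 # minutes
    mz: np.ndarray            # strictly increasing
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing within a scan")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class Feature:
    """m/z x RT window supporting one deconvoluted mass at one charge."""

    mz_lo: float
    mz_hi: float
    rt_lo: float
    rt_hi: float
    charge: int
    intensity: float
    apex_mz: float
    apex_rt: float

    def overlaps(self, other: "Feature") -> bool:
        """True when both the m/z and RT windows intersect."""
        mz_ok = self.mz_lo <= other.mz_hi and other.mz_lo <= self.mz_hi
        rt_ok = self.rt_lo <= other.rt_hi and other.rt_lo <= self.rt_hi
        return mz_ok and rt_ok


@dataclass
class ProteoformMass:
    mass: float
    mode: str                      # "monoisotopic" | "average"
    abundance: float               # relative, fraction of reported total
    features: List[Feature] = field(default_factory=list)
    intensity: float = 0.0


@dataclass
class InclusionEntry:
    mz: float
    rt: float
    rt_lo: float
    rt_hi: float
    charge: int
    parent_mass: float
    feature: Feature


@dataclass
class InclusionList:
    entries: List[InclusionEntry]
    per_mass: int


def merge_scans(scans, window: float = 0.1, mz_tol: float = 0.01):
    """Accumulate neighboring scans along RT, merging peaks of the same m/z.

    Scans are grouped into consecutive RT bins of ``window`` minutes; peaks
    within ``mz_tol`` of each other merge to an intensity-weighted mean m/z
    with summed intensity.  Output is sorted by RT.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not scans:
        return []
    scans = sorted(scans, key=lambda s: s.rt)
    groups = {}
    for s in scans:
        groups.setdefault(int(math.floor(s.rt / window)), []).append(s)
    merged = []
    for _, grp in sorted(groups.items()):
        mz = np.concatenate([s.mz for s in grp])
        inten = np.concatenate([s.intensity for s in grp])
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        # chain clustering: a gap > mz_tol starts a new merged peak
        breaks = np.nonzero(np.diff(mz) > mz_tol)[0] + 1
        idx = np.concatenate([[0], breaks, [len(mz)]])
        out_mz, out_int = [], []
        for a, b in zip(idx[:-1], idx[1:]):
            tot = inten[a:b].sum()
            out_mz.append(np.average(mz[a:b], weights=inten[a:b]) if tot > 0 else mz[a:b].mean())
            out_int.append(tot)
        rt = float(np.mean([s.rt for s in grp]))
        merged.append(CentroidScan(rt, np.array(out_mz), np.array(out_int)))
    return merged


def deconvolute_scan(scan: CentroidScan, charge_range=(10, 40), tol_ppm: float = 20.0):
    """Greedy charge assignment on one merged scan.

    Peaks are visited from most to least intense; for each, every charge in
    ``charge_range`` is tried and the one whose implied neutral mass is
    echoed by unassigned peaks at the most other charges wins.  A mass is
    reported only with support at >= 2 distinct charges.

    Returns a list of ``(mass, {charge: (mz, intensity)}, total_intensity)``
    sorted by total intensity, descending.
    """
    z_lo, z_hi = charge_range
    if z_hi < z_lo:
        raise ValueError("charge range is empty")
    mz = scan.mz
    inten = scan.intensity
    n = len(mz)
    assigned = np.zeros(n, dtype=bool)
    order = np.argsort(inten)[::-1]
    results = []
    for seed in order:
        if assigned[seed]:
            continue
        best = None
        for z in range(z_lo, z_hi + 1):
            mass = (mz[seed] - PROTON) * z
            support = {}
            for z2 in range(z_lo, z_hi + 1):
                pred = mass / z2 + PROTON
                tol = pred * tol_ppm * 1e-6
                j = np.searchsorted(mz, pred)
                cand = None
                for k in (j - 1, j):
                    if 0 <= k < n and not assigned[k] and abs(mz[k] - pred) <= tol:
                        if cand is None or inten[k] > inten[cand]:
                            cand = k
                if cand is not None:
                    support[z2] = cand
            score = (len(support), sum(inten[k] for k in support.values()))
            if best is None or score > best[0]:
                best = (score, z, support)
        (n_support, tot_int), _, support = best
        if n_support < 2:
            continue
        masses = [(mz[k] - PROTON) * z2 for z2, k in support.items()]
        weights = [inten[k] for k in support.values()]
        mass = float(np.average(masses, weights=weights))
        charge_peaks = {z2: (float(mz[k]), float(inten[k])) for z2, k in support.items()}
        for k in support.values():
            assigned[k] = True
        results.append((mass, charge_peaks, float(tot_int)))
    results.sort(key=lambda r: -r[2])
    return results


def link_features(
    merged_scans,
    per_scan_results,
    link_tol_ppm: float = 20.0,
    min_consecutive_scans: int = 3,
    min_consecutive_charges: int = 3,
    mode: str = "monoisotopic",
):
    """Link per-scan deconvolution results into confident proteoform masses.

    Masses agreeing within ``link_tol_ppm`` across at least
    ``min_consecutive_scans`` consecutive merged scans form a cluster; a
    cluster is reported only if its supporting charges include a run of at
    least ``min_consecutive_charges`` consecutive values.  One feature is
    built per charge from the supporting peaks.
    """
    clusters = []  # each: {mass, obs: [(scan_idx, rt, mass, charge_peaks, intensity)]}
    for si, (scan, results) in enumerate(zip(merged_scans, per_scan_results)):
        for mass, charge_peaks, tot in results:
            home = None
            for cl in clusters:
                if abs(mass - cl["mass"]) <= cl["mass"] * link_tol_ppm * 1e-6:
                    if home is None or abs(mass - cl["mass"]) < abs(mass - home["mass"]):
                        home = cl
            if home is None:
                home = {"mass": mass, "weight": 0.0, "obs": []}
                clusters.append(home)
            home["obs"].append((si, scan.rt, mass, charge_peaks, tot))
            w = home["weight"] + tot
            if w > 0:
                home["mass"] = (home["mass"] * home["weight"] + mass * tot) / w
            home["weight"] = w

    out = []
    for cl in clusters:
        scan_idxs = sorted({o[0] for o in cl["obs"]})
        best_run = run = 1
        for a, b in zip(scan_idxs, scan_idxs[1:]):
            run = run + 1 if b == a + 1 else 1
            best_run = max(best_run, run)
        if best_run < min_consecutive_scans:
            continue
        charges = sorted({z for o in cl["obs"] for z in o[3]})
        best_zrun = zrun = 1
        for a, b in zip(charges, charges[1:]):
            zrun = zrun + 1 if b == a + 1 else 1
            best_zrun = max(best_zrun, zrun)
        if best_zrun < min_consecutive_charges:
            continue
        features = []
        for z in charges:
            pts = [
                (rt, charge_peaks[z][0], charge_peaks[z][1])
                for (_, rt, _, charge_peaks, _) in cl["obs"]
                if z in charge_peaks
            ]
            mzs = [p[1] for p in pts]
            rts = [p[0] for p in pts]
            apex = max(pts, key=lambda p: p[2])
            features.append(
                Feature(
                    mz_lo=min(mzs),
                    mz_hi=max(mzs),
                    rt_lo=min(rts),
                    rt_hi=max(rts),
                    charge=z,
                    intensity=sum(p[2] for p in pts),
                    apex_mz=apex[1],
                    apex_rt=apex[0],
                )
            )
        total = sum(f.intensity for f in features)
        out.append(ProteoformMass(cl["mass"], mode, 0.0, features, total))
    grand = sum(p.intensity for p in out)
    for p in out:
        p.abundance = p.intensity / grand if grand > 0 else 0.0
    out.sort(key=lambda p: -p.intensity)
    return out


def deconvolute(
    scans,
    window: float = 0.1,
    mz_tol: float = 0.01,
    charge_range=(10, 40),
    tol_ppm: float = 20.0,
    link_tol_ppm: float = 20.0,
    min_consecutive_scans: int = 3,
    min_consecutive_charges: int = 3,
    mode: str = "monoisotopic",
):
    """Full pipeline: merge scans, deconvolute each, link into proteoforms."""
    merged = merge_scans(scans, window=window, mz_tol=mz_tol)
    per_scan = [deconvolute_scan(s, charge_range, tol_ppm) for s in merged]
    return link_features(
        merged,
        per_scan,
        link_tol_ppm=link_tol_ppm,
        min_consecutive_scans=min_consecutive_scans,
        min_consecutive_charges=min_consecutive_charges,
        mode=mode,
    )


def build_inclusion_list(proteoforms, per_mass: int = 4) -> InclusionList:
    """Greedy non-overlapping feature selection for targeted acquisition.

    Features across all proteoforms are sorted by intensity (descending);
    a feature is skipped when its m/z window AND RT window both overlap a
    previously selected one, or when its proteoform already has ``per_mass``
    entries.  Each entry records the highest-intensity m/z and its RT.
    """
    if per_mass < 1:
        raise ValueError("per_mass must be >= 1")
    tagged = [(f, p) for p in proteoforms for f in p.features]
    tagged.sort(key=lambda t: -t[0].intensity)
    chosen: List[InclusionEntry] = []
    counts = {id(p): 0 for p in proteoforms}
    for f, p in tagged:
        if counts[id(p)] >= per_mass:
            continue
        if any(f.overlaps(e.feature) for e in chosen):
            continue
        chosen.append(
            InclusionEntry(
                mz=f.apex_mz,
                rt=f.apex_rt,
                rt_lo=f.rt_lo,
                rt_hi=f.rt_hi,
                charge=f.charge,
                parent_mass=p.mass,
                feature=f,
            )
        )
        counts[id(p)] += 1
    return InclusionList(chosen, per_mass)


# Averagine isotope-envelope offset between the apex (most abundant)
# isotopologue mass and the monoisotopic mass, as a function of mass.
_AVG_MINUS_MONO_PER_DA = (111.1254 - 111.05429) / 111.1254
_NEUTRON = 1.00235  # average spacing of protein isotopologue peaks


def apex_to_monoisotopic(apex_mass: float) -> float:
    """Approximate monoisotopic mass from an isotope-envelope apex mass.

    For antibody-subunit masses the apex of the isotope envelope sits near
    the average mass; the averagine composition model predicts the integer
    number of neutron offsets to subtract.
    """
    n = round(apex_mass * _AVG_MINUS_MONO_PER_DA / _NEUTRON)
    return apex_mass - n * _NEUTRON
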