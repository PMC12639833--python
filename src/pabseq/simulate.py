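"""Synthetic antibody-mixture generator for all three MS data layers.

The generator emits, from a seeded ground truth, exactly the inputs the
pipeline consumes:

* bottom-up de novo peptide reads — overlapping windows over each chain
  (multi-enzyme-like cut-site jitter), Beta-mixture local confidence (high
  in well-fragmented interiors, low near read termini), isobaric read
  errors injected at a stated rate with a truth log, and w-ion Ile/Leu
  evidence on EThcD reads;
* middle-down neutral c/z fragment mass lists per subunit precursor, with
  partial site coverage biased N-terminally for c ions and C-terminally
  for z ions, Gaussian ppm noise, decoy masses, split across four emulated
  runs;
* intact proteoform masses for the subunit (monoisotopic), reduced
  (monoisotopic) and whole (average) samples, with ppm-scale mass error —
  plus optional synthetic charge-envelope centroid scans for exercising
  intact deconvolution end to end.

Chains are a conserved-motif + random-variable-region construction: the
variable region is sampled from amino-acid frequencies behind a conserved
N-terminal motif, the constant regions come from shipped synthetic
templates whose termini match the terminus classifier's motif fixture.
The same seed always reproduces the same bundle, and every ground-truth
label (residue identity, terminus class, planted fragment sites, injected
errors) is emitted alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import chem, middledown
from .bottomup import DeNovoPeptide
from .intact import CentroidScan

__all__ = [
    "SimScenario",
    "Chain",
    "Antibody",
    "ChainSet",
    "SimBundle",
    "generate_chains",
    "emit_bottomup",
    "emit_middledown",
    "emit_intact",
    "emit_scans",
    "simulate_scenario",
]

# background amino-acid frequencies for variable-region sampling
_FREQS = {
    "A": 0.074, "R": 0.042, "N": 0.044, "D": 0.059, "C": 0.033, "Q": 0.037,
    "E": 0.058, "G": 0.074, "H": 0.029, "L": 0.076, "I": 0.038, "K": 0.072,
    "M": 0.018, "F": 0.040, "P": 0.050, "S": 0.081, "T": 0.062, "W": 0.013,
    "Y": 0.033, "V": 0.067,
}
_LETTERS = tuple(_FREQS)
_WEIGHTS = np.array([_FREQS[a] for a in _LETTERS])
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()

_LC_START_MOTIFS = ("DIQMTQSP", "EIVLTQSP", "QSVLTQPP")
_FD_START_MOTIFS = ("EVQLVESG", "QVQLVQSG", "QVTLKESG")

_MIN_MASS_SEPARATION = 9.0  # Da between any two subunit / HC masses


def _load_templates():
    text = resources.files("pabseq").joinpath(
        "data/synthetic_constant_regions.fasta"
    ).read_text()
    seqs = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    return seqs


@dataclass(frozen=True)
class Chain:
    name: str
    subunit_type: str   # "LC" | "Fd" | "Fc/2"
    sequence: str

    @property
    def mono_mass(self) -> float:
        return chem.peptide_mass(self.sequence)

    @property
    def avg_mass(self) -> float:
        return chem.peptide_mass(self.sequence, average=True)

    def __len__(self):
        return len(self.sequence)


@dataclass
class Antibody:
    name: str
    lcs: List[Chain]
    fd: Chain
    fc: Chain

    @property
    def hc_sequence(self) -> str:
        return self.fd.sequence + self.fc.sequence

    @property
    def hc_mono_mass(self) -> float:
        return chem.peptide_mass(self.hc_sequence)

    @property
    def hc_avg_mass(self) -> float:
        return chem.peptide_mass(self.hc_sequence, average=True)


@dataclass
class ChainSet:
    antibodies: List[Antibody]
    chains: List[Chain]                  # unique chains
    labels: Dict[str, str] = field(default_factory=dict)  # name -> type


@dataclass
class SimScenario:
    """Study conditions for one simulated experiment."""

    n_antibodies: int = 4
    shared_fc: bool = True
    bispecific: bool = False
    abundances: Tuple[float, ...] = (3.0, 2.0, 1.0, 1.0)
    # bottom-up
    tiling_depth: int = 8
    peptide_len_mean: float = 18.0
    peptide_len_sd: float = 4.0
    peptide_len_min: int = 10
    peptide_len_max: int = 30
    overlap_min: int = 6
    overlap_max: int = 12
    isobaric_error_rate: float = 0.02
    conf_interior: Tuple[float, float] = (8.0, 2.0)
    conf_terminal: Tuple[float, float] = (2.0, 2.0)
    terminal_len: int = 2
    ethcd_fraction: float = 0.5
    w_ion_rate: float = 0.8
    w_flip_rate: float = 0.02
    # middle-down
    md_site_coverage: float = 0.6
    md_ppm_noise: float = 20.0
    md_decoy_rate: float = 0.05
    md_runs: int = 4
    md_precursor_ppm: float = 2.0
    # intact
    subunit_ppm: float = 5.0
    reduced_ppm: float = 5.0
    whole_ppm: float = 20.0
    disulfide_count: int = 16
    terminal_mods: bool = False
    seed: int = 0


@dataclass
class SimBundle:
    scenario: SimScenario
    chain_set: ChainSet
    peptides: List[DeNovoPeptide]
    peptide_labels: List[str]
    error_log: List[dict]
    md_runs: List[Dict[float, List[Tuple[float, float]]]]
    md_truth: Dict[str, dict]
    intact: Dict[str, list]


def _random_seq(rng, n: int) -> str:
    idx = rng.choice(len(_LETTERS), size=n, p=_WEIGHTS)
    return "".join(_LETTERS[i] for i in idx)


def _separated(mass: float, taken: Sequence[float], min_sep: float) -> bool:
    return all(abs(mass - t) >= min_sep for t in taken)


def generate_chains(
    n_antibodies: int = 4,
    shared_fc: bool = True,
    bispecific: bool = False,
    seed: int = 0,
) -> ChainSet:
    """Generate a labeled antibody mixture.

    With ``shared_fc`` antibodies share Fc/2 sequences in pairs (four
    antibodies yield exactly two distinct Fc/2 chains); with ``bispecific``
    the first antibody carries two light chains on a duplicated heavy
    chain.  All subunit and heavy-chain masses are kept at least 9 Da
    apart so the intact layer can address each species unambiguously.
    """
    if n_antibodies < 1:
        raise ValueError("need at least one antibody")
    rng = np.random.default_rng(int(seed))
    templates = _load_templates()
    lc_const = templates["LC_CONST"]
    fd_const = templates["FD_CONST"]
    fc_half = templates["FC_HALF"]

    taken: List[float] = []

    def draw_chain(name, stype, builder):
        for _ in range(200):
            seq = builder()
            m = chem.peptide_mass(seq)
            if _separated(m, taken, _MIN_MASS_SEPARATION):
                taken.append(m)
                return Chain(name, stype, seq)
        raise RuntimeError("could not separate chain masses; adjust scenario")

    # Fc/2 chains: template plus seeded substitutions clustered in a short
    # interior window (like a real allotype motif region); clustering keeps
    # reads that span the window unambiguous about which variant they are
    n_fc = math.ceil(n_antibodies / 2) if shared_fc else n_antibodies
    fcs = []
    for g in range(n_fc):
        def build_fc():
            seq = list(fc_half)
            lo = int(rng.integers(60, len(seq) - 80))
            pos = rng.choice(np.arange(lo, lo + 12), size=6, replace=False)
            for p in pos:
                old = seq[p]
                choices = [a for a in _LETTERS if a != old]
                seq[p] = choices[rng.integers(len(choices))]
            return "".join(seq)
        fcs.append(draw_chain(f"Fc{g + 1}", "Fc/2", build_fc))

    antibodies = []
    chains: List[Chain] = list(fcs)
    hc_masses: List[float] = []
    for i in range(n_antibodies):
        fc = fcs[i // 2 if shared_fc else i]
        for _ in range(200):
            motif = _FD_START_MOTIFS[rng.integers(len(_FD_START_MOTIFS))]
            var = _random_seq(rng, 225 - len(motif) - len(fd_const))
            seq = motif + var + fd_const
            m = chem.peptide_mass(seq)
            hc_m = m + chem.peptide_mass(fc.sequence) - chem.DEFAULT_TABLE.water_mono
            if _separated(m, taken, _MIN_MASS_SEPARATION) and _separated(
                hc_m, hc_masses, _MIN_MASS_SEPARATION
            ):
                taken.append(m)
                hc_masses.append(hc_m)
                fd = Chain(f"Fd{i + 1}", "Fd", seq)
                break
        else:
            raise RuntimeError("could not separate Fd masses")

        n_lc = 2 if (bispecific and i == 0) else 1
        lcs = []
        for j in range(n_lc):
            motif = _LC_START_MOTIFS[rng.integers(len(_LC_START_MOTIFS))]
            lcs.append(
                draw_chain(
                    f"LC{i + 1}" + (chr(ord('a') + j) if n_lc > 1 else ""),
                    "LC",
                    lambda m=motif: m + _random_seq(rng, 214 - len(m) - len(lc_const)) + lc_const,
                )
            )
        chains.extend([fd] + lcs)
        antibodies.append(Antibody(f"AB{i + 1}", lcs, fd, fc))

    labels = {c.name: c.subunit_type for c in chains}
    return ChainSet(antibodies, chains, labels)


def _sample_conf(rng, n, scenario: SimScenario):
    a, b = scenario.conf_interior
    conf = rng.beta(a, b, size=n)
    t = min(scenario.terminal_len, n // 2)
    if t:
        at, bt = scenario.conf_terminal
        conf[:t] = rng.beta(at, bt, size=t)
        conf[-t:] = rng.beta(at, bt, size=t)
    return conf


def _inject_error(rng, read: list, conf, truth_start: int):
    """Try one isobaric read error; returns a truth-log dict or None."""
    kinds = []
    for i, r in enumerate(read):
        if r == "N":
            kinds.append(("N>GG", i))
    for i in range(len(read) - 1):
        if read[i] == "T" and read[i + 1] == "V":
            kinds.append(("TV>SL", i))
        if read[i] != read[i + 1]:
            kinds.append(("swap", i))
    # keep errors away from read termini so confidence shaping stays local
    kinds = [k for k in kinds if 2 <= k[1] <= len(read) - 4]
    if not kinds:
        return None
    kind, i = kinds[rng.integers(len(kinds))]
    entry = {"kind": kind, "chain_pos": truth_start + i, "read_pos": i}
    if kind == "N>GG":
        entry["original"], entry["read_as"] = "N", "GG"
        read[i : i + 1] = ["G", "G"]
        lo, hi = max(0, i - 1), min(len(read), i + 3)
        new_conf = list(conf[:i]) + [0.0] + list(conf[i:])
        conf = np.array(new_conf)
    elif kind == "TV>SL":
        entry["original"], entry["read_as"] = "TV", "SL"
        read[i], read[i + 1] = "S", "L"
        lo, hi = max(0, i - 1), min(len(read), i + 3)
    else:
        entry["original"] = read[i] + read[i + 1]
        read[i], read[i + 1] = read[i + 1], read[i]
        entry["read_as"] = read[i] + read[i + 1]
        lo, hi = max(0, i - 1), min(len(read), i + 3)
    conf[lo:hi] = rng.beta(1.5, 6.0, size=hi - lo)  # misread region reads low
    return entry, read, conf


def emit_bottomup(
    chain_set: ChainSet,
    depth: Optional[int] = None,
    error_rate: Optional[float] = None,
    seed: Optional[int] = None,
    scenario: Optional[SimScenario] = None,
):
    """Emit overlapping de novo reads for every unique chain.

    Returns ``(peptides, labels, error_log)``; ``labels[i]`` is the truth
    terminus class of ``peptides[i]`` (START for reads beginning at chain
    position 0, END for reads finishing the chain, OTHER in between).
    Reads report Leu at every Ile position; w-ion evidence carries the
    truth at the stated coverage.
    """
    scenario = scenario or SimScenario()
    depth = scenario.tiling_depth if depth is None else depth
    error_rate = scenario.isobaric_error_rate if error_rate is None else error_rate
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(int(seed) + 1)
    peptides, labels, error_log = [], [], []
    for chain in chain_set.chains:
        L = len(chain.sequence)
        for t in range(depth):
            start = 0
            while start < L:
                ln = int(round(rng.normal(scenario.peptide_len_mean, scenario.peptide_len_sd)))
                ln = max(scenario.peptide_len_min, min(scenario.peptide_len_max, ln))
                end = min(start + ln, L)
                if L - end < scenario.peptide_len_min and end < L:
                    end = L
                if end == L:
                    start = max(0, min(start, L - scenario.peptide_len_min))
                truth = chain.sequence[start:end]
                read = list(truth.replace("I", "L"))
                conf = _sample_conf(rng, len(read), scenario)
                if rng.random() < error_rate:
                    result = _inject_error(rng, read, conf, start)
                    if result is not None:
                        entry, read, conf = result
                        entry["chain"] = chain.name
                        error_log.append(entry)
                mode = "EThcD" if rng.random() < scenario.ethcd_fraction else "HCD"
                w_ev = None
                if mode == "EThcD":
                    ev = [None] * len(read)
                    if len(read) == len(truth):
                        # length-shifting read errors would misalign per-residue
                        # evidence, so such reads carry none
                        for k, tr in enumerate(truth):
                            if tr in "IL" and read[k] == "L" and rng.random() < scenario.w_ion_rate:
                                ev[k] = tr if rng.random() >= scenario.w_flip_rate else (
                                    "L" if tr == "I" else "I"
                                )
                    w_ev = tuple(ev)
                seq = "".join(read)
                conf = np.clip(conf, 0.0, 1.0)
                peptides.append(
                    DeNovoPeptide(
                        sequence=seq,
                        confidence=tuple(float(c) for c in conf),
                        alc=float(np.mean(conf)),
                        mode=mode,
                        spectrum_id=f"{chain.name}:{t}:{start}",
                        w_evidence=w_ev,
                    )
                )
                if start == 0:
                    labels.append(f"{chain.subunit_type}-START")
                elif end == L:
                    labels.append(f"{chain.subunit_type}-END")
                else:
                    labels.append("OTHER")
                if end >= L:
                    break
                overlap = int(rng.integers(scenario.overlap_min, scenario.overlap_max + 1))
                start = max(start + 1, end - overlap)

    # junction-spanning heavy-chain reads: the bottom-up sample digests the
    # whole antibody, so peptides cross the Fd | Fc/2 hinge joint
    for ab in chain_set.antibodies:
        hc = ab.hc_sequence
        jpos = len(ab.fd.sequence)
        for t in range(depth):
            for _ in range(2):
                start = int(rng.integers(jpos - 22, jpos - 5))
                ln = int(round(rng.normal(scenario.peptide_len_mean, scenario.peptide_len_sd)))
                ln = max(scenario.peptide_len_min, min(scenario.peptide_len_max, ln))
                end = min(start + ln, len(hc))
                if end <= jpos + 3:
                    end = min(jpos + 4, len(hc))
                truth = hc[start:end]
                read = truth.replace("I", "L")
                conf = np.clip(_sample_conf(rng, len(read), scenario), 0.0, 1.0)
                peptides.append(
                    DeNovoPeptide(
                        sequence=read,
                        confidence=tuple(float(c) for c in conf),
                        alc=float(np.mean(conf)),
                        mode="HCD",
                        spectrum_id=f"{ab.name}:hinge:{t}:{start}",
                    )
                )
                labels.append("OTHER")
    return peptides, labels, error_log


def emit_middledown(
    chain_set: ChainSet,
    site_coverage: Optional[float] = None,
    ppm_noise: Optional[float] = None,
    seed: Optional[int] = None,
    scenario: Optional[SimScenario] = None,
):
    """Emit per-run precursor -> fragment-mass lists plus site bookkeeping.

    c sites are planted preferentially in the N-terminal half and z sites
    in the C-terminal half, mirroring electron-transfer fragment coverage
    of ~25 kDa subunits.
    """
    scenario = scenario or SimScenario()
    cov = scenario.md_site_coverage if site_coverage is None else site_coverage
    noise = scenario.md_ppm_noise if ppm_noise is None else ppm_noise
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(int(seed) + 2)
    runs = [dict() for _ in range(scenario.md_runs)]
    truth: Dict[str, dict] = {}
    for chain in chain_set.chains:
        seq = chain.sequence
        L = len(seq)
        tokens = chem.parse_peptide(seq.replace("I", "L"))
        prefixes = chem.prefix_masses(tokens)
        total = prefixes[-1]
        # terminal bias: c sites favored in the N-half, z sites in the
        # C-half; p_hi/p_lo average to ~cov and reach 1 when cov = 1
        p_hi = min(1.0, 1.4 * cov)
        p_lo = max(0.0, 1.0 - 1.4 * (1.0 - cov))
        c_sites, z_sites, frags = [], [], []
        for i in range(1, L):
            p_c = p_hi if i <= L / 2 else p_lo
            if rng.random() < p_c:
                c_sites.append(i)
                m = (prefixes[i - 1] + middledown.C_ION_OFFSET) * (
                    1 + rng.normal(0, noise) * 1e-6
                )
                frags.append((m, float(rng.lognormal(10, 1))))
            j = L - i  # suffix length at this cleavage site
            p_z = p_hi if j <= L / 2 else p_lo
            if rng.random() < p_z:
                z_sites.append(i)
                m = (total - prefixes[i - 1] + middledown.Z_ION_OFFSET) * (
                    1 + rng.normal(0, noise) * 1e-6
                )
                frags.append((m, float(rng.lognormal(10, 1))))
        n_decoys = int(round(scenario.md_decoy_rate * len(frags)))
        mono = chain.mono_mass
        for _ in range(n_decoys):
            frags.append((float(rng.uniform(500, mono)), float(rng.lognormal(8, 1))))
        truth[chain.name] = {
            "c_sites": c_sites,
            "z_sites": z_sites,
            "n_fragments": len(frags),
            "n_decoys": n_decoys,
        }
        assignment = rng.integers(0, scenario.md_runs, size=len(frags))
        for r in range(scenario.md_runs):
            pmass = mono * (1 + rng.normal(0, scenario.md_precursor_ppm) * 1e-6)
            sel = [frags[k] for k in range(len(frags)) if assignment[k] == r]
            if sel:
                runs[r][pmass] = sel
    return runs, truth


def emit_intact(
    chain_set: ChainSet,
    abundances: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    scenario: Optional[SimScenario] = None,
):
    """Emit whole / reduced / subunit proteoform mass lists.

    Subunit and reduced masses are monoisotopic; whole-antibody masses are
    average-mode, ``2 x (HC + LC) - n x disulfide loss`` (a bispecific
    antibody contributes all three LC-combination whole masses).  Each
    entry is ``(mass, abundance)`` with the scenario's ppm-scale error.
    """
    scenario = scenario or SimScenario()
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(int(seed) + 3)
    abs_list = list(
        abundances
        if abundances is not None
        else scenario.abundances[: len(chain_set.antibodies)]
    )
    while len(abs_list) < len(chain_set.antibodies):
        abs_list.append(1.0)

    def noisy(mass, ppm):
        return mass * (1 + rng.normal(0, ppm) * 1e-6)

    ds = chem.DEFAULT_TABLE.disulfide_loss_avg * scenario.disulfide_count
    water_avg = chem.DEFAULT_TABLE.water_avg

    sub_ab: Dict[str, float] = {}
    for ab, a in zip(chain_set.antibodies, abs_list):
        for lc in ab.lcs:
            sub_ab[lc.name] = sub_ab.get(lc.name, 0.0) + a / len(ab.lcs)
        sub_ab[ab.fd.name] = sub_ab.get(ab.fd.name, 0.0) + a
        sub_ab[ab.fc.name] = sub_ab.get(ab.fc.name, 0.0) + a
    total = sum(sub_ab.values())
    subunit = [
        (noisy(c.mono_mass, scenario.subunit_ppm), sub_ab.get(c.name, 1.0) / total)
        for c in chain_set.chains
    ]
    # the same subunit species deconvoluted in average-mass mode, for the
    # pairing arithmetic (reduced and whole intact masses are average-mode)
    subunit_avg = [
        (noisy(c.avg_mass, scenario.subunit_ppm), sub_ab.get(c.name, 1.0) / total)
        for c in chain_set.chains
    ]

    reduced = []
    seen = set()
    for ab, a in zip(chain_set.antibodies, abs_list):
        for lc in ab.lcs:
            if lc.name not in seen:
                seen.add(lc.name)
                reduced.append((noisy(lc.avg_mass, scenario.reduced_ppm), a))
        hc_name = f"HC:{ab.fd.name}+{ab.fc.name}"
        if hc_name not in seen:
            seen.add(hc_name)
            reduced.append((noisy(ab.hc_avg_mass, scenario.reduced_ppm), a))

    whole = []
    for ab, a in zip(chain_set.antibodies, abs_list):
        hc_avg = ab.hc_avg_mass
        combos = []
        if len(ab.lcs) == 1:
            combos.append((ab.lcs[0], ab.lcs[0]))
        else:
            combos.extend(
                [(ab.lcs[0], ab.lcs[0]), (ab.lcs[0], ab.lcs[1]), (ab.lcs[1], ab.lcs[1])]
            )
        for la, lb in combos:
            mass = 2 * hc_avg + la.avg_mass + lb.avg_mass - ds
            whole.append((noisy(mass, scenario.whole_ppm), a / len(combos)))

    for lst in (reduced, whole):
        tot = sum(a for _, a in lst)
        for k, (m, a) in enumerate(lst):
            lst[k] = (m, a / tot if tot else 0.0)
    return {
        "subunit": subunit,
        "subunit_avg": subunit_avg,
        "reduced": reduced,
        "whole": whole,
    }


def emit_scans(
    species: Sequence[Tuple[float, float]],
    seed: int = 0,
    charge_center: int = 27,
    charge_sd: float = 4.0,
    charge_range: Tuple[int, int] = (20, 35),
    rt_step: float = 0.02,
    rt_sigma: float = 0.15,
    rt_spacing: float = 0.6,
    ppm_noise: float = 3.0,
    base_intensity: float = 1e6,
) -> List[CentroidScan]:
    """Synthesize charge-envelope MS1 centroid scans for given species.

    ``species`` is a list of (neutral mass, relative abundance); each
    species elutes as a Gaussian RT profile centered ``rt_spacing`` minutes
    after the previous one, ionized over a Gaussian charge envelope.
    """
    rng = np.random.default_rng(int(seed) + 4)
    proton = chem.DEFAULT_TABLE.proton
    centers = [10.0 + k * rt_spacing for k in range(len(species))]
    t0, t1 = min(centers) - 0.4, max(centers) + 0.4
    scans = []
    t = t0
    while t <= t1 + 1e-9:
        mzs, ints = [], []
        for (mass, ab), mu in zip(species, centers):
            amp = base_intensity * ab * math.exp(-0.5 * ((t - mu) / rt_sigma) ** 2)
            if amp < base_intensity * 1e-4:
                continue
            for z in range(charge_range[0], charge_range[1] + 1):
                w = math.exp(-0.5 * ((z - charge_center) / charge_sd) ** 2)
                inten = amp * w
                if inten <= 0:
                    continue
                mz = (mass + z * proton) / z * (1 + rng.normal(0, ppm_noise) * 1e-6)
                mzs.append(mz)
                ints.append(inten)
        if mzs:
            order = np.argsort(mzs)
            mz_arr = np.array(mzs)[order]
            int_arr = np.array(ints)[order]
            keep = np.concatenate([[True], np.diff(mz_arr) > 1e-9])
            scans.append(CentroidScan(round(t, 4), mz_arr[keep], int_arr[keep]))
        t += rt_step
    return scans


def simulate_scenario(scenario: Optional[SimScenario] = None) -> SimBundle:
    """Generate the full three-layer bundle for one scenario."""
    scenario = scenario or SimScenario()
    chain_set = generate_chains(
        scenario.n_antibodies, scenario.shared_fc, scenario.bispecific, scenario.seed
    )
    peptides, labels, error_log = emit_bottomup(chain_set, scenario=scenario)
    md_runs, md_truth = emit_middledown(chain_set, scenario=scenario)
    intact = emit_intact(chain_set, scenario=scenario)
    return SimBundle(
        scenario=scenario,
        chain_set=chain_set,
        peptides=peptides,
        peptide_labels=labels,
        error_log=error_log,
        md_runs=md_runs,
        md_truth=md_truth,
        intact=intact,
    )
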