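"""Readers and writers for the pipeline's external plain-text formats.

* de novo peptide tables — PEAKS-style CSV
  (``Peptide, ALC (%), local confidence (%), Fraction, Scan, Mode, w ions``);
* middle-down fragment lists — per-run TSV
  (``precursor_mass, fragment_mass, intensity``);
* intact data — 3-column centroid TSV (``rt_min, mz, intensity``) or mzML
  (via pyteomics), and proteoform TSV (``mass, mode, abundance, n_features``);
* inclusion lists — instrument-ready CSV (``mz, rt_start, rt_end, z``);
* FASTA for sequenced chains, JSON for truth bundles and reports.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .bottomup import DeNovoPeptide
from .intact import CentroidScan, InclusionList, ProteoformMass

__all__ = [
    "read_peptides_csv", "write_peptides_csv",
    "read_fragment_runs", "write_fragment_run",
    "read_scans_tsv", "write_scans_tsv", "read_scans_mzml",
    "read_proteoforms_tsv", "write_proteoforms_tsv",
    "write_inclusion_csv",
    "write_fasta", "read_fasta",
    "write_json", "read_json",
]

PEPTIDE_COLUMNS = ["Peptide", "ALC (%)", "local confidence (%)", "Fraction", "Scan", "Mode", "w ions"]


def write_peptides_csv(path, peptides: Sequence[DeNovoPeptide]):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PEPTIDE_COLUMNS)
        for p in peptides:
            conf = " ".join(f"{c * 100:.0f}" for c in p.confidence)
            frac, _, scan = p.spectrum_id.partition(":")
            w_ions = (
                "".join(e if e else "." for e in p.w_evidence) if p.w_evidence else ""
            )
            w.writerow([p.sequence, f"{p.alc * 100:.1f}", conf, frac, scan, p.mode, w_ions])


def read_peptides_csv(path) -> List[DeNovoPeptide]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            conf = tuple(float(c) / 100 for c in row["local confidence (%)"].split())
            w_raw = row.get("w ions", "")
            w_ev = tuple(c if c in "IL" else None for c in w_raw) if w_raw else None
            out.append(
                DeNovoPeptide(
                    sequence=row["Peptide"],
                    confidence=conf,
                    alc=float(row["ALC (%)"]) / 100,
                    mode=row.get("Mode", "HCD"),
                    spectrum_id=f"{row.get('Fraction', '')}:{row.get('Scan', '')}",
                    w_evidence=w_ev,
                )
            )
    return out


def write_fragment_run(path, run: Dict[float, List[Tuple[float, float]]]):
    with open(path, "w") as fh:
        fh.write("precursor_mass\tfragment_mass\tintensity\n")
        for pmass in sorted(run):
            for fmass, inten in run[pmass]:
                fh.write(f"{pmass:.5f}\t{fmass:.5f}\t{inten:.3f}\n")


def read_fragment_runs(paths) -> List[Dict[float, List[Tuple[float, float]]]]:
    runs = []
    for path in paths:
        run: Dict[float, List[Tuple[float, float]]] = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                pmass, fmass, inten = line.split("\t")
                run.setdefault(float(pmass), []).append((float(fmass), float(inten)))
        runs.append(run)
    return runs


def write_scans_tsv(path, scans: Sequence[CentroidScan]):
    with open(path, "w") as fh:
        fh.write("rt_min\tmz\tintensity\n")
        for s in scans:
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{s.rt:.4f}\t{mz:.6f}\t{inten:.3f}\n")


def read_scans_tsv(path) -> List[CentroidScan]:
    by_rt: Dict[float, List[Tuple[float, float]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rt, mz, inten = line.split("\t")
            by_rt.setdefault(float(rt), []).append((float(mz), float(inten)))
    scans = []
    for rt in sorted(by_rt):
        peaks = sorted(by_rt[rt])
        scans.append(
            CentroidScan(rt, np.array([p[0] for p in peaks]), np.array([p[1] for p in peaks]))
        )
    return scans


def read_scans_mzml(path) -> List[CentroidScan]:
    """Read MS1 centroid scans from an mzML file."""
    from pyteomics import mzml as _mzml

    scans = []
    with _mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level") != 1:
                continue
            rt = float(spec["scanList"]["scan"][0]["scan start time"])
            mz = np.asarray(spec["m/z array"], dtype=float)
            inten = np.asarray(spec["intensity array"], dtype=float)
            order = np.argsort(mz)
            mz, inten = mz[order], inten[order]
            keep = np.concatenate([[True], np.diff(mz) > 0]) if len(mz) else []
            scans.append(CentroidScan(rt, mz[keep], inten[keep]))
    scans.sort(key=lambda s: s.rt)
    return scans


def write_proteoforms_tsv(path, proteoforms: Sequence[ProteoformMass]):
    with open(path, "w") as fh:
        fh.write("mass\tmode\tabundance\tn_features\n")
        for p in proteoforms:
            fh.write(f"{p.mass:.4f}\t{p.mode}\t{p.abundance:.4f}\t{len(p.features)}\n")


def read_proteoforms_tsv(path) -> List[Tuple[float, str, float]]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            mass, mode, abundance, _ = line.split("\t")
            out.append((float(mass), mode, float(abundance)))
    return out


def write_inclusion_csv(path, inclusion: InclusionList):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mz", "rt_start", "rt_end", "z", "parent_mass"])
        for e in inclusion.entries:
            w.writerow(
                [f"{e.mz:.5f}", f"{e.rt_lo:.3f}", f"{e.rt_hi:.3f}", e.charge, f"{e.parent_mass:.3f}"]
            )


def write_fasta(path, records: Sequence[Tuple[str, str]]):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> List[Tuple[str, str]]:
    records = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
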