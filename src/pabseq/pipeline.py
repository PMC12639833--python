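"""End-to-end orchestration: intact -> middle-down -> assembly -> pairing.

:func:`run_pipeline` consumes an :class:`InputBundle` (deconvoluted intact
mass lists, per-run middle-down fragment files, a de novo peptide table)
and produces sequenced subunits, refined chains, and antibody groups.
When an output directory is given every stage writes its products there
before the next stage runs, so a crashed run leaves inspectable
intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from . import assemble, bottomup, chem, io, metrics, middledown, pairing, refine
from .config import PipelineConfig

__all__ = ["InputBundle", "PipelineResult", "run_pipeline", "evaluate_against_truth"]

logger = logging.getLogger(__name__)


@dataclass
class InputBundle:
    """Deconvoluted inputs for one experiment."""

    subunit: List[Tuple[float, float]]      # (mono mass, abundance)
    reduced: List[Tuple[float, float]]      # (average mass, abundance)
    whole: List[Tuple[float, float]]        # (average mass, abundance)
    md_runs: List[Dict[float, List[Tuple[float, float]]]]
    peptides: List[bottomup.DeNovoPeptide]
    # average-mode deconvolution of the subunit sample (optional; the
    # pairing table falls back to calculated average masses without it)
    subunit_avg: List[Tuple[float, float]] = field(default_factory=list)

    @classmethod
    def from_simulation(cls, bundle) -> "InputBundle":
        return cls(
            subunit=list(bundle.intact["subunit"]),
            reduced=list(bundle.intact["reduced"]),
            whole=list(bundle.intact["whole"]),
            md_runs=bundle.md_runs,
            peptides=bundle.peptides,
            subunit_avg=list(bundle.intact.get("subunit_avg", [])),
        )


@dataclass
class SubunitResult:
    subunit_mass: float
    winner_type: Optional[str]
    sequence: Optional[str]                 # refined, Ile/Leu resolved
    assembled_sequence: Optional[str]       # pre-refinement
    md_matches: int = 0
    md_coverage: float = 0.0
    il_flagged: List[int] = field(default_factory=list)
    corrections: list = field(default_factory=list)
    report: Optional[assemble.SubunitReport] = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    subunits: Dict[float, SubunitResult]
    hc_pairings: List[pairing.HCPairing]
    groups: List[pairing.AntibodyGroup]
    warnings: List[str] = field(default_factory=list)

    def sequences_by_type(self, subunit_type: str) -> List[Tuple[str, float]]:
        return [
            (r.sequence, m)
            for m, r in self.subunits.items()
            if r.winner_type == subunit_type and r.sequence
        ]


def run_pipeline(
    inputs: InputBundle,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str] = None,
) -> PipelineResult:
    """Run the full sequencing workflow on deconvoluted inputs."""
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_json(out / "config.json")
    warnings: List[str] = []

    # -- stage 1: subunit mass list ------------------------------------
    # descending, so per-direction reachability caches build once at the
    # largest mass ceiling and are reused for the rest
    sub_masses = sorted(
        (m for m, a in inputs.subunit if a >= cfg.min_subunit_abundance),
        reverse=True,
    )
    if not sub_masses:
        raise ValueError("no subunit masses above the abundance floor")

    # -- stage 2: middle-down aggregation ------------------------------
    frag_sets = middledown.aggregate_precursors(
        inputs.md_runs,
        sub_masses,
        tol_ppm=cfg.precursor_tol_ppm,
        match_tol_ppm=cfg.md_tol_ppm,
    )
    if not any(fs.fragments for fs in frag_sets.values()):
        warnings.append("no middle-down fragments matched; assembling with T=0")
        logger.warning(warnings[-1])

    # -- stage 3: bottom-up graph --------------------------------------
    peps = bottomup.filter_peptides(
        inputs.peptides, cfg.min_alc, cfg.max_low_conf_run, cfg.low_conf_threshold
    )
    graph = bottomup.build_overlap_graph(peps, cfg.min_overlap_blocks)
    bottomup.accumulate_confidence(graph)
    term_sets = bottomup.build_terminus_sets(graph)

    # -- stage 4+5: per-subunit assembly and refinement ----------------
    subunits: Dict[float, SubunitResult] = {}
    for sm in sub_masses:
        rep = assemble.sequence_subunit(
            graph,
            term_sets,
            frag_sets[sm],
            sm,
            width=cfg.dp_width,
            capacity=cfg.dp_capacity,
            mass_tol=cfg.subunit_mass_tol,
            low_conf_threshold=cfg.low_conf_threshold,
            end_penalty=cfg.end_penalty,
            top_k=cfg.top_k,
        )
        res = SubunitResult(sm, rep.winner_type, None, None, report=rep)
        best = rep.best
        if best is not None:
            res.assembled_sequence = best.sequence
            correction = refine.spider_correct(
                best.tokens,
                peps,
                low_conf_threshold=cfg.low_conf_threshold,
                min_support=cfg.refine_min_support,
                top_k=cfg.refine_top_k,
            )
            toks, flagged = refine.resolve_ile_leu(correction.best, peps)
            res.sequence = "".join(r for r, _ in toks)
            res.il_flagged = flagged
            res.corrections = correction.log
            res.md_matches = best.T
            if len(toks) >= 2:
                res.md_coverage = middledown.md_coverage(toks, frag_sets[sm])
        else:
            warnings.append(f"subunit {sm:.2f} Da unsequenceable with all three types")
        subunits[sm] = res
    if out:
        io.write_fasta(
            out / "subunits.fasta",
            [
                (f"{r.winner_type}_{m:.2f}", r.sequence)
                for m, r in subunits.items()
                if r.sequence
            ],
        )

    # -- stage 6: pairing (average-mass mode) --------------------------
    reduced_masses = [m for m, _ in inputs.reduced]
    whole_masses = [m for m, _ in inputs.whole]
    sub_avg_masses = [m for m, _ in inputs.subunit_avg]

    def observed_avg(sequence: str) -> float:
        """Observed average subunit mass for a sequenced chain (calculated
        average mass when no average-mode observation is close enough)."""
        calc = chem.peptide_mass(sequence, average=True)
        cands = [m for m in sub_avg_masses if abs(m - calc) <= cfg.hc_mass_tol]
        return min(cands, key=lambda m: abs(m - calc)) if cands else calc

    by_type = {
        t: [
            (r.sequence, observed_avg(r.sequence))
            for r in subunits.values()
            if r.winner_type == t and r.sequence
        ]
        for t in ("LC", "Fd", "Fc/2")
    }
    hc_pairings = pairing.pair_hc(
        by_type["Fd"],
        by_type["Fc/2"],
        reduced_masses,
        enzyme=cfg.enzyme,
        peptides=peps,
        mass_tol=cfg.hc_mass_tol,
    )
    lc_with_reduced = []
    for seq, sm in by_type["LC"]:
        candidates = [m for m in reduced_masses if abs(m - sm) <= cfg.hc_mass_tol]
        obs = min(candidates, key=lambda m: abs(m - sm)) if candidates else sm
        lc_with_reduced.append((seq, obs))
    groups = pairing.pair_antibody(
        lc_with_reduced,
        hc_pairings,
        whole_masses,
        disulfide_count=cfg.disulfide_count,
        whole_tol_ppm=cfg.whole_tol_ppm,
    )
    for g in groups:
        ann = pairing.annotate_terminal_mods(
            g.lc_sequence, g.lc_observed_reduced, tol=2.0, average=True
        )
        if ann:
            g.annotations.extend(f"LC:{name}" for name in ann)

    result = PipelineResult(cfg, subunits, hc_pairings, groups, warnings)
    if out:
        _write_reports(out, result)
    return result


def _write_reports(out: Path, result: PipelineResult):
    report = {
        "subunits": [
            {
                "mass": m,
                "mass_mode": "monoisotopic",
                "type": r.winner_type,
                "sequence": r.sequence,
                "md_matches": r.md_matches,
                "md_coverage": r.md_coverage,
                "n_corrections": len([c for c in r.corrections if c.decision == "accepted"]),
                "il_flagged": r.il_flagged,
            }
            for m, r in result.subunits.items()
        ],
        "antibody_groups": [
            {
                "lc_mass": g.lc_mass,
                "hc_expected": g.hc.combined_mass,
                "hc_observed_reduced": g.hc.observed_reduced,
                "hc_ppm": g.hc.ppm,
                "whole_expected": g.expected_whole,
                "whole_observed": g.observed_whole,
                "whole_ppm": g.whole_ppm,
                "whole_mass_mode": "average",
            }
            for g in result.groups
        ],
        "warnings": result.warnings,
    }
    io.write_json(out / "report.json", report)
    with open(out / "corrections.tsv", "w") as fh:
        fh.write("subunit_mass\tposition\toriginal\treplacement\tsupport\tdecision\n")
        for m, r in result.subunits.items():
            for c in r.corrections:
                fh.write(
                    f"{m:.3f}\t{c.position}\t{c.original}\t{c.replacement}\t"
                    f"{c.support}\t{c.decision}\n"
                )
    with open(out / "pairing.tsv", "w") as fh:
        fh.write(
            "group\tchain\tsubunit_mass\treduced_mass\treduced_ppm\twhole_mass\twhole_ppm\n"
        )
        for k, g in enumerate(result.groups, 1):
            fh.write(
                f"AB{k}\tHC\t{g.hc.fd_mass:.2f}+{g.hc.fc_mass:.2f}\t"
                f"{g.hc.observed_reduced:.2f}\t{g.hc.ppm:.1f}\t"
                f"{g.observed_whole:.2f}\t{g.whole_ppm:.1f}\n"
            )
            fh.write(
                f"AB{k}\tLC\t{g.lc_mass:.2f}\t{g.lc_observed_reduced:.2f}\t"
                f"{g.lc_ppm:.1f}\t\t\n"
            )


def evaluate_against_truth(result: PipelineResult, chain_set) -> dict:
    """Score a pipeline result against the simulator's ground truth.

    Each sequenced subunit is matched to the truth chain nearest in mass;
    returns per-chain residue accuracy, the median accuracy, and the
    fraction of true LC-HC pairings recovered.
    """
    per_chain = {}
    for sm, r in result.subunits.items():
        if not r.sequence:
            continue
        truth = min(chain_set.chains, key=lambda c: abs(c.mono_mass - sm))
        acc = metrics.residue_accuracy(r.sequence, truth.sequence)
        per_chain[truth.name] = {
            "accuracy": acc,
            "type_correct": truth.subunit_type == r.winner_type,
            "md_coverage": r.md_coverage,
        }
    accs = sorted(v["accuracy"] for v in per_chain.values())
    median = accs[len(accs) // 2] if accs else 0.0
    if accs and len(accs) % 2 == 0:
        median = (accs[len(accs) // 2 - 1] + accs[len(accs) // 2]) / 2

    # true pairing recovered: some reported group joins that antibody's
    # LC and HC (matched through observed masses within tolerance)
    recovered = 0
    n_true = 0
    for ab in chain_set.antibodies:
        hc_mass = ab.hc_avg_mass
        for lc in ab.lcs:
            n_true += 1
            for g in result.groups:
                if (
                    abs(g.hc.combined_mass - hc_mass) <= 8.0
                    and abs(g.lc_mass - lc.avg_mass) <= 8.0
                ):
                    recovered += 1
                    break
    return {
        "per_chain": per_chain,
        "median_accuracy": median,
        "n_sequenced": len(per_chain),
        "pairing_recall": recovered / n_true if n_true else 0.0,
        "n_groups": len(result.groups),
    }
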