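"""Pipeline configuration: every tolerance and default in one place."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the sequencing pipeline.

    Masses in Da, tolerances in Da or ppm as named, RT in minutes.
    Serializes losslessly to/from JSON; every run logs its resolved config.
    """

    # assembly DP
    dp_width: float = 0.1               # mass discretization (Da)
    dp_capacity: int = 10               # bounded priority-queue size
    subunit_mass_tol: float = 4.0       # terminal/merge mass window (Da)
    end_penalty: float = 5.0
    top_k: int = 10
    low_conf_threshold: float = 0.5
    # bottom-up filtering / graph
    min_alc: float = 0.7
    max_low_conf_run: int = 4
    min_overlap_blocks: int = 3
    # middle-down
    md_tol_ppm: float = 50.0
    precursor_tol_ppm: float = 50.0
    # intact
    rt_window: float = 0.1              # scan merge window (min)
    mz_merge_tol: float = 0.01          # Th
    link_tol_ppm_subunit: float = 20.0
    link_tol_ppm_whole: float = 100.0
    min_consecutive_charges: int = 3
    min_consecutive_scans: int = 3
    inclusion_per_mass: int = 4
    # pairing
    hc_mass_tol: float = 4.0
    whole_tol_ppm: float = 100.0
    disulfide_count: int = 16
    enzyme: str = "IdeS"
    # refinement
    refine_min_support: int = 2
    refine_top_k: int = 5
    # misc
    min_subunit_abundance: float = 0.01
    seed: int = 0

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig(**data)
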