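"""Run configuration: a flat, fully serialised record of every knob.

A RunConfig is written verbatim into each output directory so any run
can be regenerated from its outputs alone.  Unknown keys are rejected
rather than ignored — silent typos in a config are how irreproducible
ensembles happen.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    base_seed: int = 0
    pseudocount_mode: str = "background-split"
    motif_width: int = 10
    replicates: int = 100
    n_sample: int = 50
    n_control_sets: int = 10
    kmer_k: int = 8
    collapse_revcomp: bool = False
    em_restarts: int = 5
    em_tol: float = 1e-6
    em_maxiter: int = 200
    em_pseudocount: float = 0.25
    gd_learning_rate: float = 0.05
    gd_tol: float = 1e-8
    gd_maxiter: int = 100000
    chip_top_n: int = 1000
    chip_n_bins: int = 4
    pbm_bin_spec: str = "default"   # "default" (disjoint) or "raw" (as printed)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def replace(self, **overrides) -> "RunConfig":
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
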