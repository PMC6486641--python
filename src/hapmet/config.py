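"""Pipeline configuration: every tunable constant with its default.

Defaults are the published/derived values the rest of the package uses;
a YAML config file can override any field, and CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    # haplotype score model
    score_intercept: float = 0.6927
    score_slope: float = 0.1203
    signal_offset: float = 35.0
    min_snps: int = 5
    ratio_factor: float = 3.0
    # methylation
    prior_p0: float = 0.5
    max_gap: int = 11
    nanopore_threshold: float = 0.36
    bisulfite_threshold: float = 0.5
    # recombination
    window_size: int = 100_000
    minsplit: int = 5
    cp: float = 0.1
    # DMR calling
    p_threshold: float = 1e-5
    min_sites: int = 3
    min_len: int = 50
    merge_gap: int = 100
    min_frac_significant: float = 0.5
    top_k_dmrs: int = 400

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        out = PipelineConfig(**{f.name: getattr(self, f.name) for f in fields(self)})
        for k, v in kwargs.items():
            if v is not None:
                setattr(out, k, v)
        return out
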