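"""Every tunable threshold of the pipeline, with the published defaults.

The calling thresholds (0.25 mean log2 for the interval-score arm, +/-1.0
for the segmentation arm, 3 consecutive probes, 1 kb minimum length,
|median|/MAD >= 2, cn-LOH span > 1.5 Mb, 50% overlap rules, and the qPCR
ratio bands 0.6 / 0.8 / 1.2 / 1.4) are the study's stated analysis
settings; the permutation and score defaults are this package's choices
and are documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class CbsParams:
    """Circular binary segmentation arm."""

    alpha: float = 0.01
    n_permutations: int = 1000
    min_probes: int = 3
    gain_cutoff: float = 1.0
    loss_cutoff: float = -1.0
    madr_min: float = 2.0
    seed: int = 0
    perm_block: int = 100
    exact_max_probes: int = 256
    grid_ratio: float = 1.29

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not (self.loss_cutoff < 0 < self.gain_cutoff):
            raise ValueError("cutoffs must straddle zero with symmetric signs")


@dataclass
class AdmParams:
    """Quality-weighted interval-score (ADM-2-analog) arm."""

    score_threshold: float = 6.0
    min_abs_mean_log2: float = 0.25
    min_probes: int = 3
    min_length_bp: int = 1000
    probe_error: float | None = None  # global sd; None -> robust estimate

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")


@dataclass
class RohParams:
    """Run-of-homozygosity detection on the SNP genotype channel."""

    min_snp: int = 25
    het_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.min_snp < 1:
            raise ValueError("min_snp must be >= 1")
        if not 0 <= self.het_tolerance < 1:
            raise ValueError("het_tolerance must lie in [0, 1)")


@dataclass
class CnLohParams:
    min_length_bp: int = 1_500_000  # strict: a run must span MORE than this


@dataclass
class CopyStateThresholds:
    """qPCR ratio bands for categorical copy-state calls."""

    loss_below: float = 0.6
    two_copy_low: float = 0.8
    two_copy_high: float = 1.2
    gain_above: float = 1.4

    def __post_init__(self) -> None:
        if not (self.loss_below < self.two_copy_low < self.two_copy_high < self.gain_above):
            raise ValueError("thresholds must satisfy loss < low < high < gain")


@dataclass
class PipelineParams:
    """Aggregate of every stage's parameters plus the global seed."""

    cbs: CbsParams = field(default_factory=CbsParams)
    adm: AdmParams = field(default_factory=AdmParams)
    roh: RohParams = field(default_factory=RohParams)
    cnloh: CnLohParams = field(default_factory=CnLohParams)
    qpcr: CopyStateThresholds = field(default_factory=CopyStateThresholds)
    novelty_overlap: float = 0.5
    recurrence_overlap: float = 0.5
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineParams":
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineParams":
        kwargs = dict(raw)
        for name, sub in (
            ("cbs", CbsParams),
            ("adm", AdmParams),
            ("roh", RohParams),
            ("cnloh", CnLohParams),
            ("qpcr", CopyStateThresholds),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown pipeline parameters: {sorted(unknown)}")
        return cls(**kwargs)
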