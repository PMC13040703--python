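"""Analysis configuration with the study's default thresholds."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml


@dataclasses.dataclass
class AnalysisConfig:
    """Thresholds and tuning parameters shared by all pipeline stages.

    Parameters
    ----------
    beta : int
        Soft-thresholding power applied to |Spearman rho| when building the
        weighted network adjacency.
    min_module_size : int
        Smallest feature count a detected module may have; smaller clusters
        are assigned to the background (module 0).
    merge_cut_height : float
        Modules whose eigengene dissimilarity ``1 - cor(ME_a, ME_b)`` falls
        below this height are merged.
    marked_lfc : float
        |log2 fold change| threshold of the "marked change" filter for
        differential features.
    marked_alpha : float
        BH-adjusted p-value threshold of the marked-change filter.
    axis_rho : float
        |Spearman rho| threshold for gut-to-liver axis edges.
    lefse_alpha : float
        Kruskal-Wallis screening level of the LDA effect-size ranking.
    lefse_boot : int
        Number of bootstrap rounds for the LDA effect size.
    permanova_nperm : int
        Number of label permutations for PERMANOVA.
    rng_seed : int
        Seed for every stochastic stage (bootstraps, permutations).
    """

    beta: int = 4
    min_module_size: int = 30
    merge_cut_height: float = 0.2
    marked_lfc: float = 2.5
    marked_alpha: float = 0.05
    axis_rho: float = 0.6
    lefse_alpha: float = 0.05
    lefse_boot: int = 30
    permanova_nperm: int = 999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.beta, (int,)) and self.beta >= 1):
            raise ValueError(f"beta must be a positive integer, got {self.beta!r}")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError(
                f"merge_cut_height must lie in (0, 1), got {self.merge_cut_height}"
            )
        if self.marked_lfc < 0:
            raise ValueError("marked_lfc must be non-negative")
        if not 0.0 < self.marked_alpha < 1.0:
            raise ValueError("marked_alpha must lie in (0, 1)")
        if not 0.0 < self.axis_rho <= 1.0:
            raise ValueError(f"axis_rho must lie in (0, 1], got {self.axis_rho}")
        if not 0.0 <= self.lefse_alpha <= 1.0:
            raise ValueError("lefse_alpha must lie in [0, 1]")
        if self.lefse_boot < 1:
            raise ValueError("lefse_boot must be >= 1")
        if self.permanova_nperm < 99:
            raise ValueError("permanova_nperm must be >= 99")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
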