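"""Sampler configuration and package-wide defaults.

All tunables of the hierarchy sampler live here so that runs are fully
reproducible from a seed plus a config.  Defaults follow the method's
standard settings: tree height limit 5, at most 25 discriminating columns
per node, at least 50 sequences per leaf, at least 7 bits of discriminating
information per node, node-assignment priors 0.25 (root) / 0.70 (reject) /
0.05 shared by the rest, geometric node-count factor 0.99, pattern prior
0.1, and a 95 %-identity purge for subgroup realignment.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class SamplerConfig:
    seed: int = 0
    # model-structure limits
    height_limit: int = 5
    max_patterns: int = 25
    min_leaf_sequences: int = 50
    min_node_bits: float = 7.0
    # priors
    root_prior: float = 0.25
    reject_prior: float = 0.70
    other_prior_total: float = 0.05
    geometric_factor: float = 0.99
    pattern_prior: float = 0.1
    set_prior_decay: float = 0.4
    alpha_grid: tuple = (0.02, 0.05, 0.1, 0.15, 0.2, 0.3)
    alpha_beta_b: float = 9.0  # Beta(1, b) prior on contamination
    # MSA stage
    msa_sweeps: int = 10
    msa_refine_sweeps: int = 3
    architecture_rounds: int = 4
    gap_anneal_start: float = 0.15
    path_bits_per_seq: float = 0.25
    # annealing / convergence
    initial_temperature: float = 2.0
    cooling: float = 0.95
    min_temperature: float = 0.05
    max_cycles: int = 120
    patience: int = 20  # stop after this many cycles without >= tol improvement
    improvement_tol: float = 0.1
    burn_in_sweeps: int = 20
    # subgroup refinement
    outer_rounds: int = 5  # hierarchy-sampling <-> subgroup-realignment rounds
    purge_identity: float = 0.95
    refine_architecture: bool = True

    def __post_init__(self) -> None:
        if self.height_limit < 1 or self.max_patterns < 1:
            raise ValueError("height and pattern limits must be positive")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.initial_temperature <= 0:
            raise ValueError("initial temperature must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SamplerConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "alpha_grid" in data:
            data["alpha_grid"] = tuple(data["alpha_grid"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["alpha_grid"] = list(data["alpha_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)
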