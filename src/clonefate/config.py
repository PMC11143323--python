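"""Run configuration: every load-bearing threshold, named and overridable.

The configuration is a flat key-value mapping (YAML on disk).  Unknown
keys fail validation before any stage runs; a resolved copy is written
next to the outputs of a pipeline run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Union

import yaml

PathLike = Union[str, os.PathLike]


@dataclass
class RunConfig:
    # presence / clonality
    detect_threshold: float = 0.01
    clonal_threshold: float = 0.9
    proportion_tolerance: float = 0.05
    # tumor splitting
    ubiquitous_vaf: float = 0.01
    min_shared_mutations: int = 10
    linkage_method: str = "complete"
    scale_vafs: bool = False
    # SNV / indel filters
    snv_dual_caller_vaf: float = 0.02
    snv_single_caller_vaf: float = 0.05
    snv_somatic_p: float = 0.01
    snv_min_depth: int = 30
    snv_min_alt_reads: int = 10
    germline_max_alt_reads: int = 5
    germline_max_vaf: float = 0.01
    rescue_min_vaf: float = 0.01
    indel_somatic_p: float = 0.001
    indel_min_depth: int = 50
    dinucleotide_alpha: float = 0.05
    # copy-number metrics
    loh_min_het_snps: int = 10
    loh_minor_cn_threshold: float = 0.1
    wgd_major_cn: float = 2.0
    wgd_genome_fraction: float = 0.5
    msai_denominator: str = "both"
    # cohort procedures
    bin_size: int = 5_000_000
    bin_min_count: int = 5
    bin_max_count: int = 0  # 0 = no upper bound
    downsample_iterations: int = 5000
    # engrafting-clone walk
    include_subclonal_tip: bool = True
    # global
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
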