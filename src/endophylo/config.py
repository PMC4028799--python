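"""Pipeline configuration: every fixed threshold lives here.

Defaults reflect the published workflow this package automates: read
recruitment at BLAST-style E <= 0.1, mitochondrial contig identification at
E <= 0.001 with at most five gap openings in read confirmation, de Bruijn
hash lengths 39-51 with a 200 bp contig floor, ~400 bp paired-end inserts
from 100-900 bp fragments, and 1,000 bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    recruit_evalue: float = 0.1
    mt_evalue: float = 0.001
    kmer_min: int = 39
    kmer_max: int = 51
    min_contig_len: int = 200
    bootstrap_reps: int = 1000
    max_gap_openings: int = 5
    insert_size_bp: int = 400
    fragment_min_bp: int = 100
    fragment_max_bp: int = 900
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recruit_evalue", "mt_evalue", "kmer_min", "kmer_max",
                     "min_contig_len", "bootstrap_reps", "max_gap_openings",
                     "insert_size_bp", "fragment_min_bp", "fragment_max_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.kmer_min > self.kmer_max:
            raise ValueError("kmer_min must be <= kmer_max")
        if self.kmer_min % 2 == 0 or self.kmer_max % 2 == 0:
            raise ValueError("k-mer bounds must be odd")
        if not (self.fragment_min_bp <= self.insert_size_bp <= self.fragment_max_bp):
            raise ValueError("need fragment_min_bp <= insert_size_bp <= fragment_max_bp")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
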