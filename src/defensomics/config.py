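"""Pipeline configuration: thresholds, paths, and the master seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """Every fixed constant of the pipeline in one validated record.

    Thresholds default to the survey's operating point: homology identity
    0.65 with both-sided coverage 0.8, a ±5-gene neighborhood window,
    high-quality completeness cutoff 0.90, phyla with at least 10 genomes,
    a 3% prevalence floor for per-system models, and a top-20 core
    defensome per domain.
    """

    output_dir: str = "defensomics_out"
    refdb_path: str | None = None
    genomes_dir: str | None = None
    hit_table_path: str | None = None
    call_table_path: str | None = None
    metadata_path: str | None = None

    min_identity: float = 0.65
    min_coverage: float = 0.8
    window: int = 5
    alpha: float = 0.05
    hq_completeness: float = 0.90
    min_phylum_n: int = 10
    core_k: int = 20
    prevalence_floor: float = 0.03
    rm_name_prefixes: tuple[str, ...] = ("RM", "restriction")
    seed: int = 0

    # simulation conditions
    n_genomes: int = 60
    planted_identity: float = 0.75
    completeness: float = 1.0
    n_decoys: int = 12
    refdb_per_role: int = 2
    stat_cohort: bool = True  # also emit a cohort-level statistical table

    def __post_init__(self) -> None:
        checks = [
            ("min_identity", 0.0 < self.min_identity <= 1.0),
            ("min_coverage", 0.0 < self.min_coverage <= 1.0),
            ("window", self.window >= 1),
            ("alpha", 0.0 < self.alpha < 1.0),
            ("hq_completeness", 0.0 < self.hq_completeness <= 1.0),
            ("min_phylum_n", self.min_phylum_n >= 1),
            ("core_k", self.core_k >= 1),
            ("prevalence_floor", 0.0 <= self.prevalence_floor < 1.0),
            ("n_genomes", self.n_genomes >= 1),
            ("planted_identity", 0.0 < self.planted_identity <= 1.0),
            ("completeness", 0.0 < self.completeness <= 1.0),
            ("seed", self.seed >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid config field {name!r} = {getattr(self, name)}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "rm_name_prefixes" in data:
            data["rm_name_prefixes"] = tuple(data["rm_name_prefixes"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rm_name_prefixes"] = list(self.rm_name_prefixes)
        return d

    def write_sidecar(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the scientific configuration (manifest key).

        Filesystem locations are excluded: the same study conditions hash
        identically wherever the outputs land.
        """
        d = self.to_dict()
        for key in ("output_dir", "refdb_path", "genomes_dir", "hit_table_path",
                    "call_table_path", "metadata_path"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
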