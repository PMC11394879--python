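"""Run configuration: every tunable default of the pipeline in one record.

Each CLI run embeds its configuration (plus a content hash) in the output so
that stochastic probe sampling can be reproduced exactly from the artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    # coarse-graining / network
    scheme: str = "calpha"
    cutoff: float = 13.0
    gamma: float = 1.0
    gamma_AB: float | None = None     # None: equal to gamma
    # surface probes
    layer_offsets: list[float] = field(default_factory=lambda: [4.0, 6.0])
    target_spacing: float = 2.0
    seed: int = 0
    # perturbation
    gamma_s: float | None = None      # None: equal to gamma
    r_int: float = 6.0
    # cluster prediction
    top_fraction: float = 0.10
    linkage_cutoff: float = 3.5
    min_cluster_size: int = 5
    # evaluation
    r_cutoff: float = 3.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self, **extra) -> dict:
        from . import __version__
        return {"config": self.to_dict(), "config_hash": self.hash(),
                "version": __version__, **extra}
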