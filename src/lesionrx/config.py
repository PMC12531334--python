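"""Run configuration: one structured file drives the whole pipeline.

Every pipeline stage is a deterministic function of the RunConfig (all
stage seeds derive from ``master_seed``), so the config hash plus the
package version suffice to replay any grid cell bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    # world / cohort
    dims: tuple = (24, 24, 24)
    n_networks: int = 4
    n_patients: int = 400
    lesion_size_range: tuple = (20, 400)
    # parcellation
    K: int = 4
    terms_per_network: int = 5
    term_noise_sd: float = 0.1
    term_effect: float = 1.0
    min_component_vox: int = 64
    # ground truth
    overlap_threshold: float = 0.05
    disconnectome_threshold: float = 0.5
    # grid levels
    networks: tuple = (1,)
    criteria: tuple = ("receptome",)
    rep_kinds: tuple = ("lesion",)
    te_levels: tuple = (0.9,)
    re_levels: tuple = (0.1,)
    b_obs_levels: tuple = (0.0, 0.8)
    b_unobs_levels: tuple = ()
    # representations / learners
    embedding_methods: tuple = ("PCA",)
    embedding_dims: tuple = (10,)
    baselines: tuple = ("atlas",)
    meta_learners: tuple = ("T",)
    base_algorithms: tuple = ("extremely_randomized_trees",)
    # evaluation
    k_folds: int = 10
    master_seed: int = 0

    def __post_init__(self):
        for name in ("overlap_threshold", "disconnectome_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("te_levels", "re_levels", "b_obs_levels", "b_unobs_levels"):
            if any(not 0.0 <= v <= 1.0 for v in getattr(self, name)):
                raise ValueError(f"all {name} must lie in [0, 1]")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str) -> None:
        from .io import atomic_write

        data = asdict(self)
        atomic_write(
            path, lambda tmp: open(tmp, "w").write(yaml.safe_dump(data))
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key, val in data.items():
            if isinstance(val, list):
                data[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in val
                )
        return cls(**data)
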