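"""Pipeline configuration and the deterministic seed-forking scheme.

Every stage draws its randomness from ``fork_seed(base_seed, stage_name)``
so partial reruns reproduce full runs bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Per-algorithm selection thresholds for the two classification tasks.
#: Default is 0.7; the exceptions follow the attribute-evaluation rules
#: used in the original analysis.
SELECTION_THRESHOLDS: dict[str, dict[str, float]] = {
    "organism_groups": {
        "default": 0.7,
        "deviation": 0.8,
        "pca": 0.8,
        "gini_index": 0.6,
        "info_gain": 0.6,
        "uncertainty": 0.6,
    },
    "isoforms": {
        "default": 0.7,
        "chi_square": 0.6,
        "rule": 0.6,
        "uncertainty": 0.6,
        "relief": 0.5,
        "deviation": 0.26,
    },
}


def fork_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the pipeline seed.

    CRC32 of the stage name XORed into the base seed, truncated below
    2**31 so downstream RNGs accept it.
    """
    return (int(base_seed) ^ zlib.crc32(stage.encode("utf8"))) & 0x7FFFFFFF


@dataclass
class TreeParams:
    """Pre-pruning and ensemble hyperparameters for tree induction."""

    max_depth: int | None = 20
    minimal_gain: float | None = 0.01
    min_leaf: int = 2
    forest_size: int = 100
    # feature-subset size for random trees; None means ceil(sqrt(p))
    subset_size: int | None = None


@dataclass
class SiteDef:
    """A reference coordinate and the dipeptide states of interest there."""

    position: int
    states: tuple[str, ...]


DEFAULT_SITES: tuple[SiteDef, ...] = (
    SiteDef(142, ("GC",)),
    SiteDef(208, ("GC",)),
    SiteDef(702, ("GC",)),
    SiteDef(41, ("DH", "EH")),
    SiteDef(431, ("FK", "FL", "FQ")),
    SiteDef(451, ("KC", "KF")),
)


@dataclass
class PipelineConfig:
    sd_threshold: float = 0.1
    correlation_threshold: float = 0.9
    selection_thresholds: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in SELECTION_THRESHOLDS.items()}
    )
    tree_params: TreeParams = field(default_factory=TreeParams)
    cv_folds: int = 10
    random_seed: int = 0
    reference_fasta: str | None = None
    sites: tuple[SiteDef, ...] = DEFAULT_SITES

    def __post_init__(self) -> None:
        for name, val in (
            ("sd_threshold", self.sd_threshold),
            ("correlation_threshold", self.correlation_threshold),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["sites"] = [
            {"position": s.position, "states": list(s.states)} for s in self.sites
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        sites = tuple(
            SiteDef(d["position"], tuple(d["states"])) for d in payload.pop("sites", [])
        ) or DEFAULT_SITES
        tp = payload.pop("tree_params", None)
        cfg = cls(**payload, sites=sites)
        if tp:
            cfg.tree_params = TreeParams(**tp)
        return cfg
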