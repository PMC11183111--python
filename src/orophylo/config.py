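"""Pipeline configuration: paths, engine options and stage toggles."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

DEFAULT_INTERACTIONS = ["landform:TCQ", "landform:PREC", "landform:PCQ"]
DEFAULT_RESPONSES = ["log_SR", "PD", "PDI", "NRI", "NTI",
                     "MDT", "MDT_oldest", "MDT_youngest"]


@dataclass
class PipelineConfig:
    """Everything one run of the pipeline needs.

    All randomness flows from ``seed``: each stochastic stage derives a
    named substream from it, so a rerun with the same config reproduces
    every numeric output bitwise.
    """

    tree: str
    matrix: str
    predictors: str
    output_dir: str
    checklist: str | None = None
    sister_map: str | None = None
    age_constraints: str | None = None
    matrix_orientation: str = "sites-in-rows"

    ses_engine: str = "auto"
    n_rand: int = 999
    seed: int = 0
    pd_include_root: bool = False
    knn_k: int = 8
    interactions: list[str] = field(default_factory=lambda: list(DEFAULT_INTERACTIONS))
    reference_levels: dict[str, str] = field(
        default_factory=lambda: {"landform": "Danxia", "tectonic": "craton"})
    responses: list[str] = field(default_factory=lambda: list(DEFAULT_RESPONSES))

    run_build_tree: bool = True
    run_metrics: bool = True
    run_ages: bool = True
    run_tests: bool = True
    run_fit: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for section in ("paths", "engine", "stages"):
            sub = raw.pop(section, {}) or {}
            if section == "stages":
                sub = {f"run_{k}": v for k, v in sub.items()}
            flat.update(sub)
        flat.update(raw)
        return cls(**flat)

    def validate_paths(self) -> None:
        for name in ("tree", "matrix", "predictors",
                     "checklist", "sister_map", "age_constraints"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} path does not exist: {value}")

    def to_dict(self) -> dict:
        return asdict(self)

    def substream(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the config seed."""
        import hashlib

        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)
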