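"""Pipeline configuration: every stage parameter with its default, strict
validation on load, and echoing of the resolved config into output dirs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All stage parameters.  Defaults reproduce the reference analysis:
    3 discarded volumes, 22-TR windows stepped by 1 TR, 25-TR averaging,
    0.01-0.15 Hz fifth-order band-pass, k searched over 2-10, 33 k-means
    replicates with 4000 max iterations, and 100,000 permutations."""

    # preprocessing
    n_discard: int = 3
    regress_motion: bool = False
    mad_threshold: float = 4.0
    low_hz: float = 0.01
    high_hz: float = 0.15
    filter_order: int = 5
    tr_seconds: float = 2.0
    # features
    swc_window: int = 22
    swc_step: int = 1
    aswc_window: int = 25
    # state model
    k_min: int = 2
    k_max: int = 10
    k_override: int | None = None
    replicates: int = 33
    estimate_replicates: int = 10
    max_iter: int = 4000
    # inference
    n_perm: int = 100_000
    alpha: float = 0.05
    # synthetic cohort
    n_per_group: int = 17
    n_components: int = 53
    n_volumes: int = 225
    k_true: int = 4
    separation: float = 0.9
    mean_dwell_target: float = 40.0
    noise_sd: float = 0.3
    group_effect: float = 0.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if not (0 < self.low_hz < self.high_hz < 0.5 / self.tr_seconds):
            raise ValueError("need 0 < low_hz < high_hz < Nyquist")
        if self.swc_window < 2 or self.aswc_window < 1:
            raise ValueError("window lengths too small")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_perm < 1 or not (0 < self.alpha < 1):
            raise ValueError("invalid inference parameters")

    @classmethod
    def from_file(cls, path: Path | str) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def echo(self, out_dir: Path | str) -> None:
        """Write the fully resolved config into an output directory."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "resolved_config.json").write_text(json.dumps(self.to_dict(), indent=2) + "\n")
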