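"""Run configuration: validated container plus YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import yaml

from .model import VARIANT_NAMES, ModelParams
from .variants import validate_variant_params

__all__ = ["RunConfig", "RECORDER_NAMES", "load_config", "save_config"]

RECORDER_NAMES = (
    "events",
    "sad",
    "diversity",
    "waves",
    "jumps",
    "snapshots",
    "heatmap",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    N: int
    gamma: float
    n_steps: int
    seed: Union[int, List[int]] = 0
    variant: str = "basic"
    variant_params: dict = field(default_factory=dict)
    equalize_at_wave_start: bool = False
    wave_threshold: Optional[float] = None
    substantial_threshold: float = 1e-10
    burn_in: Optional[int] = None  # None -> 10 N
    bins_per_decade: int = 5
    recorders: Sequence[str] = ("events", "sad", "diversity", "waves")
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_NAMES:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANT_NAMES}"
            )
        validate_variant_params(self.variant, self.variant_params)
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma!r}")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        burn = self.effective_burn_in
        if burn < 0 or self.n_steps <= burn:
            raise ValueError(
                f"need n_steps > burn_in >= 0, got n_steps={self.n_steps}, "
                f"burn_in={burn}"
            )
        if not self.recorders:
            raise ValueError("at least one recorder must be enabled")
        for name in self.recorders:
            if name not in RECORDER_NAMES:
                raise ValueError(
                    f"unknown recorder {name!r}; expected one of {RECORDER_NAMES}"
                )
        self.recorders = list(self.recorders)

    @property
    def effective_burn_in(self) -> int:
        return 10 * self.N if self.burn_in is None else int(self.burn_in)

    @property
    def seeds(self) -> List[int]:
        return [self.seed] if isinstance(self.seed, int) else list(self.seed)

    def to_model_params(self, seed: Optional[int] = None) -> ModelParams:
        return ModelParams(
            N=self.N,
            gamma=self.gamma,
            variant=self.variant,
            variant_params=dict(self.variant_params),
            equalize_at_wave_start=self.equalize_at_wave_start,
            seed=self.seeds[0] if seed is None else seed,
            wave_threshold=self.wave_threshold,
            substantial_threshold=self.substantial_threshold,
        )

    def to_dict(self) -> dict:
        return asdict(self)


_FIELDS = set(RunConfig.__dataclass_fields__)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Read and validate a YAML run configuration.

    Unknown keys are rejected with a message naming the key; constraint
    violations raise ``ValueError``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; "
            f"allowed: {sorted(_FIELDS)}"
        )
    return RunConfig(**raw)


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Write the canonical YAML form (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
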