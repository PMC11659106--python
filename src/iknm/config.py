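"""Analysis configuration: every pipeline constant in one place.

The defaults encode the measurement conventions the analyses assume:
10-min trajectory sampling, the 10% pause/onset speed threshold, 2-μm
arrival tolerance, 1-hr MSD fit window, 99 CSR simulations with a 3-hr
cumulation span in a 100×100 μm window, 2-μm depth slabs, and 10-μm
pulse-chase bins.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import yaml

from .core import ValidationError

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    sampling_interval: float = 10.0  # min
    pause_threshold_fraction: float = 0.1
    arrival_tolerance_um: float = 2.0
    msd_fit_window_min: float = 60.0
    msd_sampling_interval: float = 6.0  # min, lateral-drift movies
    ripley_nsims: int = 99
    ripley_span_min: float = 180.0
    window_um: tuple = (100.0, 100.0)
    depth_bins_um: float = 2.0
    pulse_bin_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.window_um = tuple(float(v) for v in self.window_um)
        self.validate()

    def validate(self) -> None:
        positive = [
            ("sampling_interval", self.sampling_interval),
            ("pause_threshold_fraction", self.pause_threshold_fraction),
            ("arrival_tolerance_um", self.arrival_tolerance_um),
            ("msd_fit_window_min", self.msd_fit_window_min),
            ("msd_sampling_interval", self.msd_sampling_interval),
            ("ripley_nsims", self.ripley_nsims),
            ("ripley_span_min", self.ripley_span_min),
            ("depth_bins_um", self.depth_bins_um),
            ("pulse_bin_um", self.pulse_bin_um),
        ]
        for name, value in positive:
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if len(self.window_um) != 2 or any(v <= 0 for v in self.window_um):
            raise ValidationError(f"invalid window {self.window_um!r}")
        if int(self.seed) != self.seed:
            raise ValidationError("seed must be an integer")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_um"] = list(self.window_um)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    # -- reproducibility --------------------------------------------------

    def config_hash(self) -> str:
        """Stable short hash of the canonical configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def child_seed(self, stage: str) -> int:
        """Fan the global seed out to a stable per-stage seed (< 2³¹).

        Stages draw from independent streams so adding or reordering one
        stage never perturbs another.
        """
        ss = np.random.SeedSequence([int(self.seed), zlib.crc32(stage.encode())])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
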