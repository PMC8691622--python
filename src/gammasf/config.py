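"""Run configuration: the analysis settings, their published defaults, and
a stable digest for provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .model import DEFAULT_BAND_WINDOWS, DEFAULT_SNR_THRESHOLD


@dataclass
class RunConfig:
    # multitaper: time-bandwidth product 3, 5 tapers, 300-2000 ms window
    nw: float = 3.0
    k: int = 5
    window: tuple[float, float] = (0.3, 2.0)
    freq_range: tuple[float, float] = (20.0, 120.0)
    band_windows: dict = field(default_factory=lambda: dict(DEFAULT_BAND_WINDOWS))
    snr_threshold: float = DEFAULT_SNR_THRESHOLD
    fit_restarts: int = 20
    decoder_split: tuple[float, float, float] = (0.60, 0.15, 0.25)
    lambda_min: float = 0.001
    lambda_max: float = 40.0
    lambda_points: int = 20
    n_boot: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls().to_dict()
        unknown = sorted(set(raw) - set(known))
        if unknown:
            raise ValueError(f"invalid config keys: {', '.join(unknown)}")
        for key in ("window", "freq_range", "decoder_split"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "band_windows" in raw:
            raw["band_windows"] = {k: tuple(v) for k, v in raw["band_windows"].items()}
        return cls(**raw)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list)), fh)
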