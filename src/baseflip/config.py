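"""Run configuration shared by the command-line pipeline.

Defaults embed the protocol constants: 5° PMF windows, 0.001 kcal/mol hills
of 2 bin-widths, 3/6/9 Å success thresholds and the 15 Å retention cutoff.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class RunConfig:
    scheme: str = "CPD"
    thresholds: tuple[float, float, float] = (3.0, 6.0, 9.0)  # Å
    retention_cutoff: float = 15.0                            # Å
    bin_width: float = 5.0                                    # degrees
    hill_weight: float = 0.001                                # kcal/mol
    hill_width_bins: float = 2.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        hi, med, low = self.thresholds
        if not (0 < hi < med < low):
            raise ValueError("thresholds must be strictly increasing")
        if self.retention_cutoff < low:
            raise ValueError("retention cutoff must be >= largest threshold")
        if self.scheme not in ("CPD", "CPDa", "CPDb"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "thresholds" in data:
            data["thresholds"] = tuple(data["thresholds"])
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)
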