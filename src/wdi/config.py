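"""Pipeline configuration with YAML round-tripping.

Every analysis constant is surfaced here — there are no magic numbers in
the code paths.  Defaults follow the published analysis protocol:
30 Hz imaging, neuropil coefficient 0.7 measured in a 40 µm ring,
ΔF/F baseline of 60 pre-trial frames, post-stimulus epochs 33–233 /
233–1000 / 1000–3600 ms with the peak inside the 1 s reward window, and
lick-triggered windows 100–33 ms pre / 33–167 ms post against a
1200–466 ms pre-lick baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    frame_rate: float = 30.0
    px_size_um: float = 1.0
    a_neuropil: float = 0.7
    ring_radius_um: float = 40.0
    n_baseline_frames: int = 60
    quiet_window_s: float = 3.0
    reward_window_s: float = 1.0
    epoch_windows_ms: dict = field(
        default_factory=lambda: {
            "early": [33.0, 233.0],
            "late": [233.0, 1000.0],
            "very_late": [1000.0, 3600.0],
        }
    )
    peak_window_ms: list = field(default_factory=lambda: [0.0, 1000.0])
    lick_pre_ms: list = field(default_factory=lambda: [-100.0, -33.0])
    lick_post_ms: list = field(default_factory=lambda: [33.0, 167.0])
    lick_baseline_ms: list = field(default_factory=lambda: [-1200.0, -466.0])
    xcorr_normalization: str = "coeff"
    xcorr_max_lag: int = 30
    seed: int = 0
    # simulation scale (used when no input data are supplied)
    n_mice: int = 6
    n_days: int = 3
    n_s2p: int = 30
    n_m1p: int = 30
    session_length_s: float = 600.0
    # paths
    input_dir: str | None = None
    out_dir: str = "wdi_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
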