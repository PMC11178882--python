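"""Run configuration: a fully serialisable description of a pipeline run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (with the inputs)."""

    seed: int = 0
    protocol_id: int = 5
    protocol_duration_ms: float | None = None   # protocol-5 length override
    frame_rate_hz: float = 500.0
    pixel_size_um: float = 0.5
    roi_shape: tuple[int, int] = (64, 64)
    power_density_mw_um2: float = 0.88
    spot_fwhm_um: float = 12.0
    n_cells: int = 1
    expression_F0: float = 100.0
    background: float = 10.0
    snr_threshold: float = 5.0
    match_tolerance_ms: float = 5.0
    motion_sigmas: tuple[float, float, float] = (1.0, 5.0, 5.0)
    motion_corr_threshold: float = 0.5
    motion_displacement_floor_px: float = 0.5
    run_thermal: bool = True
    thermal_power_mw: float = 75.0
    thermal_duration_s: float = 30.0
    out_dir: str = "scanvolt_out"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # surfaces the camera row budget early, before any rendering
        from .synthetic import max_rows_at_rate
        cap = max_rows_at_rate(self.frame_rate_hz)
        if self.roi_shape[0] > cap:
            raise ValueError(
                f"{self.roi_shape[0]} movie rows exceed the {cap}-row cap "
                f"at {self.frame_rate_hz:g} Hz (266 rows at 1 kHz)")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["roi_shape"] = list(self.roi_shape)
        d["motion_sigmas"] = list(self.motion_sigmas)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["roi_shape"] = tuple(d.get("roi_shape", (64, 64)))
        d["motion_sigmas"] = tuple(d.get("motion_sigmas", (1.0, 5.0, 5.0)))
        return cls(**d)

    def digest(self) -> str:
        """Stable hash of the scientific configuration (output paths
        excluded, so identical runs hash identically wherever written)."""
        d = asdict(self)
        d.pop("out_dir")
        d["roi_shape"] = list(self.roi_shape)
        d["motion_sigmas"] = list(self.motion_sigmas)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
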