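"""Run configuration: defaults, TOML loading, and the manifest hash.

Every numeric default equals the value the pipeline stages document (filter
band 0.5--20 Hz with measured -3 dB at 0.61/19.89 Hz, 90 µV / 500 ms
rejection, 10-trial minimum, 1.5 SD spindle threshold, 0.5--5 s duration
bounds, <0.5 s merge gap, 11--16 Hz search band).  Values from a TOML file
override the defaults; explicit keyword/CLI values override the file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "nadsleep_out"
    # simulation
    n_subjects: int = 85
    n_nap: int = 48
    n_wake: int = 37
    language_version: int = 1
    noise_rms_uv: float = 25.0
    artifact_prob: float = 0.3
    spindle_density_per_min: float = 5.0
    spindle_p2p_mean_uv: float = 40.0
    sleep_background_rms_uv: float = 15.0
    # ERP pipeline
    rejection_threshold_uv: float = 90.0
    rejection_window_ms: float = 500.0
    min_trials: int = 10
    epoch_window_ms: tuple[float, float] = (-100.0, 1000.0)
    # spindle detector
    spindle_search_band_hz: tuple[float, float] = (11.0, 16.0)
    spindle_threshold_sd: float = 1.5
    spindle_duration_bounds_s: tuple[float, float] = (0.5, 5.0)
    spindle_merge_gap_s: float = 0.5
    roi_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_subjects != self.n_nap + self.n_wake:
            raise ConfigurationError(
                f"n_subjects ({self.n_subjects}) must equal n_nap + n_wake "
                f"({self.n_nap} + {self.n_wake})")

    def hash(self) -> str:
        """Stable digest of the full configuration (recorded in manifests)."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, an optional TOML file, and overrides
    (in increasing precedence)."""
    values: dict = {}
    if path is not None:
        raw = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("epoch_window_ms", "spindle_search_band_hz",
                "spindle_duration_bounds_s"):
        if key in values:
            values[key] = tuple(values[key])
    try:
        return RunConfig(**values)
    except TypeError as e:
        raise ConfigurationError(str(e)) from e
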