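"""Analysis configuration shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Union

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable settings of the analysis.

    Attributes
    ----------
    cutoff_ms : float
        Early/visual latency cut-off on the IS clock; saccades with
        ``lat_is_ms <= cutoff_ms`` are early.  Default 170 ms.
    cutoff_method : str
        "fixed" uses ``cutoff_ms`` as-is; "breakpoint" estimates the cut-off
        from the cumulative latency curve and falls back to ``cutoff_ms``.
    alpha : float
        Significance level for every test.  Default 0.01.
    kernel_bandwidth_ms : float
        Gaussian kernel standard deviation for latency densities, ms.
    grid_step_ms : float
        Density grid resolution, ms.
    em_tol, em_max_iter, em_restarts : EM convergence settings.
    min_sample_per_fit : int
        Minimum early-saccade count for a per-duration mixture fit; smaller
        cells fall back to a pooled fit.
    max_visual_latency_ms : float
        Saccades later than this on the IS clock are treated as failures.
    markov_screen_alpha : float
        Level of the per-subject Markov-property screen (subjects failing it
        are excluded from pooled transition fits).
    ci_level : float
        Level of per-cell transition-probability confidence intervals.
    seed : int
        Master seed; all stage randomness derives from it.
    """

    cutoff_ms: float = 170.0
    cutoff_method: str = "fixed"
    alpha: float = 0.01
    kernel_bandwidth_ms: float = 40.0
    grid_step_ms: float = 1.0
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    em_restarts: int = 5
    min_sample_per_fit: int = 30
    max_visual_latency_ms: float = 1000.0
    markov_screen_alpha: float = 0.05
    ci_level: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cutoff_ms > 0:
            raise ValueError("cutoff_ms must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.kernel_bandwidth_ms <= 0:
            raise ValueError("kernel_bandwidth_ms must be > 0")

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**known)
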