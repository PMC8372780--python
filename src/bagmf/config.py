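"""Run configuration: YAML file plus programmatic overrides."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import yaml

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

ANALYSIS_MODES = ("mc", "boot", "bag")


@dataclass
class RunConfig:
    """Settings for one analysis run.

    Times are given in ns at this layer and converted to seconds where
    the numerics need them.  ``fixed_tau_m_residues`` lists inclusive
    [start, end] residue ranges whose overall correlation time is pinned
    at ``tau_m_fixed_ns`` instead of being fitted locally.
    """

    input: str | None = None
    output_dir: str = "."
    mode: str = "bag"
    seed: int = 0
    n_monte_carlo: int = 500
    tau_m_fixed_ns: float = 17.5
    fixed_tau_m_residues: list[list[int]] = dc_field(default_factory=list)
    timescale_threshold_ns: float = 0.15
    tau_m_bounds_ns: tuple[float, float] = (1.0, 100.0)
    j0_error_mode: str = "jackknife"
    smoothed_sd_normalization: str = "efron"
    dump_ensemble: bool = False
    constants: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ANALYSIS_MODES:
            raise ValueError(f"mode must be one of {ANALYSIS_MODES}")
        if self.timescale_threshold_ns <= 0:
            raise ValueError("timescale threshold must be > 0")
        if self.mode == "mc" and self.n_monte_carlo < 2:
            raise ValueError("n_monte_carlo must be >= 2 for mc mode")
        self.tau_m_bounds_ns = tuple(self.tau_m_bounds_ns)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def physical_constants(self) -> PhysicalConstants:
        return (
            DEFAULT_CONSTANTS.with_overrides(**self.constants)
            if self.constants
            else DEFAULT_CONSTANTS
        )

    def tau_m_fixed_for(self, residue: int) -> float | None:
        """Pinned tau_m (seconds) for this residue, or None if fitted."""
        for lo, hi in self.fixed_tau_m_residues:
            if lo <= residue <= hi:
                return self.tau_m_fixed_ns * 1e-9
        return None

    def to_dict(self) -> dict:
        return asdict(self)
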