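"""Run configuration with per-mode defaults.

The three supported library layouts are single-end WGBS, paired-end WGBS,
and paired-end NOMe-seq.  Feasibility thresholds (minimum overlap K0,
CpG/isolated-CpG/isolated-GpC counts K1-K3), conversion rates, the
genotype-prior weight q, and the noise-filter constants a/b all default
per mode and can be overridden individually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .model import ConversionParams

log = logging.getLogger(__name__)

MODES = ("wgbs-single", "wgbs-paired", "nome")

#: per-mode defaults: (K0, K1, K2, K3, filter_a, filter_b)
_MODE_DEFAULTS = {
    "wgbs-single": (40, 1, 0, 0, 5_000, 20_000),
    "wgbs-paired": (50, 2, 0, 0, 10_000, 28_500),
    # the noise filter was calibrated on paired WGBS; paired NOMe reuses it
    "nome": (40, 0, 0, 2, 10_000, 28_500),
}


@dataclass(frozen=True)
class FeasibilityParams:
    """Minimum requirements for adding a read to an existing chain."""

    K0: int  # overlap in bp
    K1: int  # CpG sites in the overlap
    K2: int  # isolated CpG sites in the overlap
    K3: int  # isolated GpC sites in the overlap

    def __post_init__(self) -> None:
        if min(self.K0, self.K1, self.K2, self.K3) < 0:
            raise ValueError("feasibility thresholds must be non-negative")


@dataclass(frozen=True)
class PriorParams:
    """Genotype prior confidence weight; q=0.5 disables reference guidance."""

    q: float = 0.9999

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")


@dataclass(frozen=True)
class ModelConfig:
    mode: str = "wgbs-paired"
    conversion_rate: float = 0.95  # bisulfite conversion success rate
    beta: float = 0.05  # inappropriate conversion rate
    K0: int = 50
    K1: int = 2
    K2: int = 0
    K3: int = 0
    q: float = 0.9999
    filter_a: float = 10_000.0
    filter_b: float = 28_500.0
    pass_limit: int = 50
    use_db: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @classmethod
    def from_mode(cls, mode: str, **overrides) -> "ModelConfig":
        """Per-mode defaults (overridable field by field)."""
        if mode not in _MODE_DEFAULTS:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        K0, K1, K2, K3, a, b = _MODE_DEFAULTS[mode]
        cfg = cls(mode=mode, K0=K0, K1=K1, K2=K2, K3=K3, filter_a=a, filter_b=b)
        return replace(cfg, **overrides) if overrides else cfg

    @property
    def nome(self) -> bool:
        return self.mode == "nome"

    @property
    def paired(self) -> bool:
        return self.mode in ("wgbs-paired", "nome")

    @property
    def conversion(self) -> ConversionParams:
        return ConversionParams(self.conversion_rate, self.beta)

    @property
    def feasibility(self) -> FeasibilityParams:
        return FeasibilityParams(self.K0, self.K1, self.K2, self.K3)

    @property
    def prior(self) -> PriorParams:
        return PriorParams(self.q)

    def log_settings(self) -> None:
        log.info(
            "conversion success rate %.4g (failed-conversion rate %.4g), "
            "inappropriate rate %.4g",
            self.conversion_rate,
            1.0 - self.conversion_rate,
            self.beta,
        )
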