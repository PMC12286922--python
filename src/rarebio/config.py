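"""Run configuration: analysis thresholds and generator settings.

All relative abundances are fractions in [0, 1] internally; percentages
appear only in rendered reports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

__all__ = ["RunConfig", "EventSpec", "GeneratorConfig"]


@dataclass
class EventSpec:
    """A disturbance to plant in the synthetic series.

    ``during_index`` is the 0-based chronological position of the disturbed
    sample; the preceding sample serves as pre-disturbance reference and the
    following one (when it exists) as post-disturbance.
    """

    event_id: str
    during_index: int
    n_rare_to_abun: int = 8
    n_abun_to_rare: int = 5
    fold_up: float = 30.0
    fold_down: float = 50.0


@dataclass
class GeneratorConfig:
    """Study conditions emulated by the synthetic community generator.

    Defaults mirror a coastal time series: ~200 genomospecies jointly
    mapping 12% of the reads (field range 5--18%), 19 samples over
    3 seasons x 3 years, a log-normal abundance distribution whose
    top-ranked MAG sits near 3% of the community, and seasonal preference
    vectors drawn from symmetric Dirichlets (near-uniform for generalists,
    concentrated for specialists).
    """

    n_mags: int = 200
    n_samples: int = 19
    seasons: Tuple[str, ...] = ("winter", "spring", "summer")
    years: Tuple[int, ...] = (2011, 2012, 2013)
    sad_meanlog: float = 0.0
    sad_sdlog: float = 2.0
    total_mapped_fraction: float = 0.12
    frac_generalists: float = 1.0 / 3.0
    frac_specialists: float = 1.0 / 3.0
    generalist_concentration: float = 20.0
    specialist_concentration: float = 0.8
    intermediate_concentration: float = 3.0
    events: Optional[Sequence[EventSpec]] = None
    genome_equivalents: float = 2302.6
    genome_length: int = 20000
    dispersion: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_generalists + self.frac_specialists > 1 + 1e-12:
            raise ValueError("frac_generalists + frac_specialists must be <= 1")
        if self.n_mags < 3 or self.n_samples < 2:
            raise ValueError("need at least 3 MAGs and 2 samples")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for conc in (
            self.generalist_concentration,
            self.specialist_concentration,
            self.intermediate_concentration,
        ):
            if conc <= 0:
                raise ValueError("Dirichlet concentrations must be positive")
        if not 0 < self.total_mapped_fraction <= 1:
            raise ValueError("total_mapped_fraction must be in (0, 1]")
        if self.genome_equivalents <= 0:
            raise ValueError("genome_equivalents must be positive")

    def default_events(self) -> list[EventSpec]:
        """Two mid-series disturbances whose pre/during pair shares a sub-type."""
        if self.events is not None:
            return list(self.events)
        candidates = [i for i in (10, 16) if 1 <= i < self.n_samples]
        return [
            EventSpec(event_id=f"E{j + 1}", during_index=i)
            for j, i in enumerate(candidates)
        ]


@dataclass
class RunConfig:
    """Analysis thresholds; defaults follow the field calibration.

    ``default_threshold`` (0.1% relative abundance) and
    ``breadth_abundant_cutoff`` (90%) delineate abundant populations;
    ``detection_breadth`` (10%) is the reliable-detection floor; detected
    per-sample thresholds are clamped to ``threshold_clamp`` (0.08--0.2%).
    """

    breadth_abundant_cutoff: float = 0.90
    detection_breadth: float = 0.10
    default_threshold: float = 0.001
    threshold_clamp: Tuple[float, float] = (0.0008, 0.002)
    sad_model: str = "loglog"
    q_basis: str = "cells"
    chao1_bias_corrected: bool = True
    rng_seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        for name in ("breadth_abundant_cutoff", "detection_breadth", "default_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        lo, hi = self.threshold_clamp
        if not (0 < lo <= hi < 1):
            raise ValueError("threshold_clamp must satisfy 0 < lo <= hi < 1")
        if not lo <= self.default_threshold <= hi:
            raise ValueError("threshold_clamp must contain default_threshold")
        if self.sad_model not in ("loglog", "semilog"):
            raise ValueError("sad_model must be 'loglog' or 'semilog'")
        if self.q_basis not in ("cells", "samples"):
            raise ValueError("q_basis must be 'cells' or 'samples'")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["threshold_clamp"] = list(self.threshold_clamp)
        gen = out["generator"]
        gen["seasons"] = list(gen["seasons"])
        gen["years"] = list(gen["years"])
        if gen["events"] is not None:
            gen["events"] = [dict(e) if isinstance(e, dict) else e for e in gen["events"]]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        gen = data.pop("generator", None)
        if gen is not None:
            gen = dict(gen)
            if gen.get("events"):
                gen["events"] = [EventSpec(**e) for e in gen["events"]]
            gen["seasons"] = tuple(gen.get("seasons", ("winter", "spring", "summer")))
            gen["years"] = tuple(gen.get("years", (2011, 2012, 2013)))
            data["generator"] = GeneratorConfig(**gen)
        if "threshold_clamp" in data:
            data["threshold_clamp"] = tuple(data["threshold_clamp"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
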