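"""Core in-memory containers shared across the pipeline.

The central object is :class:`CoverageMatrix`, a MAG-by-sample table of
TAD80 depth, breadth of coverage and (once normalized) relative abundance,
backed by aligned :class:`pandas.DataFrame` blocks. Sample metadata travels
as a list of :class:`SampleInfo`; disturbance events as
:class:`DisturbanceEvent`.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageMatrix",
    "SampleInfo",
    "DisturbanceEvent",
    "MagQuality",
    "samples_to_frame",
]


class CoverageMatrix:
    """Dense MAG x sample coverage table.

    Parameters
    ----------
    depth
        TAD80 depth (mean mapped-read depth after 10%/10% truncation),
        indexed by MAG id with one column per sample. Non-negative.
    breadth
        Fraction of genome positions covered by at least one read, in
        ``[0, 1]``, aligned with ``depth``.
    rel_abund
        Optional relative abundance (fraction of the community), populated
        by ``coverage.normalize_matrix``. Aligned with ``depth``.

    Absent (MAG, sample) pairs are materialized as depth 0 / breadth 0:
    downstream math treats non-detection as zero abundance.
    """

    def __init__(
        self,
        depth: pd.DataFrame,
        breadth: pd.DataFrame,
        rel_abund: Optional[pd.DataFrame] = None,
    ) -> None:
        depth = depth.astype(float)
        breadth = breadth.astype(float)
        if not depth.index.equals(breadth.index) or not depth.columns.equals(
            breadth.columns
        ):
            raise ValueError("depth and breadth must share index and columns")
        if depth.index.has_duplicates or depth.columns.has_duplicates:
            raise ValueError("duplicate MAG or sample identifiers")
        if (depth.to_numpy() < 0).any():
            raise ValueError("negative depth values")
        b = breadth.to_numpy()
        if (b < 0).any() or (b > 1).any():
            raise ValueError("breadth values outside [0, 1]")
        zero_depth = depth.to_numpy() == 0
        if (b[zero_depth] != 0).any():
            raise ValueError("breadth must be 0 wherever depth is 0")
        if rel_abund is not None:
            rel_abund = rel_abund.astype(float)
            if not rel_abund.index.equals(depth.index) or not rel_abund.columns.equals(
                depth.columns
            ):
                raise ValueError("rel_abund must align with depth")
        self.depth = depth
        self.breadth = breadth
        self.rel_abund = rel_abund

    @property
    def mag_ids(self) -> list:
        return list(self.depth.index)

    @property
    def sample_ids(self) -> list:
        return list(self.depth.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    def require_rel_abund(self) -> pd.DataFrame:
        if self.rel_abund is None:
            raise ValueError(
                "relative abundance not populated; run coverage.normalize_matrix first"
            )
        return self.rel_abund

    def to_long(self) -> pd.DataFrame:
        """Long-format view with one row per (MAG, sample) pair."""
        out = self.depth.stack().rename("tad80").reset_index()
        out.columns = ["mag_id", "sample_id", "tad80"]
        out["breadth"] = self.breadth.stack().to_numpy()
        if self.rel_abund is not None:
            out["rel_abund"] = self.rel_abund.stack().to_numpy()
        return out.sort_values(["mag_id", "sample_id"], ignore_index=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageMatrix):
            return NotImplemented
        same = self.depth.equals(other.depth) and self.breadth.equals(other.breadth)
        if self.rel_abund is None or other.rel_abund is None:
            return same and self.rel_abund is None and other.rel_abund is None
        return same and self.rel_abund.equals(other.rel_abund)

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self.shape
        tag = "normalized" if self.rel_abund is not None else "raw"
        return f"CoverageMatrix({n} MAGs x {m} samples, {tag})"


@dataclass(frozen=True)
class SampleInfo:
    """One metagenome sample.

    ``main_type`` is the season (habitat main category); ``sub_type``
    refines it by year (``season_year``). ``genome_equivalents`` is the
    sequencing effort expressed as total base pairs over the average
    community genome size, the denominator converting depth to relative
    abundance.
    """

    sample_id: str
    date: datetime.date
    main_type: str
    sub_type: str
    genome_equivalents: float
    event_id: Optional[str] = None
    event_role: Optional[str] = None

    def __post_init__(self) -> None:
        if self.genome_equivalents <= 0:
            raise ValueError(
                f"sample {self.sample_id}: genome_equivalents must be positive"
            )
        if self.event_role not in (None, "pre", "during", "post"):
            raise ValueError(
                f"sample {self.sample_id}: event_role must be pre|during|post"
            )


def samples_to_frame(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    """Tabular view of sample metadata, preserving input (chronological) order."""
    frame = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "date": [s.date for s in samples],
            "main_type": [s.main_type for s in samples],
            "sub_type": [s.sub_type for s in samples],
            "genome_equivalents": [s.genome_equivalents for s in samples],
            "event_id": [s.event_id for s in samples],
            "event_role": [s.event_role for s in samples],
        }
    )
    sub_to_main = frame.groupby("sub_type")["main_type"].nunique()
    if (sub_to_main > 1).any():
        bad = sub_to_main[sub_to_main > 1].index.tolist()
        raise ValueError(f"sub_type(s) {bad} map to more than one main_type")
    return frame


@dataclass(frozen=True)
class DisturbanceEvent:
    """A disturbance sampled as (pre, during[, post]) metagenomes."""

    event_id: str
    pre_sample: str
    during_sample: str
    post_sample: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        ids = [self.pre_sample, self.during_sample]
        if self.post_sample is not None:
            ids.append(self.post_sample)
        if len(set(ids)) != len(ids):
            raise ValueError(
                f"event {self.event_id}: pre/during/post samples must be distinct"
            )


@dataclass(frozen=True)
class MagQuality:
    """CheckM-style quality record on the fractional scale.

    ``quality_score = completeness - 5*contamination + 0.5*strain_heterogeneity``.
    """

    mag_id: str
    completeness: float
    contamination: float
    strain_heterogeneity: float = 0.0
    quality_score: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 1:
            raise ValueError(
                f"MAG {self.mag_id}: completeness {self.completeness} outside [0, 1]"
            )
        if self.contamination < 0:
            raise ValueError(f"MAG {self.mag_id}: negative contamination")
        if not 0 <= self.strain_heterogeneity <= 1:
            raise ValueError(
                f"MAG {self.mag_id}: strain heterogeneity outside [0, 1]"
            )
        score = (
            self.completeness
            - 5.0 * self.contamination
            + 0.5 * self.strain_heterogeneity
        )
        if np.isnan(self.quality_score):
            object.__setattr__(self, "quality_score", score)
        elif abs(self.quality_score - score) > 1e-6:
            raise ValueError(
                f"MAG {self.mag_id}: quality_score {self.quality_score} inconsistent "
                f"with completeness - 5*contamination + 0.5*strain_heterogeneity = {score}"
            )
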