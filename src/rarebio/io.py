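"""Readers and writers for the pipeline's tab-separated formats.

Inputs: a long-format coverage table (MAG id, sample id, TAD80 depth,
breadth), sample metadata, a CheckM-style MAG quality table, a disturbance
event table, and optionally samtools-depth-style per-base depth TSVs.
Outputs are deterministic TSVs (fixed column order, rows sorted by
mag_id then sample_id, fixed float precision) so runs are diffable.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CoverageMatrix, DisturbanceEvent, SampleInfo

__all__ = [
    "SchemaError",
    "COVERAGE_DIALECT",
    "read_coverage_table",
    "write_coverage_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_mag_quality",
    "read_events",
    "write_events",
    "read_per_base_depths",
    "read_counts_table",
    "write_results",
]

ALLOWED_SEASONS = ("winter", "spring", "summer")

#: default column-name dialect for the long coverage table; override the
#: values to ingest e.g. CoverM genome output ("Genome", "Trimmed Mean"...)
COVERAGE_DIALECT = {
    "mag_id": "mag_id",
    "sample_id": "sample_id",
    "depth": "tad80",
    "breadth": "breadth",
}


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


def _require_columns(frame: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_coverage_table(
    path: str | Path, dialect: Optional[Mapping[str, str]] = None
) -> CoverageMatrix:
    """Read a long-format coverage TSV into a dense :class:`CoverageMatrix`.

    Absent (MAG, sample) pairs become depth 0 / breadth 0. ``dialect`` maps
    the canonical keys ``mag_id``/``sample_id``/``depth``/``breadth`` to the
    file's actual column names.
    """
    names = dict(COVERAGE_DIALECT)
    if dialect:
        names.update(dialect)
    frame = pd.read_csv(path, sep="\t", dtype={names["mag_id"]: str, names["sample_id"]: str})
    _require_columns(frame, list(names.values()), path)
    frame = frame.rename(columns={v: k for k, v in names.items()})

    for row, depth, brd in zip(frame.index, frame["depth"], frame["breadth"]):
        line = row + 2  # 1-based, counting the header
        if not np.isfinite(depth) or depth < 0:
            raise SchemaError(f"{path}:{line}: invalid depth {depth}")
        if not np.isfinite(brd) or not 0 <= brd <= 1:
            raise SchemaError(f"{path}:{line}: breadth {brd} outside [0, 1]")
        if depth == 0 and brd != 0:
            raise SchemaError(f"{path}:{line}: breadth {brd} with zero depth")
    dup = frame.duplicated(subset=["mag_id", "sample_id"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise SchemaError(f"{path}:{line}: duplicate (mag_id, sample_id) pair")

    depth = frame.pivot(index="mag_id", columns="sample_id", values="depth")
    brd = frame.pivot(index="mag_id", columns="sample_id", values="breadth")
    depth = depth.fillna(0.0).sort_index().sort_index(axis=1)
    brd = brd.fillna(0.0).sort_index().sort_index(axis=1)
    depth.index.name = depth.columns.name = None
    brd.index.name = brd.columns.name = None
    return CoverageMatrix(depth, brd)


def write_coverage_table(matrix: CoverageMatrix, path: str | Path) -> Path:
    """Write the long-format coverage table (only detected pairs)."""
    long = matrix.to_long()
    long = long[long["tad80"] > 0].reset_index(drop=True)
    out = long[["mag_id", "sample_id", "tad80", "breadth"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def read_sample_metadata(
    path: str | Path, allowed_seasons: Sequence[str] = ALLOWED_SEASONS
) -> list[SampleInfo]:
    """Read sample metadata, synthesizing ``sub_type`` as ``season_year``
    when absent. File order (assumed chronological) is preserved."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(frame, ["sample_id", "date", "season", "year", "genome_equivalents"], path)
    samples = []
    for row in frame.itertuples():
        line = row.Index + 2
        season = str(row.season)
        if season not in allowed_seasons:
            raise SchemaError(
                f"{path}:{line}: unknown season {season!r}; allowed: {list(allowed_seasons)}"
            )
        ge = float(row.genome_equivalents)
        if not ge > 0:
            raise SchemaError(f"{path}:{line}: genome_equivalents must be positive")
        sub_type = getattr(row, "sub_type", None)
        if sub_type is None or (isinstance(sub_type, float) and np.isnan(sub_type)):
            sub_type = f"{season}_{int(row.year)}"
        event_id = getattr(row, "event_id", None)
        event_role = getattr(row, "event_role", None)
        if isinstance(event_id, float) and np.isnan(event_id):
            event_id = None
        if isinstance(event_role, float) and np.isnan(event_role):
            event_role = None
        samples.append(
            SampleInfo(
                sample_id=str(row.sample_id),
                date=pd.Timestamp(row.date).date(),
                main_type=season,
                sub_type=str(sub_type),
                genome_equivalents=ge,
                event_id=event_id,
                event_role=event_role,
            )
        )
    return samples


def write_sample_metadata(samples: Sequence[SampleInfo], path: str | Path) -> Path:
    rows = []
    for s in samples:
        season, _, year = s.sub_type.rpartition("_")
        rows.append(
            {
                "sample_id": s.sample_id,
                "date": s.date.isoformat(),
                "season": s.main_type,
                "year": year if season == s.main_type else s.date.year,
                "genome_equivalents": s.genome_equivalents,
                "sub_type": s.sub_type,
                "event_id": s.event_id or "",
                "event_role": s.event_role or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def read_mag_quality(path: str | Path) -> pd.DataFrame:
    """Read a CheckM-style quality table.

    Accepts either canonical column names (mag_id, completeness,
    contamination, strain_heterogeneity) or CheckM's ("Bin Id",
    "Completeness", "Contamination", "Strain heterogeneity").
    """
    frame = pd.read_csv(path, sep="\t")
    renames = {
        "Bin Id": "mag_id",
        "Completeness": "completeness",
        "Contamination": "contamination",
        "Strain heterogeneity": "strain_heterogeneity",
    }
    frame = frame.rename(columns=renames)
    _require_columns(frame, ["mag_id", "completeness", "contamination"], path)
    if "strain_heterogeneity" not in frame:
        frame["strain_heterogeneity"] = 0.0
    frame["strain_heterogeneity"] = frame["strain_heterogeneity"].fillna(0.0)
    return frame[["mag_id", "completeness", "contamination", "strain_heterogeneity"]]


def read_events(path: str | Path) -> list[DisturbanceEvent]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, ["event_id", "pre", "during"], path)
    events = []
    for row in frame.itertuples():
        post = getattr(row, "post", None)
        if post is not None and (pd.isna(post) or post == ""):
            post = None
        description = getattr(row, "description", "") or ""
        if pd.isna(description):
            description = ""
        events.append(
            DisturbanceEvent(
                event_id=str(row.event_id),
                pre_sample=str(row.pre),
                during_sample=str(row.during),
                post_sample=post,
                description=str(description),
            )
        )
    return events


def write_events(events: Sequence[DisturbanceEvent], path: str | Path) -> Path:
    frame = pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "pre": [e.pre_sample for e in events],
            "during": [e.during_sample for e in events],
            "post": [e.post_sample or "" for e in events],
            "description": [e.description for e in events],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_per_base_depths(
    path: str | Path, genome_length: Optional[int] = None
) -> dict[str, np.ndarray]:
    """Parse a samtools-depth-style TSV (contig, 1-based position, depth).

    Positions absent from the file are zero-depth only when
    ``genome_length`` is supplied; otherwise the vector holds the reported
    positions only.
    """
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "pos", "depth"],
        dtype={"contig": str, "pos": int, "depth": float},
    )
    out: dict[str, np.ndarray] = {}
    for contig, grp in frame.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy()
        if (pos < 1).any():
            raise SchemaError(f"{path}: non-positive position for contig {contig}")
        if genome_length is not None:
            if pos.max() > genome_length:
                raise SchemaError(
                    f"{path}: position {pos.max()} beyond genome_length {genome_length}"
                )
            vec = np.zeros(genome_length, dtype=float)
            vec[pos - 1] = grp["depth"].to_numpy()
        else:
            vec = grp.sort_values("pos")["depth"].to_numpy(dtype=float)
        out[str(contig)] = vec
    return out


def read_counts_table(path: str | Path) -> pd.Series:
    """Read a (category, count) TSV for the diversity estimators."""
    frame = pd.read_csv(path, sep="\t", dtype={"category": str})
    _require_columns(frame, ["category", "count"], path)
    return pd.Series(frame["count"].to_numpy(dtype=int), index=frame["category"])


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write named result tables as deterministic TSVs.

    Rows are sorted by mag_id then sample_id when those columns exist;
    floats are rendered with fixed precision so identical runs produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        table = table.copy()
        sort_cols = [c for c in ("mag_id", "sample_id", "event_id") if c in table.columns]
        if sort_cols:
            table = table.sort_values(sort_cols, kind="mergesort", ignore_index=True)
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[name] = path
    return paths
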