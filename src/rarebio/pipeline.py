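"""End-to-end orchestration: normalize -> rarity -> transitions -> niche
(-> diversity), with a JSON run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .config import RunConfig
from .containers import CoverageMatrix, DisturbanceEvent, SampleInfo, samples_to_frame
from .coverage import normalize_matrix
from .io import write_results
from .niche import classify_niche
from .rarity import RarityClassifier
from .transitions import assess_recovery, classify_transitions, recovery_summary

__all__ = ["run_all"]

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sad_fit_row(sample_id: str, threshold: float, fit) -> dict:
    row = {"sample_id": sample_id, "threshold": threshold}
    if fit is None:
        return row
    row.update(
        {
            "model": fit.model,
            "intercept": fit.intercept,
            "slope": fit.slope,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
            "breakpoint_rank": fit.breakpoint_rank,
            "breakpoint_abund": fit.breakpoint_abund,
            "used_default": fit.used_default,
        }
    )
    return row


def run_all(
    matrix: CoverageMatrix,
    samples: Sequence[SampleInfo],
    out_dir: str | Path,
    events: Optional[Sequence[DisturbanceEvent]] = None,
    config: Optional[RunConfig] = None,
    input_paths: Optional[dict] = None,
) -> dict[str, Path]:
    """Run every stage and write all result tables plus the manifest.

    The transitions stage is skipped with a logged notice when no events
    are supplied (the analyses are separable). On a stage failure, partial
    outputs are preserved alongside a FAILED marker file.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}

    try:
        t0 = time.perf_counter()
        if matrix.rel_abund is None:
            matrix = normalize_matrix(matrix, samples)
        timings["normalize"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        clf = RarityClassifier(
            breadth_abundant_cutoff=config.breadth_abundant_cutoff,
            detection_breadth=config.detection_breadth,
            default_threshold=config.default_threshold,
            threshold_clamp=config.threshold_clamp,
            sad_model=config.sad_model,
        )
        calls = clf.fit_predict(matrix)
        tables["rarity_calls"] = calls
        tables["sample_thresholds"] = pd.DataFrame(
            [
                _sad_fit_row(sid, float(clf.thresholds_[sid]), clf.sad_fits_[sid])
                for sid in matrix.sample_ids
            ]
        )
        timings["rarity"] = time.perf_counter() - t0

        if events:
            t0 = time.perf_counter()
            records = assess_recovery(classify_transitions(calls, events))
            tables["transitions"] = records
            tables["transition_summary"] = recovery_summary(records)
            timings["transitions"] = time.perf_counter() - t0
        else:
            logger.info("no disturbance events supplied; skipping transitions stage")

        t0 = time.perf_counter()
        tables["niche_profiles"] = classify_niche(
            matrix, samples, q_basis=config.q_basis,
            detection_breadth=config.detection_breadth,
        )
        timings["niche"] = time.perf_counter() - t0

        tables["samples"] = samples_to_frame(samples)
        paths = write_results(tables, out_dir)
    except Exception:
        write_results(tables, out_dir)
        (out_dir / "FAILED").write_text("pipeline failed; partial outputs preserved\n")
        raise

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "n_mags": matrix.shape[0],
        "n_samples": matrix.shape[1],
        "stage_timings_s": {k: round(v, 4) for k, v in timings.items()},
        "inputs": {
            name: _digest(Path(p)) for name, p in (input_paths or {}).items()
        },
        "outputs": {name: str(p) for name, p in paths.items()},
    }
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["run_manifest"] = manifest_path
    return paths
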