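"""Rare vs. abundant delineation from per-sample species abundance curves.

Each sample's detected populations are ranked by relative abundance and the
curve is fitted on a log scale (default: ln abundance on ln rank). A
continuous two-segment ("broken-stick") fit is searched exhaustively over
candidate knees; if it beats the single line by BIC, the fitted abundance
at the knee — clamped to the 0.08--0.2% field range — becomes the sample's
rare/abundant threshold, otherwise the 0.1% default is used. A population
is *abundant* when its relative abundance reaches the threshold AND its
genome breadth reaches 90%; it is *undetected* below 10% breadth; anything
else is *rare*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import RunConfig
from .containers import CoverageMatrix, SampleInfo

__all__ = [
    "SadFit",
    "rank_abundance_curve",
    "fit_sad",
    "detect_threshold",
    "RarityClassifier",
    "classify_rarity",
]

logger = logging.getLogger(__name__)

MIN_SEGMENT = 4  # minimum curve points on each side of a candidate knee


@dataclass
class SadFit:
    """A fitted species-abundance model for one sample.

    ``intercept``/``slope``/``r_squared`` describe the single-segment log
    model (R^2 on the regression's own response scale). When a two-segment
    model wins the BIC comparison, ``breakpoint_rank`` and
    ``breakpoint_abund`` locate the knee (fitted abundance at the knee,
    before clamping) and ``slope_after`` is the right-hand segment slope.
    """

    model: str
    intercept: float
    slope: float
    r_squared: float
    n_points: int
    breakpoint_rank: Optional[int] = None
    breakpoint_abund: Optional[float] = None
    slope_after: Optional[float] = None
    used_default: bool = False


def rank_abundance_curve(abundances: pd.Series) -> pd.DataFrame:
    """Rank detected populations by relative abundance (descending).

    Ties are broken by mag_id lexicographic order so output is invariant
    to input order. Returns columns ``rank``, ``mag_id``, ``rel_abund``.
    """
    pos = abundances[abundances > 0]
    if pos.empty:
        raise ValueError("no detected populations (all abundances zero)")
    ordered = pos.sort_index().sort_values(ascending=False, kind="mergesort")
    return pd.DataFrame(
        {
            "rank": np.arange(1, ordered.size + 1),
            "mag_id": ordered.index.to_numpy(),
            "rel_abund": ordered.to_numpy(),
        }
    )


def _transform(curve: pd.DataFrame, model: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.log(curve["rank"].to_numpy(dtype=float))
    if model == "loglog":
        y = np.log(curve["rel_abund"].to_numpy(dtype=float))
    elif model == "semilog":
        y = curve["rel_abund"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown sad model {model!r}")
    return x, y


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_sad(curve: pd.DataFrame, model: str = "loglog") -> SadFit:
    """Ordinary least squares of the (transformed) abundance on ln(rank)."""
    if len(curve) < 3:
        raise ValueError("need at least 3 curve points to fit")
    x, y = _transform(curve, model)
    if np.allclose(y, y[0]):
        raise ValueError("zero variance in response; cannot fit abundance model")
    X = np.column_stack([np.ones_like(x), x])
    coef, sse = _ols(X, y)
    tss = float(((y - y.mean()) ** 2).sum())
    return SadFit(
        model=model,
        intercept=float(coef[0]),
        slope=float(coef[1]),
        r_squared=1.0 - sse / tss,
        n_points=len(curve),
    )


def detect_threshold(
    curve: pd.DataFrame,
    config: Optional[RunConfig] = None,
    model: Optional[str] = None,
) -> tuple[float, SadFit]:
    """Detect the per-sample rare/abundant threshold from the curve's knee.

    Exhaustive search over candidate knees at ranks ``MIN_SEGMENT`` to
    ``n - MIN_SEGMENT`` for the continuous two-segment linear fit (in the
    model's transformed space) minimizing total squared error. The
    two-segment model is accepted only if it improves BIC over the single
    line; the threshold is the fitted abundance at the knee clamped to
    ``config.threshold_clamp``. Curves with fewer than 8 points, or without
    an accepted knee, fall back to ``config.default_threshold``.
    """
    config = config or RunConfig()
    model = model or config.sad_model
    n = len(curve)
    lo, hi = config.threshold_clamp

    if n < 2 * MIN_SEGMENT:
        logger.warning(
            "curve has %d points (< %d); using default threshold %.4g",
            n, 2 * MIN_SEGMENT, config.default_threshold,
        )
        fit = fit_sad(curve, model) if n >= 3 else SadFit(
            model=model, intercept=float("nan"), slope=float("nan"),
            r_squared=float("nan"), n_points=n,
        )
        fit.used_default = True
        return config.default_threshold, fit

    fit = fit_sad(curve, model)
    x, y = _transform(curve, model)
    X1 = np.column_stack([np.ones_like(x), x])
    _, sse1 = _ols(X1, y)
    tss = float(((y - y.mean()) ** 2).sum())
    if sse1 <= 1e-12 * tss:
        # single line already fits to machine precision: no knee exists
        logger.info("curve is exactly linear; default threshold %.4g", config.default_threshold)
        fit.used_default = True
        return config.default_threshold, fit

    best_sse = np.inf
    best = None  # (knee index 0-based, coefficients)
    for k in range(MIN_SEGMENT - 1, n - MIN_SEGMENT):
        hinge = np.maximum(0.0, x - x[k])
        X2 = np.column_stack([X1, hinge])
        coef, sse2 = _ols(X2, y)
        if sse2 < best_sse:
            best_sse, best = sse2, (k, coef)

    eps = np.finfo(float).tiny
    bic1 = n * np.log(max(sse1, eps) / n) + 2.0 * np.log(n)
    bic2 = n * np.log(max(best_sse, eps) / n) + 4.0 * np.log(n)
    if best is None or bic2 >= bic1:
        logger.info("no knee accepted by BIC; default threshold %.4g", config.default_threshold)
        fit.used_default = True
        return config.default_threshold, fit

    k, coef = best
    y_knee = float(coef[0] + coef[1] * x[k])
    knee_abund = float(np.exp(y_knee)) if model == "loglog" else max(y_knee, 0.0)
    fit.breakpoint_rank = int(curve["rank"].iloc[k])
    fit.breakpoint_abund = knee_abund
    fit.slope_after = float(coef[1] + coef[2])
    threshold = float(np.clip(knee_abund, lo, hi))
    if threshold != knee_abund:
        logger.info("knee abundance %.4g clamped to %.4g", knee_abund, threshold)
    return threshold, fit


class RarityClassifier(BaseEstimator):
    """Per-sample rare/abundant/undetected caller.

    scikit-learn-style estimator: ``fit`` detects one threshold per sample
    from its rank-abundance curve; ``predict`` labels every (MAG, sample)
    cell. Fitted attributes: ``thresholds_`` (Series indexed by sample) and
    ``sad_fits_`` (dict of :class:`SadFit`).

    Parameters mirror :class:`rarebio.config.RunConfig`.
    """

    def __init__(
        self,
        breadth_abundant_cutoff: float = 0.90,
        detection_breadth: float = 0.10,
        default_threshold: float = 0.001,
        threshold_clamp: tuple[float, float] = (0.0008, 0.002),
        sad_model: str = "loglog",
    ) -> None:
        self.breadth_abundant_cutoff = breadth_abundant_cutoff
        self.detection_breadth = detection_breadth
        self.default_threshold = default_threshold
        self.threshold_clamp = threshold_clamp
        self.sad_model = sad_model

    def _config(self) -> RunConfig:
        return RunConfig(
            breadth_abundant_cutoff=self.breadth_abundant_cutoff,
            detection_breadth=self.detection_breadth,
            default_threshold=self.default_threshold,
            threshold_clamp=tuple(self.threshold_clamp),
            sad_model=self.sad_model,
        )

    def fit(self, X: CoverageMatrix, y=None) -> "RarityClassifier":
        rel = X.require_rel_abund()
        config = self._config()
        thresholds = {}
        fits = {}
        for sid in X.sample_ids:
            col = rel[sid]
            if (col <= 0).all():
                logger.warning("sample %s: no detected populations; default threshold", sid)
                thresholds[sid] = config.default_threshold
                fits[sid] = None
                continue
            curve = rank_abundance_curve(col)
            thresholds[sid], fits[sid] = detect_threshold(curve, config)
        self.thresholds_ = pd.Series(thresholds, name="threshold")
        self.sad_fits_ = fits
        return self

    def predict(self, X: CoverageMatrix) -> pd.DataFrame:
        """Label every (MAG, sample) cell.

        Returns a long DataFrame with columns mag_id, sample_id, label,
        rel_abund, breadth, threshold_used. Labels partition the cells:
        undetected (breadth below the detection floor), abundant (abundance
        and breadth both at/above their cutoffs), rare (everything else).
        """
        if not hasattr(self, "thresholds_"):
            raise ValueError("RarityClassifier is not fitted")
        rel = X.require_rel_abund()
        rows = []
        for sid in X.sample_ids:
            thr = float(self.thresholds_.get(sid, self.default_threshold))
            ab = rel[sid].to_numpy()
            br = X.breadth[sid].to_numpy()
            label = np.where(
                br < self.detection_breadth,
                "undetected",
                np.where(
                    (ab >= thr) & (br >= self.breadth_abundant_cutoff),
                    "abundant",
                    "rare",
                ),
            )
            rows.append(
                pd.DataFrame(
                    {
                        "mag_id": X.mag_ids,
                        "sample_id": sid,
                        "label": label,
                        "rel_abund": ab,
                        "breadth": br,
                        "threshold_used": thr,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def fit_predict(self, X: CoverageMatrix, y=None) -> pd.DataFrame:
        return self.fit(X).predict(X)


def classify_rarity(
    matrix: CoverageMatrix,
    samples: Optional[Iterable[SampleInfo]] = None,
    config: Optional[RunConfig] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """One-shot wrapper: normalize if needed, fit thresholds, emit calls.

    Returns ``(calls, thresholds)``.
    """
    from .coverage import normalize_matrix

    config = config or RunConfig()
    if matrix.rel_abund is None:
        if samples is None:
            raise ValueError("samples required to normalize depth to relative abundance")
        matrix = normalize_matrix(matrix, samples)
    clf = RarityClassifier(
        breadth_abundant_cutoff=config.breadth_abundant_cutoff,
        detection_breadth=config.detection_breadth,
        default_threshold=config.default_threshold,
        threshold_clamp=config.threshold_clamp,
        sad_model=config.sad_model,
    )
    calls = clf.fit_predict(matrix)
    return calls, clf.thresholds_
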