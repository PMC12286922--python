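"""Niche breadth: proportional similarity, Levins' B, and
generalist/specialist classification.

The proportional similarity (PS) index compares a population's
distribution across habitat categories, ``p_i`` (its relative abundance
summed within category i over its grand sum), with the availability of
those categories, ``q_i``::

    PS = 1 - 0.5 * sum_i |p_i - q_i|

``q`` can weight categories by their share of the summed community
relative abundance ("cells" basis, the default) or by their share of the
sample count ("samples" basis). PS = 1 for the broadest possible niche
(the population tracks availability exactly) and approaches 0 only as a
population is confined to a vanishingly available category.

MAGs are scored at two category levels — season (main type) and
season-by-year (sub-type) — ranked by PS at each level (ascending, average
ties), and labelled: *generalist* when in the top tercile at both levels,
*specialist* when in the bottom tercile at both (subdivided into regular,
rank_sub >= rank_main, and strict, rank_sub < rank_main), otherwise
*intermediate*. MAGs detected in at most one sample are excluded.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import CoverageMatrix, SampleInfo, samples_to_frame

__all__ = [
    "ps_index",
    "levins_breadth",
    "NicheClassifier",
    "classify_niche",
    "ps_null_test",
]

logger = logging.getLogger(__name__)

NICHE_LABELS = (
    "generalist",
    "regular_specialist",
    "strict_specialist",
    "intermediate",
    "excluded",
)


def _category_shares(
    values: pd.Series, category_of: Mapping[str, str], categories: Sequence[str]
) -> np.ndarray:
    cats = pd.Series({s: category_of[s] for s in values.index})
    sums = values.groupby(cats).sum()
    return np.array([float(sums.get(c, 0.0)) for c in categories])


def ps_index(
    mag_abund: pd.Series,
    category_of: Mapping[str, str],
    q_basis: str = "cells",
    community_totals: Optional[pd.Series] = None,
) -> float:
    """Proportional similarity of one population to category availability.

    Parameters
    ----------
    mag_abund
        The population's relative abundance per sample (index: sample ids).
    category_of
        Sample id -> habitat category.
    q_basis
        "cells": q_i is category i's share of the summed community relative
        abundance (requires ``community_totals``); "samples": q_i is its
        share of the sample count.
    community_totals
        Per-sample summed community relative abundance (cells basis only).
    """
    missing = [s for s in mag_abund.index if s not in category_of]
    if missing:
        raise ValueError(f"samples without a category: {missing}")
    total = float(mag_abund.sum())
    if total <= 0:
        raise ValueError("PS undefined: population absent from all samples")
    categories = sorted(set(category_of[s] for s in mag_abund.index))
    p = _category_shares(mag_abund, category_of, categories) / total
    if q_basis == "cells":
        if community_totals is None:
            raise ValueError("community_totals required for q_basis='cells'")
        community_totals = community_totals.loc[mag_abund.index]
        grand = float(community_totals.sum())
        q = _category_shares(community_totals, category_of, categories) / grand
        if (q == 0).any():
            zero = [c for c, v in zip(categories, q) if v == 0]
            raise ValueError(f"category with zero community abundance: {zero}")
    elif q_basis == "samples":
        counts = pd.Series([category_of[s] for s in mag_abund.index]).value_counts()
        q = np.array([counts.get(c, 0) for c in categories], dtype=float)
        q /= q.sum()
    else:
        raise ValueError("q_basis must be 'cells' or 'samples'")
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def levins_breadth(abund_by_category: Sequence[float] | pd.Series) -> tuple[float, float]:
    """Levins' niche breadth B = 1 / sum(p_i^2) and its standardized form
    B_A = (B - 1) / (N - 1) over N habitat categories."""
    a = np.asarray(abund_by_category, dtype=float)
    if a.size < 2:
        raise ValueError("Levins' B needs at least two categories")
    total = a.sum()
    if total <= 0:
        raise ValueError("Levins' B undefined: zero total abundance")
    p = a / total
    b = 1.0 / float((p**2).sum())
    return b, (b - 1.0) / (a.size - 1.0)


def _tercile_bounds(n: int) -> tuple[int, int]:
    t = n // 3
    return t, n - t  # bottom: rank <= t; top: rank > n - t


class NicheClassifier(BaseEstimator):
    """Generalist/specialist classifier from two-level PS indices.

    scikit-learn-style estimator (clustering flavor): ``fit`` computes PS
    at the main-type and sub-type levels, ranks, Levins' B over main types,
    and labels; results live in ``profiles_`` (DataFrame) and ``labels_``.
    """

    def __init__(self, q_basis: str = "cells", detection_breadth: float = 0.10) -> None:
        self.q_basis = q_basis
        self.detection_breadth = detection_breadth

    def fit(self, X: CoverageMatrix, samples: Sequence[SampleInfo]) -> "NicheClassifier":
        rel = X.require_rel_abund()
        meta = samples_to_frame(samples).set_index("sample_id")
        missing = [s for s in X.sample_ids if s not in meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        main_of = meta["main_type"].to_dict()
        sub_of = meta["sub_type"].to_dict()
        community = rel.sum(axis=0)

        detected = (X.breadth >= self.detection_breadth).sum(axis=1)
        profiles = pd.DataFrame(index=rel.index)
        profiles.index.name = "mag_id"
        profiles["n_samples_detected"] = detected

        ps_main, ps_sub, lev_b, lev_ba = {}, {}, {}, {}
        main_cats = sorted(set(main_of[s] for s in X.sample_ids))
        for mag in rel.index:
            row = rel.loc[mag]
            if row.sum() <= 0:
                ps_main[mag] = ps_sub[mag] = np.nan
                lev_b[mag] = lev_ba[mag] = np.nan
                continue
            ps_main[mag] = ps_index(row, main_of, self.q_basis, community)
            ps_sub[mag] = ps_index(row, sub_of, self.q_basis, community)
            by_cat = _category_shares(row, main_of, main_cats)
            if len(main_cats) >= 2:
                lev_b[mag], lev_ba[mag] = levins_breadth(by_cat)
            else:  # pragma: no cover - degenerate metadata
                lev_b[mag] = lev_ba[mag] = np.nan
        profiles["ps_main"] = pd.Series(ps_main)
        profiles["ps_sub"] = pd.Series(ps_sub)
        profiles["levins_b"] = pd.Series(lev_b)
        profiles["levins_b_std"] = pd.Series(lev_ba)

        classifiable = profiles.index[(detected > 1) & profiles["ps_main"].notna()]
        if len(classifiable) < 3:
            raise ValueError(
                f"only {len(classifiable)} classifiable MAGs (< 3); cannot form terciles"
            )
        rank_main = profiles.loc[classifiable, "ps_main"].rank(method="average")
        rank_sub = profiles.loc[classifiable, "ps_sub"].rank(method="average")
        profiles["rank_main"] = rank_main
        profiles["rank_sub"] = rank_sub

        n = len(classifiable)
        bottom, top = _tercile_bounds(n)
        labels = pd.Series("excluded", index=profiles.index, name="label")
        for mag in classifiable:
            rm, rs = rank_main[mag], rank_sub[mag]
            if rm > top and rs > top:
                labels[mag] = "generalist"
            elif rm <= bottom and rs <= bottom:
                if rs < rm:
                    labels[mag] = "strict_specialist"
                else:
                    if rs == rm:
                        logger.info("MAG %s: tied specialist ranks; regular by convention", mag)
                    labels[mag] = "regular_specialist"
            else:
                labels[mag] = "intermediate"
        profiles["label"] = labels

        self.profiles_ = profiles.reset_index()
        self.labels_ = labels
        self.n_classifiable_ = n
        return self

    def fit_predict(self, X: CoverageMatrix, samples: Sequence[SampleInfo]) -> pd.Series:
        return self.fit(X, samples).labels_


def classify_niche(
    matrix: CoverageMatrix,
    samples: Sequence[SampleInfo],
    q_basis: str = "cells",
    detection_breadth: float = 0.10,
) -> pd.DataFrame:
    """One-shot wrapper returning the per-MAG niche profile table."""
    clf = NicheClassifier(q_basis=q_basis, detection_breadth=detection_breadth)
    return clf.fit(matrix, samples).profiles_


def ps_null_test(
    mag_abund: pd.Series,
    category_of: Mapping[str, str],
    q_basis: str = "cells",
    community_totals: Optional[pd.Series] = None,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> float:
    """Permutation p-value for specialism (lower PS = more specialist).

    Sample-to-category labels are permuted ``n_perm`` times and
    ``p = (1 + #{PS_perm <= PS_obs}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    sample_ids = list(mag_abund.index)
    cats = [category_of[s] for s in sample_ids]
    if len(set(cats)) < 2:
        raise ValueError("need at least two categories for a permutation null")
    ps_obs = ps_index(mag_abund, category_of, q_basis, community_totals)
    rng = np.random.default_rng(seed)
    hits = 0
    cats = np.asarray(cats, dtype=object)
    for _ in range(n_perm):
        perm = rng.permutation(cats)
        perm_map = dict(zip(sample_ids, perm))
        if ps_index(mag_abund, perm_map, q_basis, community_totals) <= ps_obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)
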