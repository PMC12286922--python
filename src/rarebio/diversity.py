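"""Richness and diversity estimators: Chao1, Chao-Shen entropy, Hill ^1D.

These correct plug-in statistics for unobserved categories: Chao1 adds a
singleton/doubleton term to the observed richness; the Chao-Shen entropy
combines a Good-Turing coverage adjustment with a Horvitz-Thompson
correction for undetected categories. Entropy is reported in nats so its
exponential is the Hill number ^1D (effective number of categories).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["chao1", "chao_shen_entropy", "hill_d1"]


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    if isinstance(counts, pd.Series):
        counts = counts.to_numpy()
    c = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
    if c.size == 0:
        raise ValueError("empty count vector")
    if not np.issubdtype(c.dtype, np.number) or (c < 0).any():
        raise ValueError("counts must be non-negative numbers")
    if not np.allclose(c, np.round(c)):
        raise ValueError("counts must be integers")
    c = np.round(c).astype(np.int64)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("at least one positive count required")
    return c


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate.

    Bias-corrected form (default): ``S_obs + F1*(F1-1) / (2*(F2+1))``,
    finite even without doubletons. Classic form: ``S_obs + F1^2/(2*F2)``,
    replaced by the F2 = 0 limit ``S_obs + F1*(F1-1)/2`` when no doubletons
    exist.
    """
    c = _as_counts(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def chao_shen_entropy(counts) -> float:
    """Chao-Shen estimate of Shannon entropy (nats).

    With sample coverage ``C = 1 - F1/n`` and adjusted frequencies
    ``p~ = C * c_i / n``::

        H = sum_i  -p~_i ln p~_i  /  (1 - (1 - p~_i)^n)

    The denominator is the probability the category is observed at all,
    a Horvitz-Thompson inclusion correction.
    """
    c = _as_counts(counts)
    n = int(c.sum())
    if n < 2:
        raise ValueError("need total count >= 2")
    f1 = int((c == 1).sum())
    coverage = 1.0 - f1 / n
    if coverage == 0.0:
        raise ValueError(
            "all categories are singletons (estimated coverage 0); "
            "the Chao-Shen estimator is undefined -- sample more deeply"
        )
    p_adj = coverage * c / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = -p_adj * np.log(p_adj) / (1.0 - (1.0 - p_adj) ** n)
    # p_adj == 1 (single category, full coverage): -1*ln(1)/1 == 0
    terms = np.where(p_adj >= 1.0, 0.0, terms)
    return float(np.sum(terms))


def hill_d1(entropy: float) -> float:
    """Hill number ^1D = exp(H): diversity in effective categories."""
    return math.exp(entropy)
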