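"""Community statistics: richness estimators, dominance filters, group tests.

Richness estimation delegates to scikit-bio's implementations of the
bias-corrected Chao1 and classic ACE estimators; the Kruskal-Wallis test
delegates to SciPy (chi-square approximation with average-rank ties),
with an exact permutation p-value available for very small samples.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .errors import InputError, UndefinedMetricError


def _as_counts(counts: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
    if arr.size == 0:
        raise UndefinedMetricError("empty abundance vector")
    if np.any(arr < 0):
        raise InputError("negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise InputError("richness estimators need integer counts")
    arr = np.round(arr).astype(np.int64)
    if arr.sum() == 0:
        raise UndefinedMetricError("all-zero abundance vector")
    return arr


def chao1(counts: Iterable[float], bias_corrected: bool = True) -> float:
    """Chao1 richness, bias-corrected by default.

    ``S_obs + F1*(F1-1) / (2*(F2+1))`` where ``F1``/``F2`` are the
    singleton and doubleton counts; the bias-corrected form is defined
    even when there are no doubletons.
    """
    return float(_skbio_chao1(_as_counts(counts), bias_corrected=bias_corrected))


def ace(counts: Iterable[float], rare_cutoff: int = 10) -> float:
    """ACE richness (species with count <= ``rare_cutoff`` treated as rare).

    When the sample-coverage estimate is zero (all rare species are
    singletons) ACE is undefined; the estimator falls back to
    bias-corrected Chao1 with a warning.
    """
    arr = _as_counts(counts)
    try:
        return float(_skbio_ace(arr, rare_threshold=rare_cutoff))
    except ValueError:
        warnings.warn(
            "ACE undefined (all rare taxa are singletons); "
            "falling back to bias-corrected Chao1",
            stacklevel=2,
        )
        return chao1(arr)


def dominance_filter(
    rel_abundance: pd.DataFrame | pd.Series,
    threshold: float,
    top_k: int | None = None,
) -> list:
    """Features whose relative abundance strictly exceeds ``threshold``.

    ``rel_abundance`` is features x samples (or a single-sample Series)
    on the 0..1 scale; a feature is retained if it exceeds the threshold
    in at least one sample.  ``top_k`` optionally caps the result to the
    k features with the highest maximum abundance.
    """
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    if isinstance(rel_abundance, pd.Series):
        rel_abundance = rel_abundance.to_frame()
    peak = rel_abundance.max(axis=1)
    kept = peak[peak > threshold]
    if threshold == 0:
        kept = kept[kept > 0]
    kept = kept.sort_values(ascending=False, kind="stable")
    if top_k is not None:
        kept = kept.iloc[:top_k]
    return list(kept.index)


class KWResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def _normalize_groups(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> list[np.ndarray]:
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise InputError("Kruskal-Wallis needs at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise InputError("Kruskal-Wallis groups must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise InputError("Kruskal-Wallis needs at least 3 observations")
    return arrays


def _h_statistic(arrays: list[np.ndarray]) -> float:
    """Tie-corrected H, computed directly from average ranks."""
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [a.size for a in arrays])
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[offsets[i] : offsets[i + 1]].sum() ** 2 / arrays[i].size
        for i in range(len(arrays))
    ) - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    ties = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if ties == 0:
        return 0.0
    return h / ties


def _group_assignments(indices: tuple[int, ...], sizes: list[int]):
    """All ways to partition ``indices`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for combo in itertools.combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in set(combo))
        for tail in _group_assignments(rest, sizes[1:]):
            yield (combo,) + tail


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    method: str = "chi2",
) -> KWResult:
    """Kruskal-Wallis rank test across >= 2 groups.

    ``method="chi2"`` (default) takes H and p from SciPy's
    implementation (chi-square with k-1 df, average-rank tie
    correction); ``method="exact"`` enumerates all label permutations
    (total N <= 10) and reports the exact tail probability of H.
    All-identical observations yield H = 0, p = 1.
    """
    arrays = _normalize_groups(groups)
    k = len(arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, k - 1, 1.0)
    if method == "chi2":
        res = sps.kruskal(*arrays)
        return KWResult(float(res.statistic), k - 1, float(res.pvalue))
    if method == "exact":
        n = pooled.size
        if n > 10:
            raise InputError("exact permutation p-value limited to N <= 10")
        sizes = [a.size for a in arrays]
        h_obs = _h_statistic(arrays)
        count = total = 0
        for split in _group_assignments(tuple(range(n)), sizes):
            total += 1
            if _h_statistic([pooled[list(idx)] for idx in split]) >= h_obs - 1e-12:
                count += 1
        return KWResult(float(h_obs), k - 1, count / total)
    raise InputError(f"unknown method {method!r}")
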