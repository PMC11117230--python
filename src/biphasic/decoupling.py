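"""The adaptive-decoupling test battery.

Euclidean dissimilarities between species in each life stage's shape
space, a Mantel test with Spearman correlation of the dissimilarities,
and the half-sample disparity-correlation resampling, overall and per
family.  A low Mantel correlation and uncorrelated stage disparities
are the signature of adaptively decoupled larval and adult evolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .shape import procrustes_variance

log = logging.getLogger(__name__)


def euclidean_dissimilarity(X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Species-by-species Euclidean distance matrix of a trait matrix."""
    arr = np.asarray(X, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values: impute before computing dissimilarities")
    D = squareform(pdist(arr, metric="euclidean"))
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(arr))
    return pd.DataFrame(D, index=index, columns=index)


@dataclass
class MantelResult:
    """Spearman Mantel statistic with one-tailed permutation p."""

    r: float
    p: float
    nperm: int
    seed: int


def _check_square(d: pd.DataFrame | np.ndarray, name: str) -> np.ndarray:
    arr = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    return arr


def mantel_test(
    d1: pd.DataFrame | np.ndarray,
    d2: pd.DataFrame | np.ndarray,
    nperm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: Spearman correlation of off-diagonal dissimilarities.

    r is the Spearman correlation (average ranks for ties) of the
    upper-triangle entries; the null permutes species labels of the
    second matrix (rows and columns simultaneously); the one-tailed p
    is ``(count(r_perm >= r_obs) + 1)/(nperm + 1)``.
    """
    a1 = _check_square(d1, "d1")
    a2 = _check_square(d2, "d2")
    if a1.shape != a2.shape:
        raise ValueError("distance matrices must have matching size")
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if list(d1.index) != list(d2.index):
            raise ValueError("distance matrices must share species labels and order")
    n = a1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = a1[iu]
    if np.ptp(v1) == 0 or np.ptp(a2[iu]) == 0:
        log.warning("mantel_test: constant distance matrix, r undefined")
        return MantelResult(r=np.nan, p=np.nan, nperm=nperm, seed=seed)
    r1 = rankdata(v1)
    r1c = r1 - r1.mean()
    r1n = np.sqrt(r1c @ r1c)

    def spearman(v2_block: np.ndarray) -> np.ndarray:
        # v2_block: (m,) or (B, m) raw upper triangles
        r2 = rankdata(v2_block, axis=-1)
        r2c = r2 - r2.mean(axis=-1, keepdims=True)
        denom = r1n * np.sqrt((r2c**2).sum(axis=-1))
        return (r2c @ r1c) / denom

    r_obs = float(spearman(a2[iu]))
    rng = np.random.default_rng(seed)
    count = 0
    block = 512
    done = 0
    while done < nperm:
        b = min(block, nperm - done)
        tri = np.empty((b, len(v1)))
        for j in range(b):
            p = rng.permutation(n)
            tri[j] = a2[np.ix_(p, p)][iu]
        count += int(np.count_nonzero(spearman(tri) >= r_obs - 1e-12))
        done += b
    p = (count + 1) / (nperm + 1)
    return MantelResult(r=r_obs, p=float(p), nperm=nperm, seed=seed)


@dataclass
class GroupDisparitySeries:
    """Paired half-sample disparities for one group of species."""

    r: float
    n_species: int
    pairs: np.ndarray  # (n_iter, 2): larval, adult disparity


@dataclass
class DisparityCorrResult:
    """Half-sample disparity correlation, global and per group.

    Each iteration draws one subset of floor(n/2) species, applied to
    both stages, and records the pair of Procrustes variances; r is the
    Spearman correlation across iterations.
    """

    r: float
    pairs: np.ndarray
    per_group: dict[str, GroupDisparitySeries] = field(default_factory=dict)
    n_iter: int = 0
    subset_size: int = 0
    seed: int = 0


def _disparity_series(
    L: np.ndarray, A: np.ndarray, n_iter: int, rng: np.random.Generator
) -> tuple[float, np.ndarray, int]:
    n = L.shape[0]
    half = n // 2
    pairs = np.empty((n_iter, 2))
    for i in range(n_iter):
        idx = rng.choice(n, size=half, replace=False)
        pairs[i, 0] = procrustes_variance(L[idx])
        pairs[i, 1] = procrustes_variance(A[idx])
    if np.ptp(pairs[:, 0]) == 0 or np.ptp(pairs[:, 1]) == 0:
        log.warning("half-sample disparity: zero-variance series, r undefined")
        return np.nan, pairs, half
    ra = rankdata(pairs[:, 0])
    rb = rankdata(pairs[:, 1])
    r = float(np.corrcoef(ra, rb)[0, 1])
    return r, pairs, half


def half_sample_disparity_correlation(
    larval: pd.DataFrame,
    adult: pd.DataFrame,
    groups: pd.Series | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> DisparityCorrResult:
    """Correlation of larval and adult disparity over half-sample subsets.

    Subsets of floor(n/2) species are drawn without replacement,
    independently across iterations; the same subset indexes both
    matrices so the two disparities are paired.  Run globally and, when
    ``groups`` is given, once per group with at least 6 species
    (smaller groups are skipped with a log note).
    """
    if list(larval.index) != list(adult.index):
        raise ValueError("larval and adult matrices must share the species index")
    L = larval.to_numpy(dtype=float)
    A = adult.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    r, pairs, half = _disparity_series(L, A, n_iter, rng)
    result = DisparityCorrResult(
        r=r, pairs=pairs, n_iter=n_iter, subset_size=half, seed=seed
    )
    if groups is not None:
        groups = pd.Series(groups).reindex(larval.index)
        for g, members in groups.groupby(groups).groups.items():
            pos = larval.index.get_indexer(members)
            if len(pos) < 6:
                log.info("half-sample disparity: group %r has < 6 species; skipped", g)
                continue
            rg, pg, hg = _disparity_series(L[pos], A[pos], n_iter, rng)
            result.per_group[str(g)] = GroupDisparitySeries(
                r=rg, n_species=len(pos), pairs=pg
            )
    return result


@dataclass
class DecouplingResult:
    """The combined adaptive-decoupling report for one paired dataset."""

    mantel: MantelResult
    disparity: DisparityCorrResult
    paired_dissimilarities: pd.DataFrame
    seed: int


def decoupling_summary(
    larval: pd.DataFrame,
    adult: pd.DataFrame,
    groups: pd.Series | None = None,
    nperm: int = 9999,
    n_iter: int = 1000,
    seed: int = 0,
) -> DecouplingResult:
    """Run the full decoupling battery on paired larval/adult matrices.

    Euclidean dissimilarities per stage, the Spearman Mantel test, the
    half-sample disparity correlations (global and per group), plus the
    paired per-species-pair dissimilarities (the numeric substrate of a
    dissimilarity density map).
    """
    if list(larval.index) != list(adult.index):
        raise ValueError("larval and adult matrices must share the species index")
    dl = euclidean_dissimilarity(larval)
    da = euclidean_dissimilarity(adult)
    mantel = mantel_test(dl, da, nperm=nperm, seed=seed)
    disparity = half_sample_disparity_correlation(
        larval, adult, groups=groups, n_iter=n_iter, seed=seed
    )
    n = len(larval)
    iu = np.triu_indices(n, k=1)
    paired = pd.DataFrame(
        {
            "species_a": np.asarray(larval.index)[iu[0]],
            "species_b": np.asarray(larval.index)[iu[1]],
            "larval_dissimilarity": dl.to_numpy()[iu],
            "adult_dissimilarity": da.to_numpy()[iu],
        }
    )
    return DecouplingResult(
        mantel=mantel, disparity=disparity, paired_dissimilarities=paired, seed=seed
    )
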