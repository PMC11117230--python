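"""Size-correcting shape transforms and disparity.

Generalized Procrustes Analysis for 2D landmark configurations,
pairwise Procrustes distance, Mosimann-style log-shape ratios for
linear measurements, iterative PCA imputation of missing cells, and
Procrustes variance (the disparity measure used throughout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LandmarkConfiguration, MeasurementTable

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Procrustes superimposition
# --------------------------------------------------------------------------

def _as_config_array(configs) -> tuple[np.ndarray, list[str]]:
    """Stack configurations into an (n, k, 2) array with specimen ids."""
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("expected an (n, k, 2) array")
        return arr, [f"s{i}" for i in range(arr.shape[0])]
    ks = {c.n_landmarks for c in configs}
    if len(ks) > 1:
        raise ValueError(f"unequal landmark counts across configurations: {sorted(ks)}")
    return (
        np.stack([c.coords for c in configs]),
        [c.specimen_id for c in configs],
    )


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances to the centroid."""
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _normalize(coords: np.ndarray, name: str) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt((centered**2).sum())
    if cs < 1e-12:
        raise ValueError(f"degenerate configuration {name!r}: centroid size ~ 0")
    return centered / cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, reflections disallowed) minimizing |target - source R|."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, d])
    return u @ flip @ vt


@dataclass
class AlignedShapes:
    """GPA output: Procrustes coordinates plus the size information GPA removed.

    ``coords`` is specimens x (2k) with landmarks flattened as
    (x1, y1, x2, y2, ...); every row has centroid at the origin and unit
    centroid size.  ``mean_shape`` is the (k, 2) consensus.
    """

    coords: pd.DataFrame
    centroid_sizes: pd.Series
    mean_shape: np.ndarray
    iterations: int

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1] // 2

    def configuration(self, specimen: str) -> np.ndarray:
        return self.coords.loc[specimen].to_numpy().reshape(-1, 2)


def gpa(configs, tol: float = 1e-10, max_iter: int = 100) -> AlignedShapes:
    """Generalized Procrustes Analysis.

    Translates each configuration to its centroid, scales to unit
    centroid size, then iteratively rotates all configurations to the
    running consensus (closed-form orthogonal solution, rotations only)
    and re-estimates the consensus until it moves less than ``tol``
    (RMS per coordinate).  The consensus is renormalized to unit
    centroid size each round, so aligned coordinates stay full-Procrustes.
    """
    arr, ids = _as_config_array(configs)
    n, k, _ = arr.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    sizes = np.array([centroid_size(c) for c in arr])
    shapes = np.stack([_normalize(c, ids[i]) for i, c in enumerate(arr)])

    consensus = _normalize(shapes[0], "consensus")
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = _normalize(shapes.mean(axis=0), "consensus")
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            break

    coords = pd.DataFrame(
        shapes.reshape(n, 2 * k),
        index=ids,
        columns=[f"{ax}{j + 1}" for j in range(k) for ax in ("x", "y")],
    )
    return AlignedShapes(
        coords=coords,
        centroid_sizes=pd.Series(sizes, index=ids, name="centroid_size"),
        mean_shape=consensus,
        iterations=iterations,
    )


def procrustes_distance(a: np.ndarray | LandmarkConfiguration,
                        b: np.ndarray | LandmarkConfiguration) -> float:
    """Partial Procrustes distance between two configurations.

    Both shapes are centered and scaled to unit centroid size, the
    optimal rotation (no reflection) is applied, and the root summed
    squared difference is returned.  Zero iff the shapes are identical
    up to a similarity transform.
    """
    ca = a.coords if isinstance(a, LandmarkConfiguration) else np.asarray(a, float)
    cb = b.coords if isinstance(b, LandmarkConfiguration) else np.asarray(b, float)
    if ca.shape != cb.shape:
        raise ValueError("landmark counts differ")
    sa = _normalize(ca, "a")
    sb = _normalize(cb, "b")
    sb = sb @ _optimal_rotation(sb, sa)
    return float(np.sqrt(((sa - sb) ** 2).sum()))


def species_mean_shapes(aligned: AlignedShapes, species: pd.Series) -> pd.DataFrame:
    """Per-species mean of aligned coordinates (for 1-2 specimens per species).

    GPA runs on all specimens; species means are the averages of the
    aligned rows, mirroring the mean-shape-per-species workflow for
    low-replication samples.
    """
    species = pd.Series(species)
    groups = species.reindex(aligned.coords.index)
    if groups.isna().any():
        missing = list(aligned.coords.index[groups.isna()])
        raise ValueError(f"specimens without a species assignment: {missing[:5]}")
    return aligned.coords.groupby(groups).mean()


# --------------------------------------------------------------------------
# Log-shape ratios
# --------------------------------------------------------------------------

@dataclass
class LsrMatrix:
    """Log-shape ratios: ln(measurement / per-species geometric mean).

    Rows sum to zero.  ``log_svl`` carries ln(snout-vent length) as the
    size variable alongside (it is excluded from the geometric mean).
    """

    values: pd.DataFrame
    log_svl: pd.Series


def log_shape_ratios(table: MeasurementTable) -> LsrMatrix:
    """Transform a complete measurement table to log-shape ratios."""
    if table.n_missing:
        raise ValueError(
            f"{table.n_missing} missing cells: impute before taking log-shape ratios"
        )
    logged = np.log(table.values)
    lsr = logged.sub(logged.mean(axis=1), axis=0)
    return LsrMatrix(values=lsr, log_svl=np.log(table.svl).rename("log_svl"))


# --------------------------------------------------------------------------
# PCA imputation
# --------------------------------------------------------------------------

@dataclass
class ImputationResult:
    table: MeasurementTable
    n_iter: int
    converged: bool


def impute_pca(
    table: MeasurementTable,
    n_components: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ImputationResult:
    """Fill missing measurement cells by iterative low-rank PCA reconstruction.

    Columns are standardized, missing cells start at the column mean
    (zero after standardization), then the rank-``n_components``
    reconstruction refills the missing cells until the imputed values
    change by less than ``tol`` (RMS).  Observed cells are never
    altered; values are back-transformed to the original scale.
    """
    X = table.values.to_numpy(dtype=float)
    mask = np.isnan(X)
    if not mask.any():
        return ImputationResult(table.copy(), n_iter=0, converged=True)
    if mask.all(axis=0).any() or mask.all(axis=1).any():
        raise ValueError("every row and column needs at least one observed value")
    n, p = X.shape
    if n_components >= min(n, p):
        raise ValueError("n_components must be < min(n_rows, n_cols)")

    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = (X - mu) / sd
    Z[mask] = 0.0

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        center = Z.mean(axis=0)
        zc = Z - center
        u, s, vt = np.linalg.svd(zc, full_matrices=False)
        recon = (u[:, :n_components] * s[:n_components]) @ vt[:n_components] + center
        delta = np.sqrt(np.mean((recon[mask] - Z[mask]) ** 2))
        Z[mask] = recon[mask]
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("impute_pca: no convergence after %d iterations", max_iter)

    filled = X.copy()
    filled[mask] = (Z * sd + mu)[mask]
    # measurements are physical lengths: floor stray non-positive
    # reconstructions at half the smallest observed value per column
    floor = np.nanmin(np.where(mask, np.nan, X), axis=0) / 2.0
    low = mask & (filled < floor)
    if low.any():
        log.warning("impute_pca: %d imputed cells floored at positive minimum",
                    int(low.sum()))
        filled[low] = np.broadcast_to(floor, filled.shape)[low]
    out = MeasurementTable(
        table.svl.copy(),
        pd.DataFrame(filled, index=table.values.index, columns=table.values.columns),
    )
    return ImputationResult(out, n_iter=it, converged=converged)


# --------------------------------------------------------------------------
# Disparity
# --------------------------------------------------------------------------

def procrustes_variance(
    X: pd.DataFrame | np.ndarray,
    groups: pd.Series | None = None,
) -> float | pd.Series:
    """Procrustes variance: mean squared distance of rows to their group mean.

    The divisor is n (population form), matching the disparity
    convention of the morphometric workflow this mirrors.  With
    ``groups`` given, returns one value per group; singleton groups get
    NaN (logged) rather than an error.
    """
    arr = np.asarray(X, dtype=float)
    if groups is None:
        return float(((arr - arr.mean(axis=0)) ** 2).sum(axis=1).mean())
    if isinstance(X, pd.DataFrame):
        groups = pd.Series(groups).reindex(X.index)
    else:
        groups = pd.Series(list(groups))
    out = {}
    for label, idx in groups.groupby(groups).groups.items():
        pos = (
            X.index.get_indexer(idx)
            if isinstance(X, pd.DataFrame)
            else np.asarray(idx, dtype=int)
        )
        if len(pos) < 2:
            log.warning("procrustes_variance: group %r has < 2 rows; NaN", label)
            out[label] = np.nan
            continue
        sub = arr[pos]
        out[label] = float(((sub - sub.mean(axis=0)) ** 2).sum(axis=1).mean())
    return pd.Series(out, name="procrustes_variance")
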