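"""Morphospace construction and permutation inference.

Covariance PCA for shape matrices, Procrustes ANOVA with sequential
(type-I) sums of squares and residual-randomization permutation
(RRPP), and multivariate shape-on-size allometry with regression
scores and predicted-shape summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class MorphospaceResult:
    """Covariance PCA of a trait matrix.

    ``var_explained`` fractions sum to 1 over the retained (non-null)
    components; the sign convention makes the largest-magnitude loading
    of each PC positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_explained: np.ndarray
    center: pd.Series


def pca(X: pd.DataFrame | np.ndarray, n_components: int | None = None) -> MorphospaceResult:
    """Principal components of column-centered data (covariance PCA)."""
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if np.isnan(arr).any():
        raise ValueError("PCA input must be complete (impute first)")
    center = arr.mean(axis=0)
    u, s, vt = np.linalg.svd(arr - center, full_matrices=False)
    keep = s > s[0] * 1e-12 if s[0] > 0 else s > -1
    rank = int(keep.sum())
    if n_components is not None:
        if n_components > rank:
            log.info("pca: requested %d components, rank is %d", n_components, rank)
        rank = min(n_components, rank)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    # sign convention: largest-|loading| entry of each PC positive
    flip = np.sign(vt[np.arange(rank), np.abs(vt).argmax(axis=1)])
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    total_var = float((np.linalg.svd(arr - center, compute_uv=False) ** 2).sum())
    names = [f"PC{i + 1}" for i in range(rank)]
    return MorphospaceResult(
        scores=pd.DataFrame(scores, index=df.index, columns=names),
        loadings=pd.DataFrame(vt.T, index=df.columns, columns=names),
        var_explained=(s**2) / total_var,
        center=pd.Series(center, index=df.columns),
    )


# --------------------------------------------------------------------------
# Design matrices for sequential fits
# --------------------------------------------------------------------------

def _main_effect(design: pd.DataFrame, name: str) -> np.ndarray:
    if name not in design.columns:
        raise KeyError(f"term {name!r} not in the design table")
    col = design[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(col, drop_first=True)
    if dummies.shape[1] == 0:
        raise ValueError(f"factor {name!r} has a single level")
    return dummies.to_numpy(dtype=float)


def term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    """Columns for one model term; ``a:b`` builds interaction products."""
    parts = term.split(":")
    mat = _main_effect(design, parts[0])
    for p in parts[1:]:
        other = _main_effect(design, p)
        mat = np.einsum("ij,ik->ijk", mat, other).reshape(len(mat), -1)
    return mat


def _hat(Xcols: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space, plus its rank."""
    q, r = np.linalg.qr(Xcols)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


# --------------------------------------------------------------------------
# Procrustes ANOVA
# --------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Sequential multivariate ANOVA with RRPP permutation inference.

    ``table`` rows are the model terms plus Residuals and Total, with
    df, SS, MS, Rsq, F, Z (effect size on log-F) and permutation p.
    """

    table: pd.DataFrame
    nperm: int
    seed: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def procrustes_anova(
    Y: pd.DataFrame | np.ndarray,
    design: pd.DataFrame,
    terms: list[str],
    nperm: int = 999,
    seed: int = 0,
) -> AnovaTable:
    """Sequential (type-I) Procrustes ANOVA of a multivariate response.

    Term sums of squares are traces of cross-product differences
    between nested least-squares fits, in the order given.  p-values
    use residual randomization under each term's reduced model: reduced
    residual rows are permuted, the term F recomputed, and
    ``p = (count >= observed + 1)/(nperm + 1)``.  Z is the position of
    the observed statistic in the log-transformed permutation
    distribution.
    """
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n = arr.shape[0]
    if len(design) != n:
        raise ValueError("design and response row counts differ")
    if nperm < 99:
        raise ValueError("nperm must be >= 99")

    centered = arr - arr.mean(axis=0)
    ss_total = float((centered**2).sum())
    if ss_total <= 1e-12:
        raise ValueError("zero total SS: constant response")

    intercept = np.ones((n, 1))
    hats = [(_hat(intercept))]
    X = intercept
    for t in terms:
        X = np.hstack([X, term_matrix(design, t)])
        hats.append(_hat(X))
    H_full, rank_full = hats[-1]
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("zero residual degrees of freedom (confounded terms)")

    dfs, sss = [], []
    for i, t in enumerate(terms):
        H_prev, r_prev = hats[i]
        H_i, r_i = hats[i + 1]
        df_i = r_i - r_prev
        if df_i == 0:
            raise ValueError(f"term {t!r} adds no estimable effect (confounded)")
        dfs.append(df_i)
        sss.append(float((((H_i - H_prev) @ arr) ** 2).sum()))
    ss_res = float((((np.eye(n) - H_full) @ arr) ** 2).sum())
    ms_res = ss_res / df_res
    f_obs = np.array(
        [
            (sss[i] / dfs[i]) / ms_res if ms_res > 0 else np.inf
            for i in range(len(terms))
        ]
    )

    # RRPP: per term, permute the reduced-model residuals.  Because the
    # projectors are nested, the reduced-model fitted part drops out of
    # both the term SS and the full-model residual SS.
    rng = np.random.default_rng(seed)
    R_full = np.eye(n) - H_full
    f_perm = np.empty((nperm, len(terms)))
    reduced_resid = [(np.eye(n) - hats[i][0]) @ arr for i in range(len(terms))]
    diff_proj = [hats[i + 1][0] - hats[i][0] for i in range(len(terms))]
    for j in range(nperm):
        p_idx = rng.permutation(n)
        for i in range(len(terms)):
            Rp = reduced_resid[i][p_idx]
            ss_i = float(((diff_proj[i] @ Rp) ** 2).sum())
            ss_r = float(((R_full @ Rp) ** 2).sum())
            if ss_r <= 0:
                f_perm[j, i] = np.inf
            else:
                f_perm[j, i] = (ss_i / dfs[i]) / (ss_r / df_res)

    rows = []
    for i, t in enumerate(terms):
        dist = np.concatenate([[f_obs[i]], f_perm[:, i]])
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(dist[np.isfinite(dist) & (dist > 0)])
        z = np.nan
        if len(logs) > 1 and logs.std(ddof=0) > 0 and np.isfinite(f_obs[i]):
            z = (np.log(f_obs[i]) - logs.mean()) / logs.std(ddof=0)
        elif not np.isfinite(f_obs[i]):
            z = np.inf
        p = (np.count_nonzero(f_perm[:, i] >= f_obs[i]) + 1) / (nperm + 1)
        rows.append(
            {
                "df": dfs[i],
                "SS": sss[i],
                "MS": sss[i] / dfs[i],
                "Rsq": sss[i] / ss_total,
                "F": f_obs[i],
                "Z": z,
                "p": p,
            }
        )
    rows.append(
        {
            "df": df_res,
            "SS": ss_res,
            "MS": ms_res,
            "Rsq": ss_res / ss_total,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "df": n - 1,
            "SS": ss_total,
            "MS": np.nan,
            "Rsq": 1.0,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows, index=[*terms, "Residuals", "Total"])
    return AnovaTable(table=table, nperm=nperm, seed=seed)


# --------------------------------------------------------------------------
# Allometry
# --------------------------------------------------------------------------

@dataclass
class AllometryResult:
    """Multivariate shape-on-size regression, whole set and per group.

    ``regression_score`` projects centered shapes onto the common size
    coefficient vector; ``predicted_shape_pc1`` is PC1 of the
    size-by-group model's fitted shapes.  ``group_stats`` holds the
    per-group R-squared and permutation p.
    """

    anova: AnovaTable
    regression_score: pd.Series
    predicted_shape_pc1: pd.Series
    slopes: pd.DataFrame
    group_stats: pd.DataFrame
    nperm: int
    seed: int


def allometry_regression(
    Y: pd.DataFrame,
    size: pd.Series,
    groups: pd.Series | None = None,
    nperm: int = 999,
    seed: int = 0,
) -> AllometryResult:
    """Shape ~ ln(size) allometry with group (family) structure.

    The whole-set model is the sequential ANOVA size + group +
    size:group (the order the allometry table prints).  Per-group
    simple regressions report R-squared with an RRPP permutation p
    (reduced model = intercept).  Groups with fewer than 3 members are
    skipped with a log note.
    """
    if not isinstance(Y, pd.DataFrame):
        Y = pd.DataFrame(np.asarray(Y, float))
    size = pd.Series(size).reindex(Y.index).astype(float)
    if size.isna().any() or not np.all(np.isfinite(size)):
        raise ValueError("size must be finite for every specimen")
    arr = Y.to_numpy(dtype=float)
    n = arr.shape[0]

    design = pd.DataFrame({"size": size})
    terms = ["size"]
    if groups is not None:
        groups = pd.Series(groups).reindex(Y.index)
        design["group"] = groups.astype(str)
        terms = ["size", "group", "size:group"]
    anova = procrustes_anova(arr, design, terms, nperm=nperm, seed=seed)

    # common regression vector (shape ~ size alone)
    x = size.to_numpy()
    xc = x - x.mean()
    yc = arr - arr.mean(axis=0)
    b = (xc @ yc) / (xc @ xc)
    b_unit = b / np.linalg.norm(b) if np.linalg.norm(b) > 0 else b
    reg_score = pd.Series(yc @ b_unit, index=Y.index, name="regression_score")

    # predicted shapes from the size(-by-group) model
    cols = [np.ones((n, 1))] + [term_matrix(design, t) for t in terms]
    Xfull = np.hstack(cols)
    beta, *_ = np.linalg.lstsq(Xfull, arr, rcond=None)
    fitted = Xfull @ beta
    fitted_c = fitted - fitted.mean(axis=0)
    u, s, vt = np.linalg.svd(fitted_c, full_matrices=False)
    flip = np.sign(vt[0, np.abs(vt[0]).argmax()])
    pred_pc1 = pd.Series(u[:, 0] * s[0] * flip, index=Y.index, name="predicted_shape_pc1")

    slope_rows = {"overall": b}
    stats_rows = {}
    rng = np.random.default_rng(seed)
    if groups is not None:
        for g, members in groups.groupby(groups).groups.items():
            pos = Y.index.get_indexer(members)
            if len(pos) < 3:
                log.info("allometry: group %r has < 3 members; skipped", g)
                continue
            yg = arr[pos]
            xg = x[pos] - x[pos].mean()
            ygc = yg - yg.mean(axis=0)
            denom = float(xg @ xg)
            if denom <= 0:
                log.info("allometry: group %r has constant size; skipped", g)
                continue
            bg = (xg @ ygc) / denom
            ss_tot = float((ygc**2).sum())
            fitted_g = np.outer(xg, bg)
            ss_mod = float((fitted_g**2).sum())
            rsq = ss_mod / ss_tot if ss_tot > 0 else np.nan
            # RRPP with intercept-only reduced model: permute centered rows
            count = 0
            for _ in range(nperm):
                perm = ygc[rng.permutation(len(pos))]
                bp = (xg @ perm) / denom
                ss_p = float((np.outer(xg, bp) ** 2).sum())
                if ss_p >= ss_mod:
                    count += 1
            stats_rows[g] = {
                "n": len(pos),
                "Rsq": rsq,
                "p": (count + 1) / (nperm + 1),
            }
            slope_rows[g] = bg
    slopes = pd.DataFrame(slope_rows, index=Y.columns).T
    group_stats = pd.DataFrame(stats_rows).T if stats_rows else pd.DataFrame(
        columns=["n", "Rsq", "p"]
    )
    return AllometryResult(
        anova=anova,
        regression_score=reg_score,
        predicted_shape_pc1=pred_pc1,
        slopes=slopes,
        group_stats=group_stats,
        nperm=nperm,
        seed=seed,
    )
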