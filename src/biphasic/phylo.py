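"""Tree-aware comparative analyses.

Blomberg's K phylogenetic signal with a tip-permutation test,
Brownian-motion ancestral state reconstruction (GLS conditional
expectations), phylomorphospace and traitgram coordinates, Stayton's
C1-C4 convergence measures with Brownian simulation significance and
multi-tree uncertainty, and disparity-through-time with branch
interpolation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .tree import Phylogeny

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# BM covariance machinery
# --------------------------------------------------------------------------

class _BmOperator:
    """Cached per-tree quantities for GLS under Brownian motion.

    ``C`` is the tip shared-path covariance; the ancestral operator maps
    tip data to conditional node expectations, vectorized over columns.
    """

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.tips = tree.tip_indices
        self.internal = tree.internal_indices
        D = tree.mrca_depth_matrix()
        self.C = D[np.ix_(self.tips, self.tips)]
        self.C_nodes_tips = D[np.ix_(self.internal, self.tips)]
        self.cho = cho_factor(self.C)
        ones = np.ones(len(self.tips))
        self.Cinv1 = cho_solve(self.cho, ones)
        self.denom = float(ones @ self.Cinv1)

    def gls_mean(self, X: np.ndarray) -> np.ndarray:
        """Phylogenetic GLS estimate of the root state per column."""
        return (self.Cinv1 @ X) / self.denom

    def node_expectations(self, X: np.ndarray) -> np.ndarray:
        """Conditional expectations of internal-node states given tips.

        X is (n_tips, q); returns (n_internal, q), ordered like
        ``tree.internal_indices``.
        """
        a = self.gls_mean(X)
        resid = X - a
        return a + self.C_nodes_tips @ cho_solve(self.cho, resid)

    def all_states(self, X: np.ndarray) -> np.ndarray:
        """(n_nodes, q) array: observed at tips, reconstructed at nodes."""
        states = np.empty((self.tree.n_nodes, X.shape[1]))
        states[self.tips] = X
        states[self.internal] = self.node_expectations(X)
        return states

    def ml_rate(self, X: np.ndarray) -> np.ndarray:
        """Per-column ML Brownian rate: (x-a)'C^-1(x-a)/n."""
        resid = X - self.gls_mean(X)
        return np.einsum("ij,ij->j", resid, cho_solve(self.cho, resid)) / len(self.tips)

    def simulate_bm(
        self, sigma2: np.ndarray, nsim: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Fast BM tip simulation: (n_tips, d, nsim) with root state 0."""
        tree = self.tree
        d = len(sigma2)
        vals = np.zeros((tree.n_nodes, d, nsim))
        scale = np.sqrt(np.asarray(sigma2))[:, None]
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            step = rng.standard_normal((d, nsim)) * (
                scale * np.sqrt(tree.edge_length[i])
            )
            vals[i] = vals[tree.parent[i]] + step
        return vals[self.tips]


def _bm_operator(tree: Phylogeny) -> _BmOperator:
    op = getattr(tree, "_bm_operator", None)
    if op is None:
        op = _BmOperator(tree)
        tree._bm_operator = op  # type: ignore[attr-defined]
    return op


def _align_tip_data(tree: Phylogeny, x) -> np.ndarray:
    """Coerce a Series/DataFrame/array of tip data to tree tip order."""
    if isinstance(x, (pd.Series, pd.DataFrame)):
        missing = set(tree.tip_labels) - set(x.index)
        if missing:
            raise ValueError(f"trait values missing for tips: {sorted(missing)[:5]}")
        x = x.loc[tree.tip_labels]
        arr = x.to_numpy(dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        if arr.shape[0] != tree.n_tips:
            raise ValueError("trait vector length must equal the number of tips")
    if arr.ndim == 1:
        arr = arr[:, None]
    if not np.all(np.isfinite(arr)):
        raise ValueError("trait data must be complete and finite")
    return arr


# --------------------------------------------------------------------------
# Blomberg's K
# --------------------------------------------------------------------------

@dataclass
class SignalResult:
    """Blomberg's K with permutation significance."""

    K: float
    p: float
    nperm: int
    seed: int


def blomberg_k(tree: Phylogeny, x, nperm: int = 999, seed: int = 0) -> SignalResult:
    """Phylogenetic signal of a 1-D trait as Blomberg's K.

    K compares the observed ratio of mean squared error about the
    phylogenetic mean to the GLS error against its Brownian
    expectation; K = 1 exactly on a star tree, > 1 when relatives are
    more similar than BM predicts.  Significance comes from permuting
    trait values across tips (one-tailed, K >= observed, add-one
    corrected).
    """
    arr = _align_tip_data(tree, x)
    if arr.shape[1] != 1:
        raise ValueError("blomberg_k expects a single trait")
    n = tree.n_tips
    if n < 4:
        raise ValueError("need at least 4 tips")
    op = _bm_operator(tree)

    def k_stat(X: np.ndarray) -> np.ndarray:
        resid = X - op.gls_mean(X)
        num = np.einsum("ij,ij->j", resid, resid)
        den = np.einsum("ij,ij->j", resid, cho_solve(op.cho, resid))
        expected = (np.trace(op.C) - n / op.denom) / (n - 1)
        return (num / den) / expected

    k_obs = float(k_stat(arr)[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n, nperm))
    flat = arr[:, 0]
    for j in range(nperm):
        perms[:, j] = flat[rng.permutation(n)]
    k_perm = k_stat(perms)
    p = (np.count_nonzero(k_perm >= k_obs) + 1) / (nperm + 1)
    return SignalResult(K=k_obs, p=float(p), nperm=nperm, seed=seed)


# --------------------------------------------------------------------------
# Ancestral state reconstruction
# --------------------------------------------------------------------------

@dataclass
class AncestralEstimates:
    """Reconstructed internal-node states under Brownian motion.

    ``node_values`` is indexed by internal-node index (the tree's
    preorder numbering); ``root_value`` is the phylogenetic GLS root
    estimate, which is also the ML root state.
    """

    node_values: pd.DataFrame
    root_value: pd.Series


def asr_bm(tree: Phylogeny, x) -> AncestralEstimates:
    """ML ancestral states for continuous traits under Brownian motion.

    Node estimates are the joint-Gaussian conditional expectations of
    node states given the tip data, with the root at its ML (GLS)
    estimate -- the fast linear-operator form of maximum likelihood
    ancestral reconstruction.  Zero-length internal branches simply
    collapse to identical estimates.
    """
    arr = _align_tip_data(tree, x)
    op = _bm_operator(tree)
    nodes = op.node_expectations(arr)
    cols = (
        list(x.columns)
        if isinstance(x, pd.DataFrame)
        else [x.name if isinstance(x, pd.Series) and x.name else "trait"]
    )
    node_values = pd.DataFrame(nodes, index=tree.internal_indices, columns=cols)
    root = node_values.loc[tree.root]
    return AncestralEstimates(node_values=node_values, root_value=root)


# --------------------------------------------------------------------------
# Phylomorphospace / traitgram
# --------------------------------------------------------------------------

@dataclass
class Phylomorphospace:
    """Plot-ready numeric projection of a phylogeny into a morphospace."""

    tip_coords: pd.DataFrame
    node_coords: pd.DataFrame
    edges: pd.DataFrame  # parent/child node ids + their 2D positions


def phylomorphospace(tree: Phylogeny, scores: pd.DataFrame) -> Phylomorphospace:
    """Project the tree into a PC score space.

    Internal nodes sit at their per-PC BM reconstructions; edges connect
    parent and child positions.  Species on the tree without scores are
    dropped (the tree is pruned, with a log note).
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 score columns")
    have = [lb for lb in tree.tip_labels if lb in scores.index]
    if len(have) < tree.n_tips:
        log.info(
            "phylomorphospace: dropping %d tips without scores",
            tree.n_tips - len(have),
        )
        tree = tree.pruned(have)
    asr = asr_bm(tree, scores)
    positions = np.empty((tree.n_nodes, scores.shape[1]))
    positions[tree.tip_indices] = scores.loc[tree.tip_labels].to_numpy()
    positions[tree.internal_indices] = asr.node_values.to_numpy()
    cols = list(scores.columns)
    tip_coords = pd.DataFrame(
        positions[tree.tip_indices], index=tree.tip_labels, columns=cols
    )
    node_coords = pd.DataFrame(
        positions[tree.internal_indices], index=tree.internal_indices, columns=cols
    )
    rows = []
    for child in range(tree.n_nodes):
        if child == tree.root:
            continue
        parent = tree.parent[child]
        rows.append(
            {
                "parent": parent,
                "child": child,
                "x0": positions[parent, 0],
                "y0": positions[parent, 1],
                "x1": positions[child, 0],
                "y1": positions[child, 1],
            }
        )
    return Phylomorphospace(tip_coords, node_coords, pd.DataFrame(rows))


@dataclass
class Traitgram:
    """Trait value against time with tree edges through reconstructed nodes."""

    times: pd.Series  # Myr before present per node id
    values: pd.Series  # observed (tips) or reconstructed (nodes)
    tip_labels: dict[int, str]
    edges: list[tuple[int, int]]


def traitgram(tree: Phylogeny, x) -> Traitgram:
    """Coordinates for a traitgram: (time before present, trait value)."""
    arr = _align_tip_data(tree, x)
    if arr.shape[1] != 1:
        raise ValueError("traitgram expects a single trait")
    asr = asr_bm(tree, x)
    values = np.empty(tree.n_nodes)
    values[tree.tip_indices] = arr[:, 0]
    values[tree.internal_indices] = asr.node_values.to_numpy()[:, 0]
    edges = [
        (int(tree.parent[c]), int(c)) for c in range(tree.n_nodes) if c != tree.root
    ]
    return Traitgram(
        times=pd.Series(tree.node_times),
        values=pd.Series(values),
        tip_labels={int(i): tree.labels[i] for i in tree.tip_indices},
        edges=edges,
    )


# --------------------------------------------------------------------------
# Stayton's convergence measures
# --------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Stayton's C1-C4 for a focal tip set, averaged over tip pairs.

    C1 is the fraction of the maximum ancestral distance closed by the
    extant pair; C2 its magnitude; C3 and C4 normalize C2 by total
    phenotypic change along the two lineages and across the MRCA's
    clade, respectively.  p-values come from BM simulations with the
    ML-estimated rate.
    """

    C1: float
    C2: float
    C3: float
    C4: float
    p1: float
    p2: float
    p3: float
    p4: float
    nsim: int
    seed: int
    focal_tips: list[str]
    n_pairs: int
    per_tree_values: dict | None = None


def _pair_geometry(tree: Phylogeny, ia: int, ib: int) -> tuple:
    mrca = tree.mrca([ia, ib])
    path_a = tree.path_to_ancestor(ia, mrca)
    path_b = tree.path_to_ancestor(ib, mrca)
    lineage_edges = [
        (path[i + 1], path[i])
        for path in (path_a, path_b)
        for i in range(len(path) - 1)
    ]
    clade = tree.clade_nodes(mrca)
    clade_edges = [(int(tree.parent[c]), int(c)) for c in clade if c != mrca]
    return path_a, path_b, lineage_edges, clade_edges


def _c_measures(
    states: np.ndarray, geometry: tuple, ia: int, ib: int
) -> np.ndarray:
    """C1..C4 for one focal pair; ``states`` is (n_nodes, d, S).

    Returns (4, S); C1 is NaN where the max ancestral distance is 0.
    """
    path_a, path_b, lineage_edges, clade_edges = geometry
    A = states[path_a]  # (a, d, S)
    B = states[path_b]
    diff = A[:, None] - B[None]  # (a, b, d, S)
    dists = np.sqrt((diff**2).sum(axis=2))
    d_max = dists.max(axis=(0, 1))
    d_tip = dists[0, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        c1 = np.where(d_max > 0, 1.0 - d_tip / d_max, np.nan)
    c2 = d_max - d_tip

    def total_change(edges: list) -> np.ndarray:
        if not edges:
            return np.zeros(states.shape[2])
        pa = states[[e[0] for e in edges]]
        ch = states[[e[1] for e in edges]]
        return np.sqrt(((pa - ch) ** 2).sum(axis=1)).sum(axis=0)

    lin = total_change(lineage_edges)
    cla = total_change(clade_edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        c3 = np.where(lin > 0, c2 / lin, np.nan)
        c4 = np.where(cla > 0, c2 / cla, np.nan)
    return np.stack([c1, c2, c3, c4])


def _averaged_measures(
    tree: Phylogeny, states: np.ndarray, pairs: list[tuple[int, int]],
    geometries: list[tuple],
) -> np.ndarray:
    per_pair = np.stack(
        [_c_measures(states, g, ia, ib) for (ia, ib), g in zip(pairs, geometries)]
    )  # (n_pairs, 4, S)
    if np.isnan(per_pair).any():
        log.warning("stayton: undefined measure for some pair (zero distance)")
    with np.errstate(invalid="ignore"):
        return np.nanmean(per_pair, axis=0)  # (4, S)


def stayton_convergence(
    tree: Phylogeny,
    X: pd.DataFrame,
    focal_tips: list[str],
    nsim: int = 1000,
    seed: int = 0,
    node_values: np.ndarray | pd.DataFrame | None = None,
) -> ConvergenceReport:
    """Stayton's C1-C4 convergence measures for a set of focal tips.

    For every unordered focal pair, the tip phenotypic distance is
    compared with the maximum distance between any two reconstructed
    states along the pair's two lineages back to their MRCA; measures
    are averaged over pairs.  Significance (when ``nsim`` > 0) is the
    proportion of BM simulations -- rate fitted to the data by ML --
    whose measure is at least the observed (add-one corrected).
    ``node_values`` can pin the internal-node states (testing hook);
    it must be indexed like ``tree.internal_indices``.
    """
    arr = _align_tip_data(tree, X)
    labels = list(focal_tips)
    if len(labels) < 2:
        raise ValueError("need at least 2 focal tips")
    idx = [tree.tip_index_of(lb) for lb in labels]

    op = _bm_operator(tree)
    states = np.empty((tree.n_nodes, arr.shape[1], 1))
    states[tree.tip_indices, :, 0] = arr
    if node_values is None:
        states[tree.internal_indices, :, 0] = op.node_expectations(arr)
    else:
        nv = (
            node_values.loc[tree.internal_indices].to_numpy()
            if isinstance(node_values, pd.DataFrame)
            else np.asarray(node_values, dtype=float)
        )
        states[tree.internal_indices, :, 0] = nv.reshape(len(tree.internal_indices), -1)

    pairs = list(itertools.combinations(idx, 2))
    geometries = [_pair_geometry(tree, ia, ib) for ia, ib in pairs]
    obs = _averaged_measures(tree, states, pairs, geometries)[:, 0]

    ps = [np.nan] * 4
    if nsim > 0:
        rng = np.random.default_rng(seed)
        sigma2 = op.ml_rate(arr)
        sim_tips = op.simulate_bm(sigma2, nsim, rng)  # (n_tips, d, nsim)
        flat = sim_tips.reshape(tree.n_tips, -1)
        sim_states = np.empty((tree.n_nodes, arr.shape[1], nsim))
        sim_states[tree.tip_indices] = sim_tips
        sim_states[tree.internal_indices] = op.node_expectations(flat).reshape(
            len(tree.internal_indices), arr.shape[1], nsim
        )
        sims = _averaged_measures(tree, sim_states, pairs, geometries)  # (4, nsim)
        ps = [
            float((np.count_nonzero(sims[k] >= obs[k]) + 1) / (nsim + 1))
            if np.isfinite(obs[k])
            else np.nan
            for k in range(4)
        ]

    return ConvergenceReport(
        C1=float(obs[0]),
        C2=float(obs[1]),
        C3=float(obs[2]),
        C4=float(obs[3]),
        p1=ps[0],
        p2=ps[1],
        p3=ps[2],
        p4=ps[3],
        nsim=nsim,
        seed=seed,
        focal_tips=labels,
        n_pairs=len(pairs),
    )


@dataclass
class MultiTreeConvergence:
    """C1-C4 distributions over alternative trees (topology uncertainty)."""

    values: pd.DataFrame  # one row per usable tree, columns C1..C4
    medians: pd.Series
    q1: pd.Series
    q3: pd.Series
    n_trees: int
    n_used: int
    focal_tips: list[str]
    seed: int


def multi_tree_convergence(
    trees: list[Phylogeny],
    X: pd.DataFrame,
    focal_tips: list[str],
    nsim: int = 0,
    seed: int = 0,
) -> MultiTreeConvergence:
    """Repeat the convergence measures across alternative trees.

    Trees missing any focal tip are skipped (logged); each usable tree
    gets the same seed so identical trees give identical values.  By
    default only the measure values are collected (``nsim=0``), the
    boxplot-style summary of topology uncertainty.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    rows = []
    for i, tree in enumerate(trees):
        tip_set = set(tree.tip_labels)
        if not set(focal_tips) <= tip_set:
            log.info("multi_tree_convergence: tree %d missing focal tips; skipped", i)
            continue
        usable = [lb for lb in tree.tip_labels if lb in X.index]
        if set(focal_tips) - set(usable):
            log.info("multi_tree_convergence: tree %d lacks scored focal tips", i)
            continue
        sub = tree if len(usable) == tree.n_tips else tree.pruned(usable)
        rep = stayton_convergence(sub, X, focal_tips, nsim=nsim, seed=seed)
        rows.append({"tree": i, "C1": rep.C1, "C2": rep.C2, "C3": rep.C3, "C4": rep.C4})
    values = pd.DataFrame(rows).set_index("tree") if rows else pd.DataFrame(
        columns=["C1", "C2", "C3", "C4"]
    )
    return MultiTreeConvergence(
        values=values,
        medians=values.median(),
        q1=values.quantile(0.25),
        q3=values.quantile(0.75),
        n_trees=len(trees),
        n_used=len(values),
        focal_tips=list(focal_tips),
        seed=seed,
    )


# --------------------------------------------------------------------------
# Disparity through time
# --------------------------------------------------------------------------

@dataclass
class DTTProfile:
    """Sum-of-variances disparity at time-bin midpoints.

    Times are Myr before present; each spanning branch contributes its
    linearly interpolated value at the bin midpoint, and disparity is
    the population variance (divisor n) of those values, summed over
    trait dimensions.
    """

    bin_edges: np.ndarray
    bin_midpoints: np.ndarray
    disparity: np.ndarray
    n_lineages: np.ndarray


def dtt_profile(
    tree: Phylogeny,
    x,
    bin_edges: np.ndarray | None = None,
    node_values: np.ndarray | pd.DataFrame | None = None,
) -> DTTProfile:
    """Disparity through time by branch interpolation, gradual-change style.

    Node states come from BM reconstruction unless pinned via
    ``node_values``.  Default bins: 10 equal-width intervals from the
    root to the present.  Bins spanned by fewer than 2 branches report
    zero disparity.
    """
    arr = _align_tip_data(tree, x)
    height = tree.height
    if bin_edges is None:
        bin_edges = np.linspace(height, 0.0, 11)
    bin_edges = np.asarray(bin_edges, dtype=float)
    mids = (bin_edges[:-1] + bin_edges[1:]) / 2.0
    if np.any(mids > height + 1e-9) or np.any(mids < -1e-9):
        raise ValueError("bin midpoints must lie within [0, root depth]")

    states = np.empty((tree.n_nodes, arr.shape[1]))
    states[tree.tip_indices] = arr
    if node_values is None:
        states[tree.internal_indices] = _bm_operator(tree).node_expectations(arr)
    else:
        nv = (
            node_values.loc[tree.internal_indices].to_numpy()
            if isinstance(node_values, pd.DataFrame)
            else np.asarray(node_values, dtype=float)
        )
        states[tree.internal_indices] = nv.reshape(len(tree.internal_indices), -1)

    times = tree.node_times
    children = np.array([i for i in range(tree.n_nodes) if i != tree.root])
    parents = tree.parent[children]
    t_child = times[children]
    t_parent = times[parents]

    disparity = np.zeros(len(mids))
    n_lineages = np.zeros(len(mids), dtype=int)
    eps = 1e-9 * max(1.0, height)  # tips sit at ~0 up to float error
    for b, t in enumerate(mids):
        span = (t_parent > t + eps) & (t_child <= t + eps)
        n_lineages[b] = int(span.sum())
        if n_lineages[b] < 2:
            continue
        frac = (t - t_child[span]) / (t_parent[span] - t_child[span])
        vals = states[children[span]] + frac[:, None] * (
            states[parents[span]] - states[children[span]]
        )
        disparity[b] = float(vals.var(axis=0, ddof=0).sum())
    return DTTProfile(
        bin_edges=bin_edges,
        bin_midpoints=mids,
        disparity=disparity,
        n_lineages=n_lineages,
    )
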