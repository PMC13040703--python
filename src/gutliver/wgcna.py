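"""Weighted correlation network core.

Robust Z standardization, unsigned soft-thresholded Spearman adjacency
(A_ij = |rho_ij|^beta), scale-free topology fit over a beta grid, topological
overlap, average-linkage module detection with a minimum module size,
module eigengenes (first principal component of the module's standardized
profiles) and eigengene-based module merging.

The feature matrix may concatenate features from several compartments and
omics layers over the same samples; origin tags travel alongside so the
downstream axis stage can keep gut and liver membership separate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

#: Consistency constant making the MAD an unbiased sigma estimate under normality.
MAD_SCALE = 1.4826


def robust_z(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-feature robust Z-scores: (x - median) / (1.4826 * MAD).

    Fallback chain for degenerate rows: MAD = 0 -> use the sample SD
    (ddof=1); SD = 0 -> the feature is constant and excluded (its ids are
    returned and the count logged).
    """
    x = matrix.to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    scale = MAD_SCALE * mad
    sd = x.std(axis=1, ddof=1, keepdims=True)
    scale = np.where(scale == 0, sd, scale)
    constant = (scale == 0).ravel()
    if constant.any():
        log.info("robust_z: %d constant features excluded", int(constant.sum()))
    keep = ~constant
    z = (x[keep] - med[keep]) / scale[keep]
    zf = pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)
    return zf, list(matrix.index[constant])


def spearman_adjacency(Z: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency A_ij = |rho_ij|^beta with tie-corrected Spearman rho.

    rho is Pearson correlation of midranks, which carries the tie correction.
    Features with fewer than 3 distinct ranks are excluded with a warning.
    """
    if Z.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    ranks = np.apply_along_axis(stats.rankdata, 1, Z.to_numpy(dtype=float))
    distinct = np.array([np.unique(r).size for r in ranks])
    bad = distinct < 3
    if bad.any():
        log.warning(
            "spearman_adjacency: %d features with < 3 distinct ranks excluded", int(bad.sum())
        )
    keep = ~bad
    ranks = ranks[keep]
    rho = np.corrcoef(ranks)
    a = np.abs(rho) ** beta
    np.fill_diagonal(a, 1.0)
    ids = Z.index[keep]
    return pd.DataFrame(a, index=ids, columns=ids)


@dataclasses.dataclass
class ScaleFreeFit:
    """Per-beta scale-free topology fit (log-log degree regression R^2)."""

    betas: list
    r_squared: list
    mean_connectivity: list
    selected_beta: int


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(freq) on log10(mean k) over equal-width connectivity bins."""
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r**2)


def scale_free_fit(
    Z: pd.DataFrame, beta_grid=range(1, 13), r2_target: float = 0.8, stabilize_tol: float = 0.02
) -> ScaleFreeFit:
    """Scale-free fit index over a beta grid and the selected beta.

    Selection: the smallest beta with R^2 >= ``r2_target``; failing that, the
    smallest beta where the curve has stabilized (|R^2(b+1) - R^2(b)| <
    ``stabilize_tol``); failing that, the grid maximum with a warning.
    """
    betas = list(beta_grid)
    r2s, ks = [], []
    base = spearman_adjacency(Z, 1)
    rho = base.to_numpy()
    for b in betas:
        a = np.abs(rho) ** b
        np.fill_diagonal(a, 1.0)
        k = a.sum(axis=1) - 1.0
        if np.allclose(k, 0):
            raise ValueError("all-zero adjacency; scale-free fit undefined")
        r2s.append(_scale_free_r2(k))
        ks.append(float(k.mean()))
    selected = None
    for b, r2 in zip(betas, r2s):
        if np.isfinite(r2) and r2 >= r2_target:
            selected = b
            break
    if selected is None:
        for i in range(len(betas) - 1):
            a, b = r2s[i], r2s[i + 1]
            if np.isfinite(a) and np.isfinite(b) and abs(b - a) < stabilize_tol:
                selected = betas[i]
                break
    if selected is None:
        selected = betas[-1]
        log.warning("scale_free_fit: no beta reached R^2 >= %g nor stabilized; using grid max %d",
                    r2_target, selected)
    return ScaleFreeFit(betas=betas, r_squared=r2s, mean_connectivity=ks, selected_beta=selected)


def tom(A: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix of an adjacency with unit diagonal.

    TOM_ij = (l_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij) with
    l_ij = sum_u A_iu A_uj over u != i, j and k_i the connectivity of i;
    TOM_ii = 1.
    """
    a = A.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    l = a @ a - 2 * a  # removes the u=i and u=j terms (diagonal is 1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (l + a) / denom
    t[~np.isfinite(t)] = 0.0
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2, 0.0, 1.0)
    return pd.DataFrame(t, index=A.index, columns=A.columns)


def _subtree_heights(node) -> list:
    """Heights of all internal merges within a cluster-node subtree."""
    out = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf():
            out.append(nd.dist)
            stack.extend([nd.left, nd.right])
    return out


def _split_recursive(node, labels_out: list) -> None:
    """Recursively split a flat cluster when its top merge is an outlier.

    A subtree with at least 3 internal merges is split into its two children
    when the gap between the top merge height and the next-highest internal
    merge exceeds the spread (range) of the remaining internal heights.
    """
    heights = sorted(_subtree_heights(node), reverse=True)
    if len(heights) >= 3:
        gap = heights[0] - heights[1]
        spread = heights[1] - heights[-1]
        if gap > spread and spread >= 0:
            _split_recursive(node.left, labels_out)
            _split_recursive(node.right, labels_out)
            return
    labels_out.append(node.pre_order(lambda leaf: leaf.id))


#: A cluster must be this much tighter inside than toward the rest of the
#: network (mean within-cluster TOM / mean member-to-nonmember TOM) to count
#: as a module rather than a chance agglomeration.  Chance clusters in
#: uncorrelated data sit near 2 (they clustered *because* they are slightly
#: tighter), genuine one-factor modules sit an order of magnitude higher.
COHESION_RATIO = 3.0


def detect_modules(dissTOM: pd.DataFrame, min_module_size: int = 30) -> tuple[np.ndarray, pd.Series]:
    """Deterministic average-linkage module detection on a TOM dissimilarity.

    The dendrogram is cut at the merge height (capped at the 0.99 quantile of
    merge heights, so the last top-level agglomerations never glue everything
    together) that maximizes first the number of clusters reaching
    ``min_module_size`` and then the number of features inside them, taking
    the lowest such height.  Branches are then recursively split where the
    top internal height gap exceeds the within-branch spread, undersized
    clusters go to background (label 0), and clusters no tighter inside than
    toward the rest of the network (see ``COHESION_RATIO``) are dissolved to
    background, so independent features yield no modules.  Surviving modules
    are numbered 1.. by decreasing size.  Returns (linkage matrix, labels).
    """
    ids = list(dissTOM.index)
    n = len(ids)
    if n < 2:
        return np.empty((0, 4)), pd.Series([0] * n, index=ids, dtype=int)
    d = dissTOM.to_numpy(dtype=float)
    d = (d + d.T) / 2
    condensed = squareform(d, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    background = pd.Series([0] * n, index=ids, dtype=int)
    if n <= min_module_size:
        log.warning(
            "detect_modules: %d features <= min_module_size %d; all background",
            n, min_module_size,
        )
        return link, background

    heights = link[:, 2]
    cap = float(np.quantile(heights, 0.99))
    candidates = np.unique(heights[heights <= cap])
    best = None  # (n_big, n_assigned, -height, flat labels)
    for h in candidates:
        flat = hierarchy.fcluster(link, t=h, criterion="distance")
        _, counts = np.unique(flat, return_counts=True)
        big = counts >= min_module_size
        key = (int(big.sum()), int(counts[big].sum()), -h)
        if best is None or key > best[0]:
            best = (key, flat)
    if best is None or best[0][0] == 0:
        log.info("detect_modules: no cluster reaches min_module_size; all background")
        return link, background
    (n_big, n_assigned, neg_h), flat = best
    cut = -neg_h

    # recursive gap-splitting of the chosen flat clusters via the tree
    tree = hierarchy.to_tree(link)
    clusters: list = []

    def descend(node):
        if (not node.is_leaf()) and node.dist > cut:
            descend(node.left)
            descend(node.right)
        else:
            _split_recursive(node, clusters)

    descend(tree)

    tom_sim = 1.0 - d
    sized = []
    for members in clusters:
        if len(members) < min_module_size:
            continue
        inside = np.array(members)
        outside = np.setdiff1d(np.arange(n), inside)
        block = tom_sim[np.ix_(inside, inside)]
        # medians, so a small tight clique cannot carry a padded cluster
        within = float(np.median(block[np.triu_indices(len(inside), k=1)]))
        if outside.size:
            cross = float(np.median(tom_sim[np.ix_(inside, outside)]))
            if cross > 0 and within / cross < COHESION_RATIO:
                log.info(
                    "detect_modules: cluster of %d dissolved (within/cross TOM %.2f)",
                    len(inside), within / cross,
                )
                continue
        sized.append(members)
    sized.sort(key=lambda c: (-len(c), min(c)))
    labels = np.zeros(n, dtype=int)
    for module_id, members in enumerate(sized, start=1):
        labels[members] = module_id
    log.info(
        "detect_modules: cut %.4f -> %d modules (sizes %s), %d background",
        cut, len(sized), [len(c) for c in sized], int((labels == 0).sum()),
    )
    return link, pd.Series(labels, index=ids, dtype=int)


def module_eigengene(Z: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Module eigengenes: first principal component across samples, unit variance.

    Sign-oriented so the mean correlation with member features is positive.
    A single-feature module's eigengene is that feature's standardized
    profile.  Returns samples x modules.
    """
    modules = sorted(set(labels[labels > 0]))
    if not modules:
        raise ValueError("no non-background modules")
    mes = {}
    for m in modules:
        block = Z.loc[labels[labels == m].index].to_numpy(dtype=float)
        centered = block - block.mean(axis=1, keepdims=True)
        if block.shape[0] == 1:
            me = centered[0]
        else:
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            me = vt[0]
        sd = me.std(ddof=1)
        if sd > 0:
            me = me / sd
        corrs = [np.corrcoef(me, row)[0, 1] for row in centered if row.std() > 0]
        if corrs and np.nanmean(corrs) < 0:
            me = -me
        mes[m] = me
    return pd.DataFrame(mes, index=Z.columns)


def merge_modules(
    Z: pd.DataFrame, labels: pd.Series, cut_height: float = 0.2
) -> tuple[pd.Series, pd.DataFrame]:
    """Iteratively merge module pairs with eigengene dissimilarity < cut_height.

    The closest pair (largest eigengene correlation) merges first; eigengenes
    are recomputed after every merge.  ``cut_height`` = 0 never merges.
    Returns relabeled modules (renumbered by decreasing size) and their
    eigengenes.
    """
    labels = labels.copy()
    while True:
        modules = sorted(set(labels[labels > 0]))
        if len(modules) < 2 or cut_height <= 0:
            break
        mes = module_eigengene(Z, labels)
        cor = np.corrcoef(mes.to_numpy().T)
        best, best_diss = None, np.inf
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                diss = 1 - cor[i, j]
                if diss < best_diss:
                    best_diss, best = diss, (modules[i], modules[j])
        if best is None or best_diss >= cut_height:
            break
        a, b = best
        labels[labels == b] = a
        log.info("merge_modules: merged module %d into %d (dissimilarity %.3f)", b, a, best_diss)
    # renumber by decreasing size, deterministic tie-break on first member
    order = sorted(
        set(labels[labels > 0]),
        key=lambda m: (-(labels == m).sum(), list(labels[labels == m].index)[0]),
    )
    mapping = {old: new for new, old in enumerate(order, start=1)}
    relabeled = labels.map(lambda v: mapping.get(v, 0)).astype(int)
    mes = module_eigengene(Z, relabeled) if order else pd.DataFrame(index=Z.columns)
    return relabeled, mes


@dataclasses.dataclass
class NetworkModel:
    """Fitted network: standardized matrix, adjacency, TOM, modules, eigengenes."""

    Z: pd.DataFrame
    origin: pd.DataFrame  # feature -> compartment, layer
    beta: int
    A: pd.DataFrame
    TOM: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series
    MEs: pd.DataFrame
    excluded: list


def build_network(tables: list, config) -> NetworkModel:
    """Full network stage over concatenated cross-compartment feature tables.

    Feature rows from all tables are stacked over the shared samples (row ids
    are prefixed ``compartment/layer:`` to stay unique); robust-Z, adjacency
    at ``config.beta``, TOM, module detection at ``config.min_module_size``
    and eigengene merging at ``config.merge_cut_height``.
    """
    sample_order = list(tables[0].sample_ids)
    blocks, origin_rows = [], []
    for t in tables:
        v = t.values[sample_order]
        prefixed = v.copy()
        prefixed.index = [f"{t.compartment}/{t.layer}:{fid}" for fid in v.index]
        blocks.append(prefixed)
        origin_rows += [
            {"feature": pid, "feature_id": str(fid), "compartment": t.compartment, "layer": t.layer}
            for pid, fid in zip(prefixed.index, v.index)
        ]
    matrix = pd.concat(blocks, axis=0)
    origin = pd.DataFrame(origin_rows).set_index("feature")
    z, excluded = robust_z(matrix)
    a = spearman_adjacency(z, config.beta)
    z = z.loc[a.index]
    t = tom(a)
    diss = 1.0 - t
    link, labels = detect_modules(diss, min_module_size=config.min_module_size)
    if (labels > 0).any():
        labels, mes = merge_modules(z, labels, cut_height=config.merge_cut_height)
    else:
        mes = pd.DataFrame(index=z.columns)
    log.info(
        "network: %d features, beta=%d, %d modules, %d background",
        z.shape[0], config.beta, int(labels.max()) if len(labels) else 0, int((labels == 0).sum()),
    )
    return NetworkModel(
        Z=z, origin=origin.loc[z.index], beta=config.beta, A=a, TOM=t,
        linkage=link, labels=labels, MEs=mes, excluded=excluded,
    )
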