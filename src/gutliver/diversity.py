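"""Alpha diversity, beta-diversity distances, ordination and PERMANOVA.

Alpha metrics use log base 2 (Shannon in bits; Pielou J = H / log2(richness)).
Beta metrics: binary Jaccard, Bray-Curtis, unweighted and weighted UniFrac
(weighted unnormalized by default); UniFrac is delegated to scikit-bio.
PCoA is classical scaling of the double-centered squared-distance matrix with
negative eigenvalues dropped from the variance denominator.  PERMANOVA uses
the pseudo-F built from total and within-group sums of squared distances with
a seeded permutation p-value under the add-one convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity as _skbio_beta

log = logging.getLogger(__name__)

BETA_METRICS = ("jaccard", "bray_curtis", "unweighted_unifrac", "weighted_unifrac")


def alpha_diversity(table, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon index, richness and Pielou's evenness.

    Shannon H = -sum p_i log_base p_i over non-zero proportions; richness is
    the count of detected features; J = H / log_base(richness), reported as
    missing when richness <= 1.  An all-zero sample yields all-missing with a
    warning.
    """
    rows = []
    for sid in table.sample_ids:
        x = table.values[sid].to_numpy(dtype=float)
        total = x.sum()
        if total == 0:
            log.warning("sample %s is all-zero; alpha diversity undefined", sid)
            rows.append({"sample": sid, "shannon": np.nan, "richness": np.nan, "pielou": np.nan})
            continue
        p = x[x > 0] / total
        h = float(-(p * np.log(p) / np.log(base)).sum())
        richness = int((x > 0).sum())
        j = h / (np.log(richness) / np.log(base)) if richness > 1 else np.nan
        rows.append({"sample": sid, "shannon": h, "richness": richness, "pielou": j})
    return pd.DataFrame(rows).set_index("sample")


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with its chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    combined = np.concatenate(groups)
    if np.all(combined == combined[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def beta_distance(table, metric: str, tree=None) -> DistanceMatrix:
    """Pairwise sample distances under one of the four supported metrics.

    Jaccard operates on presence/absence; UniFrac metrics require a rooted
    tree covering every feature with non-zero abundance (missing features are
    reported by id).
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"metric must be one of {BETA_METRICS}, got {metric!r}")
    counts = table.values.to_numpy(dtype=float).T  # samples x features
    ids = [str(s) for s in table.sample_ids]
    if metric == "jaccard":
        d = squareform(pdist(counts > 0, metric="jaccard"))
        return DistanceMatrix(d, ids=ids)
    if metric == "bray_curtis":
        return _skbio_beta("braycurtis", counts, ids=ids)
    if tree is None:
        raise ValueError(f"{metric} requires a rooted tree")
    tips = {t.name for t in tree.tips()}
    observed = [
        fid for fid, present in zip(table.feature_ids, (counts > 0).any(axis=0)) if present
    ]
    missing = sorted(set(map(str, observed)) - tips)
    if missing:
        raise ValueError(f"features absent from tree: {missing}")
    kept = [i for i, fid in enumerate(table.feature_ids) if str(fid) in tips]
    return _skbio_beta(
        metric,
        counts[:, kept],
        ids=ids,
        taxa=[str(table.feature_ids[i]) for i in kept],
        tree=tree,
        validate=True,
    )


def pcoa(dist: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinates) of a distance matrix.

    Returns (coordinates indexed by sample, proportion of variance per kept
    axis).  Axes are ordered by decreasing eigenvalue; negative eigenvalues
    are dropped from both the coordinates and the variance denominator, with
    a logged note when they occur.
    """
    d = np.asarray(dist.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigvals[0]), 1.0)
    if (eigvals < -tol).any():
        log.info(
            "pcoa: %d negative eigenvalues (min %.3g) dropped from variance denominator",
            int((eigvals < -tol).sum()), float(eigvals.min()),
        )
    keep = eigvals > tol
    lam = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(lam)
    proportions = lam / lam.sum() if lam.size else lam
    frame = pd.DataFrame(
        coords, index=list(dist.ids), columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    return frame, proportions


def pca_scores(table, standardize: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on (optionally standardized) features.

    Implemented as PCoA on Euclidean distances of the standardized feature
    matrix, which is exactly classical PCA up to axis sign.
    """
    x = table.values.to_numpy(dtype=float)  # features x samples
    if standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    d = squareform(pdist(x.T, metric="euclidean"))
    return pcoa(DistanceMatrix(d, ids=[str(s) for s in table.sample_ids]))


def permanova(
    dist: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """PERMANOVA pseudo-F and seeded permutation p-value.

    SS_total = sum of squared distances / N over all pairs; SS_within sums
    squared within-group distances / n_g.  F = (SS_between / (k-1)) /
    (SS_within / (N-k)); p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    d = np.asarray(dist.data, dtype=float)
    labels = np.asarray(grouping)
    if labels.size != d.shape[0]:
        raise ValueError("grouping length must match distance matrix")
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        bad = [str(uniq[i]) for i in np.where(sizes < 2)[0]]
        raise ValueError(f"groups of size < 2: {bad}")
    n = d.shape[0]
    k = uniq.size
    d2 = d**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    if ss_total == 0:
        log.warning("permanova: all distances zero; no structure to test")
        return 0.0, 1.0

    def pseudo_f(assignment: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(k):
            idx = np.where(assignment == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
        ss_between = ss_total - ss_within
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return float(f_obs), float(p)


def diversity_report(table, phenotypes, tree=None, config=None) -> dict:
    """Alpha table, per-metric distance matrices, ordinations, PERMANOVA."""
    from gutliver.config import AnalysisConfig

    config = config or AnalysisConfig()
    alpha = alpha_diversity(table)
    group = phenotypes.group.reindex([str(s) for s in table.sample_ids])
    out: dict = {"alpha": alpha, "beta": {}, "pcoa": {}, "permanova": {}}
    metrics = list(BETA_METRICS) if tree is not None else ["jaccard", "bray_curtis"]
    for metric in metrics:
        dm = beta_distance(table, metric, tree=tree)
        coords, prop = pcoa(dm)
        f, p = permanova(dm, group.to_numpy(), n_perm=config.permanova_nperm, seed=config.rng_seed)
        out["beta"][metric] = dm
        out["pcoa"][metric] = (coords, prop)
        out["permanova"][metric] = {"pseudo_F": f, "p": p, "n_perm": config.permanova_nperm}
        log.info("%s: PERMANOVA pseudo-F %.3f, p %.4f", metric, f, p)
    return out
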