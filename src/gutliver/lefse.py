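"""Two-class LDA effect-size ranking of differential taxa.

Procedure: total-sum scaling to one million per sample, a Kruskal-Wallis
screen at ``lefse_alpha``, then bootstrapped two-class linear discriminant
analysis.  Per bootstrap the effect of feature j is
``|delta_j + w_j * delta_proj| / 2`` where ``delta_j`` is the class-mean
difference of the feature, ``w`` the unit-norm discriminant vector and
``delta_proj`` the class-mean difference of the LDA projection; the score is
``log10(max(1, mean bootstrap effect))``, signed metadata carried as the
enriched class.  This is a defined two-class variant: the subclass stage of
the original method is omitted because the comparisons here are plain
two-group.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from gutliver.diversity import kruskal_wallis

log = logging.getLogger(__name__)

#: Shrinkage coefficient pulling the pooled covariance toward its diagonal.
COV_SHRINKAGE = 0.1
#: Total-sum scaling target per sample.
TSS_TOTAL = 1e6


@dataclasses.dataclass
class LdaScore:
    feature_id: str
    taxonomy: str
    direction: str
    score: float
    kw_p: float


def tss_scale(values: pd.DataFrame, total: float = TSS_TOTAL) -> pd.DataFrame:
    """Scale each sample (column) to sum to ``total``; all-zero columns stay zero."""
    sums = values.sum(axis=0)
    safe = sums.replace(0, 1.0)
    return values / safe * total


def kw_screen(table, classes: dict, alpha: float = 0.05) -> tuple[list, dict]:
    """Features passing the per-feature Kruskal-Wallis screen at ``alpha``.

    ``classes`` maps class label -> sample ids (two classes).  Returns the
    surviving feature ids and the per-feature KW p-values (all features).
    """
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    for label, samples in classes.items():
        if len(samples) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
    scaled = tss_scale(table.values)
    pvals: dict = {}
    survivors = []
    for fid in table.feature_ids:
        groups = [scaled.loc[fid, list(s)].to_numpy(dtype=float) for s in classes.values()]
        _, p = kruskal_wallis(groups)
        pvals[fid] = p
        if p < alpha:
            survivors.append(fid)
    log.info("KW screen: %d/%d features retained at alpha=%g", len(survivors), len(pvals), alpha)
    return survivors, pvals


def _lda_direction(x: np.ndarray, n0: int) -> np.ndarray:
    """Unit-norm discriminant direction for a two-class sample block.

    ``x`` is samples x features with the first ``n0`` rows in class 0.  The
    pooled within-class covariance is shrunk toward its diagonal; a singular
    system falls back to least squares.
    """
    a, b = x[:n0], x[n0:]
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    ca = np.cov(a, rowvar=False, ddof=1) if a.shape[0] > 1 else np.zeros((x.shape[1],) * 2)
    cb = np.cov(b, rowvar=False, ddof=1) if b.shape[0] > 1 else np.zeros((x.shape[1],) * 2)
    pooled = np.atleast_2d(((a.shape[0] - 1) * ca + (b.shape[0] - 1) * cb) / max(x.shape[0] - 2, 1))
    shrunk = (1 - COV_SHRINKAGE) * pooled + COV_SHRINKAGE * np.diag(np.diag(pooled))
    diff = mu_b - mu_a
    try:
        w = np.linalg.solve(shrunk, diff)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(shrunk, diff, rcond=None)[0]
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lda_effect_size(
    table, classes: dict, n_boot: int = 30, seed: int = 0, alpha: float = 0.05
) -> list[LdaScore]:
    """Bootstrapped LDA effect-size scores for screened features.

    ``classes`` maps the two class labels to sample-id lists.  Each bootstrap
    draws ceil(2n/3) samples per class without replacement, jitters features
    that are constant within the draw, fits the regularized discriminant and
    accumulates per-feature effects; score = log10(max(1, mean effect)).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    survivors, pvals = kw_screen(table, classes, alpha=alpha)
    if not survivors:
        return []
    (label_a, samples_a), (label_b, samples_b) = classes.items()
    scaled = tss_scale(table.values)
    xa = scaled.loc[survivors, list(samples_a)].to_numpy(dtype=float).T
    xb = scaled.loc[survivors, list(samples_b)].to_numpy(dtype=float).T
    rng = np.random.default_rng(seed)
    take_a = math.ceil(2 * xa.shape[0] / 3)
    take_b = math.ceil(2 * xb.shape[0] / 3)
    scale = max(float(scaled.to_numpy().max()), 1.0)
    effects = np.zeros(len(survivors))
    for _ in range(n_boot):
        sa = xa[rng.choice(xa.shape[0], size=take_a, replace=False)]
        sb = xb[rng.choice(xb.shape[0], size=take_b, replace=False)]
        x = np.vstack([sa, sb])
        constant = np.ptp(x, axis=0) == 0
        if constant.any():
            x = x.copy()
            x[:, constant] += rng.normal(0.0, 1e-5 * scale, size=(x.shape[0], int(constant.sum())))
        w = _lda_direction(x, sa.shape[0])
        mu_a, mu_b = x[: sa.shape[0]].mean(axis=0), x[sa.shape[0]:].mean(axis=0)
        delta = mu_b - mu_a
        delta_proj = float(delta @ w)
        effects += np.abs(delta + w * delta_proj) / 2
    effects /= n_boot
    meta = table.feature_meta or {}
    scores = []
    for fid, eff in zip(survivors, effects):
        mean_a = float(scaled.loc[fid, list(samples_a)].mean())
        mean_b = float(scaled.loc[fid, list(samples_b)].mean())
        scores.append(
            LdaScore(
                feature_id=str(fid),
                taxonomy=str(meta.get(fid, "")),
                direction=label_b if mean_b >= mean_a else label_a,
                score=float(np.log10(max(1.0, eff))),
                kw_p=pvals[fid],
            )
        )
    return scores


def top_k(scores: list[LdaScore], k: int = 10) -> list[LdaScore]:
    """The k scores with largest |score|; ties broken by kw_p then id."""
    ranked = sorted(scores, key=lambda s: (-abs(s.score), s.kw_p, s.feature_id))
    return ranked[:k]


def scores_frame(scores: list[LdaScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(s) for s in scores],
        columns=["feature_id", "taxonomy", "direction", "score", "kw_p"],
    )
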