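"""Per-feature two-group differential profiling.

Wilcoxon rank-sum per feature, Benjamini-Hochberg adjustment within one
(table, comparison) family, log2 fold change of group means on the original
scale, and the "marked change" double filter
(q < marked_alpha AND |log2fc| >= marked_lfc).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode``: ``exact`` enumerates the rank-sum null distribution;
    ``normal-approx`` uses the tie- and continuity-corrected normal
    approximation; ``auto`` chooses exact when there are no ties and
    min(n) <= 12.  Returns (U statistic of ``x``, two-sided p).  When every
    value is identical across both groups, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("exact", "normal-approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(x.size * y.size / 2), 1.0
    has_ties = np.unique(combined).size < combined.size
    if mode == "auto":
        mode = "exact" if (not has_ties and min(x.size, y.size) <= 12) else "normal-approx"
    if mode == "exact" and has_ties:
        # exact enumeration is not valid under ties; fall back
        mode = "normal-approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(1.0, res.pvalue))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(x, y, table_min_positive: float | None = None) -> float:
    """log2(mean(y) / mean(x)) with a pseudocount policy for zero means.

    A zero group mean is replaced by half the smallest positive value
    observed for the feature's table (``table_min_positive``); when both
    means are zero the fold change is 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    mx, my = float(np.mean(x)), float(np.mean(y))
    if mx == 0 and my == 0:
        return 0.0
    if mx == 0 or my == 0:
        if table_min_positive is None or table_min_positive <= 0:
            raise ValueError("zero group mean requires a positive table_min_positive")
        pseudo = table_min_positive / 2
        mx = mx or pseudo
        my = my or pseudo
    return float(np.log2(my / mx))


def differential_profile(table, group_a: list, group_b: list, config) -> pd.DataFrame:
    """Differential records for every feature, B vs A (e.g. KO-WD vs WT-ND).

    Features undetected in both groups (all-zero) are excluded before BH and
    their count logged.  ``marked`` applies the double filter
    q < ``config.marked_alpha`` AND |log2fc| >= ``config.marked_lfc``.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    for s in list(group_a) + list(group_b):
        if s not in set(table.sample_ids):
            raise ValueError(f"sample {s!r} not in table")
    A = table.values[list(group_a)]
    B = table.values[list(group_b)]
    arr = table.values.to_numpy()
    positive = arr[arr > 0]
    table_min = float(positive.min()) if positive.size else None

    detected, undetected = [], []
    for fid in table.feature_ids:
        if A.loc[fid].sum() == 0 and B.loc[fid].sum() == 0:
            undetected.append(fid)
        else:
            detected.append(fid)
    if undetected:
        log.info(
            "%s/%s: %d features undetected in both groups excluded before BH",
            table.compartment, table.layer, len(undetected),
        )

    rows = []
    for fid in detected:
        a = A.loc[fid].to_numpy(dtype=float)
        b = B.loc[fid].to_numpy(dtype=float)
        stat, p = wilcoxon_rank_sum(a, b)
        lfc = log2_fold_change(a, b, table_min_positive=table_min)
        rows.append(
            {
                "feature_id": fid,
                "compartment": table.compartment,
                "layer": table.layer,
                "mean_A": float(np.mean(a)),
                "mean_B": float(np.mean(b)),
                "log2fc": lfc,
                "p": p,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=["feature_id", "compartment", "layer", "mean_A", "mean_B", "log2fc", "p"],
    )
    if len(records):
        records["q"] = bh_adjust(records["p"].to_numpy())
        records["marked"] = (records["q"] < config.marked_alpha) & (
            records["log2fc"].abs() >= config.marked_lfc
        )
    else:
        records["q"] = []
        records["marked"] = []
    log.info(
        "%s/%s differential: %d tested, %d marked (q<%g, |lfc|>=%g)",
        table.compartment, table.layer, len(records), int(records["marked"].sum()) if len(records) else 0,
        config.marked_alpha, config.marked_lfc,
    )
    return records


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """Volcano export: log2fc, -log10 adjusted p, direction of change."""
    out = records[["feature_id", "log2fc"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_q"] = -np.log10(records["q"].to_numpy(dtype=float))
    out["direction"] = np.where(
        records["log2fc"] > 0, "up", np.where(records["log2fc"] < 0, "down", "flat")
    )
    return out
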