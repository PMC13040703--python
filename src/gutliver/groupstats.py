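"""Phenotype-level group statistics for the 2x2 (genotype x diet) design.

The two-way ANOVA is expressed through cell-mean contrasts, which for a 2x2
layout coincide with Type III sums of squares: with cells ordered
(WT-ND, WT-WD, KO-ND, KO-WD),

    genotype    c = ( 1/2,  1/2, -1/2, -1/2)
    diet        c = ( 1/2, -1/2,  1/2, -1/2)
    interaction c = (   1,   -1,   -1,    1)

SS(c) = L^2 / sum(c_i^2 / n_i) with L = sum(c_i * mean_i), tested against the
pooled within-cell mean square on (1, N - 4) degrees of freedom.  Because the
computation only needs per-cell means, SDs and ns, it applies equally to raw
data and to published summary tables.

All-pairs comparisons: Tukey-Kramer (studentized range on cell means with the
pooled MSE) and Steel-Dwass (pairwise tie-corrected Wilcoxon statistics
referred to the studentized range with df = infinity, divided by sqrt(2)).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
from scipy import stats

from gutliver.tables import GROUPS

log = logging.getLogger(__name__)

_CONTRASTS = {
    "genotype": np.array([0.5, 0.5, -0.5, -0.5]),
    "diet": np.array([0.5, -0.5, 0.5, -0.5]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


@dataclasses.dataclass(frozen=True)
class CellSummary:
    """Mean, sample SD (divisor n-1) and n of one design cell."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"cell n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("cell sd must be non-negative")


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    """F statistics and p-values of the unbalanced 2x2 two-way ANOVA."""

    F_genotype: float
    F_diet: float
    F_interaction: float
    p_genotype: float
    p_diet: float
    p_interaction: float
    df1: int
    df2: int
    mse: float


def anova2_from_summary(cells: list[CellSummary] | tuple) -> AnovaResult:
    """Two-way ANOVA from four cell summaries in (WT-ND, WT-WD, KO-ND, KO-WD) order."""
    if len(cells) != 4:
        raise ValueError(f"expected 4 cell summaries, got {len(cells)}")
    means = np.array([c.mean for c in cells], dtype=float)
    sds = np.array([c.sd for c in cells], dtype=float)
    ns = np.array([c.n for c in cells], dtype=int)
    df2 = int(ns.sum() - 4)
    mse = float(np.sum((ns - 1) * sds**2) / np.sum(ns - 1))
    out: dict = {}
    for name, c in _CONTRASTS.items():
        L = float(np.sum(c * means))
        ss = L**2 / float(np.sum(c**2 / ns))
        F = ss / mse if mse > 0 else (0.0 if ss == 0 else np.inf)
        out[f"F_{name}"] = F
        out[f"p_{name}"] = float(stats.f.sf(F, 1, df2))
    return AnovaResult(df1=1, df2=df2, mse=mse, **out)


def anova2_from_raw(values, genotype, diet) -> AnovaResult:
    """Two-way ANOVA from raw observations with per-sample genotype/diet labels."""
    values = np.asarray(values, dtype=float)
    genotype = np.asarray(genotype)
    diet = np.asarray(diet)
    cells = []
    for label in GROUPS:
        g, d = label.split("-")
        x = values[(genotype == g) & (diet == d)]
        if x.size < 2:
            raise ValueError(f"cell {label} has {x.size} observations; need >= 2")
        cells.append(CellSummary(mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), n=int(x.size)))
    return anova2_from_summary(cells)


def tukey_hsd(groups: list) -> np.ndarray:
    """Tukey-Kramer all-pairs adjusted p-values.

    Returns a symmetric k x k matrix of p-values (diagonal 1).  Uses the
    studentized-range distribution with the pooled within-group MSE; with all
    within-group variance zero and equal means, p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df = int(ns.sum() - k)
    mse = float(sum(((g - g.mean()) ** 2).sum() for g in groups) / df)
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        if mse == 0:
            pij = 1.0 if means[i] == means[j] else 0.0
        else:
            q = abs(means[i] - means[j]) / np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
            pij = float(stats.studentized_range.sf(q, k, df))
        p[i, j] = p[j, i] = min(1.0, pij)
    return p


def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized tie-corrected Wilcoxon rank-sum statistic of x within (x, y)."""
    nx, ny = x.size, y.size
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = ranks[:nx].sum()
    e = nx * (n + 1) / 2
    _, counts = np.unique(combined, return_counts=True)
    tie = np.sum(counts**3 - counts) / (n * (n - 1))
    var = nx * ny / 12 * ((n + 1) - tie)
    if var <= 0:
        return 0.0
    return float((w - e) / np.sqrt(var))


def steel_dwass(groups: list) -> np.ndarray:
    """Steel-Dwass all-pairs adjusted p-values (large-sample approximation).

    Each pair is re-ranked on its own; the standardized rank-sum statistic is
    referred to the studentized range with ``k`` groups and df = infinity via
    q = |z| * sqrt(2).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        z = _rank_sum_z(groups[i], groups[j])
        pij = float(stats.studentized_range.sf(abs(z) * np.sqrt(2), k, np.inf))
        p[i, j] = p[j, i] = min(1.0, pij)
    return p


#: Footnote letter assigned when a group differs from the given reference.
_FLAG_REFERENCES = (("a", "WT-ND"), ("b", "WT-WD"), ("c", "KO-ND"))


def significance_flags(
    groups: dict, alpha: float = 0.05, method: str = "tukey"
) -> dict:
    """Per-group significance letters vs the fixed reference groups.

    ``a``: p < alpha vs WT-ND, ``b``: vs WT-WD, ``c``: vs KO-ND, using either
    the Tukey-Kramer or Steel-Dwass all-pairs test.  A group never flags
    against itself.
    """
    unknown = set(groups) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    labels = [g for g in GROUPS if g in groups]
    data = [groups[g] for g in labels]
    if method == "tukey":
        p = tukey_hsd(data)
    elif method == "steel_dwass":
        p = steel_dwass(data)
    else:
        raise ValueError(f"unknown method {method!r}")
    idx = {g: i for i, g in enumerate(labels)}
    flags: dict = {g: set() for g in labels}
    for letter, ref in _FLAG_REFERENCES:
        if ref not in idx:
            raise ValueError(f"reference group {ref!r} absent")
        for g in labels:
            if g != ref and p[idx[g], idx[ref]] < alpha:
                flags[g].add(letter)
    return flags


def phenotype_report(phenotypes, alpha: float = 0.05) -> "pd.DataFrame":
    """Per-marker summary: cell means +/- SD, two-way ANOVA Fs, flag letters.

    Flags are computed with both Tukey-Kramer and Steel-Dwass; disagreements
    between the two tests are logged, since which applies to which marker is
    a per-marker judgement call.
    """
    import pandas as pd

    rows = []
    group = phenotypes.group
    for marker in phenotypes.phenotypes.columns:
        vals = phenotypes.phenotypes[marker]
        cells = {g: vals[group == g].to_numpy(dtype=float) for g in GROUPS}
        res = anova2_from_raw(vals.to_numpy(dtype=float), phenotypes.genotype.to_numpy(), phenotypes.diet.to_numpy())
        ft = significance_flags(cells, alpha=alpha, method="tukey")
        fs = significance_flags(cells, alpha=alpha, method="steel_dwass")
        if ft != fs:
            log.info("marker %s: Tukey and Steel-Dwass flags disagree (%s vs %s)", marker, ft, fs)
        row = {"marker": marker}
        for g in GROUPS:
            row[f"{g}_mean"] = cells[g].mean()
            row[f"{g}_sd"] = cells[g].std(ddof=1)
            row[f"{g}_flags"] = "".join(sorted(ft[g]))
        row.update(
            F_genotype=res.F_genotype, F_diet=res.F_diet, F_interaction=res.F_interaction,
            p_genotype=res.p_genotype, p_diet=res.p_diet, p_interaction=res.p_interaction,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")
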