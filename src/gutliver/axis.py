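"""Module-phenotype correlation and gut-to-liver axis network extraction.

Modules are screened on two criteria: a phenotype with |Spearman rho| >= 0.6
against the module eigengene, and a significant eigengene difference between
the extreme groups (KO-WD vs WT-ND, Wilcoxon p < 0.05).  Hepatic hub
metabolites are liver features passing the marked-change filter inside the
selected modules.  Axis edges connect gut-side features (SI or LI; any layer)
of selected modules to hubs when |Spearman rho| >= ``axis_rho`` across
samples, one subnetwork per intestinal compartment.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from gutliver.differential import wilcoxon_rank_sum

log = logging.getLogger(__name__)


def module_trait_correlation(MEs: pd.DataFrame, phenotypes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p per (module, phenotype).

    ``MEs`` and ``phenotypes`` are samples x modules / samples x markers over
    identical samples.  A constant phenotype yields missing rho/p.
    """
    if list(MEs.index) != list(phenotypes.index):
        raise ValueError("MEs and phenotypes must share identical sample order")
    rho = pd.DataFrame(index=MEs.columns, columns=phenotypes.columns, dtype=float)
    pval = rho.copy()
    for m in MEs.columns:
        for ph in phenotypes.columns:
            y = phenotypes[ph].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                log.warning("phenotype %s constant; correlation undefined", ph)
                continue
            r, p = stats.spearmanr(MEs[m].to_numpy(), y)
            rho.loc[m, ph] = r
            pval.loc[m, ph] = p
    return rho, pval


def select_modules(
    rho: pd.DataFrame,
    MEs: pd.DataFrame,
    contrast_samples: dict,
    rho_threshold: float = 0.6,
    alpha: float = 0.05,
) -> list:
    """Modules with max |rho| >= threshold AND a significant group contrast.

    ``contrast_samples`` maps the two contrast group labels (KO-WD, WT-ND)
    to their sample ids.  Both criteria are logged per module.
    """
    if len(contrast_samples) != 2:
        raise ValueError("exactly two contrast groups required")
    for label, samples in contrast_samples.items():
        if len(samples) == 0:
            raise ValueError(f"contrast group {label!r} has no samples")
        missing = set(samples) - set(MEs.index)
        if missing:
            raise ValueError(f"contrast group {label!r}: samples absent from MEs: {sorted(missing)}")
    (sa, sb) = contrast_samples.values()
    selected = []
    for m in rho.index:
        max_rho = rho.loc[m].abs().max()
        corr_ok = bool(pd.notna(max_rho) and max_rho >= rho_threshold)
        _, p = wilcoxon_rank_sum(
            MEs.loc[list(sa), m].to_numpy(), MEs.loc[list(sb), m].to_numpy()
        )
        diff_ok = p < alpha
        log.info(
            "module %s: max |rho| = %.3f (%s), contrast p = %.4f (%s)",
            m, 0.0 if pd.isna(max_rho) else max_rho,
            "pass" if corr_ok else "fail", p, "pass" if diff_ok else "fail",
        )
        if corr_ok and diff_ok:
            selected.append(m)
    return selected


def module_composition(labels: pd.Series, origin: pd.DataFrame) -> pd.DataFrame:
    """Per-module counts of taxa / enzyme / metabolite members."""
    rows = []
    for m in sorted(set(labels[labels > 0])):
        members = labels[labels == m].index
        layer = origin.loc[members, "layer"]
        rows.append(
            {
                "module": m,
                "size": len(members),
                "taxa": int((layer == "taxa").sum()),
                "enzyme": int((layer == "enzyme").sum()),
                "metabolite": int((layer == "metabolite").sum()),
            }
        )
    return pd.DataFrame(rows, columns=["module", "size", "taxa", "enzyme", "metabolite"]).set_index("module")


def hepatic_hubs(
    liver_records: pd.DataFrame,
    labels: pd.Series,
    origin: pd.DataFrame,
    selected_modules: list,
    config,
    restrict_to_selected: bool = True,
) -> pd.DataFrame:
    """Liver metabolites passing the marked-change filter, inside selected modules.

    Filter: q < ``config.marked_alpha`` (strict) and |log2fc| >=
    ``config.marked_lfc`` (inclusive).  ``restrict_to_selected`` lifts the
    module-membership requirement when False.
    """
    passing = liver_records[
        (liver_records["q"] < config.marked_alpha)
        & (liver_records["log2fc"].abs() >= config.marked_lfc)
    ].copy()
    liver_mask = (origin["compartment"] == "liver") & (origin["layer"] == "metabolite")
    id_to_feature = {
        origin.loc[f, "feature_id"]: f for f in origin.index[liver_mask]
    }
    rows = []
    for _, rec in passing.iterrows():
        feature = id_to_feature.get(str(rec["feature_id"]))
        if feature is None:
            continue
        module = int(labels.get(feature, 0))
        if restrict_to_selected and module not in selected_modules:
            continue
        rows.append(
            {
                "feature": feature,
                "feature_id": str(rec["feature_id"]),
                "module": module,
                "log2fc": float(rec["log2fc"]),
                "q": float(rec["q"]),
            }
        )
    hubs = pd.DataFrame(rows, columns=["feature", "feature_id", "module", "log2fc", "q"])
    log.info("hepatic hubs: %d of %d marked liver metabolites retained", len(hubs), len(passing))
    return hubs


@dataclasses.dataclass
class AxisNetwork:
    """Edge set of one gut-liver axis (SI-liver or LI-liver)."""

    compartment: str  # the intestinal side: SI or LI
    edges: pd.DataFrame  # gut_feature, gut_layer, gut_module, hub, rho, hub_log2fc, hub_q

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for _, e in self.edges.iterrows():
            g.add_node(e["gut_feature"], side=self.compartment, layer=e["gut_layer"],
                       module=int(e["gut_module"]))
            g.add_node(e["hub"], side="liver", layer="metabolite",
                       log2fc=float(e["hub_log2fc"]), q=float(e["hub_q"]),
                       direction="up" if e["hub_log2fc"] > 0 else "down")
            g.add_edge(e["gut_feature"], e["hub"], rho=float(e["rho"]))
        nx.write_graphml(g, path)


def extract_axis(
    Z: pd.DataFrame,
    labels: pd.Series,
    origin: pd.DataFrame,
    hubs: pd.DataFrame,
    selected_modules: list,
    config,
) -> dict:
    """SI-liver and LI-liver axis networks from the cross-compartment Z matrix.

    For each gut-side feature in a selected module and each hepatic hub, the
    tie-corrected Spearman rho across samples is computed; edges with
    |rho| >= ``config.axis_rho`` are kept.  Every emitted edge is re-checked
    against all three thresholds before return.
    """
    missing = [h for h in hubs["feature"] if h not in Z.index]
    if missing:
        raise ValueError(f"hub features absent from Z: {missing}")
    networks = {}
    for side in ("SI", "LI"):
        mask = (origin["compartment"] == side) & labels.isin(selected_modules)
        gut_features = [f for f in Z.index if mask.get(f, False)]
        rows = []
        for hub in hubs.itertuples():
            hz = Z.loc[hub.feature].to_numpy(dtype=float)
            for f in gut_features:
                rho, _ = stats.spearmanr(Z.loc[f].to_numpy(dtype=float), hz)
                if np.isfinite(rho) and abs(rho) >= config.axis_rho - 1e-12:
                    rows.append(
                        {
                            "gut_feature": f,
                            "gut_layer": origin.loc[f, "layer"],
                            "gut_module": int(labels[f]),
                            "hub": hub.feature,
                            "hub_module": int(hub.module),
                            "rho": float(rho),
                            "hub_log2fc": float(hub.log2fc),
                            "hub_q": float(hub.q),
                        }
                    )
        edges = pd.DataFrame(
            rows,
            columns=["gut_feature", "gut_layer", "gut_module", "hub", "hub_module",
                     "rho", "hub_log2fc", "hub_q"],
        )
        _assert_thresholds(edges, config)
        log.info("%s-liver axis: %d edges (|rho| >= %g)", side, len(edges), config.axis_rho)
        networks[side] = AxisNetwork(compartment=side, edges=edges)
    return networks


def _assert_thresholds(edges: pd.DataFrame, config) -> None:
    """Every emitted edge must satisfy all three published thresholds."""
    if len(edges) == 0:
        return
    ok = (
        (edges["rho"].abs() >= config.axis_rho - 1e-12)
        & (edges["hub_q"] < config.marked_alpha)
        & (edges["hub_log2fc"].abs() >= config.marked_lfc)
    )
    if not ok.all():
        raise AssertionError("axis edge violates |rho|/hub-q/hub-lfc thresholds")


def write_edges(network: AxisNetwork, path) -> None:
    """Tab-separated edge list with full-precision rho values."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = list(network.edges.columns)
        fh.write("\t".join(cols) + "\n")
        for _, e in network.edges.iterrows():
            fh.write("\t".join(str(e[c]) for c in cols) + "\n")
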