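"""End-to-end pipeline chaining every analysis stage, writing a result bundle.

The run is a pure function of (inputs, config): repeated runs with the same
seed produce byte-identical outputs.  Each stage logs input shapes, the
thresholds applied and the counts surviving each filter.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from gutliver import __version__, axis as axis_mod, wgcna
from gutliver.config import AnalysisConfig
from gutliver.differential import differential_profile, volcano_table
from gutliver.diversity import diversity_report
from gutliver.groupstats import phenotype_report
from gutliver.lefse import lda_effect_size, scores_frame, top_k
from gutliver.tables import check_sample_consistency

log = logging.getLogger(__name__)

CONTRAST = ("WT-ND", "KO-WD")  # the study's most contrasting comparison


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def run_pipeline(config: AnalysisConfig, tables: list, phenotypes, tree=None, out_dir="results"):
    """Run groupstats, differential, diversity, LDA ranking, network and axis.

    ``tables`` must share exactly the phenotype sample ids.  Returns a dict of
    in-memory results; everything is also written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    check_sample_consistency(tables, phenotypes)
    group_a = phenotypes.group_samples(CONTRAST[0])
    group_b = phenotypes.group_samples(CONTRAST[1])
    results: dict = {}

    if phenotypes.phenotypes.shape[1]:
        stats_table = phenotype_report(phenotypes)
        _write_tsv(stats_table, out / "groupstats.tsv")
        results["groupstats"] = stats_table

    diffs = {}
    for t in tables:
        key = f"{t.compartment}_{t.layer}"
        records = differential_profile(t, group_a, group_b, config)
        _write_tsv(records.set_index("feature_id"), out / f"differential_{key}.tsv")
        _write_tsv(
            volcano_table(records).set_index("feature_id"), out / f"volcano_{key}.tsv"
        )
        diffs[key] = records
    results["differential"] = diffs

    for t in tables:
        if t.layer != "taxa":
            continue
        key = f"{t.compartment}_{t.layer}"
        div = diversity_report(t, phenotypes, tree=tree, config=config)
        _write_tsv(div["alpha"], out / f"alpha_{key}.tsv")
        for metric, dm in div["beta"].items():
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
                out / f"beta_{key}_{metric}.tsv", sep="\t"
            )
            coords, prop = div["pcoa"][metric]
            coords = coords.copy()
            if coords.shape[1]:
                coords.loc["proportion_explained"] = list(prop) + [0.0] * (
                    coords.shape[1] - len(prop)
                )
            _write_tsv(coords, out / f"pcoa_{key}_{metric}.tsv")
        pd.DataFrame(div["permanova"]).T.to_csv(out / f"permanova_{key}.tsv", sep="\t")
        results[f"diversity_{key}"] = div

        scores = lda_effect_size(
            t,
            {CONTRAST[0]: group_a, CONTRAST[1]: group_b},
            n_boot=config.lefse_boot,
            seed=config.rng_seed,
            alpha=config.lefse_alpha,
        )
        ranked = top_k(scores, k=10)
        _write_tsv(scores_frame(ranked).set_index("feature_id"), out / f"lda_top10_{key}.tsv")
        _write_tsv(scores_frame(scores).set_index("feature_id"), out / f"lda_all_{key}.tsv")
        results[f"lda_{key}"] = scores

    net = wgcna.build_network(tables, config)
    assignments = net.origin.copy()
    assignments["module"] = net.labels
    _write_tsv(assignments, out / "modules.tsv", index_label="feature")
    _write_tsv(net.MEs, out / "module_eigengenes.tsv", index_label="sample")
    results["network"] = net

    sample_order = list(net.Z.columns)
    pheno_aligned = phenotypes.phenotypes.loc[sample_order]
    if net.MEs.shape[1] and pheno_aligned.shape[1]:
        rho, pval = axis_mod.module_trait_correlation(net.MEs, pheno_aligned)
        table6 = rho.abs().round(3).astype(object)
        table6[rho.abs() >= 0.6] = table6[rho.abs() >= 0.6].map(lambda v: f"{v}*")
        _write_tsv(table6, out / "module_trait_abs_rho.tsv", index_label="module")
        _write_tsv(rho, out / "module_trait_rho.tsv", index_label="module")
        _write_tsv(
            axis_mod.module_composition(net.labels, net.origin), out / "module_composition.tsv"
        )
        selected = axis_mod.select_modules(
            rho,
            net.MEs,
            {CONTRAST[1]: group_b, CONTRAST[0]: group_a},
            rho_threshold=0.6,
            alpha=0.05,
        )
        results["selected_modules"] = selected
        liver_key = "liver_metabolite"
        if liver_key in diffs:
            hubs = axis_mod.hepatic_hubs(
                diffs[liver_key], net.labels, net.origin, selected, config
            )
            networks = axis_mod.extract_axis(
                net.Z, net.labels, net.origin, hubs, selected, config
            )
            for side, network in networks.items():
                axis_mod.write_edges(network, out / f"axis_{side}_liver_edges.tsv")
                network.to_graphml(out / f"axis_{side}_liver.graphml")
            results["axis"] = networks
            results["hubs"] = hubs

    meta = {
        "config": config.to_dict(),
        "version": __version__,
        "n_samples": len(phenotypes.sample_ids),
        "tables": [
            {"compartment": t.compartment, "layer": t.layer, "n_features": t.shape[0]}
            for t in tables
        ],
        "contrast": list(CONTRAST),
    }
    with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: results under %s", out)
    return results
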