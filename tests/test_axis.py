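"""Module-trait correlation, module selection, hubs, axis extraction."""

import numpy as np
import pandas as pd
import pytest

from gutliver.axis import (
    extract_axis,
    hepatic_hubs,
    module_composition,
    module_trait_correlation,
    select_modules,
)
from gutliver.config import AnalysisConfig
from gutliver.simulate import generate_study, standard_design
from gutliver.wgcna import build_network


def shared_factor_study(seed=0, noise_sd=0.3, li_independent=True):
    """Module 1 spans SI and liver (the planted axis); module 2 is LI-only
    and carries no group effect, so only the SI-liver coupling is disease-like."""
    design = standard_design(
        blocks=[("SI", "metabolite", 50), ("LI", "metabolite", 50), ("liver", "metabolite", 50)],
        n_modules=2,
        module_size=40,
        loading=1.0,
        noise_sd=noise_sd,
        factor_effects={1: (2.0, 1.5, 1.5), 2: (0.0, 0.0, 0.0)},
        phenotype_loadings={"ALT": {1: 1.0}},
        module_blocks={1: [("SI", "metabolite"), ("liver", "metabolite")],
                       2: [("LI", "metabolite")]} if li_independent else None,
        seed=seed,
    )
    liver_members = [f for f, m in design.module_assignment.items()
                     if f.startswith("liver_") and m == 1][:4]
    for fid in liver_members:
        design.planted_lfc[fid] = 4.0
    return design, generate_study(design)


class TestModuleTrait:
    def test_phenotype_equal_to_eigengene(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(20)]
        mes = pd.DataFrame({1: rng.standard_normal(20)}, index=samples)
        pheno = pd.DataFrame({"ALT": mes[1].to_numpy()}, index=samples)
        rho, p = module_trait_correlation(mes, pheno)
        assert np.isclose(rho.loc[1, "ALT"], 1.0)
        assert p.loc[1, "ALT"] < 1e-10

    def test_constant_phenotype_missing(self):
        samples = [f"s{i}" for i in range(10)]
        mes = pd.DataFrame({1: np.arange(10.0)}, index=samples)
        pheno = pd.DataFrame({"flat": np.ones(10)}, index=samples)
        rho, _ = module_trait_correlation(mes, pheno)
        assert pd.isna(rho.loc[1, "flat"])

    def test_null_max_abs_rho_mostly_below_threshold(self):
        """At n = 28 a phenotype independent of all eigengenes rarely reaches
        the 0.6 selection threshold."""
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(28)]
        hits = 0
        for _ in range(100):
            mes = pd.DataFrame(rng.standard_normal((28, 6)), index=samples,
                               columns=range(1, 7))
            pheno = pd.DataFrame({"x": rng.standard_normal(28)}, index=samples)
            rho, _ = module_trait_correlation(mes, pheno)
            hits += float(rho.abs().to_numpy().max()) >= 0.6
        assert hits <= 20

    def test_planted_loading_dominates_matrix(self):
        design, study = shared_factor_study(seed=2)
        net = build_network(study.tables, AnalysisConfig())
        pheno = study.phenotypes.phenotypes.loc[net.Z.columns]
        rho, _ = module_trait_correlation(net.MEs, pheno)
        best_module = rho["ALT"].abs().idxmax()
        members = net.labels[net.labels == best_module].index
        si_or_liver = net.origin.loc[members, "compartment"].isin(["SI", "liver"])
        assert si_or_liver.mean() > 0.9


class TestSelectModules:
    def _mes(self, rng, n=16):
        samples = [f"s{i}" for i in range(n)]
        mes = pd.DataFrame(
            {1: np.concatenate([np.zeros(n // 2), np.ones(n // 2)]) + rng.normal(0, 0.1, n)},
            index=samples,
        )
        groups = {"KO-WD": samples[n // 2:], "WT-ND": samples[: n // 2]}
        return mes, groups

    def test_rho_just_below_threshold_excluded(self):
        rng = np.random.default_rng(3)
        mes, groups = self._mes(rng)
        rho = pd.DataFrame({"ALT": [0.59]}, index=[1])
        assert select_modules(rho, mes, groups) == []

    def test_planted_disease_module_selected(self):
        rng = np.random.default_rng(4)
        mes, groups = self._mes(rng)
        rho = pd.DataFrame({"ALT": [0.85]}, index=[1])
        assert select_modules(rho, mes, groups) == [1]

    def test_correlation_without_group_difference_excluded(self):
        """A module can correlate with a phenotype yet not differ between the
        contrast groups; such modules are dropped."""
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(16)]
        mes = pd.DataFrame({1: rng.standard_normal(16)}, index=samples)
        groups = {"KO-WD": samples[8:], "WT-ND": samples[:8]}
        rho = pd.DataFrame({"ALT": [0.9]}, index=[1])
        assert select_modules(rho, mes, groups) == []

    def test_all_zero_matrix_empty(self):
        rng = np.random.default_rng(6)
        mes, groups = self._mes(rng)
        rho = pd.DataFrame({"ALT": [0.0]}, index=[1])
        assert select_modules(rho, mes, groups) == []

    def test_missing_contrast_group_rejected(self):
        rng = np.random.default_rng(7)
        mes, groups = self._mes(rng)
        with pytest.raises(ValueError):
            select_modules(pd.DataFrame({"ALT": [0.9]}, index=[1]), mes,
                           {"KO-WD": [], "WT-ND": groups["WT-ND"]})


class TestHepaticHubs:
    def _setup(self):
        features = [f"liver/metabolite:m{i}" for i in range(6)]
        origin = pd.DataFrame(
            {
                "feature_id": [f"m{i}" for i in range(6)],
                "compartment": "liver",
                "layer": "metabolite",
            },
            index=features,
        )
        labels = pd.Series([1] * 6, index=features)
        return origin, labels

    def test_printed_toy_records(self, config):
        """Six (q, lfc) pairs: strict q < 0.05 and inclusive |lfc| >= 2.5
        leave exactly three."""
        origin, labels = self._setup()
        records = pd.DataFrame(
            {
                "feature_id": [f"m{i}" for i in range(6)],
                "q": [0.01, 0.2, 0.01, 0.04, 0.05, 0.01],
                "log2fc": [3.0, 3.0, 1.0, -2.6, 4.0, 2.5],
            }
        )
        hubs = hepatic_hubs(records, labels, origin, [1], config)
        assert sorted(hubs["feature_id"]) == ["m0", "m3", "m5"]

    def test_membership_restriction_and_lift(self, config):
        origin, labels = self._setup()
        labels.iloc[0] = 2  # module not selected
        records = pd.DataFrame(
            {"feature_id": ["m0"], "q": [0.01], "log2fc": [5.0]}
        )
        assert len(hepatic_hubs(records, labels, origin, [1], config)) == 0
        lifted = hepatic_hubs(records, labels, origin, [1], config, restrict_to_selected=False)
        assert len(lifted) == 1


class TestExtractAxis:
    def test_planted_si_liver_edge_recovered(self, config):
        design, study = shared_factor_study(seed=8)
        net = build_network(study.tables, AnalysisConfig())
        from gutliver.differential import differential_profile

        liver = [t for t in study.tables if t.compartment == "liver"][0]
        records = differential_profile(
            liver,
            study.phenotypes.group_samples("WT-ND"),
            study.phenotypes.group_samples("KO-WD"),
            config,
        )
        selected = sorted(set(net.labels[net.labels > 0]))
        hubs = hepatic_hubs(records, net.labels, net.origin, selected, config)
        assert len(hubs) > 0
        networks = extract_axis(net.Z, net.labels, net.origin, hubs, selected, config)
        assert len(networks["SI"].edges) > 0
        assert (networks["SI"].edges["rho"].abs() >= config.axis_rho).all()

    def test_null_hub_yields_no_edges(self, config):
        rng = np.random.default_rng(9)
        features = [f"SI/metabolite:g{i}" for i in range(30)] + ["liver/metabolite:hub"]
        z = pd.DataFrame(rng.standard_normal((31, 28)), index=features,
                         columns=[f"s{i}" for i in range(28)])
        origin = pd.DataFrame(
            {
                "feature_id": [f"g{i}" for i in range(30)] + ["hub"],
                "compartment": ["SI"] * 30 + ["liver"],
                "layer": "metabolite",
            },
            index=features,
        )
        labels = pd.Series([1] * 31, index=features)
        hubs = pd.DataFrame(
            {"feature": ["liver/metabolite:hub"], "feature_id": ["hub"],
             "module": [1], "log2fc": [4.0], "q": [0.01]}
        )
        networks = extract_axis(z, labels, origin, hubs, [1], config)
        assert len(networks["SI"].edges) == 0

    def test_missing_hub_rejected(self, config):
        z = pd.DataFrame(np.ones((2, 4)) * np.arange(4),
                         index=["SI/metabolite:a", "SI/metabolite:b"],
                         columns=[f"s{i}" for i in range(4)])
        origin = pd.DataFrame(
            {"feature_id": ["a", "b"], "compartment": "SI", "layer": "metabolite"},
            index=z.index,
        )
        hubs = pd.DataFrame(
            {"feature": ["liver/metabolite:gone"], "feature_id": ["gone"],
             "module": [1], "log2fc": [3.0], "q": [0.01]}
        )
        with pytest.raises(ValueError, match="gone"):
            extract_axis(z, pd.Series([1, 1], index=z.index), origin, hubs, [1], config)

    def test_perfect_rho_threshold_boundary(self):
        """axis_rho = 1 keeps only perfectly monotone pairs."""
        config = AnalysisConfig(axis_rho=1.0)
        samples = [f"s{i}" for i in range(10)]
        x = np.arange(10.0)
        near = x.copy()
        near[[8, 9]] = near[[9, 8]]  # one rank swap: rho just below 1
        features = ["SI/metabolite:perfect", "SI/metabolite:noisy", "liver/metabolite:hub"]
        z = pd.DataFrame([x, near, np.exp(x)], index=features, columns=samples)
        origin = pd.DataFrame(
            {"feature_id": ["perfect", "noisy", "hub"],
             "compartment": ["SI", "SI", "liver"], "layer": "metabolite"},
            index=features,
        )
        labels = pd.Series([1, 1, 1], index=features)
        hubs = pd.DataFrame(
            {"feature": ["liver/metabolite:hub"], "feature_id": ["hub"],
             "module": [1], "log2fc": [3.0], "q": [0.01]}
        )
        networks = extract_axis(z, labels, origin, hubs, [1], config)
        assert list(networks["SI"].edges["gut_feature"]) == ["SI/metabolite:perfect"]


class TestComposition:
    def test_counts_sum_to_module_size(self):
        features = [f"SI/taxa:t{i}" for i in range(3)] + [f"liver/metabolite:m{i}" for i in range(2)]
        origin = pd.DataFrame(
            {
                "feature_id": ["t0", "t1", "t2", "m0", "m1"],
                "compartment": ["SI"] * 3 + ["liver"] * 2,
                "layer": ["taxa"] * 3 + ["metabolite"] * 2,
            },
            index=features,
        )
        labels = pd.Series([1, 1, 0, 1, 1], index=features)
        comp = module_composition(labels, origin)
        assert comp.loc[1, "size"] == 4
        assert comp.loc[1, "taxa"] == 2 and comp.loc[1, "metabolite"] == 2
        assert comp.loc[1, ["taxa", "enzyme", "metabolite"]].sum() == comp.loc[1, "size"]
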