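"""Synthetic multi-compartment studies with planted ground truth.

The generator follows a one-factor-per-module latent Gaussian model, which is
exactly the structure the module/eigengene construct assumes, so recovery by
the network stage is a fair test.  For sample s in design cell g, module m:

    f_m(s) = mu_m(g) + eps,   eps ~ N(0, 1)
    mu_m(g) = genotype_effect*[KO] + diet_effect*[WD] + interaction*[KO & WD]

A feature j assigned to module m has log-signal

    baseline_j + loading_j * f_m(s) + shift_j(g) + N(0, noise_sd)

Metabolite/enzyme intensities are the exponentials (log-normal).  Taxa use
the same latent model on log-abundance, closed to relative abundances per
sample (softmax) and optionally multinomially sampled to integer counts.
The planted shift is applied to the KO-WD cell and calibrated as
``ln(2) * planted_lfc - loading * (mu_m(KO-WD) - mu_m(WT-ND))`` so the
expected log2 ratio of KO-WD vs WT-ND mean intensities equals the requested
log2 fold change.

Phenotypes load on the same latent factors:
``p(s) = sum_m loading[p][m] * f_m(s) + N(0, noise_sd)``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from gutliver.tables import FeatureTable, GROUPS, PhenotypeTable

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclasses.dataclass
class FeatureBlock:
    """One (compartment, layer) feature table to generate."""

    compartment: str
    layer: str
    n_features: int


@dataclasses.dataclass
class SyntheticDesign:
    """Full specification of a synthetic study, serializable as ground truth.

    ``module_assignment`` maps feature id -> module id (features absent from
    the map are background); ``loadings`` maps feature id -> latent-factor
    loading; ``factor_effects`` maps module id -> (genotype, diet,
    interaction) shifts in latent-factor units; ``phenotype_loadings`` maps
    phenotype name -> {module id: loading}; ``planted_lfc`` maps feature id
    -> target log2 fold change of KO-WD vs WT-ND.
    """

    blocks: list
    n_per_group: tuple = (6, 6, 8, 8)
    module_assignment: dict = dataclasses.field(default_factory=dict)
    loadings: dict = dataclasses.field(default_factory=dict)
    factor_effects: dict = dataclasses.field(default_factory=dict)
    phenotype_loadings: dict = dataclasses.field(default_factory=dict)
    planted_lfc: dict = dataclasses.field(default_factory=dict)
    noise_sd: float = 0.5
    taxa_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 4 or any(n < 1 for n in self.n_per_group):
            raise ValueError("n_per_group must be four positive integers")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        all_features = set(self.feature_ids())
        stray = set(self.module_assignment) - all_features
        if stray:
            raise ValueError(f"module_assignment refers to unknown features: {sorted(stray)[:5]}")
        for fid, lfc in self.planted_lfc.items():
            if fid not in all_features:
                raise ValueError(f"planted_lfc refers to unknown feature {fid!r}")
            if not np.isfinite(lfc):
                raise ValueError(f"planted_lfc for {fid!r} is not finite")
        modules = set(self.module_assignment.values())
        for ph, loads in self.phenotype_loadings.items():
            unknown = set(loads) - modules - set(self.factor_effects)
            if unknown:
                raise ValueError(f"phenotype {ph!r} loads on unknown modules: {sorted(unknown)}")

    def feature_ids(self) -> list:
        out = []
        for b in self.blocks:
            out += [f"{b.compartment}_{b.layer}_{i:04d}" for i in range(b.n_features)]
        return out

    def modules(self) -> list:
        return sorted(set(self.module_assignment.values()) | set(self.factor_effects))


def standard_design(
    blocks: list,
    n_modules: int,
    module_size: int,
    loading: float = 1.0,
    noise_sd: float = 0.5,
    n_per_group: tuple = (6, 6, 8, 8),
    factor_effects: dict | None = None,
    phenotype_loadings: dict | None = None,
    planted: dict | None = None,
    module_blocks: dict | None = None,
    taxa_depth: int | None = None,
    seed: int = 0,
) -> SyntheticDesign:
    """Convenience builder distributing equal-size modules across blocks.

    Module m takes its members round-robin from the front of each block in
    ``module_blocks[m]`` (default: all blocks), so modules span compartments
    the way shared gut-liver covariation would.  ``planted`` maps feature id
    -> log2 fold change.  Errors when a block runs out of features.
    """
    blocks = [FeatureBlock(*b) if isinstance(b, tuple) else b for b in blocks]
    by_block = {
        (b.compartment, b.layer): [f"{b.compartment}_{b.layer}_{i:04d}" for i in range(b.n_features)]
        for b in blocks
    }
    cursor = {k: 0 for k in by_block}
    assignment: dict = {}
    loadings: dict = {}
    for m in range(1, n_modules + 1):
        keys = module_blocks.get(m) if module_blocks else list(by_block)
        keys = keys or list(by_block)
        for i in range(module_size):
            key = tuple(keys[i % len(keys)])
            pool = by_block[key]
            if cursor[key] >= len(pool):
                raise ValueError(
                    f"module {m} larger than remaining features in block {key}"
                )
            fid = pool[cursor[key]]
            cursor[key] += 1
            assignment[fid] = m
            loadings[fid] = loading
    return SyntheticDesign(
        blocks=blocks,
        n_per_group=tuple(n_per_group),
        module_assignment=assignment,
        loadings=loadings,
        factor_effects=factor_effects or {},
        phenotype_loadings=phenotype_loadings or {},
        planted_lfc=dict(planted or {}),
        noise_sd=noise_sd,
        taxa_depth=taxa_depth,
        seed=seed,
    )


@dataclasses.dataclass
class SyntheticStudy:
    """Generated tables + phenotypes + the design and latent factors (truth)."""

    tables: list
    phenotypes: PhenotypeTable
    factors: pd.DataFrame  # samples x modules
    design: SyntheticDesign


def _group_means(design: SyntheticDesign) -> dict:
    """mu_m(g) for every module and design cell."""
    out: dict = {}
    for m in design.modules():
        ge, de, ie = design.factor_effects.get(m, (0.0, 0.0, 0.0))
        out[m] = {
            "WT-ND": 0.0,
            "WT-WD": de,
            "KO-ND": ge,
            "KO-WD": ge + de + ie,
        }
    return out


def generate_study(design: SyntheticDesign) -> SyntheticStudy:
    """Draw one complete study (tables, phenotypes, latent factors) from a design."""
    rng = np.random.default_rng(design.seed)
    sample_ids, genotypes, diets = [], [], []
    for g, n in zip(GROUPS, design.n_per_group):
        geno, diet = g.split("-")
        for _ in range(n):
            sample_ids.append(f"M{len(sample_ids) + 1:02d}")
            genotypes.append(geno)
            diets.append(diet)
    groups = [f"{g}-{d}" for g, d in zip(genotypes, diets)]
    n_samples = len(sample_ids)

    mu = _group_means(design)
    modules = design.modules()
    factors = pd.DataFrame(
        {
            m: np.array([mu[m][g] for g in groups]) + rng.standard_normal(n_samples)
            for m in modules
        },
        index=sample_ids,
    )

    is_kowd = np.array([g == "KO-WD" for g in groups])
    tables = []
    for block in design.blocks:
        fids = [f"{block.compartment}_{block.layer}_{i:04d}" for i in range(block.n_features)]
        # taxa log-abundances span several orders of magnitude, so that finite
        # sequencing depth produces realistic absences
        base_loc, base_sd = (0.0, 2.0) if block.layer == "taxa" else (10.0, 1.0)
        baselines = rng.normal(base_loc, base_sd, size=len(fids))
        logs = np.empty((len(fids), n_samples))
        for j, fid in enumerate(fids):
            m = design.module_assignment.get(fid)
            load = design.loadings.get(fid, 0.0)
            signal = baselines[j] + (load * factors[m].to_numpy() if m is not None else 0.0)
            lfc = design.planted_lfc.get(fid, 0.0)
            if lfc:
                dmu = (mu[m]["KO-WD"] - mu[m]["WT-ND"]) if m is not None else 0.0
                shift = LN2 * lfc - load * dmu
                signal = signal + shift * is_kowd
            logs[j] = signal + rng.normal(0.0, design.noise_sd, size=n_samples)
        if block.layer == "taxa":
            # compositional closure per sample
            expo = np.exp(logs - logs.max(axis=0, keepdims=True))
            rel = expo / expo.sum(axis=0, keepdims=True)
            if design.taxa_depth:
                counts = np.column_stack(
                    [rng.multinomial(design.taxa_depth, rel[:, s]) for s in range(n_samples)]
                ).astype(float)
                values = counts
            else:
                values = rel
        else:
            values = np.exp(logs)
        tables.append(
            FeatureTable(
                pd.DataFrame(values, index=fids, columns=sample_ids),
                compartment=block.compartment,
                layer=block.layer,
            )
        )

    phenotypes = generate_phenotypes(design, factors, genotypes, diets, rng)
    log.info(
        "generated study: %d samples, %d tables, %d modules, %d planted features",
        n_samples, len(tables), len(modules), len(design.planted_lfc),
    )
    return SyntheticStudy(tables=tables, phenotypes=phenotypes, factors=factors, design=design)


def generate_phenotypes(
    design: SyntheticDesign,
    factors: pd.DataFrame,
    genotypes: list,
    diets: list,
    rng: np.random.Generator,
) -> PhenotypeTable:
    """Phenotypes as noisy linear combinations of the latent module factors."""
    sample_ids = list(factors.index)
    pheno = pd.DataFrame(index=sample_ids)
    for name, loads in design.phenotype_loadings.items():
        unknown = set(loads) - set(factors.columns)
        if unknown:
            raise ValueError(f"phenotype {name!r} loads on unknown modules {sorted(unknown)}")
        signal = np.zeros(len(sample_ids))
        for m, w in loads.items():
            signal = signal + w * factors[m].to_numpy()
        pheno[name] = signal + rng.normal(0.0, design.noise_sd, size=len(sample_ids))
    return PhenotypeTable(
        sample_ids=sample_ids,
        genotype=pd.Series(genotypes, index=sample_ids),
        diet=pd.Series(diets, index=sample_ids),
        phenotypes=pheno,
    )


def truth_report(study: SyntheticStudy, out_dir: str | Path) -> dict:
    """Write module labels, planted fold changes and phenotype loadings as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = study.design
    paths = {
        "modules": out / "truth_modules.tsv",
        "planted_lfc": out / "truth_planted_lfc.tsv",
        "phenotype_loadings": out / "truth_phenotype_loadings.tsv",
    }
    with open(paths["modules"], "w", encoding="utf-8") as fh:
        fh.write("feature_id\tmodule\tloading\n")
        for fid in design.feature_ids():
            fh.write(
                f"{fid}\t{design.module_assignment.get(fid, 0)}\t"
                f"{float(design.loadings.get(fid, 0.0))}\n"
            )
    with open(paths["planted_lfc"], "w", encoding="utf-8") as fh:
        fh.write("feature_id\tlog2fc\n")
        for fid in design.feature_ids():
            fh.write(f"{fid}\t{float(design.planted_lfc.get(fid, 0.0))}\n")
    with open(paths["phenotype_loadings"], "w", encoding="utf-8") as fh:
        fh.write("phenotype\tmodule\tloading\n")
        for ph, loads in design.phenotype_loadings.items():
            for m, w in sorted(loads.items()):
                fh.write(f"{ph}\t{m}\t{float(w)}\n")
    return paths


def demo_design(seed: int = 0) -> SyntheticDesign:
    """A small but complete cross-compartment study for pipeline smoke runs.

    Two disease modules spanning gut and liver (with genotype/diet/interaction
    shifts), phenotypes loading on them, and a handful of strongly planted
    liver metabolites to serve as hepatic hubs.
    """
    blocks = [
        FeatureBlock("SI", "taxa", 40),
        FeatureBlock("LI", "taxa", 40),
        FeatureBlock("SI", "metabolite", 60),
        FeatureBlock("LI", "metabolite", 60),
        FeatureBlock("liver", "metabolite", 80),
        FeatureBlock("plasma", "metabolite", 40),
    ]
    design = standard_design(
        blocks=blocks,
        n_modules=2,
        module_size=36,
        loading=1.0,
        noise_sd=0.5,
        factor_effects={1: (2.0, 1.5, 1.5), 2: (0.0, 2.0, 1.0)},
        phenotype_loadings={
            "ALT": {1: 1.0},
            "hepatic_TG": {2: 1.0},
            "insulin": {1: 0.7, 2: 0.5},
        },
        taxa_depth=20000,  # typical per-sample 16S depth; yields realistic zeros
        seed=seed,
    )
    # plant strong hepatic changes on module members so hubs exist
    module_liver = [
        f for f, m in design.module_assignment.items() if f.startswith("liver_") and m == 1
    ][:4]
    for fid in module_liver:
        design.planted_lfc[fid] = 4.0
    return design
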