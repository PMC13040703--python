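"""Domain containers and TSV readers/writers for feature and phenotype tables.

File dialect: UTF-8, tab-separated, "." decimal separator, no thousands
separators; the first header cell of a feature table is ignored.  ``str(float)``
is used when writing so that numeric round trips are bitwise exact.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COMPARTMENTS = ("liver", "SI", "LI", "plasma")
LAYERS = ("taxa", "enzyme", "metabolite")
GENOTYPES = ("WT", "KO")
DIETS = ("ND", "WD")
#: The four cells of the 2x2 design in canonical order.
GROUPS = ("WT-ND", "WT-WD", "KO-ND", "KO-WD")


def _check_unique(ids, what: str) -> None:
    seen: dict = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = True
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclasses.dataclass
class FeatureTable:
    """Features x samples abundance matrix for one compartment and one layer.

    ``values`` holds non-negative intensities, counts or relative abundances
    with feature ids as the index and sample ids as columns.  ``feature_meta``
    optionally maps feature id to an annotation string (e.g. a taxonomic
    lineage ``k__;p__;...;g__``).
    """

    values: pd.DataFrame
    compartment: str
    layer: str
    feature_meta: dict | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature table contains non-finite values")
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                "negative abundance at feature "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclasses.dataclass
class PhenotypeTable:
    """Per-sample design factors plus continuous phenotype markers.

    ``genotype`` and ``diet`` are aligned to ``sample_ids``; ``phenotypes``
    is a samples x markers frame of finite reals (may have zero columns).
    """

    sample_ids: list
    genotype: pd.Series
    diet: pd.Series
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample ids")
        for name, series in (("genotype", self.genotype), ("diet", self.diet)):
            if list(series.index) != list(self.sample_ids):
                raise ValueError(f"{name} index not aligned to sample_ids")
        bad_g = set(self.genotype) - set(GENOTYPES)
        if bad_g:
            raise ValueError(f"genotype values outside {GENOTYPES}: {sorted(bad_g)}")
        bad_d = set(self.diet) - set(DIETS)
        if bad_d:
            raise ValueError(f"diet values outside {DIETS}: {sorted(bad_d)}")
        if list(self.phenotypes.index) != list(self.sample_ids):
            raise ValueError("phenotype rows not aligned to sample_ids")
        if self.phenotypes.shape[1] and not np.all(
            np.isfinite(self.phenotypes.to_numpy(dtype=float))
        ):
            raise ValueError("phenotype table contains non-finite values")

    @property
    def group(self) -> pd.Series:
        """Group label 'WT-ND' / 'WT-WD' / 'KO-ND' / 'KO-WD' per sample."""
        return self.genotype.str.cat(self.diet, sep="-")

    def group_samples(self, label: str) -> list:
        if label not in GROUPS:
            raise ValueError(f"unknown group {label!r}; expected one of {GROUPS}")
        mask = self.group == label
        return list(self.group.index[mask])

    def group_sizes(self) -> dict:
        return {g: int((self.group == g).sum()) for g in GROUPS}


def read_feature_table(
    path: str | Path, compartment: str, layer: str, feature_meta: dict | None = None
) -> FeatureTable:
    """Read a tab-separated features x samples table.

    First column holds feature ids, the header row holds sample ids.  Parse
    errors name the offending cell with its line number.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        _check_unique(sample_ids, f"sample ids in {path}")
        feature_ids: list = []
        rows: list = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"found {len(cells)}"
                )
            fid = cells[0]
            if fid in set(feature_ids):
                raise ValueError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            vals = []
            for sid, cell in zip(sample_ids, cells[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {cell!r} for "
                        f"feature {fid!r}, sample {sid!r}"
                    ) from None
                if not np.isfinite(v):
                    raise ValueError(
                        f"{path}:{lineno}: non-finite value for feature {fid!r}, "
                        f"sample {sid!r}"
                    )
                if v < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative value {cell!r} for feature "
                        f"{fid!r}, sample {sid!r}"
                    )
                vals.append(v)
            feature_ids.append(fid)
            rows.append(vals)
    values = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=float)
    log.info(
        "read feature table %s: %d features x %d samples (%s/%s)",
        path, len(feature_ids), len(sample_ids), compartment, layer,
    )
    return FeatureTable(values, compartment=compartment, layer=layer, feature_meta=feature_meta)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table in the dialect ``read_feature_table`` expects."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, table.sample_ids)) + "\n")
        for fid, row in table.values.iterrows():
            fh.write(str(fid) + "\t" + "\t".join(str(float(v)) for v in row) + "\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a tab-separated phenotype table: sample, genotype, diet, markers.

    Rows are sorted into canonical (lexicographic) sample order, so the result
    is invariant to row shuffling in the file.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    for required in ("sample", "genotype", "diet"):
        if required not in cols:
            raise ValueError(f"{path}: missing required column {required!r}")
    _check_unique(df["sample"], f"sample ids in {path}")
    df = df.sort_values("sample", kind="mergesort").reset_index(drop=True)
    sample_ids = list(df["sample"])
    pheno_cols = [c for c in cols if c not in ("sample", "genotype", "diet")]
    pheno = pd.DataFrame(index=sample_ids)
    for c in pheno_cols:
        try:
            pheno[c] = pd.to_numeric(df[c], errors="raise").to_numpy()
        except (ValueError, TypeError):
            raise ValueError(f"{path}: non-numeric value in phenotype column {c!r}") from None
    table = PhenotypeTable(
        sample_ids=sample_ids,
        genotype=pd.Series(df["genotype"].to_numpy(), index=sample_ids),
        diet=pd.Series(df["diet"].to_numpy(), index=sample_ids),
        phenotypes=pheno,
    )
    log.info("read phenotypes %s: %d samples, groups %s", path, len(sample_ids), table.group_sizes())
    return table


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        cols = list(table.phenotypes.columns)
        fh.write("\t".join(["sample", "genotype", "diet"] + cols) + "\n")
        for sid in table.sample_ids:
            row = [str(sid), table.genotype[sid], table.diet[sid]]
            row += [str(float(table.phenotypes.loc[sid, c])) for c in cols]
            fh.write("\t".join(row) + "\n")


def check_sample_consistency(tables: list, phenotypes: PhenotypeTable) -> None:
    """Require every table to cover exactly the phenotype samples.

    A mismatch is an error (listing the offending ids), never a silent
    intersection: the study design has every mouse in every compartment.
    """
    ref = set(phenotypes.sample_ids)
    for t in tables:
        got = set(t.sample_ids)
        if got != ref:
            missing = sorted(ref - got)
            extra = sorted(got - ref)
            raise ValueError(
                f"sample-id mismatch in {t.compartment}/{t.layer} table: "
                f"missing={missing}, unexpected={extra}"
            )
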