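"""Tabular input/output, count normalization, FPKM, and replicate averaging.

All files are tab-separated UTF-8; lines starting with ``#`` are comments;
no quoting.  Counts files carry a header row of sample IDs and gene IDs in
the first column.  The sample-design table declares, for every sequencing
library, its genotype, developmental stage, replicate number, whether the
genotype is a mutant, and which genotype it is paired with for stage-wise
contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MUTANT = "mutant"
NON_MUTANT = "non_mutant"

DESIGN_COLUMNS = (
    "sample_id",
    "genotype",
    "stage",
    "replicate",
    "genotype_class",
    "mutant_partner",
)

_READ_KW = dict(sep="\t", comment="#", dtype=str)


@dataclass
class SampleDesign:
    """Sample metadata: one row per library, indexed by sample ID.

    ``stages`` is the shared total order of developmental stages (e.g.
    S1..S5); every genotype is observed at every listed stage.
    """

    table: pd.DataFrame
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns and c != "sample_id"]
        if t.index.name != "sample_id":
            if "sample_id" in t.columns:
                t = t.set_index("sample_id")
            else:
                raise ValueError("design table needs a 'sample_id' column")
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs in design: {dups}")
        t = t.copy()
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        if not self.stages:
            self.stages = tuple(sorted(t["stage"].unique()))
        unknown = set(t["stage"]) - set(self.stages)
        if unknown:
            raise ValueError(f"stages outside declared order: {sorted(unknown)}")
        bad_class = set(t["genotype_class"]) - {MUTANT, NON_MUTANT}
        if bad_class:
            raise ValueError(f"unknown genotype_class values: {sorted(bad_class)}")
        # replicate IDs unique within each (genotype, stage) cell
        dup = t.reset_index().duplicated(subset=["genotype", "stage", "replicate"])
        if dup.any():
            raise ValueError("replicate IDs not unique within (genotype, stage) cells")
        # mutant/non-mutant partnering is a bijection
        for geno, sub in t.groupby("genotype"):
            partners = set(sub["mutant_partner"])
            if len(partners) != 1:
                raise ValueError(f"genotype {geno} has inconsistent mutant_partner")
            partner = partners.pop()
            if partner not in set(t["genotype"]):
                raise ValueError(f"genotype {geno} partnered with unknown {partner}")
            back = set(t.loc[t["genotype"] == partner, "mutant_partner"])
            if back != {geno}:
                raise ValueError(f"partnering not symmetric for {geno} <-> {partner}")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def genotypes(self) -> list[str]:
        """Genotypes in first-appearance order."""
        return list(dict.fromkeys(self.table["genotype"]))

    def genotype_class(self, genotype: str) -> str:
        return str(self.table.loc[self.table["genotype"] == genotype, "genotype_class"].iloc[0])

    @property
    def mutant_pairs(self) -> list[tuple[str, str]]:
        """(mutant, non-mutant partner) pairs in first-appearance order."""
        pairs = []
        for geno in self.genotypes:
            if self.genotype_class(geno) == MUTANT:
                partner = str(
                    self.table.loc[self.table["genotype"] == geno, "mutant_partner"].iloc[0]
                )
                pairs.append((geno, partner))
        return pairs

    @property
    def conditions(self) -> list[tuple[str, str]]:
        """All (genotype, stage) cells, genotype-major, stages in order."""
        return [(g, s) for g in self.genotypes for s in self.stages]

    def condition_label(self, genotype: str, stage: str) -> str:
        return f"{genotype}:{stage}"

    @property
    def condition_labels(self) -> list[str]:
        return [self.condition_label(g, s) for g, s in self.conditions]

    def samples_of(self, genotype: str, stage: str) -> list[str]:
        t = self.table
        mask = (t["genotype"] == genotype) & (t["stage"] == stage)
        return list(t.index[mask])


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared scale.

    ``scale`` is one of raw_counts, normalized_counts, fpkm, log2.
    """

    data: pd.DataFrame
    scale: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        if self.scale == "raw_counts":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise ValueError("raw counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneAnnotation:
    """TF list, GO map, gene lengths, and optional pathway membership."""

    tf_genes: set[str] = field(default_factory=set)
    go_map: dict[str, set[str]] = field(default_factory=dict)
    gene_lengths: dict[str, float] = field(default_factory=dict)
    pathway_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [g for g, ln in self.gene_lengths.items() if not ln > 0]
        if bad:
            raise ValueError(f"non-positive gene lengths for: {bad[:5]}")


# ---------------------------------------------------------------------------
# readers / writers


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, **_READ_KW)
    return SampleDesign(df)


def read_counts(counts_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a counts TSV validated against a design; columns in design order."""
    design = read_design(design_path)
    return read_counts_with_design(counts_path, design)


def read_counts_with_design(counts_path: str | Path, design: SampleDesign) -> ExpressionMatrix:
    df = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"samples in design absent from counts header: {missing}")
    extra = [s for s in df.columns if s not in set(design.sample_ids)]
    if extra:
        raise ValueError(f"samples in counts absent from design: {extra}")
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(bad):
        for c in bad:
            culprit = df[pd.to_numeric(df[c], errors="coerce").isna()].index.tolist()
            raise ValueError(f"non-numeric cell in column {c!r}, gene(s) {culprit[:3]}")
    df = df[design.sample_ids]
    return ExpressionMatrix(df, scale="raw_counts")


def write_matrix(m: ExpressionMatrix, path: str | Path, float_format: str | None = None) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_tf_list(path: str | Path) -> set[str]:
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene_id", "go_term"], dtype=str)
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["go_term"]):
        out.setdefault(g, set()).add(t)
    return out


def read_gene_lengths(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df.columns = ["gene_id", "length_bp"]
    lengths = {g: float(v) for g, v in zip(df["gene_id"], df["length_bp"])}
    return lengths


def load_annotation(
    tf_path: str | Path | None = None,
    go_path: str | Path | None = None,
    lengths_path: str | Path | None = None,
) -> GeneAnnotation:
    return GeneAnnotation(
        tf_genes=read_tf_list(tf_path) if tf_path else set(),
        go_map=read_go_map(go_path) if go_path else {},
        gene_lengths=read_gene_lengths(lengths_path) if lengths_path else {},
    )


# ---------------------------------------------------------------------------
# normalization


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (the standard count normalization).

    The per-gene reference is the geometric mean across samples, computed
    only over genes with all-positive counts; each sample's factor is the
    median of its count/reference ratios over those genes.
    """
    if m.scale != "raw_counts":
        raise ValueError(f"size_factors expects raw_counts, got {m.scale}")
    vals = m.data.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter genes or add a pseudocount"
        )
    sub = vals[allpos]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=m.data.columns, name="size_factor")


def normalize_counts(m: ExpressionMatrix, factors: pd.Series | None = None) -> ExpressionMatrix:
    if factors is None:
        factors = size_factors(m)
    data = m.data.div(factors, axis=1)
    return ExpressionMatrix(data, scale="normalized_counts")


def fpkm(m: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped reads.

    fpkm[g, j] = value[g, j] * 1e9 / (length_g * colsum_j), with the raw
    per-sample column sum as the per-million denominator.
    """
    if m.scale not in ("raw_counts", "normalized_counts"):
        raise ValueError(f"fpkm expects counts, got {m.scale}")
    missing = [g for g in m.gene_ids if g not in ann.gene_lengths]
    if missing:
        raise ValueError(f"genes without length annotation: {missing[:10]}")
    lengths = np.array([ann.gene_lengths[g] for g in m.gene_ids], dtype=float)
    vals = m.data.to_numpy(dtype=float)
    colsums = vals.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("sample with zero total counts")
    out = vals * 1e9 / (lengths[:, None] * colsums[None, :])
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns), scale="fpkm")


def average_replicates(m: ExpressionMatrix, design: SampleDesign) -> ExpressionMatrix:
    """Average replicate columns into one column per (genotype, stage)."""
    unknown = [s for s in m.sample_ids if s not in set(design.sample_ids)]
    if unknown:
        raise ValueError(f"samples not in design: {unknown}")
    cols = {}
    for geno, stage in design.conditions:
        samples = [s for s in design.samples_of(geno, stage) if s in m.data.columns]
        if not samples:
            continue
        cols[design.condition_label(geno, stage)] = m.data[samples].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols), scale=m.scale)
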