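"""Differential expression over stage-wise and between-stage contrasts.

Two contrast families are enumerated from the sample design: stage-wise
(mutant vs. its partnered non-mutant, at each stage) and between-stage
(adjacent developmental stages, within each genotype).  The internal test
is deliberately lightweight: a pooled two-sample t-test on
log2(normalized count + 1) with Benjamini-Hochberg adjustment per
contrast.  The pooled (equal-variance) form is used rather than Welch's
because with triplicate groups the Welch-Satterthwaite degrees of freedom
collapse toward 2, which puts a hard floor on attainable p-values and
makes even very large fold changes undetectable at stringent FDR; with
equal group sizes the pooled test keeps df = n_a + n_b - 2.  It is not a
negative-binomial GLM; users with externally computed DE tables (e.g.
from a count-model package) can load them through
:func:`import_de_tables` and bypass the internal test entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix, GeneAnnotation, SampleDesign

STAGE_WISE = "stage_wise"
BETWEEN_STAGE = "between_stage"

#: pseudocount on the normalized-count scale; bounds log2fc for zero counts
PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class Contrast:
    kind: str  # stage_wise | between_stage
    genotype_a: str
    stage_a: str
    genotype_b: str
    stage_b: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in (STAGE_WISE, BETWEEN_STAGE):
            raise ValueError(f"unknown contrast kind {self.kind}")
        if self.kind == STAGE_WISE and self.stage_a != self.stage_b:
            raise ValueError("stage_wise contrast must compare the same stage")
        if self.kind == BETWEEN_STAGE and self.genotype_a != self.genotype_b:
            raise ValueError("between_stage contrast must stay within one genotype")


@dataclass
class DEThresholds:
    """Significance gates: adjusted p < alpha and |log2 fold change| > lfc_min."""

    alpha: float = 0.01
    lfc_min: float = 1.0
    enrichment_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")


@dataclass
class DETable:
    """Per-gene DE results for one contrast.

    ``table`` columns: log2fc, pvalue, padj, is_de; index = gene IDs.
    ``underpowered`` flags contrasts tested with <2 replicates per group,
    for which p-values are set to 1 and only log2fc is informative.
    """

    contrast: Contrast
    table: pd.DataFrame
    underpowered: bool = False

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_de"]])


def enumerate_contrasts(design: SampleDesign) -> list[Contrast]:
    """All stage-wise and between-stage contrasts implied by the design.

    For a 4-genotype (two mutant pairs) x 5-stage design this yields
    2 x 5 = 10 stage-wise and 4 x 4 = 16 between-stage contrasts.
    """
    out: list[Contrast] = []
    for mut, wt in design.mutant_pairs:
        for stage in design.stages:
            out.append(
                Contrast(
                    STAGE_WISE, mut, stage, wt, stage, label=f"{mut}_vs_{wt}.{stage}"
                )
            )
    for geno in design.genotypes:
        for lo, hi in zip(design.stages[:-1], design.stages[1:]):
            out.append(
                Contrast(
                    BETWEEN_STAGE, geno, hi, geno, lo, label=f"{geno}.{hi}_vs_{lo}"
                )
            )
    return out


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_contrast(
    m: ExpressionMatrix,
    design: SampleDesign,
    contrast: Contrast,
    thresholds: DEThresholds | None = None,
) -> DETable:
    """Pooled two-sample t-test on log2(normalized + 1) between the groups.

    log2fc = log2((mean_a + 1) / (mean_b + 1)) on the normalized-count
    scale.  Genes with zero counts in all samples of both groups get
    p = 1 and log2fc = 0.  With fewer than 2 replicates in either group
    the table is flagged ``underpowered`` and all p-values are 1.
    """
    thresholds = thresholds or DEThresholds()
    if m.scale not in ("normalized_counts", "raw_counts"):
        raise ValueError(f"test_contrast expects counts, got scale {m.scale}")
    samples_a = design.samples_of(contrast.genotype_a, contrast.stage_a)
    samples_b = design.samples_of(contrast.genotype_b, contrast.stage_b)
    if not samples_a or not samples_b:
        raise ValueError(f"contrast {contrast.label}: empty group")
    A = m.data[samples_a].to_numpy(dtype=float)
    B = m.data[samples_b].to_numpy(dtype=float)
    c0 = PSEUDOCOUNT
    log2fc = np.log2(A.mean(axis=1) + c0) - np.log2(B.mean(axis=1) + c0)

    underpowered = min(A.shape[1], B.shape[1]) < 2
    if underpowered:
        pvals = np.ones(A.shape[0])
    else:
        la, lb = np.log2(A + c0), np.log2(B + c0)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(la, lb, axis=1, equal_var=True)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    allzero = (A.sum(axis=1) == 0) & (B.sum(axis=1) == 0)
    pvals = np.where(allzero, 1.0, pvals)
    log2fc = np.where(allzero, 0.0, log2fc)

    padj = bh_adjust(pvals)
    is_de = (padj < thresholds.alpha) & (np.abs(log2fc) > thresholds.lfc_min)
    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "padj": padj, "is_de": is_de},
        index=m.data.index,
    )
    return DETable(contrast, table, underpowered=underpowered)


def run_all_contrasts(
    m: ExpressionMatrix,
    design: SampleDesign,
    thresholds: DEThresholds | None = None,
) -> list[DETable]:
    return [test_contrast(m, design, c, thresholds) for c in enumerate_contrasts(design)]


def de_union(tables: Iterable[DETable]) -> set[str]:
    """Genes differentially expressed in at least one contrast."""
    tables = list(tables)
    if not tables:
        raise ValueError("no DE tables given")
    out: set[str] = set()
    for t in tables:
        out |= t.de_genes
    return out


def de_tf_set(tables: Iterable[DETable], ann: GeneAnnotation) -> set[str]:
    """Transcription factors differentially expressed in at least one contrast."""
    return de_union(tables) & ann.tf_genes


def export_de_tables(tables: Iterable[DETable], path: str | Path) -> None:
    rows = []
    for t in tables:
        sub = t.table.reset_index(names="gene_id")
        sub.insert(0, "contrast_label", t.contrast.label)
        rows.append(sub[["contrast_label", "gene_id", "log2fc", "pvalue", "padj"]])
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def import_de_tables(
    path: str | Path,
    design: SampleDesign,
    thresholds: DEThresholds | None = None,
) -> list[DETable]:
    """Load externally computed DE tables; is_de is recomputed from thresholds.

    Expects columns (contrast_label, gene_id, log2fc, pvalue[, padj]); a
    missing padj column is recomputed per contrast by BH.
    """
    thresholds = thresholds or DEThresholds()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contrast_label": str, "gene_id": str})
    required = {"contrast_label", "gene_id", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    bad = df[df["pvalue"].isna() | df["log2fc"].isna()]
    if len(bad):
        raise ValueError(f"malformed DE rows at lines {(bad.index + 2).tolist()[:5]}")
    known = {c.label: c for c in enumerate_contrasts(design)}
    out = []
    for label, sub in df.groupby("contrast_label", sort=False):
        if label not in known:
            raise ValueError(f"unknown contrast label {label!r}")
        sub = sub.set_index("gene_id")
        padj = (
            sub["padj"].to_numpy(dtype=float)
            if "padj" in sub.columns and sub["padj"].notna().all()
            else bh_adjust(sub["pvalue"].to_numpy(dtype=float))
        )
        table = pd.DataFrame(
            {
                "log2fc": sub["log2fc"].astype(float),
                "pvalue": sub["pvalue"].astype(float),
                "padj": padj,
            },
            index=sub.index,
        )
        table["is_de"] = (table["padj"] < thresholds.alpha) & (
            table["log2fc"].abs() > thresholds.lfc_min
        )
        out.append(DETable(known[label], table))
    return out
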