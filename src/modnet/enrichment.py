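"""GO-term over-representation per module (one-sided Fisher / hypergeometric).

Each (module, term) pair with at least one annotated member gene is tested
for over-representation against a background universe (all annotated genes
by default), and Benjamini-Hochberg FDR is applied jointly across all
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ModuleSet
from .diffexp import bh_adjust
from .expression_io import GeneAnnotation

RESULT_COLUMNS = ("module_id", "go_term", "k", "n", "K_bg", "N_bg", "pvalue", "padj", "enriched")


def hypergeom_tail(k: int, n: int, K_bg: int, N_bg: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N_bg, K_bg, n).

    k annotated genes in a module of size n, against K_bg annotated genes
    in a background of N_bg; equivalent to a one-sided Fisher exact test.
    """
    if not (0 <= k <= min(n, K_bg) and n <= N_bg and K_bg <= N_bg):
        raise ValueError(f"impossible counts k={k} n={n} K_bg={K_bg} N_bg={N_bg}")
    return float(stats.hypergeom.sf(k - 1, N_bg, K_bg, n))


def enrich_modules(
    ms: ModuleSet,
    ann: GeneAnnotation,
    background: str = "all_annotated",
    enrichment_alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every (module, term) with k >= 1; BH across the full result set."""
    if not ann.go_map:
        raise ValueError("empty GO map")
    if background == "all_annotated":
        universe = set(ann.go_map)
    elif background == "de_genes":
        universe = set(ms.assignment.index) & set(ann.go_map)
    else:
        raise ValueError(f"unknown background {background!r}")
    N_bg = len(universe)
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in ann.go_map[g]:
            term_genes.setdefault(t, set()).add(g)
    rows = []
    for module_id in ms.module_ids:
        members = set(ms.members(module_id)) & universe
        n = len(members)
        if n == 0:
            warnings.warn(f"module {module_id} has no annotated genes; skipped")
            continue
        local: dict[str, int] = {}
        for g in members:
            for t in ann.go_map[g]:
                local[t] = local.get(t, 0) + 1
        for term, k in sorted(local.items()):
            K_bg = len(term_genes[term])
            rows.append(
                {
                    "module_id": module_id,
                    "go_term": term,
                    "k": k,
                    "n": n,
                    "K_bg": K_bg,
                    "N_bg": N_bg,
                    "pvalue": hypergeom_tail(k, n, K_bg, N_bg),
                }
            )
    out = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c not in ("padj", "enriched")])
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
        out["enriched"] = out["padj"] < enrichment_alpha
    else:
        out["padj"] = []
        out["enriched"] = []
    return out
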