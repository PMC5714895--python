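"""Overlap of predicted edges with a reference regulatory network.

Predicted TF -> module edges are compared against an external (regulator,
target) edge list from a reference species through a many-to-many ortholog
map.  A predicted edge scores a TF -> gene overlap for each module member
whose ortholog pair hits a reference edge, and one TF -> module overlap if
at least one member matches.  Because the ortholog map may be
many-to-many, matched pairs are reported both in source-gene space and in
reference-gene space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .clustering import ModuleSet
from .consensus import ConsensusNetwork


@dataclass
class ReferenceNetwork:
    edges: set[tuple[str, str]]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_regulators(self) -> int:
        return len({r for r, _ in self.edges})

    @property
    def n_targets(self) -> int:
        return len({t for _, t in self.edges})


@dataclass
class OrthologMap:
    pairs: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [g for g, refs in self.pairs.items() if not refs]
        if empty:
            raise ValueError(f"ortholog entries with no reference gene: {empty[:5]}")

    def get(self, gene: str) -> set[str]:
        return self.pairs.get(gene, set())


@dataclass
class OverlapReport:
    tf_module_overlaps: int
    tf_gene_overlaps: int  # unique (source TF, source gene) pairs
    tf_gene_overlaps_ref_space: int  # unique (reference TF, reference gene) pairs
    matched_edges: pd.DataFrame  # tf, module, gene, ref_regulator, ref_target


def read_reference_network(path: str | Path) -> ReferenceNetwork:
    edges = _read_edge_file(path)
    return ReferenceNetwork(edges=edges)


def _read_edge_file(path: str | Path) -> set[tuple[str, str]]:
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"{path}:{lineno}: expected two tab-separated IDs")
        edges.add((parts[0], parts[1]))
    return edges


def merge_reference_networks(paths: Sequence[str | Path]) -> tuple[ReferenceNetwork, pd.DataFrame]:
    """Union of several reference edge lists, with per-source counts."""
    merged: set[tuple[str, str]] = set()
    rows = []
    for p in paths:
        edges = _read_edge_file(p)
        rows.append(
            {
                "source": str(p),
                "n_edges": len(edges),
                "n_regulators": len({r for r, _ in edges}),
                "n_targets": len({t for _, t in edges}),
            }
        )
    for p in paths:
        merged |= _read_edge_file(p)
    net = ReferenceNetwork(edges=merged)
    rows.append(
        {
            "source": "merged",
            "n_edges": net.n_edges,
            "n_regulators": net.n_regulators,
            "n_targets": net.n_targets,
        }
    )
    return net, pd.DataFrame(rows)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    pairs: dict[str, set[str]] = {}
    for src, ref in _read_edge_file(path):
        pairs.setdefault(src, set()).add(ref)
    return OrthologMap(pairs)


def overlap_counts(
    net: ConsensusNetwork,
    ms: ModuleSet,
    ref: ReferenceNetwork,
    om: OrthologMap,
    mode: str = "any",
) -> OverlapReport:
    """Count predicted edges recovered in the reference network.

    mode="any" (default) matches if any ortholog pair hits a reference
    edge; mode="first" restricts each source gene to its lexicographically
    first reference ortholog (a strict best-hit stand-in for maps whose
    ranking is unavailable).
    """
    if not om.pairs:
        raise ValueError("empty ortholog map")
    if mode not in ("any", "first"):
        raise ValueError(f"unknown mode {mode!r}")

    def orths(gene: str) -> set[str]:
        o = om.get(gene)
        if mode == "first" and o:
            return {min(o)}
        return o

    matched_modules: set[tuple[str, str]] = set()
    matched_pairs: set[tuple[str, str]] = set()
    matched_ref_pairs: set[tuple[str, str]] = set()
    rows = []
    for _, row in net.edges.iterrows():
        tf, module = row["tf"], row["module"]
        tf_orths = orths(tf)
        if not tf_orths:
            continue
        try:
            members = ms.members(int(module))
        except (ValueError, TypeError):
            members = ms.members(module)  # type: ignore[arg-type]
        for g in members:
            for to in sorted(tf_orths):
                for go in sorted(orths(g)):
                    if (to, go) in ref.edges:
                        matched_modules.add((tf, module))
                        matched_pairs.add((tf, g))
                        matched_ref_pairs.add((to, go))
                        rows.append(
                            {
                                "tf": tf,
                                "module": module,
                                "gene": g,
                                "ref_regulator": to,
                                "ref_target": go,
                            }
                        )
    matched = pd.DataFrame(rows, columns=["tf", "module", "gene", "ref_regulator", "ref_target"])
    return OverlapReport(
        tf_module_overlaps=len(matched_modules),
        tf_gene_overlaps=len(matched_pairs),
        tf_gene_overlaps_ref_space=len(matched_ref_pairs),
        matched_edges=matched,
    )
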