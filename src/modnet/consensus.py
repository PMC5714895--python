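"""Consensus edge calling, network assembly, and edge classification.

Each inference method contributes its top-ranked candidate pairs; an edge's
support is the number of methods retaining it, and the consensus keeps
edges with support >= min_support (5-of-5 for the stringent network,
>= 4-of-5 for the extended one).  The assembled network mixes two edge
kinds: directed TF -> module regulatory edges, and one undirected
membership edge linking each TF to the co-expression module it belongs to.

Directed edges are colored by the regulating TF's differential-expression
pattern across contrast families, with precedence black > green > blue >
red > grey:

* black - between-stage DE in every mutant and every non-mutant genotype
  (stage-driven regulation unaffected by the mutations);
* green - between-stage DE in all non-mutants but no mutant (regulation
  lost in mutants);
* blue  - between-stage DE in no non-mutant but in at least one mutant
  (regulation gained in mutants);
* red   - stage-wise DE in the focal mutant vs. non-mutant pair at one or
  more stages (stage-specific mutation effect);
* grey  - none of the above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import ModuleSet
from .diffexp import BETWEEN_STAGE, STAGE_WISE, DETable
from .expression_io import MUTANT, SampleDesign
from .inference import ScoreMatrix

CATEGORIES = ("black", "green", "blue", "red", "grey")

EDGE_COLUMNS = ("tf", "module", "support", "methods", "category")


@dataclass
class ConsensusConfig:
    """per_method_top: fraction (<1) or absolute count of pairs each method keeps."""

    per_method_top: float | int = 0.01
    min_support: int = 5

    def resolve_top(self, n_pairs: int) -> int:
        if isinstance(self.per_method_top, float) and self.per_method_top < 1:
            return max(1, math.ceil(self.per_method_top * n_pairs))
        return int(self.per_method_top)


@dataclass
class ConsensusNetwork:
    """Directed regulatory edges plus undirected TF-membership edges."""

    edges: pd.DataFrame  # columns tf, module, support, methods, category
    membership: pd.DataFrame  # columns tf, module
    n_regulators: int
    n_modules: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def candidate_universe(self) -> int:
        return self.n_regulators * self.n_modules


def call_edges(scores: Sequence[ScoreMatrix], cfg: ConsensusConfig) -> ConsensusNetwork:
    """Vote over per-method top lists; keep pairs with enough support.

    Ties at the retention boundary are broken by (score desc, regulator ID,
    module ID) so the kept list is deterministic.
    """
    if not scores:
        raise ValueError("no score matrices given")
    if cfg.min_support > len(scores):
        raise ValueError("min_support exceeds the number of methods")
    ref = scores[0].scores
    for sm in scores[1:]:
        if list(sm.scores.index) != list(ref.index) or list(sm.scores.columns) != list(
            ref.columns
        ):
            raise ValueError("score matrices cover different candidate universes")
    n_pairs = ref.size
    n_keep = cfg.resolve_top(n_pairs)
    support: dict[tuple[str, str], list[str]] = {}
    for sm in scores:
        long = sm.long()
        long = long.sort_values(
            ["score", "regulator", "module"], ascending=[False, True, True]
        ).head(n_keep)
        for tf, mod in zip(long["regulator"], long["module"]):
            support.setdefault((tf, str(mod)), []).append(sm.method)
    rows = [
        {
            "tf": tf,
            "module": mod,
            "support": len(methods),
            "methods": ",".join(methods),
            "category": "",
        }
        for (tf, mod), methods in support.items()
        if len(methods) >= cfg.min_support
    ]
    edges = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    if len(edges):
        edges = edges.sort_values(["tf", "module"], ignore_index=True)
    return ConsensusNetwork(
        edges=edges,
        membership=pd.DataFrame(columns=["tf", "module"]),
        n_regulators=ref.shape[0],
        n_modules=ref.shape[1],
    )


def add_membership_edges(net: ConsensusNetwork, ms: ModuleSet) -> ConsensusNetwork:
    """One undirected edge per network TF that was itself clustered."""
    rows = []
    for tf in sorted(set(net.edges["tf"])):
        if tf in ms.assignment.index:
            rows.append({"tf": tf, "module": str(ms.assignment.loc[tf])})
    net.membership = pd.DataFrame(rows, columns=["tf", "module"])
    return net


def _tf_de_flags(
    tfs: Iterable[str], de_tables: Sequence[DETable], design: SampleDesign
) -> pd.DataFrame:
    """Per-TF booleans: between-stage DE per genotype, stage-wise DE per pair."""
    tfs = list(tfs)
    kinds = {t.contrast.kind for t in de_tables}
    for needed in (STAGE_WISE, BETWEEN_STAGE):
        if needed not in kinds:
            raise ValueError(f"missing DE table family: {needed}")
    flags = pd.DataFrame(index=pd.Index(tfs, name="tf"))
    for geno in design.genotypes:
        hit = set()
        for t in de_tables:
            if t.contrast.kind == BETWEEN_STAGE and t.contrast.genotype_a == geno:
                hit |= t.de_genes
        flags[f"between:{geno}"] = [tf in hit for tf in tfs]
    for mut, wt in design.mutant_pairs:
        hit = set()
        for t in de_tables:
            if (
                t.contrast.kind == STAGE_WISE
                and {t.contrast.genotype_a, t.contrast.genotype_b} == {mut, wt}
            ):
                hit |= t.de_genes
        flags[f"stagewise:{mut}"] = [tf in hit for tf in tfs]
    return flags


def classify_edges(
    net: ConsensusNetwork,
    de_tables: Sequence[DETable],
    design: SampleDesign,
    focal_pair: tuple[str, str] | None = None,
) -> ConsensusNetwork:
    """Color each directed edge by its TF's DE pattern (see module docstring).

    ``focal_pair`` names the mutant/non-mutant pair whose stage-wise
    contrasts drive the red rule; default is the design's first mutant pair.
    """
    mutants = [g for g in design.genotypes if design.genotype_class(g) == MUTANT]
    non_mutants = [g for g in design.genotypes if design.genotype_class(g) != MUTANT]
    if focal_pair is None:
        focal_pair = design.mutant_pairs[0]
    flags = _tf_de_flags(net.edges["tf"].unique(), de_tables, design)

    def categorize(tf: str) -> str:
        bet = {g: bool(flags.loc[tf, f"between:{g}"]) for g in design.genotypes}
        mut_all = all(bet[g] for g in mutants)
        mut_any = any(bet[g] for g in mutants)
        wt_all = all(bet[g] for g in non_mutants)
        wt_any = any(bet[g] for g in non_mutants)
        if mut_all and wt_all:
            return "black"
        if wt_all and not mut_any:
            return "green"
        if not wt_any and mut_any:
            return "blue"
        if bool(flags.loc[tf, f"stagewise:{focal_pair[0]}"]):
            return "red"
        return "grey"

    net.edges["category"] = [categorize(tf) for tf in net.edges["tf"]]
    return net


def network_summary(net: ConsensusNetwork) -> dict:
    counts = {c: int((net.edges["category"] == c).sum()) for c in CATEGORIES}
    universe = net.candidate_universe
    return {
        "n_edges": net.n_edges,
        "n_distinct_tfs": int(net.edges["tf"].nunique()),
        "n_distinct_modules": int(net.edges["module"].nunique()),
        "category_counts": counts,
        "candidate_universe": universe,
        "fraction_of_universe": net.n_edges / universe if universe else 0.0,
        "n_membership_edges": len(net.membership),
    }


def export_network(net: ConsensusNetwork, path: str | Path, fmt: str = "tsv_edgelist") -> None:
    path = Path(path)
    if fmt == "tsv_edgelist":
        directed = net.edges.copy()
        directed["edge_type"] = "regulatory"
        member = net.membership.copy()
        member["support"] = 0
        member["methods"] = ""
        member["category"] = ""
        member["edge_type"] = "membership"
        both = pd.concat([directed, member], ignore_index=True)
        both["n_regulators"] = net.n_regulators
        both["n_modules"] = net.n_modules
        both.to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        # multigraph: a TF may carry both a regulatory and a membership edge
        # to the same module
        g = nx.MultiDiGraph(n_regulators=net.n_regulators, n_modules=net.n_modules)
        for _, row in net.edges.iterrows():
            g.add_edge(
                row["tf"],
                f"module:{row['module']}",
                support=int(row["support"]),
                methods=row["methods"],
                category=row["category"],
                edge_type="regulatory",
            )
        for _, row in net.membership.iterrows():
            g.add_edge(row["tf"], f"module:{row['module']}", edge_type="membership")
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_network(path: str | Path) -> ConsensusNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "module": str, "methods": str})
    df["methods"] = df["methods"].fillna("")
    df["category"] = df["category"].fillna("")
    edges = df[df["edge_type"] == "regulatory"][list(EDGE_COLUMNS)].reset_index(drop=True)
    membership = df[df["edge_type"] == "membership"][["tf", "module"]].reset_index(drop=True)
    n_reg = int(df["n_regulators"].iloc[0]) if len(df) else 0
    n_mod = int(df["n_modules"].iloc[0]) if len(df) else 0
    return ConsensusNetwork(
        edges=edges, membership=membership, n_regulators=n_reg, n_modules=n_mod
    )
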