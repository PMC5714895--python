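"""Benchmark helpers: score planted-truth recovery of pipeline outputs.

Predicted module IDs are arbitrary labels, so evaluation first maps each
predicted module to the planted module with the largest member overlap,
then scores edges in that mapped space.  Recall is counted over *all*
planted edges (a planted edge whose regulator never reached the candidate
universe counts as a miss).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .clustering import ModuleSet
from .consensus import ConsensusNetwork
from .inference import ScoreMatrix
from .simulate import GroundTruth


def map_predicted_modules(ms: ModuleSet, truth: GroundTruth) -> dict[int, int]:
    """predicted module id -> planted module id by majority member overlap."""
    out: dict[int, int] = {}
    for pm in ms.module_ids:
        members = ms.members(pm)
        votes: dict[int, int] = {}
        for g in members:
            tm = truth.module_assignment.get(g)
            if tm is not None:
                votes[tm] = votes.get(tm, 0) + 1
        if votes:
            out[pm] = max(sorted(votes), key=votes.get)
    return out


def true_edge_labels(
    sm: ScoreMatrix, truth: GroundTruth, module_map: Mapping[int, int]
) -> np.ndarray:
    """0/1 labels over the score matrix's candidate pairs."""
    labels = np.zeros(sm.scores.shape, dtype=int)
    for j, pm in enumerate(sm.scores.columns):
        tm = module_map.get(int(pm))
        if tm is None:
            continue
        for i, tf in enumerate(sm.scores.index):
            if (tf, tm) in truth.edges:
                labels[i, j] = 1
    return labels


def edge_auroc(sm: ScoreMatrix, truth: GroundTruth, module_map: Mapping[int, int]) -> float:
    """AUROC of the method's ranking of planted vs. non-planted pairs."""
    labels = true_edge_labels(sm, truth, module_map).ravel()
    if labels.sum() in (0, len(labels)):
        return float("nan")
    return float(roc_auc_score(labels, sm.scores.to_numpy().ravel()))


def consensus_precision_recall(
    net: ConsensusNetwork, truth: GroundTruth, module_map: Mapping[int, int]
) -> tuple[float, float]:
    """Precision over predicted edges, recall over all planted edges."""
    predicted = set()
    for _, row in net.edges.iterrows():
        tm = module_map.get(int(row["module"]))
        if tm is not None:
            predicted.add((row["tf"], tm))
    if not net.n_edges:
        return 0.0, 0.0
    tp = len(predicted & truth.edges)
    precision = tp / net.n_edges
    recall = tp / len(truth.edges) if truth.edges else 0.0
    return precision, recall


def topk_precision(
    sm: ScoreMatrix, truth: GroundTruth, module_map: Mapping[int, int], k: int
) -> float:
    """Precision of a single method's top-k pairs against the planted edges."""
    long = sm.long().sort_values(
        ["score", "regulator", "module"], ascending=[False, True, True]
    ).head(k)
    tp = 0
    for tf, mod in zip(long["regulator"], long["module"]):
        tm = module_map.get(int(mod))
        if tm is not None and (tf, tm) in truth.edges:
            tp += 1
    return tp / k if k else 0.0
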