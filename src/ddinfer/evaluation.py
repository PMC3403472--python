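"""Sensitivity / fold-change evaluation against a gold standard, and sd sweeps.

Because structurally confirmed DDIs are scarce, only gold pairs that are
actually candidate variables count as recoverable positives:

    sensitivity = TP / |gold ∩ D|
    fold change = (TP / Total) / (|gold ∩ D| / |D|)

Fold change is the model's precision relative to the gold density in the
candidate set; predicting every candidate gives fold change exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .io_formats import DDIPairSet, DomainComposition, PPINetwork, harmonize
from .parsimony_core import (
    CandidateDDISet,
    build_candidate_pairs,
    build_lp,
    compute_weights,
    round_predictions,
    solve_lp,
)

logger = logging.getLogger("ddinfer")

__all__ = ["EvaluationResult", "evaluate_predictions", "evaluate_counts", "sweep_sd"]


@dataclass(frozen=True)
class EvaluationResult:
    total_predictions: int
    true_positives: int
    gold_in_candidates: int
    candidate_size: int

    @property
    def sensitivity(self) -> float | None:
        """TP over recoverable gold pairs; None when no gold pair is a candidate."""
        if self.gold_in_candidates == 0:
            return None
        return self.true_positives / self.gold_in_candidates

    @property
    def fold_change(self) -> float:
        """Precision over gold density in the candidate set; 0 for empty predictions."""
        if self.total_predictions == 0 or self.gold_in_candidates == 0:
            return 0.0
        precision = self.true_positives / self.total_predictions
        density = self.gold_in_candidates / self.candidate_size
        return precision / density


def evaluate_counts(
    total_predictions: int,
    true_positives: int,
    gold_in_candidates: int,
    candidate_size: int,
) -> EvaluationResult:
    """Evaluation from raw counts (e.g. externally reported prediction totals)."""
    if true_positives > min(total_predictions, gold_in_candidates):
        raise ValueError("true_positives exceeds predictions or recoverable gold")
    return EvaluationResult(
        total_predictions, true_positives, gold_in_candidates, candidate_size
    )


def evaluate_predictions(
    predictions: DDIPairSet,
    gold: DDIPairSet,
    candidates: CandidateDDISet,
) -> EvaluationResult:
    """Score a predicted DDI set against gold, within the candidate universe."""
    outside = predictions.pairs - candidates.pairs
    if outside:
        raise ValueError(
            f"{len(outside)} predicted pair(s) outside the candidate set, "
            f"e.g. {sorted(outside)[0]}"
        )
    gold_in = gold.pairs & candidates.pairs
    tp = len(predictions.pairs & gold_in)
    if not predictions.pairs:
        logger.warning("evaluating an empty prediction set; fold change is 0")
    if not gold_in:
        logger.warning("no gold pair is a candidate; sensitivity undefined")
    return EvaluationResult(
        total_predictions=len(predictions.pairs),
        true_positives=tp,
        gold_in_candidates=len(gold_in),
        candidate_size=len(candidates.pairs),
    )


def sweep_sd(
    network: PPINetwork,
    composition: DomainComposition,
    gold: DDIPairSet,
    model: Literal["ilp", "wilp"] = "wilp",
    sd_values: Iterable[float] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1),
    K: int = 50,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Run inference + evaluation across a grid of sd values.

    Returns one row per sd with columns sd, total, TP, sensitivity,
    fold_change (plus solver diagnostics).  The candidate set, and for the
    weighted model the weights, are built once and reused.
    """
    net, _ = harmonize(network, composition)
    candidates = build_candidate_pairs(net, composition)
    weights = (
        compute_weights(net, composition, candidates, K) if model == "wilp" else None
    )
    rows = []
    for sd in sd_values:
        sol = solve_lp(build_lp(candidates, net, sd=sd, weights=weights))
        if sol.solver_status != "optimal":
            raise RuntimeError(f"solve failed at sd={sd}: {sol.message}")
        preds = round_predictions(sol, threshold)
        ev = evaluate_predictions(preds, gold, candidates)
        rows.append(
            {
                "sd": sd,
                "total": ev.total_predictions,
                "TP": ev.true_positives,
                "sensitivity": ev.sensitivity,
                "fold_change": ev.fold_change,
                "objective": sol.objective,
                "n_fractional": sol.n_fractional,
            }
        )
    return pd.DataFrame(rows)
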