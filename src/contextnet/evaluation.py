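"""Pooled gold-standard evaluation of predicted TF targets.

Context-specific predictions cannot be benchmarked condition by condition —
ChIP experiments are themselves condition-specific — so the assessment pools:
all context-specific targets of a TF form the prediction set, and the union
of available ChIP-seq/ChIP-chip target sets (restricted to genes that carry a
binding site for the TF) forms the gold standard.  The null universe is the
TF's binding-site gene universe; within it the contingency table gives
sensitivity x/K, specificity ((N-K)-(n-x))/(N-K) and a hypergeometric
enrichment p-value against random prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .overlap import hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = ["EvaluationResult", "build_gold_standard", "evaluate_tf", "augment_gold"]


@dataclass(frozen=True)
class EvaluationResult:
    """Contingency counts and derived statistics for one TF.

    N: binding-site universe size; K: gold-standard positives within it;
    n: predicted targets; x: true positives among the predictions.
    """

    tf_label: str
    universe_size: int
    positives: int
    predicted: int
    true_positive: int
    sensitivity: float
    specificity: float
    p_value: float

    def rounded(self, digits: int = 4) -> "EvaluationResult":
        """Copy with the derived statistics rounded for reporting."""
        return EvaluationResult(
            self.tf_label,
            self.universe_size,
            self.positives,
            self.predicted,
            self.true_positive,
            round(self.sensitivity, digits),
            round(self.specificity, digits),
            round(self.p_value, digits),
        )


def build_gold_standard(chip_target_sets, tfbs_universe) -> frozenset:
    """Pool ChIP target sets and keep only genes with a known binding site.

    Returns (union of the ChIP target sets) intersected with
    ``tfbs_universe``.  An empty result is allowed but warned about, since
    the evaluation degenerates.
    """
    uni = frozenset(str(g).upper() for g in tfbs_universe)
    if not uni:
        raise ValueError("empty TFBS universe")
    pooled: frozenset = frozenset()
    for s in chip_target_sets:
        genes = getattr(s, "genes", s)
        pooled = pooled | frozenset(str(g).upper() for g in genes)
    gold = pooled & uni
    if not gold:
        logger.warning("gold standard is empty after restriction to the TFBS universe")
    return gold


def _result(tf_label: str, N: int, K: int, n: int, x: int) -> EvaluationResult:
    if K == 0 or K == N:
        raise ValueError("degenerate gold standard (K=0 or K=N): sensitivity/specificity undefined")
    sensitivity = x / K
    specificity = ((N - K) - (n - x)) / (N - K)
    p = hypergeom_tail(N, K, n, x)
    return EvaluationResult(tf_label, N, K, n, x, sensitivity, specificity, p)


def evaluate_tf(predictions, gold, universe, tf_label: str = "") -> EvaluationResult:
    """Contingency evaluation of pooled predictions against a gold standard.

    ``gold`` and ``predictions`` are restricted to ``universe``; members
    outside it are dropped with a warning.
    """
    uni = frozenset(str(g).upper() for g in universe)
    gold_set = frozenset(str(g).upper() for g in gold)
    pred_set = frozenset(str(g).upper() for g in predictions)
    if not gold_set <= uni:
        logger.warning(
            "evaluate_tf: dropping %d gold gene(s) outside the universe", len(gold_set - uni)
        )
        gold_set &= uni
    if not pred_set <= uni:
        logger.warning(
            "evaluate_tf: dropping %d predicted gene(s) outside the universe",
            len(pred_set - uni),
        )
        pred_set &= uni
    N, K, n = len(uni), len(gold_set), len(pred_set)
    x = len(pred_set & gold_set)
    return _result(tf_label, N, K, n, x)


def augment_gold(
    predictions, gold, universe, extra_positives, tf_label: str = ""
) -> EvaluationResult:
    """Re-evaluate after adding extra positives (e.g. newly ChIP-validated genes).

    The universe and the prediction set are held fixed; the gold standard
    grows by ``extra_positives``, which must lie inside the universe and be
    disjoint from the current gold standard.  True positives grow by the
    extras that were predicted.
    """
    uni = frozenset(str(g).upper() for g in universe)
    gold_set = frozenset(str(g).upper() for g in gold) & uni
    pred_set = frozenset(str(g).upper() for g in predictions) & uni
    extra = frozenset(str(g).upper() for g in extra_positives)
    if not extra <= uni:
        raise ValueError("extra positives must lie inside the universe")
    if extra & gold_set:
        raise ValueError("extra positives overlap the existing gold standard")
    N = len(uni)
    K = len(gold_set) + len(extra)
    n = len(pred_set)
    x = len(pred_set & gold_set) + len(extra & pred_set)
    return _result(tf_label, N, K, n, x)
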