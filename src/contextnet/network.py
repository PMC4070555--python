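"""Criterion (C) and output assembly: condition counting, triples, candidate targets.

A (TFBS set, functional set) pair that passed the overlap test and was
activated in at least k conditions (default 10) becomes an association; every
(pair, activated condition) combination is emitted as a context triple.
Within an association, individual candidate targets are the overlap genes
that show high fold changes (|linear FC| >= 1.5, i.e. |log2FC| >= log2 1.5)
in at least ceil(0.3 * k) of the supporting conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .expression import ScreenResult
from .geneset_io import FoldChangeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "ContextTriple",
    "CandidateTarget",
    "assemble_network",
    "select_candidate_targets",
    "pool_tf_targets",
]


@dataclass(frozen=True)
class AssociationRecord:
    """A mined TF-function association: one row of the network."""

    tfbs_name: str
    tf_label: str | None
    func_name: str
    overlap_genes: frozenset
    overlap_q: float  # criterion (A) q-value
    supporting_conditions: tuple
    n_conditions: int

    @property
    def pair_id(self) -> str:
        return f"{self.tfbs_name}|{self.func_name}"


@dataclass(frozen=True)
class ContextTriple:
    """The atomic output unit: (TF, functional set, condition)."""

    tf_label: str | None
    func_name: str
    condition: str
    z_overlap: float
    q_overlap_expression: float
    tfbs_name: str = ""


@dataclass(frozen=True)
class CandidateTarget:
    """One overlap gene scored by the high-fold-change rule."""

    gene: str
    tf_label: str | None
    func_name: str
    n_highfc_conditions: int
    passed: bool
    in_matrix: bool = True


def assemble_network(
    screened: ScreenResult, k: int = 10
) -> tuple[list[AssociationRecord], list[ContextTriple]]:
    """Apply criterion (C): keep pairs activated in >= k conditions.

    Returns the association records and one triple per (record, activated
    condition); the triple count equals the sum of the records' condition
    counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    calls = screened.calls
    records: list[AssociationRecord] = []
    triples: list[ContextTriple] = []
    if len(calls) == 0:
        return records, triples
    activated = calls[calls["activated"]]
    for pair_id, grp in activated.groupby("pair_id", sort=True):
        if len(grp) < k:
            continue
        ov = screened.overlaps[pair_id]
        conds = tuple(grp["condition"])
        records.append(
            AssociationRecord(
                tfbs_name=ov.tfbs_name,
                tf_label=ov.tf_label,
                func_name=ov.func_name,
                overlap_genes=ov.overlap_genes,
                overlap_q=ov.q_value,
                supporting_conditions=conds,
                n_conditions=len(conds),
            )
        )
        for _, row in grp.iterrows():
            triples.append(
                ContextTriple(
                    tf_label=ov.tf_label,
                    func_name=ov.func_name,
                    condition=row["condition"],
                    z_overlap=float(row["z_overlap"]),
                    q_overlap_expression=float(row["q_overlap"]),
                    tfbs_name=ov.tfbs_name,
                )
            )
    logger.info("criterion C: %d associations, %d triples at k=%d", len(records), len(triples), k)
    return records, triples


def required_condition_count(frac: float, k: int, strict_gt: bool = False) -> int:
    """Number of high-FC conditions a target must reach: ceil(frac*k), or
    floor(frac*k)+1 under the strict '>' reading."""
    if strict_gt:
        return int(math.floor(frac * k)) + 1
    return int(math.ceil(frac * k))


def select_candidate_targets(
    record: AssociationRecord,
    matrix: FoldChangeMatrix,
    fc_threshold: float = 1.5,
    frac: float = 0.3,
    k: int = 10,
    strict_gt: bool = False,
    all_conditions: bool = False,
) -> list[CandidateTarget]:
    """Score each overlap gene of an association by the high-FC rule.

    ``fc_threshold`` is a linear fold change; the rule is applied on the log2
    scale as |log2FC| >= log2(fc_threshold).  Counting is restricted to the
    record's supporting conditions unless ``all_conditions`` is set.  A gene
    absent from the matrix counts zero high-FC conditions and is flagged.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    need = required_condition_count(frac, k, strict_gt)
    log_thr = math.log2(fc_threshold)
    conds = list(matrix.conditions) if all_conditions else [
        c for c in record.supporting_conditions if c in matrix.data.columns
    ]
    sub = matrix.data.loc[:, conds] if conds else matrix.data.iloc[:, :0]
    out: list[CandidateTarget] = []
    for gene in sorted(record.overlap_genes):
        if gene in sub.index:
            vals = sub.loc[gene].to_numpy(dtype=float)
            n_high = int(np.sum(np.abs(vals[~np.isnan(vals)]) >= log_thr))
            in_matrix = True
        else:
            n_high = 0
            in_matrix = False
            logger.warning("target gene %s absent from the matrix", gene)
        out.append(
            CandidateTarget(
                gene=gene,
                tf_label=record.tf_label,
                func_name=record.func_name,
                n_highfc_conditions=n_high,
                passed=n_high >= need,
                in_matrix=in_matrix,
            )
        )
    return out


def pool_tf_targets(
    records: list[AssociationRecord],
    targets: list[CandidateTarget],
    tf: str,
) -> frozenset:
    """Union of the passed candidate targets over all of a TF's associations.

    This is the pooled, condition-agnostic prediction set used for
    gold-standard evaluation.
    """
    tf_records = [r for r in records if r.tf_label == tf]
    if not tf_records:
        logger.warning("pool_tf_targets: no association records for TF %r", tf)
        return frozenset()
    record_keys = {(r.tf_label, r.func_name) for r in tf_records}
    pooled = {
        t.gene
        for t in targets
        if t.passed and (t.tf_label, t.func_name) in record_keys and t.tf_label == tf
    }
    return frozenset(pooled)
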