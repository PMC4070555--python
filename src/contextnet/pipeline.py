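"""End-to-end orchestration: preprocessing -> overlap -> expression -> network.

:func:`mine` is the in-memory driver used by tests, simulations and the CLI;
:func:`run_pipeline` wraps it with file output (TSV/JSON artifacts plus a run
manifest).  Any stage error aborts the run and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .expression import ScreenResult, condition_screen
from .geneset_io import FoldChangeMatrix, GeneSetCollection, filter_by_size
from .network import (
    AssociationRecord,
    CandidateTarget,
    ContextTriple,
    assemble_network,
    select_candidate_targets,
)
from .overlap import all_pairwise_overlaps

logger = logging.getLogger(__name__)

__all__ = ["MiningResult", "mine", "run_pipeline"]


@dataclass
class MiningResult:
    """Everything one mining run produced."""

    records: list[AssociationRecord]
    triples: list[ContextTriple]
    targets: list[CandidateTarget]
    screen: ScreenResult | None
    universe: frozenset
    counts: dict = field(default_factory=dict)

    def passed_targets(self) -> list[CandidateTarget]:
        return [t for t in self.targets if t.passed]


def mine(
    tfbs: GeneSetCollection,
    funcs: GeneSetCollection,
    matrix: FoldChangeMatrix,
    config: PipelineConfig | None = None,
) -> MiningResult:
    """Run criteria (A)-(C) and target selection on in-memory inputs."""
    config = (config or PipelineConfig()).validate()

    # analysis universe and size filtering on measurable genes
    set_union = tfbs.all_genes() | funcs.all_genes()
    if config.universe_policy == "matrix":
        universe = set_union & frozenset(matrix.genes)
    else:
        universe = set_union
    tfbs_f = filter_by_size(tfbs, config.min_set, config.max_set, universe=universe)
    funcs_f = filter_by_size(funcs, config.min_set, config.max_set, universe=universe)
    counts = {
        "universe_size": len(universe),
        "tfbs_sets": len(tfbs_f),
        "func_sets": len(funcs_f),
        "conditions": len(matrix.conditions),
    }
    if len(tfbs_f) == 0 or len(funcs_f) == 0:
        raise ValueError("no gene sets survive size filtering")

    overlaps = all_pairwise_overlaps(tfbs_f, funcs_f, universe, q_overlap=config.q_overlap)
    counts["overlap_pairs_retained"] = len(overlaps)
    if not overlaps:
        return MiningResult([], [], [], None, frozenset(universe), counts)

    screen = condition_screen(
        overlaps,
        matrix,
        q_sig=config.q_expr,
        q_nonsig=config.q_parent,
        tfbs_genes={s.name: s.genes for s in tfbs_f},
        func_genes={s.name: s.genes for s in funcs_f},
    )
    counts["activated_calls"] = int(screen.calls["activated"].sum()) if len(screen.calls) else 0

    records, triples = assemble_network(screen, k=config.k)
    counts["associations"] = len(records)
    counts["triples"] = len(triples)

    targets: list[CandidateTarget] = []
    for rec in records:
        targets.extend(
            select_candidate_targets(
                rec,
                matrix,
                fc_threshold=config.fc_threshold,
                frac=config.frac,
                k=config.k,
                strict_gt=config.strict_gt,
                all_conditions=config.highfc_all_conditions,
            )
        )
    counts["candidate_targets"] = len(targets)
    counts["passed_targets"] = sum(t.passed for t in targets)
    return MiningResult(records, triples, targets, screen, frozenset(universe), counts)


def _records_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tfbs_name": r.tfbs_name,
                "tf_label": r.tf_label or "",
                "func_name": r.func_name,
                "n_overlap_genes": len(r.overlap_genes),
                "overlap_genes": ";".join(sorted(r.overlap_genes)),
                "overlap_q": r.overlap_q,
                "n_conditions": r.n_conditions,
                "supporting_conditions": ";".join(r.supporting_conditions),
            }
            for r in records
        ]
    )


def _triples_frame(triples: list[ContextTriple]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf_label": t.tf_label or "",
                "tfbs_name": t.tfbs_name,
                "func_name": t.func_name,
                "condition": t.condition,
                "z_overlap": t.z_overlap,
                "q_overlap_expression": t.q_overlap_expression,
            }
            for t in triples
        ]
    )


def _targets_frame(targets: list[CandidateTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": t.gene,
                "tf_label": t.tf_label or "",
                "func_name": t.func_name,
                "n_highfc_conditions": t.n_highfc_conditions,
                "passed": t.passed,
                "in_matrix": t.in_matrix,
            }
            for t in targets
        ]
    )


def _network_json(result: MiningResult) -> dict:
    nodes: dict[str, dict] = {}
    edges: list[dict] = []
    for r in result.records:
        tf = r.tf_label or r.tfbs_name
        nodes.setdefault(tf, {"id": tf, "type": "tf"})
        nodes.setdefault(r.func_name, {"id": r.func_name, "type": "function"})
        edges.append(
            {
                "source": tf,
                "target": r.func_name,
                "type": "tf-func",
                "tfbs_name": r.tfbs_name,
                "n_conditions": r.n_conditions,
            }
        )
    for t in result.passed_targets():
        tf = t.tf_label or ""
        nodes.setdefault(t.gene, {"id": t.gene, "type": "gene"})
        edges.append(
            {
                "source": tf,
                "target": t.gene,
                "type": "tf-gene",
                "func_name": t.func_name,
                "n_highfc_conditions": t.n_highfc_conditions,
            }
        )
    return {"nodes": sorted(nodes.values(), key=lambda n: n["id"]), "edges": edges}


def _checksum(text: str) -> str:
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def run_pipeline(
    config: PipelineConfig,
    tfbs: GeneSetCollection,
    funcs: GeneSetCollection,
    matrix: FoldChangeMatrix,
    out_dir: str | Path,
) -> MiningResult:
    """Mine and write TSV/JSON artifacts plus a run manifest into ``out_dir``.

    On any stage failure the partially written outputs are removed before
    the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    try:
        result = mine(tfbs, funcs, matrix, config)
        write("associations.tsv", lambda p: _records_frame(result.records).to_csv(p, sep="\t", index=False))
        write("triples.tsv", lambda p: _triples_frame(result.triples).to_csv(p, sep="\t", index=False))
        write("targets.tsv", lambda p: _targets_frame(result.targets).to_csv(p, sep="\t", index=False))
        write("network.json", lambda p: p.write_text(json.dumps(_network_json(result), indent=1)))
        if result.screen is not None:
            write("screen_calls.tsv", lambda p: result.screen.to_tsv(p))
        manifest = {
            "config": config.to_dict(),
            "inputs": {
                "tfbs_sets": len(tfbs),
                "func_sets": len(funcs),
                "matrix_shape": list(matrix.shape),
                "tfbs_checksum": _checksum(",".join(sorted(tfbs.names))),
                "func_checksum": _checksum(",".join(sorted(funcs.names))),
            },
            "counts": result.counts,
        }
        write("manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=1)))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return result
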