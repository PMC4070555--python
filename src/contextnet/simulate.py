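"""Synthetic data with planted context-specific regulons.

The generator emulates the statistical structure the mining criteria assume,
at the scale of a real expression compendium:

* a universe of ~20,000 measured genes (typical of a whole-genome array);
* large TFBS and functional gene-set collections (600 sets each by default,
  400-500 genes per set — real motif and GO collections, truncated at the
  500-gene filter, live at this end of the size range);
* heavy co-membership between the two collections: by default every diagonal
  (TFBS_i, functional_i) pair shares a forced block of ``background_overlap``
  genes.  Real TFBS and GO collections overlap massively, which is what makes
  the overlap test retain many pairs and gives the per-condition BH families
  their size;
* log2 fold-change profiles that are i.i.d. Gaussian noise, plus, for each
  *planted regulon*, an additive shift of ``delta`` on the pair's shared
  genes in the planted conditions.  Non-overlap members of the parent sets
  receive noise only, so the parent signal is pure dilution of the overlap
  shift;
* a protein-interaction graph wiring each planted target to interactors
  inside its functional set, for annotation-extension tests.

Everything is reproducible from the design's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .geneset_io import Category, FoldChangeMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedRegulon",
    "SimulationDesign",
    "GroundTruth",
    "SimulatedData",
    "simulate",
    "null_design",
    "recovery_design",
]


@dataclass(frozen=True)
class PlantedRegulon:
    """One planted (TFBS set, functional set) regulon.

    ``conditions`` are condition indices (0-based) in which the overlap genes
    are shifted by ``delta`` on the log2 scale.
    """

    tfbs_index: int
    func_index: int
    overlap_size: int
    conditions: tuple = ()
    delta: float = 0.0


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic compendium.

    Defaults describe the reference condition: a 20,000-gene universe,
    600 TFBS x 600 functional sets of 400-500 genes, 30 conditions,
    fold-change noise sd 1.8 and a 30-gene forced co-membership block on
    every diagonal pair.
    """

    n_genes: int = 20_000
    n_tfbs_sets: int = 600
    n_func_sets: int = 600
    set_size_range: tuple = (400, 500)
    n_conditions: int = 30
    background_overlap: int = 30
    planted_regulons: tuple = ()
    noise_sd: float = 1.8
    ppi_interactors_per_target: int = 10
    ppi_background_edges: int = 500
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid set_size_range")
        if self.n_genes < 2 * hi:
            raise ValueError("universe too small for the requested set sizes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.background_overlap > lo:
            raise ValueError("background overlap exceeds the minimum set size")
        used_t, used_f = set(), set()
        for r in self.planted_regulons:
            if not (0 <= r.tfbs_index < self.n_tfbs_sets and 0 <= r.func_index < self.n_func_sets):
                raise ValueError("planted regulon references a nonexistent set")
            if r.overlap_size > lo:
                raise ValueError("planted overlap exceeds the minimum set size")
            if r.tfbs_index in used_t or r.func_index in used_f:
                raise ValueError("each set may participate in at most one planted regulon")
            used_t.add(r.tfbs_index)
            used_f.add(r.func_index)
            if any(c < 0 or c >= self.n_conditions for c in r.conditions):
                raise ValueError("planted condition index out of range")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the true triples and the true targets per regulon."""

    triples: tuple  # of (tf_label, func_name, condition)
    targets: dict  # (tf_label, func_name) -> frozenset of genes

    @property
    def pairs(self) -> frozenset:
        return frozenset(self.targets)


class SimulatedData(NamedTuple):
    tfbs: GeneSetCollection
    funcs: GeneSetCollection
    matrix: FoldChangeMatrix
    graph: nx.Graph
    truth: GroundTruth


def _labels(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate(design: SimulationDesign) -> SimulatedData:
    """Generate one synthetic compendium from ``design``.

    Forced-overlap pairs (planted regulons and diagonal co-membership pairs)
    are built with *exact* overlaps: the shared block and the two private
    remainders are drawn disjointly, so the pair's observed intersection is
    precisely the planted block.  Sets outside any forced pair are plain
    random draws.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = np.array(_labels("G", design.n_genes))
    conditions = _labels("C", design.n_conditions)
    lo, hi = design.set_size_range

    tf_labels = _labels("TF", design.n_tfbs_sets)
    tfbs_names = [f"{t}_BS" for t in tf_labels]
    func_names = _labels("FN", design.n_func_sets)

    planted_t = {r.tfbs_index: r for r in design.planted_regulons}
    planted_f = {r.func_index: r for r in design.planted_regulons}

    tf_genes: dict[int, np.ndarray] = {}
    fn_genes: dict[int, np.ndarray] = {}
    overlap_of: dict[tuple[int, int], np.ndarray] = {}

    # forced pairs: planted regulons, then diagonal co-membership for the rest
    forced: list[tuple[int, int, int]] = [
        (r.tfbs_index, r.func_index, r.overlap_size) for r in design.planted_regulons
    ]
    n_diag = min(design.n_tfbs_sets, design.n_func_sets)
    for i in range(n_diag):
        if i in planted_t or i in planted_f:
            continue
        if design.background_overlap > 0:
            forced.append((i, i, design.background_overlap))

    for ti, fi, s in forced:
        n_t = int(rng.integers(lo, hi + 1))
        n_f = int(rng.integers(lo, hi + 1))
        draw = rng.choice(design.n_genes, size=n_t + n_f - s, replace=False)
        shared, t_priv, f_priv = draw[:s], draw[s : n_t], draw[n_t :]
        tf_genes[ti] = np.concatenate([shared, t_priv])
        fn_genes[fi] = np.concatenate([shared, f_priv])
        overlap_of[(ti, fi)] = shared

    for i in range(design.n_tfbs_sets):
        if i not in tf_genes:
            tf_genes[i] = rng.choice(design.n_genes, size=int(rng.integers(lo, hi + 1)), replace=False)
    for j in range(design.n_func_sets):
        if j not in fn_genes:
            fn_genes[j] = rng.choice(design.n_genes, size=int(rng.integers(lo, hi + 1)), replace=False)

    tfbs = GeneSetCollection(
        [
            GeneSet(
                tfbs_names[i],
                frozenset(genes[tf_genes[i]]),
                category=Category.TFBS,
                tf_label=tf_labels[i],
                description="synthetic TFBS set",
            )
            for i in range(design.n_tfbs_sets)
        ]
    )
    funcs = GeneSetCollection(
        [
            GeneSet(
                func_names[j],
                frozenset(genes[fn_genes[j]]),
                category=Category.GO_BP,
                description="synthetic functional set",
            )
            for j in range(design.n_func_sets)
        ]
    )

    values = rng.normal(0.0, design.noise_sd, size=(design.n_genes, design.n_conditions))
    for r in design.planted_regulons:
        if r.delta != 0.0 and r.conditions:
            idx = overlap_of[(r.tfbs_index, r.func_index)]
            values[np.ix_(idx, np.array(r.conditions))] += r.delta
    matrix = FoldChangeMatrix(pd.DataFrame(values, index=genes, columns=conditions))

    # interaction graph: wire each planted target to interactors inside its
    # functional set, plus background edges
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for r in design.planted_regulons:
        if r.delta == 0.0:
            continue
        member_idx = fn_genes[r.func_index]
        for g_idx in overlap_of[(r.tfbs_index, r.func_index)]:
            partners = member_idx[member_idx != g_idx]
            m = min(design.ppi_interactors_per_target, partners.size)
            chosen = rng.choice(partners, size=m, replace=False)
            for p_idx in chosen:
                graph.add_edge(genes[g_idx], genes[p_idx])
    for _ in range(design.ppi_background_edges):
        a, b = rng.choice(design.n_genes, size=2, replace=False)
        graph.add_edge(genes[a], genes[b])

    triples = tuple(
        (tf_labels[r.tfbs_index], func_names[r.func_index], conditions[c])
        for r in design.planted_regulons
        if r.delta != 0.0
        for c in r.conditions
    )
    targets = {
        (tf_labels[r.tfbs_index], func_names[r.func_index]): frozenset(
            genes[overlap_of[(r.tfbs_index, r.func_index)]]
        )
        for r in design.planted_regulons
        if r.delta != 0.0
    }
    truth = GroundTruth(triples=triples, targets=targets)
    logger.info(
        "simulated %d genes x %d conditions, %d+%d sets, %d planted regulon(s)",
        design.n_genes,
        design.n_conditions,
        design.n_tfbs_sets,
        design.n_func_sets,
        len(targets),
    )
    return SimulatedData(tfbs, funcs, matrix, graph, truth)


def null_design(seed: int = 0, n_conditions: int = 30) -> SimulationDesign:
    """Null calibration design: no expression signal anywhere.

    Scaled to a 2,000-gene universe with proportionally scaled sets (60x60
    sets of 40-50 genes, co-membership blocks of 10) so that the overlap
    criterion still retains pairs and the null genuinely stresses the
    expression screen.
    """
    return SimulationDesign(
        n_genes=2_000,
        n_tfbs_sets=60,
        n_func_sets=60,
        set_size_range=(40, 50),
        n_conditions=n_conditions,
        background_overlap=10,
        planted_regulons=(),
        seed=seed,
    )


def recovery_design(
    seed: int = 0,
    delta: float = 2.0,
    overlap_size: int = 30,
    n_planted_conditions: int = 12,
) -> SimulationDesign:
    """Parameter-recovery design: one signal regulon at reference scale.

    The regulon shifts its 30 shared genes by ``delta`` log2 units in the
    first 12 of 30 conditions; all other co-membership pairs carry no
    expression signal.
    """
    return SimulationDesign(
        planted_regulons=(
            PlantedRegulon(
                tfbs_index=0,
                func_index=0,
                overlap_size=overlap_size,
                conditions=tuple(range(n_planted_conditions)),
                delta=delta,
            ),
        ),
        seed=seed,
    )
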