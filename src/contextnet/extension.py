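"""Guilt-by-association annotation extension through protein-interaction neighborhoods.

Many genes carry no GO/KEGG annotation and are invisible to gene-set based
mining.  For each gene g with interaction partners L(g) and each functional
set F not already containing g, the overlap |L(g) & F| is tested with the
hypergeometric upper tail over the extension universe; when the uncorrected
p-value is at or below p0 (default 1e-4) the annotation F is transferred to
g.  A single extension round is performed and original annotations are
always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx

from .geneset_io import GeneSet, GeneSetCollection
from .overlap import hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = ["AnnotationTransfer", "read_edge_list", "write_edge_list", "extend_annotations"]


@dataclass(frozen=True)
class AnnotationTransfer:
    """One evaluated (gene, functional set) transfer candidate."""

    gene: str
    func_name: str
    neighborhood_size: int
    overlap: int
    p_value: float
    accepted: bool


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column TSV edge list into an undirected interaction graph.

    Edges are deduplicated, self-loops dropped, symbols upper-cased.
    """
    g = nx.Graph()
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path.name}:{lineno}: expected two tab-separated columns")
            a, b = parts[0].strip().upper(), parts[1].strip().upper()
            if a == b:
                continue
            g.add_edge(a, b)
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def extend_annotations(
    funcs: GeneSetCollection,
    graph: nx.Graph,
    p0: float = 1e-4,
    universe=None,
) -> tuple[GeneSetCollection, list[AnnotationTransfer]]:
    """Extend functional annotations through interaction neighborhoods.

    Parameters
    ----------
    funcs : GeneSetCollection
        Functional gene sets to extend.
    graph : networkx.Graph
        Undirected protein-interaction graph (gene symbols as nodes).
    p0 : float
        Uncorrected hypergeometric p-value threshold for a transfer.
    universe : iterable of str, optional
        Extension universe; defaults to graph nodes plus all annotated genes.

    Returns
    -------
    (extended collection, list of evaluated transfers)
        The collection is a copy; original memberships are retained and each
        accepted (gene, set) transfer adds the gene to the set.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty interaction graph")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must lie in [0, 1]")
    if universe is None:
        uni = frozenset(str(n).upper() for n in graph.nodes()) | funcs.all_genes()
    else:
        uni = frozenset(str(g).upper() for g in universe)
    N = len(uni)

    set_genes = {s.name: s.genes & uni for s in funcs}
    transfers: list[AnnotationTransfer] = []
    added: dict[str, set] = {s.name: set() for s in funcs}

    for gene in sorted(str(n).upper() for n in graph.nodes()):
        if gene not in uni:
            continue
        L = {str(v).upper() for v in graph.neighbors(gene)} & uni
        n_draw = len(L)
        if n_draw == 0:
            continue
        for s in funcs:
            if gene in s.genes:
                continue
            Fg = set_genes[s.name]
            K = len(Fg)
            if K == 0:
                continue
            x = len(L & Fg)
            p = hypergeom_tail(N, K, n_draw, x)
            accepted = p <= p0
            transfers.append(
                AnnotationTransfer(
                    gene=gene,
                    func_name=s.name,
                    neighborhood_size=n_draw,
                    overlap=x,
                    p_value=p,
                    accepted=accepted,
                )
            )
            if accepted:
                added[s.name].add(gene)

    new_sets = [
        replace(s, genes=frozenset(s.genes | added[s.name])) if added[s.name] else s
        for s in funcs
    ]
    n_accepted = sum(len(v) for v in added.values())
    logger.info("annotation extension: %d transfer(s) accepted at p0=%g", n_accepted, p0)
    extended = GeneSetCollection(new_sets)
    return extended, transfers
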