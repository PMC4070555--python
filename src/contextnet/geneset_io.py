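"""Gene-set and fold-change I/O with the preprocessing rules of the mining pipeline.

Gene sets travel in GMT format (tab-separated: name, description, member
genes).  Fold-change profiles travel as a TSV matrix: first column gene (or
probe) symbols, remaining columns one log2 fold-change profile per
test/control condition.  Gene identity is case-insensitive and normalised to
uppercase throughout, since motif collections and array annotations rarely
agree on capitalisation.

Preprocessing rules implemented here:

* probe-level profiles are collapsed to gene level by averaging the probes
  mapped to each gene (missing values ignored);
* gene sets are restricted to the analysis universe and kept only if their
  measurable size lies within [10, 500];
* for transcription factors represented by several binding-site (TFBS) sets,
  a ``<TF>_all`` union set is appended so that regulation visible only on the
  pooled binding repertoire can be detected.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "GeneSet",
    "GeneSetCollection",
    "FoldChangeMatrix",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_fold_changes",
    "read_probe_map",
    "collapse_probes",
    "filter_by_size",
    "build_tf_union_sets",
    "default_tf_label",
]


class Category(str, enum.Enum):
    """Origin of a gene set."""

    TFBS = "TFBS"
    GO_BP = "GO_BP"
    GO_CC = "GO_CC"
    GO_MF = "GO_MF"
    KEGG = "KEGG"
    OTHER = "OTHER"


class GmtParseError(ValueError):
    """Raised when a GMT file cannot be parsed."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols.

    Parameters
    ----------
    name : str
        Unique identifier, e.g. a TFBS motif name or a GO/KEGG term code.
    genes : frozenset of str
        Member gene symbols, uppercase, deduplicated, non-empty.
    category : Category
        Collection the set came from.
    tf_label : str or None
        For TFBS sets, the transcription factor the motif belongs to.
    description : str
        Free-text description (second GMT column).
    """

    name: str
    genes: frozenset
    category: Category = Category.OTHER
    tf_label: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def restricted(self, universe: Iterable[str]) -> "GeneSet | None":
        """Return a copy restricted to ``universe``; None if no gene survives."""
        kept = self.genes & frozenset(universe)
        if not kept:
            return None
        return replace(self, genes=kept)


class GeneSetCollection:
    """An ordered collection of uniquely named :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet], universe: Iterable[str] | None = None):
        self.sets: list[GeneSet] = list(sets)
        names = [s.name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate set name(s): {sorted(dupes)}")
        member_union = frozenset().union(*(s.genes for s in self.sets)) if self.sets else frozenset()
        if universe is None:
            self.universe = member_union
        else:
            self.universe = frozenset(g.upper() for g in universe)
            if not member_union <= self.universe:
                raise ValueError("universe does not cover all member genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def all_genes(self) -> frozenset:
        return frozenset().union(*(s.genes for s in self.sets)) if self.sets else frozenset()


def default_tf_label(name: str) -> str:
    """Derive a TF label from a motif-style set name.

    Strips a leading ``V$`` (TRANSFAC convention) and takes the token before
    the first underscore: ``V$AHR_01`` -> ``AHR``; ``E2F1_all`` -> ``E2F1``.
    """
    s = name[2:] if name.startswith("V$") else name
    return s.split("_")[0] if "_" in s else s


def read_gmt(
    path: str | Path,
    category: Category = Category.OTHER,
    tf_labeler: Callable[[str], str] | None = None,
) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each line must carry at least three tab-separated fields (name,
    description, one or more genes).  Duplicate genes within a line are
    collapsed; gene symbols are upper-cased.  Duplicate set names raise.

    Parameters
    ----------
    path : path
    category : Category
        Category assigned to every set in the file.
    tf_labeler : callable, optional
        Maps a set name to a TF label (use :func:`default_tf_label` for
        motif-style names).  Applied only when given.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in seen:
                raise GmtParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise GmtParseError(f"{path.name}:{lineno}: set {name!r} has no genes")
            tf = tf_labeler(name) if tf_labeler is not None else None
            sets.append(GeneSet(name, genes, category=category, tf_label=tf, description=description))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT (genes sorted for determinism)."""
    path = Path(path)
    with path.open("w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


class FoldChangeMatrix:
    """Per-gene log2 fold-change values across named test/control conditions.

    Thin wrapper over a pandas DataFrame (genes on the index, conditions on
    the columns, NaN for missing measurements).
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str).str.upper()
        if data.index.duplicated().any():
            dupes = sorted(set(data.index[data.index.duplicated()]))
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if data.columns.duplicated().any():
            raise ValueError("duplicate condition identifiers")
        self.data = data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")

    def __repr__(self) -> str:  # pragma: no cover
        return f"FoldChangeMatrix({self.shape[0]} genes x {self.shape[1]} conditions)"


def read_fold_changes(path: str | Path) -> FoldChangeMatrix:
    """Read a TSV fold-change matrix (first column gene/probe ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FoldChangeMatrix(df)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Read a two-column probe->gene TSV (header optional, columns probe, gene)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe, gene")
    first = df.iloc[0]
    if str(first[0]).lower() in {"probe", "probe_id"}:
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["probe", "gene"]
    return df.reset_index(drop=True)


def collapse_probes(matrix: FoldChangeMatrix, probe_map: pd.DataFrame | Mapping[str, str]) -> FoldChangeMatrix:
    """Collapse a probe-level matrix to gene level by averaging.

    Per gene and condition the value is the arithmetic mean of the mapped
    probes' values, ignoring missing values.  Unmapped probes are dropped.
    A probe mapped to more than one gene is an error.
    """
    if isinstance(probe_map, Mapping):
        pm = pd.DataFrame({"probe": list(probe_map.keys()), "gene": list(probe_map.values())})
    else:
        pm = probe_map[["probe", "gene"]].copy()
    # probe ids are matched case-insensitively, like gene symbols
    pm["probe"] = pm["probe"].astype(str).str.upper()
    pm["gene"] = pm["gene"].astype(str).str.upper()
    pm = pm.drop_duplicates()
    multi = pm.groupby("probe")["gene"].nunique()
    ambiguous = multi[multi > 1].index.tolist()
    if ambiguous:
        raise ValueError(f"probe(s) mapped to more than one gene: {ambiguous[:5]}")

    mapping = pm.set_index("probe")["gene"]
    df = matrix.data
    mapped = df.index.intersection(mapping.index)
    dropped = len(df.index) - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropping %d unmapped probe(s)", dropped)
    sub = df.loc[mapped]
    genes = mapping.loc[mapped]
    collapsed = sub.groupby(genes.values).mean()  # skipna by default
    collapsed.index.name = "gene"
    return FoldChangeMatrix(collapsed)


def filter_by_size(
    collection: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    universe: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Retain sets whose (measurable) size lies within [min_size, max_size].

    When ``universe`` is given, sets are first restricted to it and sizes are
    measured on the restriction — a set that shrinks below ``min_size``
    measurable genes is dropped, since downstream statistics only ever see
    measurable genes.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError("require 1 <= min_size <= max_size")
    uni = frozenset(g.upper() for g in universe) if universe is not None else None
    kept: list[GeneSet] = []
    for s in collection:
        if uni is None or s.genes <= uni:
            t = s
        else:
            t = s.restricted(uni)
        if t is not None and min_size <= len(t) <= max_size:
            kept.append(t)
    n_dropped = len(collection) - len(kept)
    if n_dropped:
        logger.info("filter_by_size: dropped %d of %d sets", n_dropped, len(collection))
    return GeneSetCollection(kept, universe=uni)


def build_tf_union_sets(collection: GeneSetCollection) -> GeneSetCollection:
    """Append a ``<TF>_all`` union set for every TF with two or more TFBS sets.

    A TF can recognise several distinct binding-site motifs; regulation spread
    across motifs may only reach significance on the pooled set.  Original
    sets are retained; union sets carry the same TF label and category TFBS.
    """
    by_tf: dict[str, list[GeneSet]] = {}
    for s in collection:
        if s.category is Category.TFBS and s.tf_label:
            by_tf.setdefault(s.tf_label, []).append(s)
    new_sets = list(collection.sets)
    for tf, members in sorted(by_tf.items()):
        if len(members) < 2:
            continue
        name = f"{tf}_all"
        if name in collection:
            logger.warning("build_tf_union_sets: %s already present, skipping", name)
            continue
        union = frozenset().union(*(m.genes for m in members))
        new_sets.append(
            GeneSet(
                name,
                union,
                category=Category.TFBS,
                tf_label=tf,
                description=f"union of {len(members)} TFBS sets for {tf}",
            )
        )
    return GeneSetCollection(new_sets)
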