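"""Criterion (B): per-condition gene-set Z statistics and the composite screen.

For each retained (TFBS, functional) pair and each microarray condition the
pipeline computes a gene-randomisation z-score for three sets: the TFBS set,
the functional set and their overlap.  The z-score compares the mean log2
fold-change of the set's measured members against the condition's global
distribution:

    z = (mean(members) - mean(all genes)) * sqrt(n_members) / sd(all genes)

with the sample standard deviation (ddof=1) over all measured genes, and a
two-sided normal p-value (both activation and repression count).  Within each
condition, p-values are converted to BH q-values in three separate families
(one per role) so that like is compared with like.

A pair is ACTIVATED in a condition when the overlap is significant
(q <= q_sig, default 0.02) while neither parent set is (q > q_nonsig,
default 0.05): the expression change must be pronounced in the overlap
compared to both individual sets, otherwise the signal is attributable to
the function or the binding repertoire as a whole rather than to the TF
acting through that function.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geneset_io import FoldChangeMatrix
from .overlap import OverlapResult, bh_qvalues

logger = logging.getLogger(__name__)

__all__ = ["SetConditionStat", "ScreenResult", "set_zscore", "condition_screen"]

ROLE_OVERLAP = "overlap"
ROLE_TFBS = "tfbs"
ROLE_FUNC = "func"


@dataclass(frozen=True)
class SetConditionStat:
    """Z statistic of one gene set in one condition."""

    set_id: str
    condition: str
    role: str
    n_measured: int
    z: float
    p_value: float
    q_value: float


@dataclass
class ScreenResult:
    """Output of :func:`condition_screen`.

    Attributes
    ----------
    stats : DataFrame
        Long format: set_id, condition, role, n_measured, z, p, q.
    calls : DataFrame
        One row per (pair, condition): pair_id, condition, z_overlap,
        q_overlap, q_tfbs, q_func, activated.
    overlaps : dict
        pair_id -> the criterion-A :class:`OverlapResult` the pair came from.
    q_sig, q_nonsig : float
        Thresholds the activation calls were made at.
    """

    stats: pd.DataFrame
    calls: pd.DataFrame
    overlaps: dict = field(default_factory=dict)
    q_sig: float = 0.02
    q_nonsig: float = 0.05

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)


def set_zscore(values: pd.Series, members) -> tuple[float, float]:
    """Z statistic of a gene set against one condition's global distribution.

    Parameters
    ----------
    values : Series
        All genes' log2 fold-changes for the condition (NaN = missing).
    members : iterable of str
        The gene set (symbols matched case-insensitively).

    Returns
    -------
    (z, p) with p the two-sided standard-normal tail.
    """
    v = values.dropna()
    if len(v) < 2:
        raise ValueError("need at least two measured genes in the condition")
    sd = float(v.std(ddof=1))
    if sd <= 0.0:
        raise ValueError("zero variance across measured genes: z undefined")
    member_set = {str(g).upper() for g in members}
    mv = v[v.index.isin(member_set)]
    if len(mv) == 0:
        raise ValueError("no member gene measured in this condition")
    z = (float(mv.mean()) - float(v.mean())) * math.sqrt(len(mv)) / sd
    p = 2.0 * float(norm.sf(abs(z)))
    return z, min(p, 1.0)


def _dedup_overlap_sets(overlaps: list[OverlapResult]) -> tuple[dict, dict]:
    """Map pair_id -> overlap-set key, plus key -> gene frozenset (deduplicated)."""
    key_of_pair: dict[str, str] = {}
    genes_of_key: dict[str, frozenset] = {}
    by_genes: dict[frozenset, str] = {}
    for ov in overlaps:
        g = ov.overlap_genes
        if g not in by_genes:
            key = f"overlap:{ov.pair_id}"
            by_genes[g] = key
            genes_of_key[key] = g
        key_of_pair[ov.pair_id] = by_genes[g]
    return key_of_pair, genes_of_key


def condition_screen(
    overlaps: list[OverlapResult],
    matrix: FoldChangeMatrix,
    q_sig: float = 0.02,
    q_nonsig: float = 0.05,
    tfbs_genes: dict | None = None,
    func_genes: dict | None = None,
) -> ScreenResult:
    """Run the criterion-(B) expression screen for every retained pair.

    ``tfbs_genes`` / ``func_genes`` map set names to their (universe
    restricted) gene frozensets; when omitted they cannot be reconstructed
    from the overlap alone, so they are required whenever ``overlaps`` refer
    to parent sets — the mining driver passes them.  Conditions with fewer
    than two measured genes are skipped with a warning.
    """
    if not overlaps:
        raise ValueError("no overlaps to screen")
    if tfbs_genes is None or func_genes is None:
        raise ValueError("tfbs_genes and func_genes mappings are required")

    key_of_pair, genes_of_key = _dedup_overlap_sets(overlaps)

    # role -> ordered list of (set_id, genes)
    tf_names = sorted({ov.tfbs_name for ov in overlaps})
    fn_names = sorted({ov.func_name for ov in overlaps})
    ov_keys = sorted(genes_of_key)
    roles: list[tuple[str, str, frozenset]] = (
        [(ROLE_TFBS, n, frozenset(tfbs_genes[n])) for n in tf_names]
        + [(ROLE_FUNC, n, frozenset(func_genes[n])) for n in fn_names]
        + [(ROLE_OVERLAP, k, genes_of_key[k]) for k in ov_keys]
    )

    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    n_genes = len(gene_index)
    n_sets = len(roles)
    # membership as index lists (sets are small relative to the matrix)
    member_idx = [
        np.fromiter((gene_index[g] for g in genes if g in gene_index), dtype=np.int64)
        for _, _, genes in roles
    ]
    V = matrix.data.to_numpy(dtype=float)

    rows: list[tuple] = []
    q_lookup: dict[tuple[str, str], tuple[float, float, int]] = {}  # (set_id, cond) -> (z, q, n)
    for c_pos, cond in enumerate(matrix.conditions):
        v = V[:, c_pos]
        meas = ~np.isnan(v)
        n_all = int(meas.sum())
        if n_all < 2:
            logger.warning("condition %s has <2 measured genes; skipped", cond)
            continue
        mu = float(v[meas].mean())
        sd = float(v[meas].std(ddof=1))
        if sd <= 0.0:
            logger.warning("condition %s has zero variance; skipped", cond)
            continue
        z_arr = np.full(n_sets, np.nan)
        nm_arr = np.zeros(n_sets, dtype=np.int64)
        for s in range(n_sets):
            mi = member_idx[s]
            mm = mi[meas[mi]]
            nm_arr[s] = mm.size
            if mm.size:
                z_arr[s] = (v[mm].mean() - mu) * math.sqrt(mm.size) / sd
        p_arr = np.minimum(2.0 * norm.sf(np.abs(z_arr)), 1.0)
        q_arr = np.full(n_sets, np.nan)
        role_labels = np.array([r for r, _, _ in roles])
        for role in (ROLE_TFBS, ROLE_FUNC, ROLE_OVERLAP):
            mask = (role_labels == role) & (nm_arr > 0)
            if mask.any():
                q_arr[mask] = bh_qvalues(p_arr[mask])
        for s, (role, set_id, _) in enumerate(roles):
            if nm_arr[s] == 0:
                continue
            rows.append((set_id, cond, role, int(nm_arr[s]), float(z_arr[s]), float(p_arr[s]), float(q_arr[s])))
            q_lookup[(set_id, cond)] = (float(z_arr[s]), float(q_arr[s]), int(nm_arr[s]))

    stats = pd.DataFrame(rows, columns=["set_id", "condition", "role", "n_measured", "z", "p", "q"])

    call_rows: list[tuple] = []
    for ov in overlaps:
        okey = key_of_pair[ov.pair_id]
        for cond in matrix.conditions:
            o = q_lookup.get((okey, cond))
            t = q_lookup.get((ov.tfbs_name, cond))
            f = q_lookup.get((ov.func_name, cond))
            if o is None or t is None or f is None:
                continue  # a role unmeasured in this condition: no call
            z_o, q_o, _ = o
            _, q_t, _ = t
            _, q_f, _ = f
            activated = (q_o <= q_sig) and (q_t > q_nonsig) and (q_f > q_nonsig)
            call_rows.append((ov.pair_id, cond, z_o, q_o, q_t, q_f, activated))
    calls = pd.DataFrame(
        call_rows,
        columns=["pair_id", "condition", "z_overlap", "q_overlap", "q_tfbs", "q_func", "activated"],
    )
    n_act = int(calls["activated"].sum()) if len(calls) else 0
    logger.info("criterion B: %d activated (pair, condition) calls", n_act)
    return ScreenResult(
        stats=stats,
        calls=calls,
        overlaps={ov.pair_id: ov for ov in overlaps},
        q_sig=q_sig,
        q_nonsig=q_nonsig,
    )
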