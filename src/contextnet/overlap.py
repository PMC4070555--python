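"""Criterion (A): hypergeometric overlap significance between TFBS and functional sets.

A TFBS gene set that shares significantly more genes with a functional gene
set than chance expects is a candidate transcription network: the shared
genes are the channel through which the TF may regulate the function.  Every
(TFBS, functional) pair is tested with the hypergeometric upper tail over the
shared analysis universe, q-values are computed over the complete tested
family by Benjamini-Hochberg, and pairs with q <= q_overlap (default 0.02)
and a non-empty overlap are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .geneset_io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["OverlapResult", "hypergeom_tail", "bh_qvalues", "all_pairwise_overlaps"]


@dataclass(frozen=True)
class OverlapResult:
    """One tested (TFBS set, functional set) pair.

    ``universe_size``/``tfbs_size``/``func_size``/``overlap_size`` are the
    N/K/n/x of the hypergeometric test, all measured within the analysis
    universe.
    """

    tfbs_name: str
    func_name: str
    overlap_genes: frozenset
    universe_size: int
    tfbs_size: int
    func_size: int
    overlap_size: int
    p_value: float
    q_value: float
    tf_label: str | None = None

    @property
    def pair_id(self) -> str:
        return f"{self.tfbs_name}|{self.func_name}"


def hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """Inclusive upper tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    N: universe size; K: category size; n: draw size; x: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= x <= min(K, n)):
        raise ValueError(f"overlap x={x} outside [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(x - 1, N, K, n))


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return q.reshape(p.shape)


def _hypergeom_sf_grid(N: int, K: np.ndarray, n: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Inclusive upper tail P(X >= x) for a grid of draws from one universe.

    K: (T,) category sizes; n: (F,) draw sizes; x: (T, F) observed overlaps.
    Equivalent to :func:`hypergeom_tail` element-wise but evaluates the pmf
    once per distinct (K, n) row (gammaln log-binomials, reverse cumulative
    sum), which is orders of magnitude faster on large set collections.
    """
    KK = np.repeat(K, n.size)
    nn = np.tile(n, K.size)
    rows, inv = np.unique(np.stack([KK, nn], axis=1), axis=0, return_inverse=True)
    Ku = rows[:, 0].astype(np.int64)
    nu = rows[:, 1].astype(np.int64)
    m = np.minimum(Ku, nu)
    M = int(m.max()) + 1 if m.size else 1
    j = np.arange(M)[None, :]

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    with np.errstate(invalid="ignore"):
        logpmf = (
            log_comb(Ku[:, None], j)
            + log_comb(N - Ku[:, None], nu[:, None] - j)
            - log_comb(N, nu)[:, None]
        )
    valid = (j <= m[:, None]) & (nu[:, None] - j <= N - Ku[:, None]) & (j <= nu[:, None])
    pmf = np.where(valid, np.exp(np.where(valid, logpmf, -np.inf)), 0.0)
    sf = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]  # sf[u, v] = P(X >= v)
    np.minimum(sf, 1.0, out=sf)
    return sf[inv, x.ravel()].reshape(x.shape)


def all_pairwise_overlaps(
    tfbs: GeneSetCollection,
    funcs: GeneSetCollection,
    universe,
    q_overlap: float = 0.02,
) -> list[OverlapResult]:
    """Test every (TFBS, functional) pair for overlap enrichment.

    The BH family is the full cross-product of tested pairs.  Returns pairs
    with q <= ``q_overlap`` and at least one shared gene; their shared genes
    are the TF's candidate targets for that function.
    """
    uni = sorted({g.upper() for g in universe})
    if not uni:
        raise ValueError("empty analysis universe")
    N = len(uni)
    idx = {g: i for i, g in enumerate(uni)}

    def membership(coll: GeneSetCollection) -> np.ndarray:
        M = np.zeros((len(coll), N), dtype=bool)
        for r, s in enumerate(coll):
            cols = [idx[g] for g in s.genes if g in idx]
            M[r, cols] = True
        return M

    T = membership(tfbs)
    F = membership(funcs)
    K = T.sum(axis=1)
    n = F.sum(axis=1)
    x = T.astype(np.float32) @ F.astype(np.float32).T
    x = np.rint(x).astype(np.int64)

    # vectorised inclusive upper tail
    p = _hypergeom_sf_grid(N, K.astype(np.int64), n.astype(np.int64), x)
    q = bh_qvalues(p)

    results: list[OverlapResult] = []
    keep = (q <= q_overlap) & (x >= 1)
    tf_sets = list(tfbs)
    fn_sets = list(funcs)
    uni_set = frozenset(uni)
    for i, j in zip(*np.nonzero(keep)):
        ts, fs = tf_sets[i], fn_sets[j]
        genes = (ts.genes & fs.genes) & uni_set
        results.append(
            OverlapResult(
                tfbs_name=ts.name,
                func_name=fs.name,
                overlap_genes=frozenset(genes),
                universe_size=N,
                tfbs_size=int(K[i]),
                func_size=int(n[j]),
                overlap_size=int(x[i, j]),
                p_value=float(p[i, j]),
                q_value=float(q[i, j]),
                tf_label=ts.tf_label,
            )
        )
    logger.info(
        "criterion A: %d of %d pairs retained at q<=%.3g", len(results), x.size, q_overlap
    )
    return results
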