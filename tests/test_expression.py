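import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextnet.expression import condition_screen, set_zscore
from contextnet.geneset_io import FoldChangeMatrix, GeneSet
from contextnet.overlap import OverlapResult


def series(values, prefix="G"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


class TestSetZscore:
    def test_member_mean_equal_to_global_mean_gives_zero(self):
        v = series([1.0, 1.0, 2.0, 2.0])
        z, p = set_zscore(v, ["G0", "G3"])  # member mean = 1.5 = global mean
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_expected_z_matches_shift_times_sqrt_n(self, rng):
        """E[z] ~ delta*sqrt(n) for a member subset shifted by delta."""
        n_genes, n_members, delta, reps = 400, 25, 0.8, 4000
        members = [f"G{i}" for i in range(n_members)]
        zs = np.empty(reps)
        for r in range(reps):
            vals = rng.normal(0, 1, n_genes)
            vals[:n_members] += delta
            zs[r] = set_zscore(series(vals), members)[0]
        # delta*sqrt(n), with the finite-membership correction: the shift also
        # moves the global mean by f*delta and inflates the global sd
        f = n_members / n_genes
        sd_infl = math.sqrt(1 + f * (1 - f) * delta**2)
        expected = delta * (1 - f) * math.sqrt(n_members) / sd_infl
        se = zs.std(ddof=1) / math.sqrt(reps)
        assert abs(zs.mean() - expected) < 3 * se + 0.02 * expected

    def test_doubling_shift_doubles_expected_z(self, rng):
        n_genes, n_members, reps = 400, 25, 2000
        members = [f"G{i}" for i in range(n_members)]
        means = []
        for delta in (0.5, 1.0):
            zs = np.empty(reps)
            for r in range(reps):
                vals = rng.normal(0, 1, n_genes)
                vals[:n_members] += delta
                zs[r] = set_zscore(series(vals), members)[0]
            means.append(zs.mean())
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.1)

    @given(
        c=st.floats(min_value=-5, max_value=5, allow_nan=False),
        s=st.floats(min_value=0.1, max_value=10, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_affine_invariance(self, c, s):
        """Adding a constant or rescaling a condition leaves z unchanged."""
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, 100)
        members = [f"G{i}" for i in range(10)]
        z0, _ = set_zscore(series(vals), members)
        z1, _ = set_zscore(series(s * vals + c), members)
        assert z1 == pytest.approx(z0, abs=1e-9)

    def test_null_rejection_rate_is_five_percent(self, rng):
        """Under i.i.d. normal values and random membership, |z|>1.96 ~5% of the time."""
        n_genes, n_members, reps = 300, 20, 10_000
        hits = 0
        idx = np.arange(n_genes)
        for _ in range(reps):
            vals = rng.normal(0, 1, n_genes)
            members = rng.choice(idx, n_members, replace=False)
            mu, sd = vals.mean(), vals.std(ddof=1)
            z = (vals[members].mean() - mu) * math.sqrt(n_members) / sd
            hits += abs(z) > 1.96
        assert hits / reps == pytest.approx(0.05, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            set_zscore(series([1.0, 1.0, 1.0]), ["G0"])
        with pytest.raises(ValueError, match="member"):
            set_zscore(series([1.0, 2.0]), ["NOT_THERE"])
        with pytest.raises(ValueError, match="two measured"):
            set_zscore(series([1.0, np.nan]), ["G0"])

    def test_missing_members_excluded_from_n(self):
        v = series([2.0, np.nan, 0.0, 0.0, 0.0, 0.0])
        z, _ = set_zscore(v, ["G0", "G1"])  # G1 unmeasured -> n_measured = 1
        mu, sd = v.dropna().mean(), v.dropna().std(ddof=1)
        assert z == pytest.approx((2.0 - mu) * 1.0 / sd)


def _screen_fixture(shift_what: str):
    """One condition, one retained pair; parents of 450 genes, overlap 25.

    Background values are symmetric standard-normal quantile grids scaled by
    sd=2 (each parent's private block has mean ~0 by construction), so the
    outcome is deterministic: shifting only the 25 shared genes by +2 leaves
    each parent's z at ~1.1 (diluted) while the overlap z is ~5.

    shift_what: 'overlap' shifts only the 25 shared genes; 'tfbs' shifts the
    whole TFBS parent set (so the parent itself is significant).
    """
    from scipy.stats import norm

    n_genes = 5000
    genes = [f"G{i:05d}" for i in range(n_genes)]
    overlap = genes[:25]
    tf_genes = frozenset(genes[:450])
    fn_genes = frozenset(overlap) | frozenset(genes[450:875])
    vals = np.zeros(n_genes)

    def quantile_grid(n):
        return norm.ppf((np.arange(n) + 0.5) / n) * 2.0

    vals[25:450] = quantile_grid(425)  # TFBS-private block
    vals[450:875] = quantile_grid(425)  # functional-private block
    vals[875:] = quantile_grid(n_genes - 875)
    vals[:25] = 2.0
    if shift_what == "tfbs":
        vals[25:450] += 2.0
    matrix = FoldChangeMatrix(pd.DataFrame({"C0": vals}, index=genes))
    ov = OverlapResult(
        tfbs_name="T0",
        func_name="F0",
        overlap_genes=frozenset(overlap),
        universe_size=n_genes,
        tfbs_size=450,
        func_size=450,
        overlap_size=25,
        p_value=1e-20,
        q_value=1e-18,
        tf_label="TF0",
    )
    return [ov], matrix, {"T0": tf_genes}, {"F0": fn_genes}


class TestConditionScreen:
    def test_overlap_shift_activates_pair(self):
        overlaps, matrix, tg, fg = _screen_fixture("overlap")
        res = condition_screen(overlaps, matrix, tfbs_genes=tg, func_genes=fg)
        call = res.calls.iloc[0]
        assert bool(call["activated"])
        assert call["q_overlap"] <= 0.02
        assert call["q_tfbs"] > 0.05 and call["q_func"] > 0.05

    def test_parent_shift_does_not_activate(self):
        overlaps, matrix, tg, fg = _screen_fixture("tfbs")
        res = condition_screen(overlaps, matrix, tfbs_genes=tg, func_genes=fg)
        assert not bool(res.calls.iloc[0]["activated"])

    def test_stats_match_scalar_zscore(self):
        """The vectorised screen reproduces set_zscore for every role."""
        overlaps, matrix, tg, fg = _screen_fixture("overlap")
        res = condition_screen(overlaps, matrix, tfbs_genes=tg, func_genes=fg)
        col = matrix.data["C0"]
        for _, row in res.stats.iterrows():
            genes = {
                "tfbs": tg["T0"],
                "func": fg["F0"],
                "overlap": overlaps[0].overlap_genes,
            }[row["role"]]
            z_ref, p_ref = set_zscore(col, genes)
            assert row["z"] == pytest.approx(z_ref, abs=1e-9)
            assert row["p"] == pytest.approx(p_ref, abs=1e-9)

    def test_activation_implies_significant_overlap(self):
        overlaps, matrix, tg, fg = _screen_fixture("overlap")
        res = condition_screen(overlaps, matrix, tfbs_genes=tg, func_genes=fg)
        act = res.calls[res.calls["activated"]]
        assert (act["q_overlap"] <= res.q_sig).all()

    def test_null_condition_rarely_activates(self):
        activated = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 3000
            genes = [f"G{i:05d}" for i in range(n)]
            overlap = frozenset(genes[:25])
            tg = {"T0": frozenset(genes[:400])}
            fg = {"F0": overlap | frozenset(genes[400:775])}
            matrix = FoldChangeMatrix(
                pd.DataFrame({"C0": rng.normal(0, 1, n)}, index=genes)
            )
            ov = OverlapResult("T0", "F0", overlap, n, 400, 400, 25, 1e-9, 1e-8, "TF0")
            res = condition_screen([ov], matrix, tfbs_genes=tg, func_genes=fg)
            activated += int(res.calls["activated"].sum())
        assert activated <= 2  # ~0.4 expected at q<=0.02 over 20 null conditions

    def test_sparse_condition_skipped(self):
        overlaps, matrix, tg, fg = _screen_fixture("overlap")
        bad = matrix.data.copy()
        bad["C1"] = np.nan
        bad.loc[bad.index[0], "C1"] = 1.0  # single measured gene
        res = condition_screen(
            overlaps, FoldChangeMatrix(bad), tfbs_genes=tg, func_genes=fg
        )
        assert set(res.stats["condition"]) == {"C0"}

    def test_requires_overlaps(self, matrix_factory):
        with pytest.raises(ValueError):
            condition_screen([], matrix_factory(np.zeros((3, 1))), tfbs_genes={}, func_genes={})
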