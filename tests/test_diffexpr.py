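"""Differential-expression stage: AC test vs an independent oracle, BH vs a
step-up oracle, normalization arithmetic, selection criteria and clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from p53mirnet import (
    CountTable,
    SelectionCriteria,
    apply_selection_criteria,
    audic_claverie_pvalue,
    cluster_dems,
    differential_table,
    normalize,
)


def ac_oracle(x: int, y: int, N1: int, N2: int) -> float:
    """Independent tail construction via the negative-binomial identity:
    p(y|x) = NB(y; x+1, N1/(N1+N2)), so tails come from scipy's nbinom CDF."""
    q = N1 / (N1 + N2)
    lower = nbinom.cdf(y, x + 1, q)
    upper = nbinom.sf(y - 1, x + 1, q)  # exact survival fn, no cancellation
    return float(min(1.0, 2.0 * min(lower, upper)))


class TestAudicClaverie:
    def test_equals_nbinom_oracle_on_grid(self):
        """200-case grid agrees with the independent tail-summation oracle to 1e-10 relative."""
        cases = []
        for x in (0, 1, 2, 5, 10, 50, 200, 1000):
            for y in (0, 1, 3, 8, 20, 100, 500):
                for N1, N2 in ((10**6, 10**6), (10**6, 2 * 10**6),
                               (5 * 10**5, 10**6), (10**7, 3 * 10**6)):
                    cases.append((x, y, N1, N2))
        assert len(cases) >= 200
        for x, y, N1, N2 in cases:
            got = audic_claverie_pvalue(x, y, N1, N2)
            want = ac_oracle(x, y, N1, N2)
            assert got == pytest.approx(want, rel=1e-10), (x, y, N1, N2)

    def test_degenerate_and_bounds(self):
        assert audic_claverie_pvalue(0, 0, 10**6, 10**6) == 1.0
        with pytest.raises(ValueError):
            audic_claverie_pvalue(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            audic_claverie_pvalue(0, 0, 0, 10)

    @given(
        x=st.integers(0, 500), y=st.integers(0, 500),
        N1=st.integers(10**4, 10**7), N2=st.integers(10**4, 10**7),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, x, y, N1, N2):
        """Swapping (x, N1) with (y, N2) flips the tails into each other up to
        the point mass p(y|x), so the two-sided values differ by at most twice
        that mass (an exact consequence of I_{1-q}(b, a) = 1 - I_q(a, b))."""
        p1 = audic_claverie_pvalue(x, y, N1, N2)
        p2 = audic_claverie_pvalue(y, x, N2, N1)
        assert 0 < p1 <= 1
        if max(p1, p2) < 1e-300:  # both at the underflow floor
            return
        points = (nbinom.pmf(y, x + 1, N1 / (N1 + N2))
                  + nbinom.pmf(x, y + 1, N2 / (N1 + N2)))
        assert abs(p1 - p2) <= 2 * points + 1e-9 * max(p1, p2)

    def test_monotone_in_count_difference(self):
        """For fixed x and equal totals, p decreases as |y - x| grows."""
        x, N = 50, 10**6
        ps_up = [audic_claverie_pvalue(x, y, N, N) for y in range(x, x + 60, 5)]
        assert all(a >= b for a, b in zip(ps_up, ps_up[1:]))
        ps_down = [audic_claverie_pvalue(x, y, N, N) for y in range(x, 0, -5)]
        assert all(a >= b for a, b in zip(ps_down, ps_down[1:]))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up BH by explicit sort: q_(i) = min over j>=i of p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestDifferentialTable:
    def _table(self, counts: dict, totals: dict) -> CountTable:
        return CountTable(counts=pd.DataFrame(counts), totals=pd.Series(totals))

    def test_rpm_and_pseudocount(self):
        ct = self._table({"c": [50, 0], "t": [100, 80]},
                         {"c": 10_000_000, "t": 10_000_000})
        rpm = normalize(ct)
        assert rpm.loc[0, "c"] == pytest.approx(5.0)
        assert rpm.loc[1, "c"] == 0.0  # zero stays zero outside ratios
        df = differential_table(ct, "c", "t")
        # zero control count -> ratio uses the 0.01 RPM stand-in
        assert df.loc[1, "log2fc"] == pytest.approx(np.log2(8.0 / 0.01))

    def test_column_sums_match_assigned_fraction(self, rng):
        counts = rng.integers(0, 1000, size=(30, 2))
        totals = counts.sum(axis=0) + rng.integers(1000, 5000, size=2)
        ct = self._table({"a": counts[:, 0], "b": counts[:, 1]},
                         {"a": totals[0], "b": totals[1]})
        rpm = normalize(ct)
        for j, lib in enumerate(("a", "b")):
            assert rpm[lib].sum() == pytest.approx(1e6 * counts[:, j].sum() / totals[j])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            CountTable(counts=pd.DataFrame({"a": [1]}), totals=pd.Series({"a": 0}))

    def test_bh_equals_stepup_oracle(self, rng):
        for _ in range(5):
            p = rng.uniform(size=200)
            counts = rng.integers(0, 300, size=(200, 2))
            ct = self._table({"c": counts[:, 0], "t": counts[:, 1]},
                             {"c": 10**6, "t": 10**6})
            df = differential_table(ct, "c", "t")
            np.testing.assert_allclose(df["p_adjusted"], bh_oracle(df["p"].to_numpy()),
                                       rtol=1e-12)
            # independent random p-vector through the same oracle
            from statsmodels.stats.multitest import multipletests
            np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1],
                                       bh_oracle(p), rtol=1e-12)

    def test_single_mirna_adjustment_is_identity(self):
        ct = self._table({"c": [5], "t": [30]}, {"c": 10**6, "t": 10**6})
        df = differential_table(ct, "c", "t")
        assert df.loc[0, "p_adjusted"] == pytest.approx(df.loc[0, "p"])

    def test_null_type_one_error(self, rng):
        """No planted effect over 2000 miRNAs: raw p<0.05 within 3 binomial SDs of 0.05."""
        n = 2000
        lam = rng.poisson(300, size=n) + 1
        x = rng.poisson(lam)
        y = rng.poisson(lam)
        ct = self._table({"c": x, "t": y}, {"c": 10**7, "t": 10**7})
        df = differential_table(ct, "c", "t")
        frac = (df["p"] < 0.05).mean()
        sd = (0.05 * 0.95 / n) ** 0.5
        assert abs(frac - 0.05) < 3 * sd


class TestSelection:
    def _frames(self, rows):
        df = pd.DataFrame(rows, columns=["mirna", "l1", "p1", "l2", "p2"])
        r1 = df[["mirna", "l1", "p1"]].rename(columns={"l1": "log2fc", "p1": "p"})
        r2 = df[["mirna", "l2", "p2"]].rename(columns={"l2": "log2fc", "p2": "p"})
        return r1, r2

    def test_weak_fold_change_excluded(self):
        r1, r2 = self._frames([("m1", 0.9, 1e-5, 2.0, 1e-5)])
        assert len(apply_selection_criteria(r1, r2).table) == 0

    def test_nonsignificant_excluded(self):
        r1, r2 = self._frames([("m1", 2.0, 0.02, 2.0, 0.02)])
        assert len(apply_selection_criteria(r1, r2).table) == 0

    def test_conflicting_signs_logged_not_error(self):
        r1, r2 = self._frames([("m1", 2.0, 1e-5, -2.0, 1e-5)])
        dems = apply_selection_criteria(r1, r2)
        assert len(dems.table) == 0
        assert dems.excluded_conflicts == ["m1"]

    def test_count_criterion_uses_raw_counts(self):
        base = dict(rpm_control=1.0, rpm_treated=4.0)
        r1 = pd.DataFrame([dict(mirna="m1", log2fc=2.0, p=1e-5,
                                count_control=4, count_treated=9, **base)])
        r2 = pd.DataFrame([dict(mirna="m1", log2fc=2.0, p=1e-5,
                                count_control=2, count_treated=8, **base)])
        assert len(apply_selection_criteria(r1, r2).table) == 0  # never above 10
        r2.loc[0, "count_treated"] = 11
        assert len(apply_selection_criteria(r1, r2).table) == 1

    def test_replicate_swap_invariance(self, published_dems):
        r1, r2 = published_dems.replicate_frames()
        a = apply_selection_criteria(r1, r2).table.index
        b = apply_selection_criteria(r2, r1).table.index
        assert set(a) == set(b)

    def test_mismatched_universe_rejected(self):
        r1, _ = self._frames([("m1", 2.0, 1e-5, 2.0, 1e-5)])
        _, r2 = self._frames([("m2", 2.0, 1e-5, 2.0, 1e-5)])
        with pytest.raises(ValueError):
            apply_selection_criteria(r1, r2)


class TestClustering:
    def test_fixture_partition_matches_direction(self, published_dems):
        r1, r2 = published_dems.replicate_frames()
        dems = cluster_dems(apply_selection_criteria(r1, r2))
        up = dems.table[dems.table["direction"] == "up"]["cluster"]
        down = dems.table[dems.table["direction"] == "down"]["cluster"]
        assert set(up) == {1} and set(down) == {2}

    def test_identical_rows_share_cluster(self):
        t = pd.DataFrame(
            {"rep1_log2fc": [2.0, 2.0, -3.0], "rep2_log2fc": [2.1, 2.1, -2.9],
             "rep1_p": [1e-3] * 3, "rep2_p": [1e-3] * 3,
             "direction": ["up", "up", "down"]},
            index=pd.Index(["a", "b", "c"], name="mirna"),
        )
        from p53mirnet import DEMSet
        out = cluster_dems(DEMSet(table=t))
        assert out.table.loc["a", "cluster"] == out.table.loc["b", "cluster"]
        assert out.table.loc["a", "cluster"] != out.table.loc["c", "cluster"]

    def test_permutation_invariance(self, published_dems, rng):
        r1, r2 = published_dems.replicate_frames()
        dems = apply_selection_criteria(r1, r2)
        ref = cluster_dems(dems).table["cluster"]
        perm = rng.permutation(len(dems.table))
        from p53mirnet import DEMSet
        shuffled = DEMSet(table=dems.table.iloc[perm])
        got = cluster_dems(shuffled).table["cluster"]
        assert got.sort_index().equals(ref.sort_index())
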