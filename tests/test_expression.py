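"""FPKM/TMM, the DE stand-in, MA values, and the exact enrichment tests."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromintegrate.expression import (
    ContingencyTable2x2,
    binding_de_summary,
    bound_genes,
    ddct,
    de_test_standin,
    fisher_exact_2x2,
    fpkm,
    gene_mark_signal,
    hypergeom_overlap,
    ma_values,
    tmm_factors,
)
from chromintegrate.intervals import Gene, GenomeAnnotation, GenomicInterval, PeakSet
from chromintegrate.signal import SignalTrack
from chromintegrate.simulate import ExpressionMatrix


def make_matrix(data: dict, lengths=None, n_wt=None):
    """ExpressionMatrix from {sample: counts}; samples named wt_*/ko_*."""
    counts = pd.DataFrame(data)
    counts.index = [f"g{i}" for i in range(len(counts))]
    meta = []
    for name in counts.columns:
        genotype = "wt" if name.startswith("wt") else "ko"
        meta.append({"sample": name, "genotype": genotype,
                     "replicate": int(name[-1])})
    if lengths is None:
        lengths = pd.Series(1000.0, index=counts.index)
    else:
        lengths = pd.Series(lengths, index=counts.index, dtype=float)
    return ExpressionMatrix(counts, pd.DataFrame(meta), lengths)


class TestFpkm:
    def test_formula_worked_example(self):
        # 100 counts on a 1-kb gene in a 1e6 library -> FPKM 100
        mat = make_matrix({"wt_1": [100, 10**6 - 100]}, lengths=[1000, 1000])
        assert fpkm(mat).iloc[0, 0] == pytest.approx(100.0)

    def test_zero_count_zero_fpkm(self):
        mat = make_matrix({"wt_1": [0, 500]})
        assert fpkm(mat).iloc[0, 0] == 0.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(50)
        counts = rng.integers(0, 500, (20, 4))
        lengths = rng.integers(200, 5000, 20)
        mat = make_matrix(
            {f"wt_{j}": counts[:, j] for j in range(2)}
            | {f"ko_{j}": counts[:, j + 2] for j in range(2)},
            lengths=lengths,
        )
        out = fpkm(mat)
        for i in range(20):
            for j, col in enumerate(mat.counts.columns):
                expected = counts[i, j] * 1e9 / counts[:, j].sum() / lengths[i]
                assert out.iloc[i][col] == pytest.approx(expected)


class TestTmm:
    def test_identical_samples_unit_factors(self):
        mat = make_matrix({"wt_1": [10, 20, 30], "ko_1": [10, 20, 30]})
        np.testing.assert_allclose(tmm_factors(mat), [1.0, 1.0])

    def test_proportional_samples_unit_factors(self):
        mat = make_matrix({"wt_1": [10, 20, 30, 40], "ko_1": [20, 40, 60, 80]})
        np.testing.assert_allclose(tmm_factors(mat), [1.0, 1.0], atol=1e-12)

    def test_five_gene_hand_oracle(self):
        """One inflated gene; the survivors of the double trim all carry
        M = log2(1/3), so the factor pair is (sqrt(3), 1/sqrt(3)) and the
        TMM-effective library sizes become equal."""
        mat = make_matrix(
            {"wt_1": [100, 200, 300, 400, 1000],
             "ko_1": [100, 200, 300, 400, 5000]}
        )
        f = tmm_factors(mat)
        np.testing.assert_allclose(f, [math.sqrt(3), 1 / math.sqrt(3)], rtol=1e-9)
        eff = mat.counts.sum(axis=0) * f
        assert eff.iloc[0] == pytest.approx(eff.iloc[1])

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            tmm_factors(make_matrix({"wt_1": [1, 2, 3]}))


class TestDeTestStandin:
    def test_identical_genotypes_p_one_unchanged(self):
        mat = make_matrix(
            {"wt_1": [50, 500], "wt_2": [50, 500],
             "ko_1": [50, 500], "ko_2": [50, 500]}
        )
        out = de_test_standin(mat)
        assert (out.pvalue == 1.0).all()
        assert (out.status == "unchanged").all()

    def test_bh_adjustment_worked_example(self):
        # step-up rule on (0.01, 0.02, 0.03) gives (0.03, 0.03, 0.03)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def _matrix_with_fold(self, fold, n_background=60):
        rng = np.random.default_rng(51)
        base = rng.integers(200, 2000, n_background)
        data = {}
        for name in ("wt_1", "wt_2", "wt_3", "ko_1", "ko_2", "ko_3"):
            jitter = rng.normal(1.0, 0.02, n_background)
            col = np.round(base * jitter).astype(int)
            if name.startswith("ko"):
                col = np.concatenate([[int(1000 * fold)], col])
            else:
                col = np.concatenate([[1000], col])
            data[name] = col
        return make_matrix(data)

    def test_fold_change_gate_blocks_small_effects(self):
        out = de_test_standin(self._matrix_with_fold(1.4))
        assert out.loc["g0", "adj_pvalue"] < 0.05
        assert out.loc["g0", "status"] == "unchanged"

    def test_large_fold_change_called_up(self):
        out = de_test_standin(self._matrix_with_fold(3.0))
        assert out.loc["g0", "status"] == "up"

    def test_not_expressed_excluded_from_testing_universe(self):
        rng = np.random.default_rng(52)
        data = {}
        for name in ("wt_1", "wt_2", "ko_1", "ko_2"):
            col = rng.integers(500, 1500, 30)
            col[0] = 0  # gene g0 silent everywhere
            data[name] = col
        out = de_test_standin(make_matrix(data))
        assert out.loc["g0", "status"] == "not_expressed"
        assert np.isnan(out.loc["g0", "adj_pvalue"])

    def test_null_type_i_rate_quick(self):
        """No true differences: raw p < 0.05 for ~5% of genes (3 seeds)."""
        rates = []
        for seed in (60, 61, 62):
            rng = np.random.default_rng(seed)
            mu = rng.lognormal(5, 1, 300)
            data = {
                name: rng.poisson(mu)
                for name in ("wt_1", "wt_2", "wt_3", "ko_1", "ko_2", "ko_3")
            }
            out = de_test_standin(make_matrix(data))
            rates.append((out.pvalue < 0.05).mean())
        assert np.mean(rates) <= 0.07


class TestGeneMarkSignal:
    def _ann(self):
        genes = [Gene("gA", "chrT", "+", 3000, 5999, 3000),
                 Gene("gB", "chrT", "-", 9999, 8000, 2000)]
        return GenomeAnnotation({"chrT": 10_000}, genes)

    def test_uniform_track(self):
        tr = SignalTrack(50, {"chrT": np.full(200, 2.5)})
        sig = gene_mark_signal(tr, self._ann())
        assert sig["gA"] == pytest.approx(2.5)

    def test_edge_gene_window_clipped(self):
        # gB promoter window [7999, 11999) clips to [7999, 10000): the mean
        # is taken over the clipped window, so a uniform track stays uniform
        tr = SignalTrack(50, {"chrT": np.full(200, 4.0)})
        sig = gene_mark_signal(tr, self._ann())
        assert sig["gB"] == pytest.approx(4.0)

    def test_matches_window_mean_oracle(self):
        rng = np.random.default_rng(53)
        values = rng.random(200)
        tr = SignalTrack(50, {"chrT": values})
        sig = gene_mark_signal(tr, self._ann(), window="genebody")
        per_bp = np.repeat(values, 50)
        assert sig["gA"] == pytest.approx(per_bp[3000:6000].mean())


class TestMaValues:
    def test_equal_signal_zero_m(self):
        s = pd.Series({"g": 4.0})
        out = ma_values(s, s)
        assert out.loc["g", "M"] == 0.0

    def test_pseudocount_worked_example(self):
        out = ma_values(pd.Series({"g": 0.0}), pd.Series({"g": 3.0}), c=1.0)
        assert out.loc["g", "M"] == pytest.approx(2.0)  # log2(4/1)

    def test_matches_elementwise_oracle_and_rejects_negatives(self):
        rng = np.random.default_rng(54)
        wt = pd.Series(rng.random(20), index=[f"g{i}" for i in range(20)])
        ko = pd.Series(rng.random(20), index=wt.index)
        out = ma_values(wt, ko, c=0.5)
        np.testing.assert_allclose(out["M"], np.log2((ko + 0.5) / (wt + 0.5)))
        np.testing.assert_allclose(
            out["A"], 0.5 * (np.log2(ko + 0.5) + np.log2(wt + 0.5)))
        with pytest.raises(ValueError, match="negative"):
            ma_values(wt - 10, ko)


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration over all tables with the observed margins."""
    n1, k = a + b, a + c
    N = a + b + c + d
    n2 = N - n1
    lo, hi = max(0, k - n2), min(k, n1)
    denom = math.comb(N, k)
    probs = {
        x: Fraction(math.comb(n1, x) * math.comb(n2, k - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    def test_printed_counts_reproduce_published_p(self):
        _, p = fisher_exact_2x2(ContingencyTable2x2(382, 222, 263, 103))
        assert p == pytest.approx(0.0062, abs=5e-4)

    def test_identical_rows_p_one(self):
        _, p = fisher_exact_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert p == pytest.approx(1.0)

    def test_diagonal_enumeration_example(self):
        _, p = fisher_exact_2x2(ContingencyTable2x2(3, 0, 0, 3))
        assert p == pytest.approx(0.1)

    def test_zero_margin_convention(self):
        _, p = fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 3))
        assert p == 1.0

    def test_row_swap_invariance(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))[1]
            p2 = fisher_exact_2x2(ContingencyTable2x2(c, d, a, b))[1]
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_enumeration_and_scipy_on_random_tables(self):
        rng = np.random.default_rng(56)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))[1]
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)
            assert p == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestHypergeomOverlap:
    def test_zero_overlap_p_one(self):
        assert hypergeom_overlap(100, 10, 10, 0) == pytest.approx(1.0)

    def test_complete_overlap_worked_example(self):
        assert hypergeom_overlap(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeom_overlap(40, 15, 12, k) for k in range(0, 13)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_matches_literal_draw_enumeration(self):
        # N <= 12: enumerate every n-subset of the universe
        for N, K, n in [(8, 3, 4), (10, 5, 5), (12, 6, 3)]:
            hits = set(range(K))
            draws = list(itertools.combinations(range(N), n))
            for k in range(0, min(n, K) + 1):
                exact = sum(len(hits.intersection(d)) >= k for d in draws) / len(draws)
                assert hypergeom_overlap(N, K, n, k) == pytest.approx(exact)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 5, 5, 6)


class TestBindingDeSummary:
    def _de(self, statuses):
        return pd.DataFrame(
            {"status": statuses},
            index=[f"g{i}" for i in range(len(statuses))],
        )

    def test_twelve_gene_fixture_hand_table(self):
        statuses = ["up"] * 4 + ["down"] * 4 + ["unchanged"] * 4
        bound = pd.Series(
            [True, True, False, False,   # up: 2 bound
             True, True, True, False,    # down: 3 bound
             True, False, True, False],
            index=[f"g{i}" for i in range(12)],
        )
        table, fractions, (_, p) = binding_de_summary(self._de(statuses), bound)
        assert (table.a, table.b, table.c, table.d) == (2, 2, 3, 1)
        assert fractions["up_bound_fraction"] == 0.5
        assert fractions["down_bound_fraction"] == 0.75
        assert p == pytest.approx(fisher_oracle(2, 2, 3, 1))

    def test_all_bound_p_one(self):
        statuses = ["up"] * 3 + ["down"] * 3
        bound = pd.Series(True, index=[f"g{i}" for i in range(6)])
        table, fractions, (_, p) = binding_de_summary(self._de(statuses), bound)
        assert fractions == {"up_bound_fraction": 1.0, "down_bound_fraction": 1.0}
        assert p == 1.0

    def test_no_de_genes_error(self):
        with pytest.raises(ValueError, match="no differentially"):
            binding_de_summary(self._de(["unchanged"] * 3),
                               pd.Series(True, index=["g0", "g1", "g2"]))

    def test_bound_genes_promoter_window(self):
        genes = [Gene("gA", "chrT", "+", 5000, 7999, 3000)]
        ann = GenomeAnnotation({"chrT": 20_000}, genes)
        inside = PeakSet([GenomicInterval("chrT", 6900, 7100)])
        outside = PeakSet([GenomicInterval("chrT", 7100, 7300)])
        assert bound_genes(inside, ann).loc["gA"]
        assert not bound_genes(outside, ann).loc["gA"]


class TestDdct:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((20.0, 18.0, 21.0, 19.0), 1.0),   # ddCt = 0
            ((21.0, 18.0, 21.0, 19.0), 0.5),   # ddCt = 1
            ((19.0, 18.0, 22.0, 19.0), 4.0),   # ddCt = -2
        ],
    )
    def test_worked_examples(self, args, expected):
        assert ddct(*args) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct(float("nan"), 1.0, 2.0, 3.0)
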