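"""Fragment filtering, spike factors, coverage and profile matrices vs oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from chromintegrate.intervals import GenomicInterval, PeakSet
from chromintegrate.signal import (
    FragmentSet,
    SignalTrack,
    coverage_track,
    filter_fragments,
    mean_over_interval,
    profile_matrix,
    spike_scale_factors,
    write_bedgraph,
)
from chromintegrate.simulate import (
    FACTOR_BINDER,
    Library,
    SimulationConfig,
    generate_annotation,
    generate_truth,
    simulate_fragments,
)

LIB = Library("x", "wt", 1)


def frags(rows, lib=LIB):
    return FragmentSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "species"]), lib
    )


class TestFilterFragments:
    def test_strict_length_rule(self):
        fs = frags([("chrT", 0, 1999, "target"), ("chrT", 0, 2000, "target")])
        out = filter_fragments(fs)
        assert len(out) == 1
        assert out.df.iloc[0]["end"] == 1999

    def test_dedup_collapses_identical(self):
        fs = frags([("chrT", 5, 100, "target")] * 2 + [("chrT", 5, 101, "target")])
        assert len(filter_fragments(fs)) == 2
        assert len(filter_fragments(fs, dedup=False)) == 3

    def test_matches_list_comprehension_oracle(self):
        rng = np.random.default_rng(0)
        rows = [
            ("chrT", int(s), int(s + w), "target")
            for s, w in zip(rng.integers(0, 5000, 200), rng.integers(1, 3000, 200))
        ]
        out = filter_fragments(frags(rows), max_len=2000, dedup=True)
        expected = sorted({r for r in rows if r[2] - r[1] < 2000})
        got = sorted(map(tuple, out.df.to_records(index=False)))
        assert got == expected


class TestSpikeScaleFactors:
    def _sets(self, spike_counts):
        out = []
        for i, n in enumerate(spike_counts):
            rows = [("spike_chr1", j, j + 100, "spike") for j in range(n)]
            rows += [("chrT", 0, 100, "target")]
            out.append(frags(rows, Library("x", "wt", i + 1)))
        return out

    def test_min_reference_formula(self):
        norm = spike_scale_factors(self._sets([1000, 2000]))
        assert norm.factors[Library("x", "wt", 1)] == 1.0
        assert norm.factors[Library("x", "wt", 2)] == 0.5

    def test_single_library(self):
        norm = spike_scale_factors(self._sets([123]))
        assert norm.factors[Library("x", "wt", 1)] == 1.0

    def test_zero_spike_errors(self):
        with pytest.raises(ValueError, match="no spike-in"):
            spike_scale_factors(self._sets([100, 0]))

    def test_order_invariance_and_all_le_one(self):
        sets = self._sets([300, 150, 600])
        a = spike_scale_factors(sets).factors
        b = spike_scale_factors(sets[::-1]).factors
        assert a == b
        assert all(v <= 1.0 for v in a.values())
        assert min(a.values()) < 1.0 <= max(a.values())

    def test_recovers_true_scale_factors(self):
        """Libraries simulated at relative yields (1, 0.5, 0.25) are recovered
        within 5% relative error from their spike counts at depth 1e5."""
        cfg = SimulationConfig(seed=11, n_chroms=1, chrom_length=2_000_000,
                               n_genes=200, depth=100_000, n_replicates=3,
                               spike_in_fraction=0.1,
                               scale_factors=(1.0, 0.5, 0.25))
        ann = generate_annotation(cfg)
        truth = generate_truth(cfg, ann)
        libs = [Library(FACTOR_BINDER, "wt", r) for r in (1, 2, 3)]
        norm = spike_scale_factors(
            [simulate_fragments(cfg, truth, lib) for lib in libs]
        )
        for lib, expected in zip(libs, (1.0, 0.5, 0.25)):
            assert norm.factors[lib] == pytest.approx(expected, rel=0.05)


class TestCoverageTrack:
    SIZES = {"chrT": 10_000}

    def test_single_fragment_two_bins(self):
        fs = frags([("chrT", 0, 100, "target")])
        tr = coverage_track(fs, self.SIZES, bin_size=50, factor=0.5)
        assert tr.values["chrT"][0] == 0.5
        assert tr.values["chrT"][1] == 0.5
        assert tr.values["chrT"][2:].sum() == 0

    def test_empty_all_zero(self):
        tr = coverage_track(frags([]), self.SIZES, 50)
        assert tr.values["chrT"].sum() == 0

    def test_spike_excluded(self):
        fs = frags([("chrT", 0, 100, "spike")])
        assert coverage_track(fs, self.SIZES, 50).values["chrT"].sum() == 0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(1)
        rows = [
            ("chrT", int(s), int(s + w), "target")
            for s, w in zip(rng.integers(0, 9000, 300), rng.integers(1, 900, 300))
        ]
        bs = 50
        tr = coverage_track(frags(rows), self.SIZES, bs)
        # oracle: a fragment covers bin k iff it overlaps [k*bs, (k+1)*bs)
        expected = np.zeros(200)
        for _, s, e, _ in rows:
            for k in range(200):
                if s < (k + 1) * bs and k * bs < e:
                    expected[k] += 1
        np.testing.assert_allclose(tr.values["chrT"], expected)

    def test_additive_over_disjoint_fragment_sets(self):
        rng = np.random.default_rng(2)
        rows = [
            ("chrT", int(s), int(s + w), "target")
            for s, w in zip(rng.integers(0, 9000, 100), rng.integers(1, 500, 100))
        ]
        whole = coverage_track(frags(rows), self.SIZES, 50)
        part = (coverage_track(frags(rows[:40]), self.SIZES, 50)
                + coverage_track(frags(rows[40:]), self.SIZES, 50))
        np.testing.assert_allclose(whole.values["chrT"], part.values["chrT"])

    def test_bad_bin_size(self):
        with pytest.raises(ValueError):
            coverage_track(frags([]), self.SIZES, 0)


def make_track(values, bin_size=50, chrom="chrT"):
    return SignalTrack(bin_size, {chrom: np.asarray(values, dtype=float)})


class TestProfileMatrix:
    def test_uniform_track_all_ones(self):
        tr = make_track(np.ones(200))
        anchors = PeakSet([GenomicInterval("chrT", 4000, 5000)])
        mat = profile_matrix(tr, anchors, flank=1000, n_bins=10)
        np.testing.assert_allclose(mat, 1.0)

    def test_chrom_start_boundary_zeroed(self):
        tr = make_track(np.ones(200))
        anchors = PeakSet([GenomicInterval("chrT", 0, 100)])  # midpoint 50
        mat = profile_matrix(tr, anchors, flank=1000, n_bins=10)
        assert mat[0, 0] == 0.0          # [-950, -750): fully off-chromosome
        assert mat[0, -1] == 1.0

    def test_matches_hand_resampled_ramp(self):
        ramp = np.arange(100, dtype=float)
        tr = make_track(ramp, bin_size=50)
        rng = np.random.default_rng(3)
        anchors = PeakSet(
            [GenomicInterval("chrT", int(s), int(s) + 200)
             for s in rng.integers(500, 4000, 5)]
        )
        flank, n_bins = 500, 10  # out-bin width 100 = 2 track bins
        mat = profile_matrix(tr, anchors, flank, n_bins)
        for i, iv in enumerate(anchors):
            mid = (iv.start + iv.end) // 2
            for j in range(n_bins):
                x0 = mid - flank + j * 100
                per_bp = ramp[np.arange(x0, x0 + 100) // 50]
                assert mat[i, j] == pytest.approx(per_bp.mean())

    def test_empty_anchors_error(self):
        with pytest.raises(ValueError):
            profile_matrix(make_track(np.ones(10)), PeakSet(), 100, 4)


class TestMeanOverInterval:
    def test_simple_average(self):
        tr = make_track([1.0, 3.0], bin_size=50)
        assert mean_over_interval(tr, "chrT", 0, 100) == 2.0
        assert mean_over_interval(tr, "chrT", 25, 75) == 2.0

    def test_clipping_counts_outside_as_zero(self):
        tr = make_track([4.0], bin_size=50)
        assert mean_over_interval(tr, "chrT", -50, 50) == 2.0


def test_bedgraph_writer_round_numbers(tmp_path):
    tr = make_track([0.0, 2.0, 0.0, 1.5], bin_size=50)
    path = tmp_path / "t.bedgraph"
    write_bedgraph(tr, path, {"chrT": 180})
    lines = path.read_text().strip().splitlines()
    assert lines == ["chrT\t50\t100\t2", "chrT\t150\t180\t1.5"]


def test_normalized_ko_wt_ratio_recovers_gain(small_cfg):
    """Spike-normalized KO/WT mean repressive-mark signal over bound-gene
    promoters recovers the configured knockout gain fold within 10%."""
    from chromintegrate.simulate import MARK_REPRESSIVE, generate_truth
    from chromintegrate.expression import gene_mark_signal

    cfg = dataclasses.replace(small_cfg, depth=100_000)
    ann = generate_annotation(cfg)
    truth = generate_truth(cfg, ann)
    libs = [Library(MARK_REPRESSIVE, g, r) for g in ("wt", "ko") for r in (1, 2)]
    filtered = {l: filter_fragments(simulate_fragments(cfg, truth, l)) for l in libs}
    norm = spike_scale_factors(list(filtered.values()))
    tracks = {
        l: coverage_track(filtered[l], ann.chrom_sizes, 50, norm.factors[l])
        for l in libs
    }
    bound = [g for g in ann.genes if truth.bound_flags[g.gene_id]]
    means = {}
    for genotype in ("wt", "ko"):
        glibs = [l for l in libs if l.genotype == genotype]
        tr = tracks[glibs[0]] + tracks[glibs[1]]
        sig = gene_mark_signal(tr.scaled(0.5), ann)
        means[genotype] = sig.loc[[g.gene_id for g in bound]].mean()
    ratio = means["ko"] / means["wt"]
    assert ratio == pytest.approx(cfg.ko_h3k27me3_gain_fold, rel=0.10)
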