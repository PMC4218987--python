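import logging

import numpy as np
import pytest
from repliprof._errors import ConfigError, StageError
from repliprof.processing import (
    correct_cnv,
    count_reads_per_fragment,
    digest_genome,
    filter_experiments,
    filter_fragments,
    ratio_to_control,
    remove_length_bias,
    zscore_experiments,
)
from repliprof.synthetic import GenomeSpec, random_genome

from conftest import make_fragments, make_matrix


# ---------------------------------------------------------------------------
# digest_genome
# ---------------------------------------------------------------------------

class TestDigest:
    def test_worked_example(self, toy_genome_seq):
        frags = digest_genome(toy_genome_seq)
        assert list(map(tuple, frags.df[["start", "end"]].to_numpy())) == [
            (0, 2),
            (2, 8),
            (8, 14),
        ]

    def test_no_site_single_fragment(self):
        g = GenomeSpec((("c1", 10),), {"c1": "AAAAACCCCC"})
        frags = digest_genome(g)
        assert len(frags) == 1
        assert (frags.df.iloc[0]["start"], frags.df.iloc[0]["end"]) == (0, 10)

    def test_leading_empty_fragment_dropped(self):
        g = GenomeSpec((("c1", 8),), {"c1": "GATCGATC"})
        frags = digest_genome(g)
        assert list(map(tuple, frags.df[["start", "end"]].to_numpy())) == [(0, 4), (4, 8)]

    def test_case_insensitive(self):
        g = GenomeSpec((("c1", 8),), {"c1": "gatcGaTc"})
        assert len(digest_genome(g)) == 2

    def test_n_characters_never_match(self):
        g = GenomeSpec((("c1", 8),), {"c1": "GANCGNTC"})
        assert len(digest_genome(g)) == 1

    def test_overlapping_sites(self):
        g = GenomeSpec((("c1", 5),), {"c1": "AAAAA"})
        frags = digest_genome(g, site="AA")
        # overlapping matches at 0,1,2,3 -> cuts there; zero-length dropped
        assert frags.tiles_genome(g)

    def test_empty_site_rejected(self, toy_genome_seq):
        with pytest.raises(ConfigError):
            digest_genome(toy_genome_seq, site="")

    def test_requires_sequence(self, toy_genome):
        with pytest.raises(ConfigError):
            digest_genome(toy_genome)

    def test_tiling_on_random_genomes(self):
        g = random_genome((30_000, 20_000), seed=6)
        frags = digest_genome(g)
        assert frags.tiles_genome(g)
        for chrom, length in g.chromosomes:
            sub = frags.df[frags.df["chrom"] == chrom]
            assert sub["length"].sum() == length


# ---------------------------------------------------------------------------
# count_reads_per_fragment
# ---------------------------------------------------------------------------

class TestCountReads:
    def test_worked_example(self, tiling_fragments):
        counts, unassigned = count_reads_per_fragment(
            [("c1", 0), ("c1", 1), ("c1", 5)], tiling_fragments
        )
        assert counts.tolist() == [2, 1, 0]
        assert unassigned == 0

    def test_empty_stream(self, tiling_fragments):
        counts, unassigned = count_reads_per_fragment([], tiling_fragments)
        assert counts.tolist() == [0, 0, 0]
        assert unassigned == 0

    def test_half_open_boundary(self, tiling_fragments):
        counts, _ = count_reads_per_fragment([("c1", 2), ("c1", 8)], tiling_fragments)
        assert counts.tolist() == [0, 1, 1]

    def test_unknown_chromosome_unassigned(self, tiling_fragments):
        counts, unassigned = count_reads_per_fragment(
            [("cX", 3), ("c1", 3)], tiling_fragments
        )
        assert counts.sum() == 1
        assert unassigned == 1

    def test_position_in_gap_unassigned(self):
        frags = make_fragments([("c1", 0, 5), ("c1", 10, 20)])
        counts, unassigned = count_reads_per_fragment([("c1", 7)], frags)
        assert counts.sum() == 0
        assert unassigned == 1

    def test_read_conservation(self, rng, tiling_fragments):
        reads = [("c1", int(p)) for p in rng.integers(0, 20, 500)]
        counts, unassigned = count_reads_per_fragment(reads, tiling_fragments)
        assert counts.sum() + unassigned == 500


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestFilterFragments:
    def test_min_length_strict(self):
        frags = make_fragments([("c1", 0, 100), ("c1", 100, 250), ("c1", 250, 401)])
        m = make_matrix(np.ones((3, 2)), frags)
        out, report = filter_fragments(m, min_length=150, max_zero_experiments=10)
        assert out.values.index.tolist() == [1, 2]  # 100 bp removed; 150 and 151 kept
        assert report.removed["short_fragment"] == [0]

    def test_pervasive_zero_strict_more_than(self):
        frags = make_fragments([("c1", i * 200, (i + 1) * 200) for i in range(2)])
        vals = np.array([[0, 0, 0, 5], [0, 0, 3, 5]])  # zeros in 3 and 2 of 4 cols
        m = make_matrix(vals, frags)
        out, report = filter_fragments(m, min_length=1, max_zero_experiments=2)
        assert out.values.index.tolist() == [1]
        assert report.removed["pervasive_zero"] == [0]

    def test_blacklist(self):
        frags = make_fragments([("c1", i * 200, (i + 1) * 200) for i in range(3)])
        m = make_matrix(np.ones((3, 2)), frags)
        out, report = filter_fragments(m, min_length=1, max_zero_experiments=10, blacklist={1})
        assert out.values.index.tolist() == [0, 2]

    def test_noop_report_all_zeros(self):
        frags = make_fragments([("c1", i * 200, (i + 1) * 200) for i in range(3)])
        m = make_matrix(np.ones((3, 2)), frags)
        out, report = filter_fragments(m, min_length=150, max_zero_experiments=2)
        assert out.values.equals(m.values)
        assert all(len(v) == 0 for v in report.removed.values())

    def test_accounting_invariant(self, rng):
        frags = make_fragments(
            [("c1", s, s + l) for s, l in zip(range(0, 4000, 400), rng.integers(100, 300, 10))]
        )
        m = make_matrix(rng.poisson(2, (10, 4)), frags)
        out, report = filter_fragments(m, min_length=150, max_zero_experiments=2)
        assert report.retained == len(out.values)
        removed_union = set().union(*map(set, report.removed.values()))
        assert report.retained + len(removed_union) == report.input_size

    def test_all_removed_errors(self):
        frags = make_fragments([("c1", 0, 50)])
        m = make_matrix(np.ones((1, 2)), frags)
        with pytest.raises(StageError):
            filter_fragments(m, min_length=150, max_zero_experiments=10)

    def test_rule_commutation(self, rng):
        """Surviving row set equals intersection of per-rule survivors."""
        frags = make_fragments(
            [("c1", s, s + l) for s, l in zip(range(0, 4000, 400), rng.integers(100, 300, 10))]
        )
        m = make_matrix(rng.poisson(0.8, (10, 4)), frags)
        blacklist = {2, 7}
        try:
            out, _ = filter_fragments(m, 150, 1, blacklist)
        except StageError:
            return
        a = set(filter_fragments(m, 150, 10**9)[0].values.index) if True else None
        b = set(filter_fragments(m, 0, 1)[0].values.index)
        c = set(filter_fragments(m, 0, 10**9, blacklist)[0].values.index)
        assert set(out.values.index) == a & b & c


class TestFilterExperiments:
    def test_strict_fewer_than(self):
        frags = make_fragments([("c1", 0, 200)])
        m = make_matrix(np.array([[99_999, 100_000]]), frags)
        out, report = filter_experiments(m, min_reads=100_000)
        assert list(out.values.columns) == ["e1"]
        assert report.removed["low_depth"] == ["e0"]

    def test_zero_threshold_keeps_all(self):
        frags = make_fragments([("c1", 0, 200)])
        m = make_matrix(np.array([[0, 5]]), frags)
        out, _ = filter_experiments(m, min_reads=0)
        assert out.n_experiments == 2

    def test_single_survivor_valid(self):
        frags = make_fragments([("c1", 0, 200)])
        m = make_matrix(np.array([[10, 200_000]]), frags)
        out, _ = filter_experiments(m, min_reads=100_000)
        assert out.n_experiments == 1

    def test_all_removed_errors(self):
        frags = make_fragments([("c1", 0, 200)])
        m = make_matrix(np.array([[1, 2]]), frags)
        with pytest.raises(StageError):
            filter_experiments(m, min_reads=100_000)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestCorrectCnv:
    def test_doubled_chromosome_equalized(self, rng):
        rows = [("c1", i * 200, (i + 1) * 200) for i in range(10)] + [
            ("c2", i * 200, (i + 1) * 200) for i in range(10)
        ]
        frags = make_fragments(rows)
        base = rng.poisson(100, (20, 2)).astype(float)
        base[10:] *= 2  # duplicated chromosome
        m = make_matrix(base, frags)
        out = correct_cnv(m)
        chroms = out.row_fragments()["chrom"].to_numpy()
        for col in out.values.columns:
            med1 = np.median(out.values[col].to_numpy()[chroms == "c1"])
            med2 = np.median(out.values[col].to_numpy()[chroms == "c2"])
            assert med1 == pytest.approx(med2, rel=1e-9)

    def test_balanced_matrix_unchanged(self):
        rows = [("c1", i * 200, (i + 1) * 200) for i in range(4)] + [
            ("c2", i * 200, (i + 1) * 200) for i in range(4)
        ]
        frags = make_fragments(rows)
        m = make_matrix(np.full((8, 2), 7.0), frags)
        out = correct_cnv(m)
        assert np.allclose(out.values.to_numpy(), 7.0)

    def test_median_ratio_factors(self):
        rows = [("c1", i * 200, (i + 1) * 200) for i in range(3)] + [
            ("c2", i * 200, (i + 1) * 200) for i in range(3)
        ]
        frags = make_fragments(rows)
        m = make_matrix(np.array([[2.0], [2.0], [2.0], [6.0], [6.0], [6.0]]), frags)
        out = correct_cnv(m)
        v = out.values.iloc[:, 0].to_numpy()
        # factors 1 and 1/3 up to the shared global median scale
        assert v[0] / v[3] == pytest.approx(1.0)

    def test_zero_median_chromosome_untouched(self, caplog):
        rows = [("c1", i * 200, (i + 1) * 200) for i in range(3)] + [
            ("c2", i * 200, (i + 1) * 200) for i in range(3)
        ]
        frags = make_fragments(rows)
        m = make_matrix(np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]]), frags)
        with caplog.at_level(logging.WARNING):
            out = correct_cnv(m)
        assert np.allclose(out.values.iloc[3:, 0], 0.0)
        assert any("non-positive median" in r.message for r in caplog.records)


class TestZscore:
    def test_worked_example(self):
        frags = make_fragments([("c1", i * 200, (i + 1) * 200) for i in range(3)])
        m = make_matrix(np.array([[1.0], [2.0], [3.0]]), frags)
        out = zscore_experiments(m)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        assert np.allclose(out.values.iloc[:, 0].to_numpy(), expected)

    def test_idempotent(self, rng):
        frags = make_fragments([("c1", i * 200, (i + 1) * 200) for i in range(50)])
        m = make_matrix(rng.normal(5, 2, (50, 3)), frags)
        once = zscore_experiments(m)
        twice = zscore_experiments(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    def test_contract_mean_zero_std_one(self, rng):
        frags = make_fragments([("c1", i * 200, (i + 1) * 200) for i in range(40)])
        m = make_matrix(rng.poisson(50, (40, 4)).astype(float), frags)
        out = zscore_experiments(m)
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(out.values.std(axis=0, ddof=0) - 1) < 1e-9)

    def test_constant_column_error_names_experiment(self):
        frags = make_fragments([("c1", i * 200, (i + 1) * 200) for i in range(3)])
        m = make_matrix(np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]), frags)
        with pytest.raises(StageError, match="e1"):
            zscore_experiments(m)


class TestRemoveLengthBias:
    def _linear_fixture(self, rng, n=400, slope=0.01, noise=1.0):
        lengths = rng.integers(150, 1500, n)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        frags = make_fragments(
            [("c1", int(s), int(s + l)) for s, l in zip(starts, lengths)]
        )
        signal = slope * lengths + rng.normal(0, noise, n)
        return frags, make_matrix(signal[:, None], frags), lengths

    def test_linear_bias_removed(self, rng):
        frags, m, lengths = self._linear_fixture(rng)
        out = remove_length_bias(m)
        r = np.corrcoef(out.values.iloc[:, 0].to_numpy(), lengths)[0, 1]
        assert abs(r) < 0.05

    def test_length_independent_signal_preserved(self, rng):
        frags, m, lengths = self._linear_fixture(rng, slope=0.0, noise=1.0)
        out = remove_length_bias(m)
        # trend is ~constant; signal changed only slightly
        assert np.corrcoef(
            out.values.iloc[:, 0].to_numpy(), m.values.iloc[:, 0].to_numpy()
        )[0, 1] > 0.9

    def test_exact_line_zero_noise(self):
        # lengths linear in rank -> running mean reproduces the line exactly
        n = 200
        lengths = np.arange(150, 150 + 2 * n, 2)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        frags = make_fragments(
            [("c1", int(s), int(s + l)) for s, l in zip(starts, lengths)]
        )
        m = make_matrix((0.05 * lengths)[:, None].astype(float), frags)
        out = remove_length_bias(m, bandwidth=11)
        resid = out.values.iloc[:, 0].to_numpy() - out.values.iloc[:, 0].mean()
        interior = resid[10:-10]
        assert np.allclose(interior, 0.0, atol=1e-9)

    def test_bandwidth_shrunk_with_warning(self, rng, caplog):
        frags, m, _ = self._linear_fixture(rng, n=10)
        with caplog.at_level(logging.WARNING):
            remove_length_bias(m, bandwidth=100)
        assert any("shrinking" in r.message for r in caplog.records)

    def test_column_mean_preserved(self, rng):
        frags, m, _ = self._linear_fixture(rng)
        out = remove_length_bias(m)
        assert out.values.iloc[:, 0].mean() == pytest.approx(
            m.values.iloc[:, 0].mean(), rel=1e-9
        )


class TestRatioToControl:
    def _fixture(self, s_col, control_cols):
        n = len(s_col)
        frags = make_fragments([("c1", i * 200, (i + 1) * 200) for i in range(n)])
        vals = np.column_stack([s_col] + control_cols).astype(float)
        gates = ["S"] + ["G1G2"] * len(control_cols)
        return make_matrix(vals, frags, gates=gates)

    def test_scalar_division(self):
        m = self._fixture([4.0, 8.0, 6.0], [[2.0, 2.0, 2.0]])
        out = ratio_to_control(m, rezscore=False)
        assert np.allclose(out.values["e0"].to_numpy(), [2.0, 4.0, 3.0])

    def test_low_control_fragment_dropped(self, caplog):
        m = self._fixture([4.0, 8.0, 6.0], [[0.0, 2.0, 2.0], [0.0, 2.0, 2.0]])
        with caplog.at_level(logging.INFO):
            out = ratio_to_control(m, rezscore=False, floor_quantile=0.0)
        assert 0 not in out.values.index
        assert len(out.values) == 2
        assert np.isfinite(out.values.to_numpy()).all()

    def test_self_ratio_constant_column_flagged(self, caplog):
        # one S column identical to the single control: ratio == 1 everywhere
        m = self._fixture([2.0, 3.0, 4.0], [[2.0, 3.0, 4.0]])
        with pytest.raises(StageError):
            ratio_to_control(m, rezscore=False)

    def test_missing_control_column_error(self):
        m = self._fixture([1.0, 2.0, 3.0], [[1.0, 1.0, 1.0]])
        with pytest.raises(ConfigError):
            ratio_to_control(m, control_columns=["nope"])

    def test_no_controls_error(self):
        frags = make_fragments([("c1", 0, 200)])
        m = make_matrix(np.array([[1.0]]), frags, gates=["S"])
        with pytest.raises(ConfigError):
            ratio_to_control(m)

    def test_rezscore_output_normalized(self, rng):
        n = 50
        frags = make_fragments([("c1", i * 200, (i + 1) * 200) for i in range(n)])
        vals = np.column_stack(
            [rng.poisson(100, n), rng.poisson(100, n), rng.poisson(100, n)]
        ).astype(float)
        m = make_matrix(vals, frags, gates=["S", "G1G2", "G1G2"])
        out = ratio_to_control(m)
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(out.values.std(axis=0, ddof=0) - 1) < 1e-9)


class TestFragmentTableValidation:
    def test_overlap_rejected(self):
        with pytest.raises(ConfigError):
            make_fragments([("c1", 0, 100), ("c1", 50, 150)])

    def test_unsorted_rejected(self):
        with pytest.raises(ConfigError):
            make_fragments([("c1", 100, 200), ("c1", 0, 100)])

    def test_noncontiguous_chromosome_blocks_rejected(self):
        with pytest.raises(ConfigError):
            make_fragments([("c1", 0, 100), ("c2", 0, 100), ("c1", 100, 200)])

    def test_zero_length_rejected(self):
        with pytest.raises(ConfigError):
            make_fragments([("c1", 5, 5)])
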