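"""Per-locus depth averaging, k-mer mappability, window counts, log ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from smartmap.coverage import (
    average_depth_over_loci,
    bin_loci_by_score,
    count_high_signal_windows,
    depth_normalized_log_ratio,
    umap_like_score,
)


def _loci(*triples):
    return pd.DataFrame(
        [{"contig": c, "start0": s, "end": e} for c, s, e in triples]
    )


class TestAverageDepth:
    def test_constant_signal(self):
        dense = {"c": np.full(100, 5.0)}
        out = average_depth_over_loci(dense, _loci(("c", 10, 30)))
        assert out["mean"].tolist() == [5.0]

    def test_half_covered_locus(self):
        sig = np.zeros(100)
        sig[10:20] = 2.0
        out = average_depth_over_loci({"c": sig}, _loci(("c", 10, 30)))
        assert out["mean"].tolist() == [1.0]

    def test_overlapping_loci_each_get_own_mean(self):
        sig = np.zeros(100)
        sig[0:5] = 2.0
        out = average_depth_over_loci(
            {"c": sig}, _loci(("c", 0, 10), ("c", 5, 15))
        )
        assert out["mean"].tolist() == [1.0, 0.0]

    def test_matches_per_bp_loop_oracle(self):
        rng = np.random.default_rng(5)
        sig = rng.uniform(0, 3, size=500)
        loci = _loci(*[("c", int(s), int(s) + int(l))
                       for s, l in zip(rng.integers(0, 400, 30),
                                       rng.integers(1, 100, 30))])
        out = average_depth_over_loci({"c": sig}, loci)
        for row in out.itertuples(index=False):
            naive = sum(sig[b] for b in range(row.start0, row.end)) / (row.end - row.start0)
            assert row.mean == pytest.approx(naive, abs=1e-9)

    def test_unknown_contig_raises(self):
        with pytest.raises(KeyError):
            average_depth_over_loci({"c": np.zeros(10)}, _loci(("x", 0, 5)))


class TestMappability:
    def test_all_unique_kmers_score_one(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        k = 20
        kmers = [seq[i:i + k] for i in range(len(seq) - k + 1)]
        assert len(set(kmers)) == len(kmers)  # construction check
        scores = umap_like_score({"c": seq}, k=k)["c"]
        assert np.all(scores == 1.0)

    def test_tandem_duplication_interior_zero(self):
        rng = np.random.default_rng(1)
        u = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        k = 20
        scores = umap_like_score({"c": u + u}, k=k)["c"]
        # bases covered only by within-copy k-mers are fully non-unique
        assert np.all(scores[: len(u) - k + 1] == 0.0)
        assert np.all(scores[len(u) + k - 1:] == 0.0)

    def test_worked_example_two_nonunique_covering_kmers(self):
        """A base covered by 50 k-mers of which exactly 2 are duplicated
        elsewhere scores 48/50 = 0.96."""
        rng = np.random.default_rng(2)
        k = 50
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        b = 200  # covered by k-mers starting at 151..200
        dup1 = core[160:160 + k]
        dup2 = core[180:180 + k]
        spacer1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        spacer2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        genome = {"c": core + spacer1 + dup1 + spacer2 + dup2}
        # construction check: exactly two of the covering k-mers non-unique
        seq = genome["c"]
        all_kmers = [seq[i:i + k] for i in range(len(seq) - k + 1)]
        from collections import Counter
        counts = Counter(all_kmers)
        covering = [seq[s:s + k] for s in range(b - k + 1, b + 1)]
        assert sum(counts[km] > 1 for km in covering) == 2
        scores = umap_like_score(genome, k=k)["c"]
        assert scores[b] == pytest.approx(0.96)

    def test_short_contig_scores_zero(self):
        scores = umap_like_score({"tiny": "ACGT"}, k=50)["tiny"]
        assert scores.shape == (4,) and np.all(scores == 0.0)

    def test_scores_in_unit_interval_and_rename_invariant(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        s1 = umap_like_score({"a": seq}, k=15)["a"]
        s2 = umap_like_score({"z": seq}, k=15)["z"]
        assert np.array_equal(s1, s2)
        assert s1.min() >= 0.0 and s1.max() <= 1.0


class TestBinning:
    def test_single_bin_when_all_scores_one(self):
        t = pd.DataFrame({"score": [1.0, 1.0, 1.0]})
        out = bin_loci_by_score(t)
        assert len(out) == 1
        assert out["count"].tolist() == [3]
        assert out["bin_left"].iloc[0] == pytest.approx(0.99)

    def test_adjacent_bins(self):
        t = pd.DataFrame({"score": [0.005, 0.015]})
        out = bin_loci_by_score(t)
        assert out["bin_left"].tolist() == pytest.approx([0.0, 0.01])
        assert out["count"].tolist() == [1, 1]

    def test_median_within_bin(self):
        t = pd.DataFrame({"score": [0.5, 0.505, 0.509], "v": [1.0, 2.0, 3.0]})
        out = bin_loci_by_score(t, value_col="v")
        assert out["median"].tolist() == [2.0]


class TestWindows:
    def test_empty_track(self):
        counts = count_high_signal_windows({"c": np.zeros(1000)}, [10, 20])
        assert counts == {10.0: 0, 20.0: 0}

    def test_single_hot_window(self):
        sig = np.zeros(1000)
        sig[200:400] = 75.0
        counts = count_high_signal_windows({"c": sig}, [60, 70, 80, 90])
        assert [counts[t] for t in (60.0, 70.0, 80.0, 90.0)] == [1, 1, 0, 0]

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(8)
        sig = rng.uniform(0, 100, size=5000)
        counts = count_high_signal_windows({"c": sig}, list(range(0, 100, 10)))
        vals = [counts[float(t)] for t in range(0, 100, 10)]
        assert vals == sorted(vals, reverse=True)

    def test_partial_final_window_uses_true_length(self):
        sig = np.zeros(250)
        sig[200:250] = 100.0  # final 50 bp window, mean 100
        counts = count_high_signal_windows({"c": sig}, [50.0])
        assert counts[50.0] == 1


class TestLogRatios:
    def _table(self, values):
        df = _loci(*[("c", 10 * i, 10 * i + 10) for i in range(len(values))])
        df["mean"] = values
        return df

    def test_identical_tracks_all_zero(self):
        a = self._table([1.0, 2.0, 3.0])
        _, mean_abs, skipped = depth_normalized_log_ratio(a, a, 100, 100)
        assert mean_abs == 0.0 and skipped == 0

    def test_scaling_cancels(self):
        a = self._table([2.0, 4.0, 6.0])
        b = self._table([1.0, 2.0, 3.0])
        out, mean_abs, _ = depth_normalized_log_ratio(a, b, 200, 100)
        assert np.allclose(out["log_ratio"], 0.0, atol=1e-12)
        assert mean_abs == pytest.approx(0.0, abs=1e-12)

    def test_natural_log_value_and_base_choice(self):
        a = self._table([4.0])
        b = self._table([1.0])
        _, mean_abs, _ = depth_normalized_log_ratio(a, b, 10, 10)
        assert mean_abs == pytest.approx(math.log(4))
        _, mean_abs2, _ = depth_normalized_log_ratio(a, b, 10, 10, log_base=2)
        assert mean_abs2 == pytest.approx(2.0)

    def test_zero_loci_skipped_without_pseudocount(self):
        a = self._table([1.0, 0.0])
        b = self._table([1.0, 1.0])
        out, _, skipped = depth_normalized_log_ratio(a, b, 10, 10)
        assert skipped == 1
        assert np.isnan(out["log_ratio"].iloc[1])
        _, _, skipped_pc = depth_normalized_log_ratio(a, b, 10, 10, pseudocount=1e-7)
        assert skipped_pc == 0
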