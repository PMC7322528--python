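"""Signal-over-peak matrices, co-occupancy, and the co-bound partition."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mchron.chromstate import (
    SignalTrack,
    compare_groups,
    cooccupancy_fractions,
    mean_signal_matrix,
    nearest_gene_values,
    partition_cobound,
    read_bedgraph,
    regulatory_groups,
    write_bedgraph,
)
from mchron.intervals import GenomicInterval, Peak, TSSRecord


def P(c, s, e, pid):
    return Peak(GenomicInterval(c, s, e), pid)


def mean_signal_oracle(track, peak, chrom_len=10_000):
    per_bp = np.zeros(chrom_len)
    for (s, e), v in zip(track.intervals.get(peak.chrom, []), track.values.get(peak.chrom, [])):
        per_bp[s:e] = v
    return per_bp[peak.start : peak.end].mean()


class TestMeanSignal:
    def test_constant_and_halved_track(self):
        t = SignalTrack.from_records("m", [("c", 0, 1000, 2.0)])
        assert t.mean_over(GenomicInterval("c", 100, 300)) == 2.0
        t2 = SignalTrack.from_records("m", [("c", 0, 100, 0.0), ("c", 100, 200, 4.0)])
        assert t2.mean_over(GenomicInterval("c", 0, 200)) == 2.0

    def test_uncovered_bases_count_zero(self):
        t = SignalTrack.from_records("m", [("c", 0, 50, 3.0)])
        assert t.mean_over(GenomicInterval("c", 0, 150)) == pytest.approx(1.0)
        assert t.mean_over(GenomicInterval("chrZ", 0, 10)) == 0.0

    def test_matches_per_bp_oracle(self, rng):
        for trial in range(100):
            # random non-overlapping segments via sorted breakpoints
            bps = np.sort(rng.choice(10_000, size=20, replace=False))
            records = [
                ("c", int(s), int(e), float(rng.normal()))
                for s, e in zip(bps[::2], bps[1::2])
            ]
            track = SignalTrack.from_records("m", records)
            peaks = [
                P("c", int(s), int(s) + int(w), f"p{i}")
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 9_000, 15), rng.integers(1, 900, 15))
                )
            ]
            mat = mean_signal_matrix(peaks, [track])
            for p in peaks:
                assert mat.loc[p.peak_id, "m"] == pytest.approx(
                    mean_signal_oracle(track, p), abs=1e-9
                )

    def test_overlapping_track_rejected(self):
        with pytest.raises(ValueError):
            SignalTrack.from_records("m", [("c", 0, 100, 1.0), ("c", 50, 150, 2.0)])

    def test_bedgraph_round_trip(self, tmp_path):
        t = SignalTrack.from_records(
            "m", [("chr1", 0, 100, 1.5), ("chr1", 200, 300, 2.5), ("chr2", 0, 50, 0.25)]
        )
        f = tmp_path / "m.bedGraph"
        write_bedgraph(t, f)
        back = read_bedgraph(f, "m")
        for c in t.intervals:
            assert np.array_equal(t.intervals[c], back.intervals[c])
            assert np.array_equal(t.values[c], back.values[c])


class TestRegulatoryGroups:
    def test_two_archetypes_recovered(self):
        """Promoter-like (high K4me3) vs enhancer-like (high K4me1) split."""
        rng = np.random.default_rng(7)
        rows, truth = [], []
        for i in range(60):
            promoter_like = i < 30
            truth.append(int(promoter_like))
            k4me3 = 5.0 if promoter_like else 0.5
            k4me1 = 0.5 if promoter_like else 5.0
            rows.append(
                [k4me3 + rng.normal(0, 0.1), k4me1 + rng.normal(0, 0.1)]
            )
        mat = pd.DataFrame(rows, columns=["H3K4me3", "H3K4me1"],
                           index=[f"p{i}" for i in range(60)])
        groups, signatures = regulatory_groups(mat, k=2, seed=0)
        assert adjusted_rand_score(truth, groups.to_numpy()) == 1.0

    def test_k1_single_group(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 3)))
        groups, _ = regulatory_groups(mat, k=1, seed=0)
        assert set(groups) == {0}

    def test_duplicating_rows_keeps_centroids(self, rng):
        mat = pd.DataFrame(
            np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(4, 0.2, (15, 2))]),
            index=[f"p{i}" for i in range(30)],
        )
        dup = pd.concat([mat, mat.set_axis([f"q{i}" for i in range(30)])])
        g1, s1 = regulatory_groups(mat, k=2, seed=0)
        g2, s2 = regulatory_groups(dup, k=2, seed=0)
        # same centroids up to label order
        got = np.sort(s2.to_numpy().round(6), axis=0)
        want = np.sort(s1.to_numpy().round(6), axis=0)
        assert np.allclose(got, want, atol=1e-6)


class TestCooccupancy:
    def test_fractions(self):
        targets = [P("c", i * 100, i * 100 + 50, f"t{i}") for i in range(4)]
        sets = {
            "self": targets,
            "half": [GenomicInterval("c", 0, 60), GenomicInterval("c", 100, 160)],
            "none": [GenomicInterval("c", 5000, 5100)],
        }
        res = {r.factor: r.fraction for r in cooccupancy_fractions(targets, sets)}
        assert res == {"self": 1.0, "half": 0.5, "none": 0.0}

    def test_premerging_never_changes_fraction(self, rng):
        from mchron.intervals import merge_consensus

        for _ in range(30):
            targets = [
                P("c", int(s), int(s) + int(w), f"t{i}")
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 9000, 20), rng.integers(1, 400, 20))
                )
            ]
            factor = [
                P("c", int(s), int(s) + int(w), f"f{i}")
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 9000, 25), rng.integers(1, 400, 25))
                )
            ]
            merged = merge_consensus([factor], min_sets=1)
            raw = cooccupancy_fractions(targets, {"f": factor})[0].fraction
            pre = cooccupancy_fractions(targets, {"f": merged})[0].fraction
            assert raw == pre

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            cooccupancy_fractions([], {"f": [GenomicInterval("c", 0, 10)]})


class TestPartitionCobound:
    def test_disjoint_identical_and_counts(self):
        A = [P("c", i * 100, i * 100 + 50, f"a{i}") for i in range(10)]
        B_hit = [P("c", i * 100 + 25, i * 100 + 75, f"b{i}") for i in range(3)]
        B_miss = [P("c", 5000 + i * 100, 5000 + i * 100 + 50, f"bm{i}") for i in range(4)]
        parts = partition_cobound(A, B_hit + B_miss)
        assert len(parts["co_bound"]) == 3
        assert len(parts["A_only"]) == 7
        assert len(parts["B_only"]) == 4
        disjoint_A = partition_cobound(A, B_miss)
        assert disjoint_A["co_bound"] == []
        same = partition_cobound(A, A)
        assert len(same["co_bound"]) == len(A) and same["A_only"] == same["B_only"] == []

    def test_partition_covers_all_inputs(self, rng):
        for _ in range(50):
            A = [
                P("c", int(s), int(s) + int(w), f"a{i}")
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 9000, 30), rng.integers(1, 300, 30))
                )
            ]
            B = [
                P("c", int(s), int(s) + int(w), f"b{i}")
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 9000, 30), rng.integers(1, 300, 30))
                )
            ]
            parts = partition_cobound(A, B)
            ids = [p.peak_id for group in parts.values() for p in group]
            assert len(ids) == len(set(ids))  # disjoint
            # every A peak appears; every B peak is either B_only or co-represented
            a_ids = {p.peak_id for p in A}
            assert a_ids == {p.peak_id for p in parts["co_bound"] + parts["A_only"]}
            b_only = {p.peak_id for p in parts["B_only"]}
            covered_b = {
                p.peak_id
                for p in B
                if any(p.interval.overlap_bp(q.interval) >= 1 for q in A)
            }
            assert b_only == {p.peak_id for p in B} - covered_b


class TestCompareGroups:
    def test_identical_distributions(self, rng):
        vals = {f"a{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 40))}
        vals |= {f"b{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 40))}
        groups = {
            "g1": [P("c", i, i + 1, f"a{i}") for i in range(40)],
            "g2": [P("c", i, i + 1, f"b{i}") for i in range(40)],
        }
        p = compare_groups(vals, groups, "student_t").loc["g1", "g2"]
        assert p > 0.01

    def test_planted_shift_detected_by_rank_sum(self, rng):
        vals = {f"co{i}": float(v) for i, v in enumerate(rng.normal(2, 1, 100))}
        vals |= {f"a{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 100))}
        groups = {
            "co_bound": [P("c", i, i + 1, f"co{i}") for i in range(100)],
            "A_only": [P("c", i, i + 1, f"a{i}") for i in range(100)],
        }
        p = compare_groups(vals, groups, "wilcoxon_rank_sum").loc["co_bound", "A_only"]
        assert p < 1e-6

    def test_label_order_invariance(self, rng):
        vals = {f"x{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 30))}
        peaks = [P("c", i, i + 1, f"x{i}") for i in range(30)]
        g1 = {"a": peaks[:15], "b": peaks[15:]}
        g2 = {"b": peaks[15:], "a": peaks[:15]}
        assert compare_groups(vals, g1).equals(compare_groups(vals, g2))

    def test_degenerate_group_skipped(self, rng):
        vals = {"x0": 1.0}
        groups = {"tiny": [P("c", 0, 1, "x0")],
                  "ok": [P("c", i, i + 1, f"y{i}") for i in range(5)]}
        vals |= {f"y{i}": float(i) for i in range(5)}
        with pytest.warns(UserWarning):
            mat = compare_groups(vals, groups)
        assert list(mat.index) == ["ok"]


class TestNearestGeneValues:
    def test_values_attached_by_nearest_tss(self):
        tss = [TSSRecord("gA", "c", 1000), TSSRecord("gB", "c", 9000)]
        peaks = [P("c", 900, 1100, "near_a"), P("c", 8500, 8600, "near_b")]
        out = nearest_gene_values(peaks, tss, {"gA": 1.5, "gB": -2.0})
        assert out == {"near_a": 1.5, "near_b": -2.0}
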