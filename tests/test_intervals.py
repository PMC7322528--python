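"""Interval model, I/O round-trips, and peak geometry vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mchron.intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    TSSRecord,
    annotate_peak_category,
    assign_peaks_to_genes,
    extend_around_midpoint,
    merge_consensus,
    overlap_flags,
    read_intervals,
    write_bed6,
    write_narrowpeak,
)


def P(chrom, start, end, pid, strand=".", **kw):
    return Peak(GenomicInterval(chrom, start, end, strand), pid, **kw)


class TestInvariantsAndIO:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)
        with pytest.raises(ValueError):
            Peak(GenomicInterval("chr1", 100, 200), "p", summit=200)

    def test_bed6_field_mapping(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("chr1\t100\t200\tp1\t5\t+\n")
        (peak,) = read_intervals(f, "bed6")
        assert peak == P("chr1", 100, 200, "p1", "+", score=5.0)

    def test_narrowpeak_summit_offset(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t200\tp1\t0\t.\t7.5\t-1\t-1\t50\n")
        (peak,) = read_intervals(f, "narrowPeak")
        assert peak.summit == 150
        assert peak.score == 7.5

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("chr1\t100\t200\tp1\t0\t+\nchr1\tnope\t300\tp2\t0\t+\n")
        with pytest.raises(ValueError, match=":2:"):
            read_intervals(f, "bed6")

    def test_negative_coordinates_rejected(self, tmp_path):
        f = tmp_path / "a.bed"
        f.write_text("chr1\t-10\t200\tp1\t0\t+\n")
        with pytest.raises(ValueError):
            read_intervals(f, "bed6")

    @pytest.mark.parametrize("fmt", ["bed6", "narrowPeak"])
    def test_round_trip_identity(self, tmp_path, rng, fmt):
        peaks = []
        for i in range(30):
            start = int(rng.integers(0, 9000))
            end = start + int(rng.integers(50, 800))
            summit = int(rng.integers(start, end)) if fmt == "narrowPeak" else None
            peaks.append(
                Peak(
                    GenomicInterval("chr1", start, end, "+"),
                    f"p{i}",
                    summit=summit,
                    score=float(rng.integers(0, 100)),
                )
            )
        f = tmp_path / "x"
        (write_bed6 if fmt == "bed6" else write_narrowpeak)(peaks, f)
        back = read_intervals(f, fmt)
        if fmt == "bed6":
            assert [(p.chrom, p.start, p.end, p.peak_id, p.score) for p in back] == [
                (p.chrom, p.start, p.end, p.peak_id, p.score) for p in peaks
            ]
        else:
            assert back == peaks


class TestExtendAroundMidpoint:
    @pytest.mark.parametrize(
        "start,end,flank,expected",
        [
            (1000, 1200, 250, (850, 1350)),
            (0, 10, 250, (0, 255)),
            # odd width: midpoint floor((100+201)/2)=150, left edge clips at 0
            (100, 201, 250, (0, 400)),
        ],
    )
    def test_worked_examples(self, start, end, flank, expected):
        (out,) = extend_around_midpoint([P("chr1", start, end, "p")], flank)
        assert (out.start, out.end) == expected

    def test_rejects_nonpositive_flank(self):
        with pytest.raises(ValueError):
            extend_around_midpoint([P("chr1", 0, 10, "p")], 0)

    @given(
        start=st.integers(0, 10_000),
        width=st.integers(1, 2_000),
        flank=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_width_is_twice_flank_unless_clipped(self, start, width, flank):
        (out,) = extend_around_midpoint([P("c", start, start + width, "p")], flank)
        mid = (2 * start + width) // 2
        if mid - flank >= 0:
            assert out.width == 2 * flank
        else:
            assert out.start == 0 and out.end == mid + flank


def consensus_oracle(peak_sets, min_sets, chrom_len=10_000):
    """Per-basepair coverage counting (distinct sets per base)."""
    cov = np.zeros(chrom_len, dtype=int)
    for pset in peak_sets:
        hit = np.zeros(chrom_len, dtype=bool)
        for p in pset:
            hit[p.start : p.end] = True
        cov += hit
    keep = cov >= min_sets
    out = []
    i = 0
    while i < chrom_len:
        if keep[i]:
            j = i
            while j < chrom_len and keep[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


class TestMergeConsensus:
    def test_worked_example(self):
        sets = [
            [P("c", 100, 200, "a")],
            [P("c", 150, 250, "b")],
            [P("c", 400, 500, "c")],
        ]
        out = merge_consensus(sets, 2)
        assert [(iv.start, iv.end) for iv in out] == [(150, 200)]

    def test_identity_and_disjoint(self):
        a = [P("c", 10, 50, "a"), P("c", 100, 160, "b")]
        assert [(iv.start, iv.end) for iv in merge_consensus([a, a], 2)] == [
            (10, 50),
            (100, 160),
        ]
        b = [P("c", 300, 340, "x")]
        assert merge_consensus([a, b], 2) == []

    def test_min_sets_exceeds_inputs(self):
        with pytest.raises(ValueError):
            merge_consensus([[P("c", 0, 5, "a")]], 2)

    def test_matches_per_bp_oracle_on_random_instances(self, rng):
        for trial in range(120):
            n_sets = int(rng.integers(2, 6))
            sets = []
            for s in range(n_sets):
                peaks = []
                for i in range(int(rng.integers(1, 51))):
                    start = int(rng.integers(0, 9_900))
                    end = start + int(rng.integers(1, 400))
                    peaks.append(P("c", start, min(end, 10_000), f"s{s}p{i}"))
                sets.append(peaks)
            min_sets = int(rng.integers(1, n_sets + 1))
            got = [(iv.start, iv.end) for iv in merge_consensus(sets, min_sets)]
            assert got == consensus_oracle(sets, min_sets), (trial, min_sets)


class TestOverlapFlags:
    def test_fraction_half(self):
        A = [P("c", 0, 10, "a"), P("c", 20, 30, "b"), P("c", 40, 50, "x"),
             P("c", 60, 70, "y")]
        B = [GenomicInterval("c", 5, 25)]
        flags, frac = overlap_flags(A, B)
        assert frac == 0.5
        assert flags == {"a": True, "b": True, "x": False, "y": False}

    def test_self_overlap_is_total(self):
        A = [P("c", 0, 10, "a"), P("c", 20, 30, "b")]
        assert overlap_flags(A, A)[1] == 1.0

    def test_adjacent_half_open_do_not_overlap(self):
        flags, frac = overlap_flags([P("c", 100, 200, "a")], [GenomicInterval("c", 200, 300)])
        assert frac == 0.0

    def test_monotone_in_min_overlap(self, rng):
        A = [P("c", int(s), int(s) + int(w), f"p{i}")
             for i, (s, w) in enumerate(zip(rng.integers(0, 5000, 40), rng.integers(1, 300, 40)))]
        B = [GenomicInterval("c", int(s), int(s) + int(w))
             for s, w in zip(rng.integers(0, 5000, 40), rng.integers(1, 300, 40))]
        fracs = [overlap_flags(A, B, mo)[1] for mo in (100, 50, 10, 1)]
        assert fracs == sorted(fracs)

    def test_empty_A_errors(self):
        with pytest.raises(ValueError):
            overlap_flags([], [GenomicInterval("c", 0, 10)])


def nearest_tss_oracle(peaks, tss, window):
    """All-pairs O(n*m) nearest-TSS assignment."""
    out = {}
    for p in peaks:
        best = None
        for t in tss:
            if t.chrom != p.chrom:
                continue
            if p.start <= t.tss < p.end:
                d = 0
            else:
                d = min(abs(t.tss - p.start), abs(t.tss - (p.end - 1)))
            key = (d, t.gene_id)
            if best is None or key < best[0]:
                best = (key, t)
        if best is not None:
            d, t = best[0][0], best[1]
            out[p.peak_id] = (t.gene_id, "promoter" if d <= window else "distal", d)
    return out


class TestAssignPeaksToGenes:
    def test_worked_distances(self):
        tss = [TSSRecord("g1", "c", 5000)]
        links, _ = assign_peaks_to_genes(
            [P("c", 4900, 4950, "near"), P("c", 3000, 3400, "far")], tss
        )
        by_id = {l.peak_id: l for l in links}
        # distance measured to the nearest included base (4949), not the
        # exclusive end: 5000 - 4949 = 51
        assert by_id["near"].distance == 51 and by_id["near"].link_type == "promoter"
        assert by_id["far"].distance == 1601 and by_id["far"].link_type == "distal"

    def test_equidistant_tie_breaks_lexicographically(self):
        tss = [TSSRecord("gB", "c", 900), TSSRecord("gA", "c", 1300)]
        links, _ = assign_peaks_to_genes([P("c", 1000, 1200, "p")], tss)
        # distances: to gB = 100, to gA = 101 -> gB; make a true tie:
        tss = [TSSRecord("gB", "c", 900), TSSRecord("gA", "c", 1299)]
        links, _ = assign_peaks_to_genes([P("c", 1000, 1200, "p")], tss)
        assert links[0].gene_id == "gA"

    def test_promoter_peak_choice_is_closest(self):
        tss = [TSSRecord("g1", "c", 5000)]
        peaks = [P("c", 4000, 4200, "far"), P("c", 4800, 4900, "near")]
        _, promoter_peak = assign_peaks_to_genes(peaks, tss)
        assert promoter_peak == {"g1": "near"}

    def test_missing_chromosome_warns_and_skips(self):
        with pytest.warns(UserWarning):
            links, _ = assign_peaks_to_genes(
                [P("chrZ", 0, 100, "p")], [TSSRecord("g", "chr1", 50)]
            )
        assert links == []

    def test_matches_all_pairs_oracle_on_random_instances(self, rng):
        for trial in range(100):
            peaks = [
                P("c", int(s), int(s) + int(w), f"p{i}")
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 50_000, 200), rng.integers(1, 600, 200))
                )
            ]
            tss = [
                TSSRecord(f"g{j:02d}", "c", int(t))
                for j, t in enumerate(rng.integers(0, 50_000, 50))
            ]
            links, _ = assign_peaks_to_genes(peaks, tss, 1500)
            got = {l.peak_id: (l.gene_id, l.link_type, l.distance) for l in links}
            assert got == nearest_tss_oracle(peaks, tss, 1500), trial


class TestAnnotatePeakCategory:
    @pytest.fixture()
    def model(self):
        return GeneModel(
            tss=[TSSRecord("g1", "c", 10_000, "+")],
            gene_spans={"g1": GenomicInterval("c", 10_000, 16_000, "+")},
            exons={
                "g1": [
                    GenomicInterval("c", 10_000, 11_000, "+"),
                    GenomicInterval("c", 15_000, 16_000, "+"),
                ]
            },
        )

    def test_precedence_and_window(self, model):
        peaks = [
            P("c", 10_200, 10_400, "near_tss"),       # promoter (within 1 kb) and exonic
            P("c", 12_000, 12_300, "intronic"),       # in gene span, no exon
            P("c", 15_200, 15_400, "exonic"),         # exon, > 1 kb from TSS
            P("c", 30_000, 30_200, "intergenic"),
        ]
        cats = annotate_peak_category(peaks, model, promoter_window=1000)
        assert cats == {
            "near_tss": "promoter",
            "intronic": "intron",
            "exonic": "exon",
            "intergenic": "distal_intergenic",
        }
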