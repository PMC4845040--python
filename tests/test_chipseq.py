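import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xenoduct.annotation import PromoterWindow, TranscriptModel, promoter_windows
from xenoduct.chipseq import (
    Peak,
    distance_report,
    intersect_promoters,
    load_peaks,
    peak_center,
    unique_peaks,
)


def naive_unique(treated, control):
    """O(n*m) reference: half-open overlap of >= 1 base."""
    kept = []
    for p in treated:
        if not any(
            c.chrom == p.chrom and p.start < c.end and c.start < p.end
            for c in control
        ):
            kept.append(p)
    return kept


def naive_intersect(peaks, windows):
    """All-pairs scan; window covers 1-based [start, end], peak (start, end]."""
    hits = []
    for p in peaks:
        for w in windows:
            if w.chrom == p.chrom and p.start + 1 <= w.end and p.end >= w.start:
                hits.append((p, w))
    return hits


def _random_fixture(rng, n_peaks, n_windows):
    chroms = ["chr1", "chr2"]
    peaks = []
    for i in range(n_peaks):
        s = int(rng.integers(0, 50_000))
        peaks.append(
            Peak(chroms[int(rng.integers(2))], s, s + int(rng.integers(1, 800)), "t")
        )
    windows = []
    for i in range(n_windows):
        tss = int(rng.integers(2_500, 50_000))
        flank = int(rng.integers(100, 2_500))
        windows.append(
            PromoterWindow(
                f"TX{i}", f"G{i}", chroms[int(rng.integers(2))],
                "+" if rng.random() < 0.5 else "-",
                tss - flank, tss + flank, tss, flank,
            )
        )
    return peaks, windows


class TestLoadPeaks:
    def test_bed_parsing_sorting_and_rejects(self, tmp_path, caplog):
        bed = tmp_path / "p.bed"
        bed.write_text(
            "track name=x\n"
            "chr1\t500\t600\n"
            "chr1\t100\t200\tpk1\t37\t.\t1.5\n"  # narrowPeak-ish extras ignored
            "chr1\t300\t250\n"                    # end < start: rejected
        )
        with caplog.at_level("WARNING"):
            peaks = load_peaks(bed, "rifampin")
        assert [(p.start, p.end) for p in peaks] == [(100, 200), (500, 600)]
        assert peaks[0].score == 37.0
        assert "start >= end" in caplog.text


class TestUniquePeaks:
    def test_overlapping_peak_removed(self):
        treated = [Peak("c", 100, 200, "t"), Peak("c", 300, 400, "t"), Peak("c", 500, 600, "t")]
        control = [Peak("c", 350, 420, "v")]
        assert [(p.start, p.end) for p in unique_peaks(treated, control)] == [
            (100, 200), (500, 600),
        ]

    def test_empty_control_is_identity(self):
        treated = [Peak("c", 1, 5, "t")]
        assert unique_peaks(treated, []) == treated

    def test_book_ended_peak_retained(self):
        # half-open: [200,300) shares no base with [100,200)
        treated = [Peak("c", 200, 300, "t")]
        control = [Peak("c", 100, 200, "v")]
        assert unique_peaks(treated, control) == treated
        assert naive_unique(treated, control) == treated

    def test_idempotent_and_subset(self, rng):
        peaks, _ = _random_fixture(rng, 200, 0)
        control = [Peak(p.chrom, p.start + 50, p.end + 50, "v") for p in peaks[:80]]
        once = unique_peaks(peaks, control)
        assert set(once) <= set(peaks)
        assert unique_peaks(once, control) == once


class TestPeakCenter:
    @pytest.mark.parametrize(
        "start,end,expected", [(100, 200, 150.0), (100, 201, 150.5)]
    )
    def test_half_integral_center(self, start, end, expected):
        assert peak_center(Peak("c", start, end, "t")) == expected


class TestIntersectPromoters:
    def _window(self, tss, strand="+", flank=2000, chrom="chr1"):
        return PromoterWindow("TX", "G", chrom, strand, tss - flank, tss + flank, tss, flank)

    def test_center_beyond_flank_still_hits(self):
        w = self._window(10_000)
        hit = intersect_promoters([Peak("chr1", 11_899, 12_300, "t")], [w])
        assert len(hit) == 1
        assert hit[0].signed_distance == pytest.approx(2099.5)

    def test_peak_outside_window_no_hit(self):
        w = self._window(10_000)
        assert intersect_promoters([Peak("chr1", 20_000, 20_100, "t")], [w]) == []

    def test_stranded_distance_antisymmetric_under_strand_flip(self):
        peak = Peak("chr1", 10_500, 10_700, "t")
        plus = intersect_promoters([peak], [self._window(10_000, "+")])[0]
        minus = intersect_promoters([peak], [self._window(10_000, "-")])[0]
        assert plus.signed_distance == -minus.signed_distance

    def test_genomic_mode_ignores_strand(self):
        peak = Peak("chr1", 10_500, 10_700, "t")
        d = [
            intersect_promoters([peak], [self._window(10_000, s)], distance_mode="genomic")[0].signed_distance
            for s in "+-"
        ]
        assert d[0] == d[1] == pytest.approx(600.0)

    def test_chrom_style_mismatch_fatal(self):
        w = self._window(10_000, chrom="1")
        with pytest.raises(ValueError, match="chr"):
            intersect_promoters([Peak("chr1", 9_000, 9_100, "t")], [w])

    def test_matches_naive_scan_on_random_fixtures(self, rng):
        for _ in range(30):
            peaks, windows = _random_fixture(rng, int(rng.integers(5, 150)), int(rng.integers(1, 40)))
            got = intersect_promoters(peaks, windows)
            expected = naive_intersect(peaks, windows)
            assert len(got) == len(expected)
            assert {(h.peak, h.transcript_id) for h in got} == {
                (p, w.transcript_id) for p, w in expected
            }


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    t_start=st.integers(0, 1000),
    t_len=st.integers(1, 300),
    c_start=st.integers(0, 1000),
    c_len=st.integers(1, 300),
)
def test_uniqueness_agrees_with_naive_on_adversarial_pairs(t_start, t_len, c_start, c_len):
    treated = [Peak("c", t_start, t_start + t_len, "t")]
    control = [Peak("c", c_start, c_start + c_len, "v")]
    assert unique_peaks(treated, control) == naive_unique(treated, control)


class TestDistanceReport:
    def test_empty_hits_give_empty_table_with_header(self):
        per_gene, per_iso = distance_report([])
        assert per_gene.empty and "signed_distance" in per_gene.columns

    def test_representative_isoform_has_smallest_abs_distance(self):
        t1 = TranscriptModel("TXa", "G", "chr1", "+", 9_999, 20_000)   # tss 10000
        t2 = TranscriptModel("TXb", "G", "chr1", "+", 10_999, 21_000)  # tss 11000
        windows = promoter_windows([t1, t2])
        peaks = [Peak("chr1", 10_850, 10_950, "t")]  # center 10900
        per_gene, per_iso = distance_report(intersect_promoters(peaks, windows))
        assert len(per_iso) == 2 and len(per_gene) == 1
        assert per_gene.loc[0, "transcript_id"] == "TXb"  # |−100| < |900|
        assert per_gene.loc[0, "signed_distance"] == pytest.approx(-100.0)

    def test_one_row_per_hit_gene(self, rng):
        ts = [
            TranscriptModel(f"TX{i}", f"G{i}", "chr1", "+", 10_000 * i + 999, 10_000 * i + 5_000)
            for i in range(1, 4)
        ]
        windows = promoter_windows(ts)
        peaks = [Peak("chr1", w.tss - 50, w.tss + 50, "t") for w in windows]
        per_gene, _ = distance_report(intersect_promoters(peaks, windows))
        assert sorted(per_gene["gene_symbol"]) == ["G1", "G2", "G3"]
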