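"""Interval algebra: extension, subtraction, intersection, consensus, CTCF k-means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_overlap_mask, frame_key_set, random_peakset
from enhancerhub.intervals import (
    PeakSet,
    SignalMatrix,
    TssAnnotation,
    consensus_regions,
    ctcf_high_regions,
    extend_summits,
    intersect_overlapping,
    read_bed,
    subtract_overlapping,
    tss_windows,
    write_bed,
)


class TestExtendSummits:
    def test_summit_extension_gives_fixed_width(self):
        peaks = PeakSet.from_records("s", [("chr1", 800, 1500, None, None, 200)])
        out = extend_summits(peaks, flank=100)
        row = out.df.iloc[0]
        assert (row.start, row.end) == (900, 1100)
        assert row.end - row.start == 200

    def test_clipping_at_chromosome_start(self):
        peaks = PeakSet.from_records("s", [("chr1", 0, 100, None, None, 40)])
        out = extend_summits(peaks, flank=100)
        row = out.df.iloc[0]
        assert (row.start, row.end) == (0, 140)

    def test_all_widths_equal_two_flank_unless_clipped(self, rng):
        n = 500
        starts = rng.integers(0, 50_000, n)
        widths = rng.integers(50, 400, n)
        summits = rng.integers(0, 1, n) + widths // 2
        recs = [("chr1", int(s), int(s + w), None, None, int(m))
                for s, w, m in zip(starts, widths, summits)]
        out = extend_summits(PeakSet.from_records("s", recs), flank=100)
        widths_out = (out.df["end"] - out.df["start"]).to_numpy()
        clipped = out.df["start"].to_numpy() == 0
        assert (widths_out[~clipped] == 200).all()
        assert (widths_out[clipped] <= 200).all()

    def test_missing_summit_rejected(self):
        peaks = PeakSet.from_records("s", [("chr1", 0, 100)])
        with pytest.raises(ValueError, match="summit"):
            extend_summits(peaks, flank=100)


class TestTssWindows:
    def test_window_and_clamp(self):
        tss = TssAnnotation(pd.DataFrame(
            {"gene_id": ["g1", "g2"], "chrom": ["chr2", "chr2"],
             "position": [10_000, 1_000], "strand": ["+", "-"]}))
        out = tss_windows(tss, flank=2500)
        rows = {r.name: (r.start, r.end) for r in out.df.itertuples(index=False)}
        assert rows["g1"] == (7_500, 12_500)
        assert rows["g2"] == (0, 3_500)

    def test_widths(self, rng):
        pos = rng.integers(0, 100_000, 200)
        tss = TssAnnotation(pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(200)], "chrom": "chr1",
             "position": pos, "strand": "+"}))
        out = tss_windows(tss, flank=2500)
        widths = out.df["end"] - out.df["start"]
        clipped = out.df["start"] == 0
        assert (widths[~clipped] == 5000).all()


class TestSubtractIntersect:
    def test_one_bp_overlap_is_removed_or_selected(self):
        a = PeakSet.from_records("a", [("chr1", 900, 1100)])
        b = PeakSet.from_records("b", [("chr1", 1099, 1300)])
        assert len(subtract_overlapping(a, b)) == 0
        assert frame_key_set(intersect_overlapping(a, b)) == {("chr1", 900, 1100)}

    def test_empty_b_is_identity_for_subtract(self):
        a = PeakSet.from_records("a", [("chr1", 10, 20), ("chr2", 5, 9)])
        b = PeakSet.from_records("b", [])
        assert frame_key_set(subtract_overlapping(a, b)) == frame_key_set(a)
        assert len(intersect_overlapping(a, b)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_against_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peakset(rng, int(rng.integers(1, 400)), "a")
        b = random_peakset(rng, int(rng.integers(0, 400)), "b")
        oracle = brute_overlap_mask(a, b)
        assert frame_key_set(intersect_overlapping(a, b)) == frame_key_set(
            a.with_df(a.df[oracle])
        )
        assert frame_key_set(subtract_overlapping(a, b)) == frame_key_set(
            a.with_df(a.df[~oracle])
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_subtract_and_intersect_partition_a(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peakset(rng, 300, "a")
        b = random_peakset(rng, 200, "b")
        sub = subtract_overlapping(a, b)
        inter = intersect_overlapping(a, b)
        assert len(sub) + len(inter) == len(a)
        merged = pd.concat([sub.df, inter.df]).sort_values(
            ["chrom", "start", "end"], ignore_index=True
        )
        pd.testing.assert_frame_equal(merged, a.df)

    def test_outputs_stay_sorted(self, rng):
        a = random_peakset(rng, 200, "a")
        b = random_peakset(rng, 100, "b")
        for out in (subtract_overlapping(a, b), intersect_overlapping(a, b)):
            df = out.df
            assert df.equals(df.sort_values(["chrom", "start", "end"], ignore_index=True))


class TestConsensus:
    def test_retained_only_if_supported_everywhere(self):
        ref = PeakSet.from_records("ref", [("chr1", 100, 200), ("chr1", 500, 600)])
        others = [
            PeakSet.from_records(f"s{i}", [("chr1", 150, 160)]) for i in range(5)
        ]
        out = consensus_regions([ref] + others)
        assert frame_key_set(out) == {("chr1", 100, 200)}  # chr1:500-600 unsupported

    def test_unknown_reference_fails(self):
        sets = [PeakSet.from_records(s, [("chr1", 0, 10)]) for s in ("a", "b")]
        with pytest.raises(ValueError, match="reference"):
            consensus_regions(sets, reference="nope")

    @pytest.mark.parametrize("seed", range(5))
    def test_against_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = [random_peakset(rng, 150, f"s{i}") for i in range(4)]
        out = consensus_regions(sets, reference="s0")
        masks = [brute_overlap_mask(sets[0], s) for s in sets[1:]]
        expected = sets[0].with_df(sets[0].df[np.logical_and.reduce(masks)])
        assert frame_key_set(out) == frame_key_set(expected)


class TestCtcfHigh:
    @staticmethod
    def _planted(rng, n_high=200, n_low=200, n_samples=4, high_mean=100.0, low_mean=1.0):
        regions = pd.DataFrame(
            [("chr1", 1000 * i, 1000 * i + 200) for i in range(n_high + n_low)],
            columns=["chrom", "start", "end"],
        )
        values = np.vstack(
            [
                np.abs(rng.normal(high_mean, 5.0, (n_high, n_samples))),
                np.abs(rng.normal(low_mean, 0.3, (n_low, n_samples))),
            ]
        )
        return SignalMatrix(regions, [f"s{i}" for i in range(n_samples)], values)

    @staticmethod
    def _region_keys(df):
        return set(zip(df["chrom"], df["start"], df["end"]))

    def test_planted_high_cluster_recovered_exactly(self, rng):
        sig = self._planted(rng)
        out = ctcf_high_regions(sig, k=2, seed=0)
        assert frame_key_set(out) == self._region_keys(sig.regions.iloc[:200])

    def test_identical_rows_fail(self):
        regions = pd.DataFrame(
            [("chr1", 0, 10), ("chr1", 20, 30)], columns=["chrom", "start", "end"]
        )
        sig = SignalMatrix(regions, ["a", "b"], np.ones((2, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            ctcf_high_regions(sig, k=2, seed=0)

    def test_scale_and_row_order_invariance(self, rng):
        sig = self._planted(rng)
        base = frame_key_set(ctcf_high_regions(sig, k=2, seed=0))
        scaled = SignalMatrix(sig.regions, sig.samples, sig.values * 7.3)
        assert frame_key_set(ctcf_high_regions(scaled, k=2, seed=0)) == base
        perm = rng.permutation(len(sig.regions))
        shuffled = SignalMatrix(sig.regions.iloc[perm], sig.samples, sig.values[perm])
        assert frame_key_set(ctcf_high_regions(shuffled, k=2, seed=0)) == base

    def test_output_is_subset_partitioning_input(self, rng):
        sig = self._planted(rng, n_high=30, n_low=50)
        out = ctcf_high_regions(sig, k=2, seed=0)
        all_keys = self._region_keys(sig.regions)
        out_keys = frame_key_set(out)
        assert out_keys <= all_keys
        assert len(out_keys) + (len(all_keys) - len(out_keys)) == len(all_keys)


class TestBedIO:
    def test_roundtrip_and_narrowpeak_summit(self, tmp_path):
        p = tmp_path / "peaks.narrowPeak"
        p.write_text(
            "chr1\t100\t500\tpk1\t10\t.\t5.0\t-1\t-1\t150\n"
            "chr2\t0\t1\tsummit1\t3\t.\t1.0\t-1\t-1\t-1\n"
        )
        ps = read_bed(p, "s")
        by_name = {r.name: r for r in ps.df.itertuples(index=False)}
        assert by_name["pk1"].summit == 150
        assert by_name["summit1"].summit == 0  # 1-bp record: the base is the summit
        out = tmp_path / "out.bed"
        write_bed(ps, out)
        again = read_bed(out, "s2", summit_from_midpoint=False)
        assert frame_key_set(again) == frame_key_set(ps)


@given(
    start=st.integers(min_value=0, max_value=10_000),
    length=st.integers(min_value=1, max_value=1000),
    flank=st.integers(min_value=1, max_value=500),
)
@settings(max_examples=50, deadline=None)
def test_extension_width_property(start, length, flank):
    """Extended summit peaks always have width 2*flank unless left-clipped."""
    summit = length // 2
    ps = PeakSet.from_records("s", [("chr1", start, start + length, None, None, summit)])
    out = extend_summits(ps, flank)
    row = out.df.iloc[0]
    if start + summit >= flank:
        assert row.end - row.start == 2 * flank
    else:
        assert row.start == 0
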