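"""Loop catalogs: bedpe I/O, A2A filtering, depth normalization, intersection."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_overlap_mask, frame_key_set, random_peakset
from enhancerhub.intervals import PeakSet
from enhancerhub.loops import (
    EPITable,
    LoopSet,
    active_tss,
    filter_a2a_loops,
    intersect_epi_pairs,
    normalize_depth,
    read_bedpe,
    threshold_high_interactions,
    write_bedpe,
)


def make_loopset(sample_id, rows, depth=1_000_000):
    df = pd.DataFrame(
        rows, columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "contact_count"]
    )
    return LoopSet(sample_id, df, valid_pairs_depth=depth)


class TestBedpeIO:
    def test_roundtrip_preserves_fields(self, tmp_path):
        rows = [
            ("chr1", 0, 2500, "chr1", 50_000, 52_500, 7.0),
            ("chr1", 10_000, 12_500, "chr1", 90_000, 92_500, 3.0),
            ("chr2", 5_000, 7_500, "chr2", 40_000, 42_500, 12.0),
        ]
        ls = make_loopset("s", rows)
        p = tmp_path / "loops.bedpe"
        write_bedpe(ls, p)
        back = read_bedpe(p, depth=ls.valid_pairs_depth, sample_id="s")
        pd.testing.assert_frame_equal(
            back.df.sort_values(["chromA", "startA"], ignore_index=True),
            ls.df.sort_values(["chromA", "startA"], ignore_index=True),
        )
        assert back.valid_pairs_depth == 1_000_000

    def test_trans_and_short_cis_dropped_and_counted(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text(
            "chr1\t0\t2500\tchr2\t50000\t52500\t5\n"  # trans
            "chr1\t0\t2500\tchr1\t5000\t7500\t5\n"  # midpoints 6250 apart
            "chr1\t0\t2500\tchr1\t50000\t52500\t5\n"
        )
        ls = read_bedpe(p, depth=10)
        assert len(ls) == 1
        assert ls.dropped == {"trans": 1, "short_cis": 1}

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t0\t2500\tchr1\t50000\t52500\t5\nchr1\tnope\t2500\tchr1\t9\t10\t1\n")
        with pytest.raises(ValueError, match=":2"):
            read_bedpe(p, depth=10)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            make_loopset("s", [], depth=0)


class TestActiveTss:
    def test_examples(self):
        windows = PeakSet.from_records("tss", [("chr1", 0, 5000, "g1"), ("chr1", 20_000, 25_000, "g2")])
        k4 = PeakSet.from_records("k4", [("chr1", 4_000, 4_500)])
        out = active_tss(windows, k4)
        assert list(out.df["name"]) == ["g1"]
        empty = PeakSet.from_records("k4", [])
        assert len(active_tss(windows, empty)) == 0

    def test_against_oracle(self, rng):
        windows = random_peakset(rng, 200, "tss")
        k4 = random_peakset(rng, 150, "k4")
        out = active_tss(windows, k4)
        oracle = brute_overlap_mask(windows, k4)
        assert frame_key_set(out) == frame_key_set(windows.with_df(windows.df[oracle]))


def simple_epi_inputs():
    """One gene window, one enhancer, loops exercising both orientations."""
    windows = PeakSet.from_records("tss", [("chr1", 97_500, 102_500, "geneA")])
    enhancers = PeakSet.from_records("enh", [("chr1", 149_900, 150_100)])
    return windows, enhancers


class TestFilterA2A:
    def test_tss_to_enhancer_loop_yields_record(self):
        windows, enhancers = simple_epi_inputs()
        loops = make_loopset("s", [("chr1", 100_000, 102_500, "chr1", 147_500, 150_000, 7.0)])
        out = filter_a2a_loops(loops, windows, enhancers)
        assert len(out) == 1
        rec = out.df.iloc[0]
        assert rec.gene_id == "geneA"
        assert rec.enhancer_id == "chr1:149900-150100"
        assert rec.contact_count == 7.0

    def test_enhancer_enhancer_loop_excluded(self):
        windows, enhancers = simple_epi_inputs()
        loops = make_loopset("s", [("chr1", 147_500, 150_000, "chr1", 200_000, 202_500, 4.0)])
        out = filter_a2a_loops(loops, windows, enhancers)
        assert len(out) == 0
        assert loops.dropped["no_epi_match"] == 1

    def test_orientation_symmetry(self, rng):
        windows = PeakSet.from_records(
            "tss", [("chr1", i * 20_000, i * 20_000 + 5_000, f"g{i}") for i in range(10)]
        )
        enhancers = PeakSet.from_records(
            "enh", [("chr1", 7_000 + i * 20_000, 7_200 + i * 20_000) for i in range(10)]
        )
        rows = []
        for _ in range(60):
            gi, ei = rng.integers(0, 10), rng.integers(0, 10)
            a = ("chr1", gi * 20_000, gi * 20_000 + 2_500)
            b = ("chr1", 5_000 + ei * 20_000, 7_500 + ei * 20_000)
            if abs((a[1] + a[2]) / 2 - (b[1] + b[2]) / 2) < 10_000:
                continue
            rows.append((*a, *b, float(rng.integers(1, 50))))
        fwd = filter_a2a_loops(make_loopset("s", rows), windows, enhancers)
        swapped = [(r[3], r[4], r[5], r[0], r[1], r[2], r[6]) for r in rows]
        rev = filter_a2a_loops(make_loopset("s", swapped), windows, enhancers)
        pd.testing.assert_frame_equal(fwd.df, rev.df)

    def test_counts_summed_across_bin_pairs(self):
        windows, enhancers = simple_epi_inputs()
        loops = make_loopset(
            "s",
            [
                ("chr1", 97_500, 100_000, "chr1", 147_500, 150_000, 3.0),
                ("chr1", 100_000, 102_500, "chr1", 150_000, 152_500, 4.0),
            ],
        )
        out = filter_a2a_loops(loops, windows, enhancers)
        assert len(out) == 1
        assert out.df.iloc[0].contact_count == 7.0

    def test_count_conservation_when_anchors_match_one_feature(self):
        windows, enhancers = simple_epi_inputs()
        rows = [
            ("chr1", 100_000, 102_500, "chr1", 147_500, 150_000, 5.0),
            ("chr1", 300_000, 302_500, "chr1", 400_000, 402_500, 9.0),  # matches nothing
        ]
        loops = make_loopset("s", rows)
        out = filter_a2a_loops(loops, windows, enhancers)
        assert out.df["contact_count"].sum() <= loops.total_counts()
        assert out.df["contact_count"].sum() == 5.0


class TestNormalizeDepth:
    def test_factors_relative_to_deepest(self):
        a = make_loopset("A", [("chr1", 0, 2500, "chr1", 50_000, 52_500, 10.0)], depth=1_000_000)
        b = make_loopset("B", [("chr1", 0, 2500, "chr1", 50_000, 52_500, 20.0)], depth=2_000_000)
        na, nb = normalize_depth([a, b])
        assert na.norm_factor == 2.0
        assert nb.norm_factor == 1.0
        # proportional counts equalize at the shared loop
        assert na.df.iloc[0].contact_count == nb.df.iloc[0].contact_count == 20.0

    def test_single_sample_unchanged(self):
        a = make_loopset("A", [("chr1", 0, 2500, "chr1", 50_000, 52_500, 10.0)])
        (na,) = normalize_depth([a])
        assert na.norm_factor == 1.0
        assert na.df.iloc[0].contact_count == 10.0


class TestThreshold:
    def test_at_or_above_knee_kept(self):
        t = EPITable("s", pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "enhancer_id": ["e1", "e2", "e3"],
             "contact_count": [5.0, 3.0, 1.0]}))
        out = threshold_high_interactions(t, 3.0)
        assert sorted(out.df["contact_count"]) == [3.0, 5.0]

    def test_knee_below_all_is_identity(self):
        t = EPITable("s", pd.DataFrame(
            {"gene_id": ["g1"], "enhancer_id": ["e1"], "contact_count": [5.0]}))
        assert len(threshold_high_interactions(t, 0.5)) == 1

    def test_matches_brute_force_filter(self, rng):
        n = 200
        counts = rng.uniform(0.1, 100.0, n)
        t = EPITable("s", pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)],
             "enhancer_id": [f"e{i}" for i in range(n)],
             "contact_count": counts}))
        knee = 40.0
        out = threshold_high_interactions(t, knee)
        assert out.keys() == {
            (f"g{i}", f"e{i}") for i in range(n) if counts[i] >= knee
        }


def epi_from_keys(sample_id, keys, count=10.0):
    return EPITable(sample_id, pd.DataFrame(
        {"gene_id": [g for g, _ in keys], "enhancer_id": [e for _, e in keys],
         "contact_count": [count] * len(keys)}))


class TestIntersectPairs:
    def test_pair_must_be_in_every_table(self):
        shared = [("g1", "e1"), ("g2", "e2")]
        tables = [
            epi_from_keys("s1", shared + [("g3", "e3")]),
            epi_from_keys("s2", shared + [("g4", "e1")]),
            epi_from_keys("s3", shared),
            epi_from_keys("s4", shared),
        ]
        out = intersect_epi_pairs(tables)
        assert out.keys() == set(shared)

    def test_min_count_and_per_sample_columns(self):
        t1 = epi_from_keys("s1", [("g1", "e1")], count=10.0)
        t2 = epi_from_keys("s2", [("g1", "e1")], count=4.0)
        out = intersect_epi_pairs([t1, t2])
        rec = out.df.iloc[0]
        assert rec.contact_count == 4.0
        assert rec.count_s1 == 10.0 and rec.count_s2 == 4.0

    def test_disjoint_namespaces_fail(self):
        t1 = epi_from_keys("s1", [("g1", "eA")])
        t2 = epi_from_keys("s2", [("g1", "eB")])
        with pytest.raises(ValueError, match="namespace"):
            intersect_epi_pairs([t1, t2])

    def test_against_brute_force_key_intersection(self, rng):
        universe = [(f"g{i}", f"e{j}") for i in range(12) for j in range(12)]
        tables = []
        chosen = []
        for s in range(4):
            idx = rng.choice(len(universe), size=70, replace=False)
            keys = [universe[i] for i in idx]
            chosen.append(set(keys))
            tables.append(epi_from_keys(f"s{s}", keys))
        out = intersect_epi_pairs(tables)
        assert out.keys() == set.intersection(*chosen)

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            epi_from_keys("s", [("g1", "e1"), ("g1", "e1")])
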