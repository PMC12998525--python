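"""Chromatin-loop catalogs and enhancer-promoter interaction filtering.

Loops arrive as all-to-all bedpe files (two cis anchors per line plus a
contact count, 2.5 kb bins, >= 10 kb minimum cis distance) together with
a per-sample valid-pairs sequencing depth. The workflow implemented here:

1. read the bedpe catalog (trans and short-range lines are dropped and
   counted),
2. keep loops joining an active TSS window (H3K4me3-marked promoter) to
   a distal enhancer region — the "A2A filtering" step — yielding an
   enhancer-promoter interaction (EPI) table keyed by (gene, enhancer),
3. normalize contact counts to the deepest sample,
4. threshold at the knee point of the ranked count distribution,
5. intersect (gene, enhancer) keys across samples to retain the pairs
   present in every cell line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import PeakSet, intersect_overlapping

__all__ = [
    "LoopSet",
    "EPITable",
    "read_bedpe",
    "write_bedpe",
    "active_tss",
    "filter_a2a_loops",
    "normalize_depth",
    "threshold_high_interactions",
    "intersect_epi_pairs",
]

LOOP_COLUMNS = ["chromA", "startA", "endA", "chromB", "startB", "endB", "contact_count"]

EPI_COLUMNS = [
    "gene_id",
    "enhancer_id",
    "enh_chrom",
    "enh_start",
    "enh_end",
    "contact_count",
]


@dataclass
class LoopSet:
    """Cis anchor pairs with contact counts plus the library's valid-pairs depth."""

    sample_id: str
    df: pd.DataFrame = field(repr=False)
    valid_pairs_depth: int = 1
    #: multiplicative factor already applied to contact counts (1.0 = raw)
    norm_factor: float = 1.0
    #: lines dropped at parse time, keyed by reason
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.valid_pairs_depth <= 0:
            raise ValueError("valid_pairs_depth must be a positive integer")
        df = self.df.copy().reset_index(drop=True)
        missing = set(LOOP_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"LoopSet frame missing columns: {sorted(missing)}")
        if len(df) and (df["contact_count"] < 0).any():
            raise ValueError("negative contact count")
        self.df = df[LOOP_COLUMNS + [c for c in df.columns if c not in LOOP_COLUMNS]]

    def __len__(self) -> int:
        return len(self.df)

    def total_counts(self) -> float:
        return float(self.df["contact_count"].sum())


@dataclass
class EPITable:
    """Unique (gene, enhancer) interaction records for one sample."""

    sample_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy().reset_index(drop=True)
        missing = {"gene_id", "enhancer_id", "contact_count"} - set(df.columns)
        if missing:
            raise ValueError(f"EPITable frame missing columns: {sorted(missing)}")
        if df.duplicated(subset=["gene_id", "enhancer_id"]).any():
            raise ValueError("duplicate (gene_id, enhancer_id) keys in EPITable")
        if len(df) and (df["contact_count"] < 0).any():
            raise ValueError("negative contact count in EPITable")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> set[tuple[str, str]]:
        return set(zip(self.df["gene_id"], self.df["enhancer_id"]))


# ---------------------------------------------------------------------------
# bedpe I/O


def read_bedpe(
    path,
    depth: int,
    sample_id: str | None = None,
    count_column: int = 7,
    min_cis_distance: int = 10_000,
) -> LoopSet:
    """Parse a bedpe loop catalog.

    Parameters
    ----------
    path
        Tab-separated file: chromA startA endA chromB startB endB ... with
        a numeric contact-count column.
    depth
        The sample's deduplicated valid-pairs count (used later for
        cross-sample normalization).
    count_column
        1-based index of the contact-count column (default 7).
    min_cis_distance
        Minimum anchor-midpoint separation; closer pairs are dropped and
        counted, as are trans (different-chromosome) pairs.
    """
    path = str(path)
    rows = []
    dropped = {"trans": 0, "short_cis": 0}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < count_column:
                raise ValueError(
                    f"{path}:{ln}: expected >= {count_column} columns, got {len(parts)}"
                )
            try:
                ca, sa, ea = parts[0], int(parts[1]), int(parts[2])
                cb, sb, eb = parts[3], int(parts[4]), int(parts[5])
                count = float(parts[count_column - 1])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed bedpe line") from exc
            if ca != cb:
                dropped["trans"] += 1
                continue
            if abs((sa + ea) / 2 - (sb + eb) / 2) < min_cis_distance:
                dropped["short_cis"] += 1
                continue
            rows.append((ca, sa, ea, cb, sb, eb, count))
    df = pd.DataFrame(rows, columns=LOOP_COLUMNS)
    return LoopSet(sample_id or path, df, valid_pairs_depth=depth, dropped=dropped)


def write_bedpe(loops: LoopSet, path) -> None:
    df = loops.df[LOOP_COLUMNS]
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# filtering


def active_tss(tss_windows: PeakSet, h3k4me3: PeakSet) -> PeakSet:
    """TSS windows overlapping >= 1 H3K4me3 peak (active promoters)."""
    return intersect_overlapping(tss_windows, h3k4me3)


def _feature_trees(peaks: PeakSet, id_from_name: bool) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in peaks.df.itertuples(index=False):
        if id_from_name and row.name is not None:
            fid = str(row.name)
        else:
            fid = f"{row.chrom}:{row.start}-{row.end}"
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, (fid, row.chrom, row.start, row.end)
        )
    return trees


def enhancer_id(chrom: str, start: int, end: int) -> str:
    """Canonical coordinate-based identifier of a consensus enhancer."""
    return f"{chrom}:{start}-{end}"


def filter_a2a_loops(
    loops: LoopSet, active_tss_windows: PeakSet, enhancers: PeakSet
) -> EPITable:
    """Extract enhancer-promoter interactions from an all-to-all loop catalog.

    For every loop, each assignment of one anchor to an active TSS window
    (giving a gene) and the other to an enhancer region — in either
    orientation — yields a candidate (gene, enhancer) record. Counts for
    the same key across multiple bin pairs are summed; a loop matching
    the same key through both orientations contributes its count once.
    Loops matching neither pattern are excluded (their number is available
    as ``loops.dropped['no_epi_match']`` on the input LoopSet).
    """
    tss_trees = _feature_trees(active_tss_windows, id_from_name=True)
    enh_trees = _feature_trees(enhancers, id_from_name=False)

    agg: dict[tuple[str, str], float] = {}
    enh_coords: dict[str, tuple[str, int, int]] = {}
    n_unmatched = 0
    for row in loops.df.itertuples(index=False):
        anchors = ((row.chromA, row.startA, row.endA), (row.chromB, row.startB, row.endB))
        pairs = set()
        for (tc, ts, te), (ec, es, ee) in (anchors, anchors[::-1]):
            genes = tss_trees.get(tc, IntervalTree()).overlap(ts, te)
            if not genes:
                continue
            enhs = enh_trees.get(ec, IntervalTree()).overlap(es, ee)
            for g in genes:
                for e in enhs:
                    pairs.add((g.data[0], e.data))
        if not pairs:
            n_unmatched += 1
            continue
        for gene, (eid, echrom, estart, eend) in pairs:
            agg[(gene, eid)] = agg.get((gene, eid), 0.0) + row.contact_count
            enh_coords[eid] = (echrom, estart, eend)
    loops.dropped["no_epi_match"] = n_unmatched

    records = [
        (gene, eid, *enh_coords[eid], count) for (gene, eid), count in sorted(agg.items())
    ]
    df = pd.DataFrame(records, columns=EPI_COLUMNS)
    return EPITable(loops.sample_id, df)


def normalize_depth(loopsets: Sequence[LoopSet]) -> list[LoopSet]:
    """Scale each sample's counts by ``depth_max / depth_sample``.

    All samples are normalized to the sample with the highest valid-pairs
    depth, whose factor is exactly 1.0.
    """
    if not loopsets:
        raise ValueError("need at least one LoopSet")
    depths = [ls.valid_pairs_depth for ls in loopsets]
    if any(d <= 0 for d in depths):
        raise ValueError("zero or negative valid_pairs_depth")
    depth_max = max(depths)
    out = []
    for ls in loopsets:
        factor = depth_max / ls.valid_pairs_depth
        df = ls.df.copy()
        df["contact_count"] = df["contact_count"] * factor
        out.append(
            replace(ls, df=df, norm_factor=ls.norm_factor * factor, dropped=dict(ls.dropped))
        )
    return out


def threshold_high_interactions(table: EPITable, knee_value: float) -> EPITable:
    """Keep records with ``contact_count >= knee_value`` (highly interactive)."""
    if knee_value <= 0:
        raise ValueError("knee_value must be positive")
    return EPITable(table.sample_id, table.df[table.df["contact_count"] >= knee_value])


def intersect_epi_pairs(tables: Sequence[EPITable]) -> EPITable:
    """(gene, enhancer) keys present in every sample's EPI table.

    The consolidated contact count is the minimum across samples; the
    per-sample normalized counts are retained as ``count_<sample>``
    columns. Tables must share an enhancer namespace (ids from a common
    consensus peak set).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 EPI tables to intersect")
    namespaces = [set(t.df["enhancer_id"]) for t in tables]
    nonempty = [ns for ns in namespaces if ns]
    if len(nonempty) >= 2 and not set.intersection(*nonempty):
        ids = [t.sample_id for t in tables]
        raise ValueError(
            f"EPI tables {ids} have disjoint enhancer namespaces; "
            "enhancer ids must come from a shared consensus peak set"
        )
    keys = set.intersection(*(t.keys() for t in tables))
    base = tables[0].df
    kept = base[[k in keys for k in zip(base["gene_id"], base["enhancer_id"])]].copy()
    kept = kept.set_index(["gene_id", "enhancer_id"])
    counts = []
    for t in tables:
        s = t.df.set_index(["gene_id", "enhancer_id"])["contact_count"]
        counts.append(s.reindex(kept.index))
        kept[f"count_{t.sample_id}"] = s.reindex(kept.index)
    kept["contact_count"] = pd.concat(counts, axis=1).min(axis=1)
    kept = kept.reset_index().sort_values(["gene_id", "enhancer_id"], ignore_index=True)
    return EPITable("intersection", kept)
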