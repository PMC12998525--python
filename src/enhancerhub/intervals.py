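"""Genomic interval algebra on BED-style region sets.

All coordinates are 0-based, half-open (BED convention). Region sets are
kept sorted by (chrom, start, end) and every operation returns a sorted
set again. The overlap criterion throughout is >= 1 bp, matching default
bedtools semantics; "subtract" removes whole intervals rather than
clipping bases, because peaks are treated as atomic regulatory elements.

The operations here build the distal-open-active (DOA) cascade used to
nominate enhancer candidates: ATAC summits are extended to fixed-width
peaks, promoter windows around annotated TSS are removed, the remainder
is intersected with H3K27ac peaks, CTCF-high structural regions are
subtracted, and finally a multi-sample consensus keeps regions supported
by every cell line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakSet",
    "SignalMatrix",
    "TssAnnotation",
    "extend_summits",
    "tss_windows",
    "subtract_overlapping",
    "intersect_overlapping",
    "consensus_regions",
    "ctcf_high_regions",
    "read_bed",
    "write_bed",
    "read_tss",
]

#: canonical column order of the interval frame inside a PeakSet
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "summit"]


def _as_interval_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a frame to the canonical BED columns, adding missing optionals."""
    df = df.copy()
    for col, default in (("name", None), ("score", np.nan), ("summit", np.nan)):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df[BED_COLUMNS]


@dataclass
class PeakSet:
    """A per-sample, sorted collection of genomic intervals.

    Parameters
    ----------
    sample_id
        Label of the sample (cell line) the peaks belong to.
    df
        Frame with columns ``chrom, start, end`` and optional
        ``name, score, summit``; ``summit`` is an offset from ``start``.
    """

    sample_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = _as_interval_frame(self.df)
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate in PeakSet")
            if (df["start"] >= df["end"]).any():
                raise ValueError("interval with start >= end in PeakSet")
            s = df["summit"]
            bad = s.notna() & ((s < 0) | (s >= df["end"] - df["start"]))
            if bad.any():
                raise ValueError("summit offset outside its interval")
            neg_score = df["score"].notna() & (df["score"] < 0)
            if neg_score.any():
                raise ValueError("negative score in PeakSet")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort", ignore_index=True)
        object.__setattr__(self, "df", df)

    @classmethod
    def from_records(cls, sample_id: str, records: Iterable[tuple]) -> "PeakSet":
        """Build from ``(chrom, start, end[, name[, score[, summit]]])`` tuples."""
        rows = [list(r) + [None] * (6 - len(r)) for r in records]
        df = pd.DataFrame(rows, columns=BED_COLUMNS)
        return cls(sample_id, df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    def with_df(self, df: pd.DataFrame) -> "PeakSet":
        return PeakSet(self.sample_id, df)


@dataclass
class TssAnnotation:
    """TSS records: one or more ``(gene_id, chrom, position, strand)`` rows."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = {"gene_id", "chrom", "position", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"TssAnnotation missing columns: {sorted(missing)}")
        df["position"] = df["position"].astype(np.int64)
        if len(df):
            if (df["position"] < 0).any():
                raise ValueError("negative TSS position")
            if not df["strand"].isin(["+", "-"]).all():
                raise ValueError("strand must be '+' or '-'")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SignalMatrix:
    """Per-region, per-sample nonnegative signal (e.g. CTCF occupancy).

    Unlike :class:`PeakSet`, the regions frame keeps its given row order
    so that rows stay aligned with the value matrix.
    """

    regions: pd.DataFrame  # columns chrom, start, end, one row per region
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        regions = self.regions.reset_index(drop=True)
        missing = {"chrom", "start", "end"} - set(regions.columns)
        if missing:
            raise ValueError(f"SignalMatrix regions missing columns: {sorted(missing)}")
        if len(regions):
            if (regions["start"] < 0).any() or (regions["start"] >= regions["end"]).any():
                raise ValueError("invalid region coordinates in SignalMatrix")
        self.regions = regions
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(regions), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(regions)} regions, {len(self.samples)} samples)"
            )
        if (self.values < 0).any():
            raise ValueError("SignalMatrix values must be nonnegative")


# ---------------------------------------------------------------------------
# overlap machinery


def _overlap_mask(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each interval of `a` overlap (>=1 bp) any of `b`?

    Uses, per chromosome, a searchsorted on b starts plus a prefix max of
    b ends: interval (s, e) overlaps some b iff among b-intervals with
    start < e there is one with end > s.
    """
    out = np.zeros(len(a), dtype=bool)
    if not len(a) or not len(b):
        return out
    b_by_chrom = {c: g for c, g in b.groupby("chrom", sort=False)}
    for chrom, ga in a.groupby("chrom", sort=False):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        b_starts = gb["start"].to_numpy()
        b_end_prefix_max = np.maximum.accumulate(gb["end"].to_numpy())
        idx = np.searchsorted(b_starts, ga["end"].to_numpy(), side="left")
        has_candidate = idx > 0
        hit = np.zeros(len(ga), dtype=bool)
        hit[has_candidate] = (
            b_end_prefix_max[idx[has_candidate] - 1] > ga["start"].to_numpy()[has_candidate]
        )
        out[ga.index.to_numpy()] = hit
    return out


# ---------------------------------------------------------------------------
# operations


def extend_summits(peaks: PeakSet, flank: int) -> PeakSet:
    """Fixed-width peaks around summits: ``[summit - flank, summit + flank)``.

    Every interval must carry a summit offset; the left edge is clipped at
    the chromosome start (0). Use ``flank=100`` for the 200 bp ATAC/CTCF
    peaks of the discovery cascade.
    """
    if flank <= 0:
        raise ValueError("flank must be a positive number of bp")
    df = peaks.df
    if df["summit"].isna().any():
        n_missing = int(df["summit"].isna().sum())
        raise ValueError(
            f"{n_missing} interval(s) without a summit in sample "
            f"{peaks.sample_id!r}; extend_summits requires summit offsets"
        )
    abs_summit = df["start"].to_numpy() + df["summit"].to_numpy().astype(np.int64)
    start = np.maximum(abs_summit - flank, 0)
    end = abs_summit + flank
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "name": df["name"].to_numpy(),
            "score": df["score"].to_numpy(),
            "summit": abs_summit - start,
        }
    )
    return PeakSet(peaks.sample_id, out)


def tss_windows(tss: TssAnnotation, flank: int = 2500) -> PeakSet:
    """Promoter windows ``[pos - flank, pos + flank)`` carrying gene ids.

    The default of 2500 bp per side (5 kb total) spans one 2.5 kb HiChIP
    bin on either side of the TSS.
    """
    if flank <= 0:
        raise ValueError("flank must be a positive number of bp")
    df = tss.df
    start = np.maximum(df["position"].to_numpy() - flank, 0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": start,
            "end": df["position"].to_numpy() + flank,
            "name": df["gene_id"].to_numpy(),
        }
    )
    return PeakSet("tss", out)


def subtract_overlapping(a: PeakSet, b: PeakSet) -> PeakSet:
    """Intervals of `a` with zero bp of overlap against every interval of `b`.

    Whole-interval exclusion (bedtools ``intersect -v``), not base clipping.
    """
    mask = _overlap_mask(a.df, b.df)
    return a.with_df(a.df[~mask])


def intersect_overlapping(a: PeakSet, b: PeakSet) -> PeakSet:
    """Intervals of `a` overlapping (>= 1 bp) at least one interval of `b`.

    `a`'s coordinates are preserved: this is selection (bedtools
    ``intersect -u``), not clipping.
    """
    mask = _overlap_mask(a.df, b.df)
    return a.with_df(a.df[mask])


def consensus_regions(sets: Sequence[PeakSet], reference: str | None = None) -> PeakSet:
    """Reference intervals supported (>= 1 bp overlap) by every other set.

    Parameters
    ----------
    sets
        Two or more per-sample peak sets.
    reference
        ``sample_id`` of the set whose coordinates anchor the consensus;
        defaults to the first set.
    """
    if len(sets) < 2:
        raise ValueError("consensus_regions needs at least 2 peak sets")
    if reference is None:
        ref = sets[0]
    else:
        matches = [s for s in sets if s.sample_id == reference]
        if not matches:
            known = [s.sample_id for s in sets]
            raise ValueError(f"reference sample {reference!r} not among {known}")
        ref = matches[0]
    mask = np.ones(len(ref.df), dtype=bool)
    for other in sets:
        if other is ref:
            continue
        mask &= _overlap_mask(ref.df, other.df)
    return ref.with_df(ref.df[mask])


def ctcf_high_regions(signal: SignalMatrix, k: int = 2, seed: int = 0) -> PeakSet:
    """Regions of the k-means cluster with the highest mean signal.

    Clusters the per-region signal vectors into `k` groups (seeded
    k-means++, 10 restarts) and returns the regions of the cluster whose
    centroid has the largest mean across samples — the "CTCF-high"
    structural regions to be subtracted from DOA candidates.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    if len(signal.regions) < 2:
        raise ValueError("need at least 2 regions to cluster")
    n_distinct = len(np.unique(signal.values, axis=0))
    if n_distinct < k:
        raise ValueError(
            f"degenerate clustering: only {n_distinct} distinct signal rows "
            f"for k={k} clusters"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(signal.values)
    high_cluster = int(np.argmax(km.cluster_centers_.mean(axis=1)))
    keep = labels == high_cluster
    return PeakSet("ctcf_high", signal.regions[keep])


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(
    path,
    sample_id: str | None = None,
    summit_from_midpoint: bool = False,
) -> PeakSet:
    """Read BED3/BED6, MACS summit BED, or narrowPeak into a PeakSet.

    narrowPeak (10 columns) summit offsets are taken from column 10
    (-1 meaning absent). One-bp records (MACS ``*_summits.bed``) get
    ``summit = 0`` so the record's base is the summit. With
    ``summit_from_midpoint=True``, summit-less wider intervals get their
    midpoint as a summit surrogate; otherwise they stay summit-less and
    :func:`extend_summits` will reject them.
    """
    path = str(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = np.nan
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            summit = np.nan
            if len(parts) >= 10:  # narrowPeak: col 10 is the summit offset
                off = int(parts[9])
                if off >= 0:
                    summit = off
            if np.isnan(summit):
                if end - start == 1:
                    summit = 0
                elif summit_from_midpoint:
                    summit = (end - start) // 2
            rows.append((chrom, start, end, name, score, summit))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    return PeakSet(sample_id or path, df)


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED6 (name '.', score '0' where absent); summits are not emitted."""
    df = peaks.df
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            name = row.name if row.name is not None else "."
            score = 0 if pd.isna(row.score) else row.score
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score}\t.\n")


def read_tss(path) -> TssAnnotation:
    """Read a TSS table (TSV with header gene_id, chrom, position, strand)."""
    df = pd.read_csv(path, sep="\t")
    return TssAnnotation(df)


def write_tss(tss: TssAnnotation, path) -> None:
    tss.df.to_csv(path, sep="\t", index=False)
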