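"""Gene classification from differential expression and enhancer-hub counting.

Genes are classed from TF-knockdown DE tables as *down* (log2FC < -0.25
and FDR < 0.05), *nonregulated* (-0.15 < log2FC < 0.15 and FDR > 0.25)
or *other* — strict inequalities, so boundary values fall outside both
windows. Genes down in every cell line are the common TF-dependent set.
Hub connectivity of a gene is the number of distinct distal TF peaks
overlapping enhancers looped to it; dependent genes sit in larger hubs
than nonregulated genes, which is tested with an unpaired two-sided
Student's t (pooled variance; Welch available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .intervals import PeakSet, subtract_overlapping
from .loops import EPITable

__all__ = [
    "DEFAULT_THRESHOLDS",
    "HubComparison",
    "classify_genes",
    "common_dependent_genes",
    "common_class_genes",
    "count_connected_peaks",
    "compare_hub_groups",
    "read_de_table",
]

DEFAULT_THRESHOLDS = dict(down_lfc=-0.25, down_fdr=0.05, nr_lfc=0.15, nr_fdr=0.25)


def read_de_table(path) -> pd.DataFrame:
    """Read a DE table (TSV with header: gene_id, log2fc, fdr)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    rename = {"log2foldchange": "log2fc", "padj": "fdr"}
    df = df.rename(columns=rename)
    missing = {"gene_id", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return df[["gene_id", "log2fc", "fdr"]]


def classify_genes(
    de: pd.DataFrame,
    down_lfc: float = -0.25,
    down_fdr: float = 0.05,
    nr_lfc: float = 0.15,
    nr_fdr: float = 0.25,
) -> pd.DataFrame:
    """Partition genes into down / nonregulated / other.

    down: log2fc < down_lfc AND fdr < down_fdr;
    nonregulated: |log2fc| < nr_lfc AND fdr > nr_fdr; otherwise other.
    All inequalities strict. Returns a frame (gene_id, cls).
    """
    if not (nr_lfc > 0 > down_lfc):
        raise ValueError("thresholds must satisfy nr_lfc > 0 > down_lfc")
    fdr = de["fdr"].to_numpy(dtype=float)
    if ((fdr < 0) | (fdr > 1)).any():
        raise ValueError("FDR values must lie in [0, 1]")
    lfc = de["log2fc"].to_numpy(dtype=float)
    down = (lfc < down_lfc) & (fdr < down_fdr)
    nonreg = (np.abs(lfc) < nr_lfc) & (fdr > nr_fdr)
    cls = np.where(down, "down", np.where(nonreg, "nonregulated", "other"))
    return pd.DataFrame({"gene_id": de["gene_id"].to_numpy(), "cls": cls})


def common_class_genes(classifications: Sequence[pd.DataFrame], cls: str) -> set[str]:
    """Genes assigned to `cls` in every sample's classification."""
    if len(classifications) < 2:
        raise ValueError("need classifications from at least 2 samples")
    sets = [set(c.loc[c["cls"] == cls, "gene_id"]) for c in classifications]
    return set.intersection(*sets)


def common_dependent_genes(classifications: Sequence[pd.DataFrame]) -> set[str]:
    """Genes classed down in every sample (common TF-dependent genes)."""
    return common_class_genes(classifications, "down")


def count_connected_peaks(
    genes: Iterable[str],
    epi: EPITable,
    tf_peaks: PeakSet,
    tss_windows: PeakSet,
) -> pd.DataFrame:
    """Distinct distal TF peaks connected to each gene through loops.

    A TF peak counts for a gene iff it (i) does not overlap any TSS
    window (distal) and (ii) overlaps at least one enhancer looped to the
    gene in `epi`. A peak reached through several enhancers of the same
    gene is counted once. Genes absent from `epi` get 0.

    Returns a frame (gene_id, n_peaks).
    """
    distal = subtract_overlapping(tf_peaks, tss_windows)
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(distal.df.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, i)

    epi_df = epi.df
    needed = {"enh_chrom", "enh_start", "enh_end"}
    if not needed.issubset(epi_df.columns):
        raise ValueError("EPITable lacks enhancer coordinates needed for peak counting")
    counts = []
    for gene in genes:
        rows = epi_df[epi_df["gene_id"] == gene]
        peak_ids: set[int] = set()
        for r in rows.itertuples(index=False):
            tree = trees.get(r.enh_chrom)
            if tree is None:
                continue
            peak_ids.update(hit.data for hit in tree.overlap(r.enh_start, r.enh_end))
        counts.append((gene, len(peak_ids)))
    return pd.DataFrame(counts, columns=["gene_id", "n_peaks"])


@dataclass(frozen=True)
class HubComparison:
    t_statistic: float
    p_value: float
    mean_down: float
    mean_nonregulated: float


def compare_hub_groups(
    down_counts: Iterable[float],
    nonreg_counts: Iterable[float],
    welch: bool = False,
) -> HubComparison:
    """Two-sided unpaired t test of hub connectivity between gene classes.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption. Two groups with zero variance and equal
    means return t=0, p=1.
    """
    a = np.asarray(list(down_counts), dtype=float)
    b = np.asarray(list(nonreg_counts), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return HubComparison(0.0, 1.0, float(a.mean()), float(b.mean()))
        raise ValueError("both groups have zero variance but different means")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return HubComparison(float(t), float(p), float(a.mean()), float(b.mean()))
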