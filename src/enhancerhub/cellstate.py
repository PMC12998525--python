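"""Tumor cell-state diagram scoring (classical vs basal-like commitment).

Each unit (cell or bulk sample) gets a classical and a basal signature
score: the mean, over signature genes present, of within-gene
standardized (z-scored) expression. The basal score is flipped to
negative and added to the classical score, giving the tumor-type
(commitment) score on the x-axis; the intermediate (coexpressor) score,

    intermediate = (classical + basal) - |classical - basal|
                 = 2 * min(classical, basal),

is the y-axis. Committed units sit at the left/right extremes with
intermediate ~ 0; units coexpressing both programs sit at the top
middle. For bulk panels, genes are projected onto the same diagram via
their Pearson correlation with the per-sample classical and basal score
vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SignatureSets",
    "signature_score",
    "cell_state_diagram",
    "state_scores",
    "bulk_gene_projection",
]


@dataclass(frozen=True)
class SignatureSets:
    """Classical and basal subtype gene sets."""

    classical_genes: frozenset
    basal_genes: frozenset

    def __post_init__(self) -> None:
        c = frozenset(self.classical_genes)
        b = frozenset(self.basal_genes)
        if not c or not b:
            raise ValueError("both signature sets must be nonempty")
        overlap = c & b
        if overlap:
            warnings.warn(
                f"{len(overlap)} gene(s) appear in both signatures: "
                f"{sorted(overlap)[:5]}...",
                stacklevel=2,
            )
        object.__setattr__(self, "classical_genes", c)
        object.__setattr__(self, "basal_genes", b)


def signature_score(expr: pd.DataFrame, genes: Iterable[str]) -> pd.Series:
    """Per-unit mean of within-gene z-scored expression over a gene set.

    `expr` is genes x units (log-normalized upstream). Signature genes
    missing from the matrix are skipped with a warning; zero-variance
    genes contribute a z-score of 0. Fails if no signature gene is
    present.
    """
    genes = set(genes)
    present = [g for g in expr.index if g in genes]
    if not present:
        raise ValueError(f"no signature gene present in the matrix; set was {sorted(genes)}")
    missing = genes - set(present)
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from the matrix and skipped",
            stacklevel=2,
        )
    sub = expr.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)  # population SD (ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub - mu) / sd, 0.0)
    return pd.Series(z.mean(axis=0), index=expr.columns, name="score")


def state_scores(classical: pd.Series, basal: pd.Series) -> pd.DataFrame:
    """Combine per-unit classical/basal scores into the diagram coordinates."""
    tumor_type = classical - basal  # classical + flipped basal
    intermediate = (classical + basal) - tumor_type.abs()
    return pd.DataFrame(
        {
            "classical_score": classical,
            "basal_score": basal,
            "tumor_type_score": tumor_type,
            "intermediate_score": intermediate,
        }
    )


def cell_state_diagram(expr: pd.DataFrame, sigs: SignatureSets) -> pd.DataFrame:
    """Score every unit of a genes x units matrix onto the state diagram.

    Returns a frame indexed by unit with columns classical_score,
    basal_score, tumor_type_score (x-axis) and intermediate_score
    (y-axis). A guard warns when the matrix looks like raw integer counts
    (scores assume log-normalized input).
    """
    vals = expr.to_numpy()
    if vals.size and np.allclose(vals, np.round(vals)) and vals.max() > 30:
        warnings.warn(
            "expression matrix looks like raw integer counts; scores assume "
            "library-normalized, log-transformed input",
            stacklevel=2,
        )
    classical = signature_score(expr, sigs.classical_genes)
    basal = signature_score(expr, sigs.basal_genes)
    return state_scores(classical, basal)


def bulk_gene_projection(expr_bulk: pd.DataFrame, sigs: SignatureSets) -> pd.DataFrame:
    """Project genes onto the state diagram via Pearson correlation.

    For a bulk genes x samples matrix, computes each gene's Pearson r
    against the per-sample classical and basal scores, then applies the
    same tumor-type / intermediate formulas to the pair (r_classical,
    r_basal). Genes with zero variance across samples get missing values.
    Requires >= 3 samples.
    """
    if expr_bulk.shape[1] < 3:
        raise ValueError("bulk projection needs at least 3 samples")
    classical = signature_score(expr_bulk, sigs.classical_genes)
    basal = signature_score(expr_bulk, sigs.basal_genes)

    x = expr_bulk.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xsd = x.std(axis=1)
    zero_var = xsd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance gene(s) emitted as missing",
            stacklevel=2,
        )

    def _corr(scores: pd.Series) -> np.ndarray:
        s = scores.to_numpy(dtype=float)
        sc = s - s.mean()
        ssd = s.std()
        if ssd == 0:
            return np.full(len(x), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ sc) / (len(s) * xsd * ssd)
        r[zero_var] = np.nan
        return r

    r_classical = pd.Series(_corr(classical), index=expr_bulk.index)
    r_basal = pd.Series(_corr(basal), index=expr_bulk.index)
    out = state_scores(r_classical, r_basal)
    out.columns = [
        "r_classical",
        "r_basal",
        "tumor_type_score",
        "intermediate_score",
    ]
    return out


def read_signatures(path) -> SignatureSets:
    """Read a two-column TSV (gene, set) with set in {classical, basal}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "set"])
    c = frozenset(df.loc[df["set"] == "classical", "gene"])
    b = frozenset(df.loc[df["set"] == "basal", "gene"])
    return SignatureSets(c, b)
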