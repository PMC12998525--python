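"""Seeded generators for every input the discovery pipeline consumes.

The generators emulate the statistical structure of the real study
inputs at desk scale: multi-sample peak catalogs with shared and
sample-unique regions plus a CTCF-high decoy subset, cis loop catalogs
whose background contact counts decay exponentially with rank while
planted gene-enhancer links sit in a clearly separated high-count
regime, knockdown DE tables with planted down/nonregulated/buffer
classes, expression matrices with classical-committed, basal-committed
and coexpressing populations, bimodal log-intensity marker tables, and
confluency curves constructed on the Bliss independence surface plus a
chosen synergy offset.

Every generator is a pure function of :class:`SimConfig` (seed
included); truth tables are returned alongside each dataset so that
stage-level recovery can be asserted without re-derivation. The default
scale (2 chromosomes x 5 Mb, 300 genes, 6 samples) runs the full
pipeline in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import PeakSet, SignalMatrix, TssAnnotation, write_bed, write_tss
from .loops import LoopSet, write_bedpe
from .pheno import ConfluencyCurve
from .cellstate import SignatureSets

__all__ = [
    "SimConfig",
    "PeakTruth",
    "generate_genome_and_tss",
    "generate_peak_sets",
    "generate_loops",
    "generate_de_tables",
    "generate_expression",
    "generate_intensities",
    "generate_marker_calls",
    "generate_confluency",
    "gene_classes",
    "write_simulation",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the defaults acting as the
    reference conditions every recovery test runs under."""

    seed: int = 0
    # genome shape
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    slot_spacing: int = 10_000  # one entity per slot keeps features distal
    n_genes: int = 300
    n_samples: int = 6
    # peaks
    n_shared_peaks: int = 40  # truth enhancers, present in every sample
    n_unique_peaks: int = 15  # per-sample-only peaks, removed by consensus
    n_ctcf_regions: int = 40
    ctcf_high_fraction: float = 0.3  # CTCF-high decoys, removed by subtraction
    atac_flank: int = 100
    tss_flank: int = 2500
    # loops
    bin_size: int = 2500
    min_cis_distance: int = 10_000
    depth_base: int = 1_000_000  # sample i gets depth_base * (i + 1)
    loop_decay_rate: float = 0.004
    n_background_links: int = 2000
    background_count_max: float = 50.0
    planted_count_min: int = 200
    planted_count_max: int = 400
    n_noise_loops: int = 100
    # gene classes and hub wiring
    n_dependent_genes: int = 30
    n_nonregulated_genes: int = 40
    n_buffer_genes: int = 20
    hub_k_dependent: int = 6
    hub_k_nonregulated: int = 2
    de_effect: float = 1.0  # planted |log2FC| of dependent genes
    # cell-state populations (classical, basal, coexpressor) and effect (SD units)
    state_populations: tuple[int, int, int] = (200, 200, 200)
    state_effect: float = 2.0
    n_signature_genes: int = 30
    n_background_genes: int = 40
    # marker intensity mixture (log scale)
    intensity_log_means: tuple[float, float] = (1.0, 4.0)
    intensity_log_sds: tuple[float, float] = (0.5, 0.5)
    intensity_weight_negative: float = 0.5
    n_intensity_cells: int = 2000
    # confluency / synergy
    effect_a: float = 0.4
    effect_b: float = 0.3

    def __post_init__(self) -> None:
        if self.hub_k_dependent <= self.hub_k_nonregulated:
            raise ValueError("hub_k_dependent must exceed hub_k_nonregulated")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_samples"):
            if getattr(self, name) < 0 or (name != "n_genes" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.loop_decay_rate <= 0:
            raise ValueError("loop_decay_rate must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class PeakTruth:
    """Planted ground truth emitted next to the generated peak catalogs."""

    enhancers: PeakSet  # consensus-coordinate enhancer regions, named by id
    enhancer_centers: pd.DataFrame  # enhancer_id, chrom, center
    decoys: PeakSet  # CTCF-high regions that would otherwise pass consensus
    ctcf_high: PeakSet


def _rng(cfg: SimConfig, *stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, *stage])


def _layout(cfg: SimConfig) -> dict:
    """Deterministic assignment of genome slots to entities.

    One entity per ``slot_spacing`` window guarantees: TSS pairwise
    distances exceed 2x the promoter flank, enhancers are distal to every
    promoter window, and each loop anchor maps to at most one feature.
    """
    rng = _rng(cfg, 0)
    chroms = list(cfg.chrom_sizes)
    slots = [
        (c, s * cfg.slot_spacing + cfg.slot_spacing // 2)
        for c in chroms
        for s in range(cfg.chrom_length // cfg.slot_spacing)
    ]
    n_ctcf_high = round(cfg.ctcf_high_fraction * cfg.n_ctcf_regions)
    need = (
        cfg.n_genes
        + cfg.n_shared_peaks
        + cfg.n_ctcf_regions
        + cfg.n_samples * cfg.n_unique_peaks
    )
    if need > len(slots):
        raise ValueError(
            f"infeasible density: {need} entities for {len(slots)} genome slots; "
            "increase chrom_length or n_chroms"
        )
    order = rng.permutation(len(slots))
    cursor = 0

    def take(n: int) -> list[tuple[str, int]]:
        nonlocal cursor
        sel = [slots[i] for i in order[cursor : cursor + n]]
        cursor += n
        return sel

    gene_slots = take(cfg.n_genes)
    enhancer_slots = take(cfg.n_shared_peaks)
    ctcf_slots = take(cfg.n_ctcf_regions)
    unique_slots = {sid: take(cfg.n_unique_peaks) for sid in cfg.sample_ids}
    free_slots = [slots[i] for i in order[cursor:]]
    return {
        "genes": gene_slots,
        "enhancers": enhancer_slots,
        "ctcf": ctcf_slots,
        "ctcf_high": ctcf_slots[:n_ctcf_high],
        "unique": unique_slots,
        "free": free_slots,
    }


# ---------------------------------------------------------------------------
# genome / peaks


def generate_genome_and_tss(cfg: SimConfig) -> tuple[TssAnnotation, dict[str, int]]:
    """Gene TSS annotation plus chromosome sizes.

    TSS are placed one per genome slot so no two promoter windows overlap.
    """
    lay = _layout(cfg)
    rng = _rng(cfg, 1)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    df = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:04d}" for i in range(cfg.n_genes)],
            "chrom": [c for c, _ in lay["genes"]],
            "position": [p for _, p in lay["genes"]],
            "strand": strands,
        }
    )
    return TssAnnotation(df), cfg.chrom_sizes


def _enh_id(cfg: SimConfig, chrom: str, center: int) -> str:
    # matches the consensus coordinates the pipeline derives (ATAC summit +- flank)
    return f"{chrom}:{center - cfg.atac_flank}-{center + cfg.atac_flank}"


def generate_peak_sets(
    cfg: SimConfig, tss: TssAnnotation
) -> tuple[dict[str, dict[str, PeakSet]], SignalMatrix, PeakTruth]:
    """Per-sample ATAC/H3K27ac/H3K4me3/TF peak catalogs plus CTCF signal.

    Shared enhancer peaks appear in every sample; unique peaks in exactly
    one; CTCF-high decoy regions carry shared ATAC and H3K27ac signal too
    (so only the CTCF subtraction removes them); TF peaks sit inside
    every shared enhancer. Returns (per-sample track dict, CTCF signal
    matrix, truth).
    """
    lay = _layout(cfg)
    rng = _rng(cfg, 2)
    enh_centers = lay["enhancers"]
    decoy_centers = lay["ctcf_high"]
    n_high = len(decoy_centers)

    def summit_peaks(centers, half=200):
        return [(c, p - half, p + half, None, np.nan, half) for c, p in centers]

    def flat_peaks(centers, half):
        return [(c, p - half, p + half) for c, p in centers]

    tss_centers = list(zip(tss.df["chrom"], tss.df["position"]))
    peaksets: dict[str, dict[str, PeakSet]] = {}
    for sid in cfg.sample_ids:
        atac = (
            summit_peaks(enh_centers)
            + summit_peaks(decoy_centers)
            + summit_peaks(lay["unique"][sid])
            + summit_peaks(tss_centers)
        )
        h3k27ac = flat_peaks(enh_centers, 500) + flat_peaks(decoy_centers, 500)
        h3k4me3 = flat_peaks(tss_centers, 500)
        tf = flat_peaks(enh_centers, 25)
        peaksets[sid] = {
            "atac": PeakSet.from_records(sid, atac),
            "h3k27ac": PeakSet.from_records(sid, h3k27ac),
            "h3k4me3": PeakSet.from_records(sid, h3k4me3),
            "tf": PeakSet.from_records(sid, tf),
        }

    # CTCF occupancy matrix over extended CTCF peaks; background rows are a
    # constant baseline so that ctcf_high_fraction = 0 degenerates cleanly
    ctcf_regions = pd.DataFrame(
        [(c, p - cfg.atac_flank, p + cfg.atac_flank) for c, p in lay["ctcf"]],
        columns=["chrom", "start", "end"],
    )
    n_ctcf_samples = min(4, cfg.n_samples)
    values = np.ones((cfg.n_ctcf_regions, n_ctcf_samples))
    if n_high:
        # the first n_high CTCF slots are the planted high (decoy) regions
        values[:n_high] = np.clip(
            rng.normal(100.0, 10.0, size=(n_high, n_ctcf_samples)), 1e-3, None
        )
    signal = SignalMatrix(ctcf_regions, cfg.sample_ids[:n_ctcf_samples], values)

    truth = PeakTruth(
        enhancers=PeakSet.from_records(
            "truth",
            [
                (c, p - cfg.atac_flank, p + cfg.atac_flank, _enh_id(cfg, c, p))
                for c, p in enh_centers
            ],
        ),
        enhancer_centers=pd.DataFrame(
            [(_enh_id(cfg, c, p), c, p) for c, p in enh_centers],
            columns=["enhancer_id", "chrom", "center"],
        ),
        decoys=PeakSet.from_records(
            "decoys", [(c, p - cfg.atac_flank, p + cfg.atac_flank) for c, p in decoy_centers]
        ),
        ctcf_high=PeakSet.from_records(
            "ctcf_high",
            [(c, p - cfg.atac_flank, p + cfg.atac_flank) for c, p in decoy_centers],
        ),
    )
    return peaksets, signal, truth


# ---------------------------------------------------------------------------
# gene classes and hub wiring


def gene_classes(cfg: SimConfig, tss: TssAnnotation) -> pd.DataFrame:
    """Planted class of every gene: dependent / nonregulated / buffer / other."""
    n = cfg.n_genes
    n_dep, n_nr, n_buf = (
        cfg.n_dependent_genes,
        cfg.n_nonregulated_genes,
        cfg.n_buffer_genes,
    )
    if n_dep + n_nr + n_buf > n:
        raise ValueError("gene class sizes exceed n_genes")
    cls = ["dependent"] * n_dep + ["nonregulated"] * n_nr + ["buffer"] * n_buf
    cls += ["other"] * (n - len(cls))
    return pd.DataFrame({"gene_id": tss.df["gene_id"].to_numpy(), "true_class": cls})


def _plant_links(cfg: SimConfig, tss: TssAnnotation, truth: PeakTruth, rng) -> pd.DataFrame:
    """Wire dependent and nonregulated genes to same-chromosome enhancers."""
    classes = gene_classes(cfg, tss)
    enh = truth.enhancer_centers
    tss_df = tss.df.set_index("gene_id")
    rows = []
    margin = cfg.min_cis_distance + 2 * cfg.bin_size
    for gene, true_class in classes.itertuples(index=False):
        k_base = {"dependent": cfg.hub_k_dependent, "nonregulated": cfg.hub_k_nonregulated}.get(
            true_class, 0
        )
        if k_base == 0:
            continue
        # per-gene jitter of +-1 enhancer keeps the class mean at k_base
        # while giving hub sizes realistic within-class variance
        k = max(1, k_base + int(rng.integers(-1, 2)))
        g = tss_df.loc[gene]
        eligible = enh[
            (enh["chrom"] == g["chrom"]) & ((enh["center"] - g["position"]).abs() >= margin)
        ]
        if len(eligible) < k:
            raise ValueError(
                f"gene {gene}: only {len(eligible)} eligible enhancers for k={k}; "
                "increase n_shared_peaks or chrom_length"
            )
        chosen = eligible.iloc[rng.choice(len(eligible), size=k, replace=False)]
        for e in chosen.itertuples(index=False):
            rows.append((gene, e.enhancer_id, e.chrom, e.center, g["position"], true_class))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "enhancer_id", "chrom", "enh_center", "tss_position", "true_class"],
    )


def generate_loops(
    cfg: SimConfig, tss: TssAnnotation, truth: PeakTruth
) -> tuple[list[LoopSet], set[tuple[str, str]], pd.DataFrame]:
    """Per-sample loop catalogs with planted gene-enhancer links.

    Planted links get raw counts around a per-link base value scaled by
    each sample's depth, so depth normalization equalizes them; background
    links (random non-truth gene-enhancer pairs, different per sample)
    follow an exponentially decaying rank profile far below the planted
    regime; noise loops join unassigned genome slots and match no feature.
    Returns (loopsets, truth key set, link table).
    """
    rng = _rng(cfg, 3)
    links = _plant_links(cfg, tss, truth, rng)
    truth_keys = set(zip(links["gene_id"], links["enhancer_id"]))
    base_counts = rng.integers(cfg.planted_count_min, cfg.planted_count_max + 1, len(links))

    depths = [cfg.depth_base * (i + 1) for i in range(cfg.n_samples)]
    depth_max = max(depths)
    enh = truth.enhancer_centers
    tss_df = tss.df
    margin = cfg.min_cis_distance + 2 * cfg.bin_size

    def bin_of(pos: int) -> tuple[int, int]:
        start = (pos // cfg.bin_size) * cfg.bin_size
        return start, start + cfg.bin_size

    free = _layout(cfg)["free"]
    by_chrom: dict[str, list[int]] = {}
    for c, p in free:
        by_chrom.setdefault(c, []).append(p)

    loopsets = []
    for i, sid in enumerate(cfg.sample_ids):
        srng = _rng(cfg, 3, i + 1)
        scale = depths[i] / depth_max
        rows = []
        for (g, e, chrom, center, pos, _), base in zip(links.itertuples(index=False), base_counts):
            sa, ea = bin_of(pos)
            sb, eb = bin_of(center)
            rows.append((chrom, sa, ea, chrom, sb, eb, max(1, round(base * scale))))
        # background gene-enhancer pairs, resampled independently per sample
        g_ids = tss_df["gene_id"].to_numpy()
        g_chrom = tss_df["chrom"].to_numpy()
        g_pos = tss_df["position"].to_numpy()
        e_ids = enh["enhancer_id"].to_numpy()
        e_chrom = enh["chrom"].to_numpy()
        e_center = enh["center"].to_numpy()
        n_bg = 0
        attempts = 0
        while n_bg < cfg.n_background_links and attempts < cfg.n_background_links * 20:
            attempts += 1
            gi = int(srng.integers(len(g_ids)))
            ei = int(srng.integers(len(e_ids)))
            if e_chrom[ei] != g_chrom[gi] or abs(e_center[ei] - g_pos[gi]) < margin:
                continue
            if (g_ids[gi], e_ids[ei]) in truth_keys:
                continue
            count = max(
                1, round(cfg.background_count_max * np.exp(-cfg.loop_decay_rate * n_bg) * scale)
            )
            sa, ea = bin_of(int(g_pos[gi]))
            sb, eb = bin_of(int(e_center[ei]))
            rows.append((g_chrom[gi], sa, ea, g_chrom[gi], sb, eb, count))
            n_bg += 1
        # pure-noise loops on unassigned slots: match neither TSS nor enhancer
        n_noise = 0
        attempts = 0
        while n_noise < cfg.n_noise_loops and attempts < cfg.n_noise_loops * 20:
            attempts += 1
            chrom = str(srng.choice(list(by_chrom)))
            ps = by_chrom[chrom]
            if len(ps) < 2:
                continue
            pa, pb = (int(x) for x in srng.choice(ps, size=2, replace=False))
            if abs(pa - pb) < margin:
                continue
            sa, ea = bin_of(pa)
            sb, eb = bin_of(pb)
            rows.append((chrom, sa, ea, chrom, sb, eb, int(srng.integers(1, 6))))
            n_noise += 1
        df = pd.DataFrame(
            rows,
            columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "contact_count"],
        )
        loopsets.append(LoopSet(sid, df, valid_pairs_depth=depths[i]))
    return loopsets, truth_keys, links


# ---------------------------------------------------------------------------
# DE tables


def generate_de_tables(cfg: SimConfig, tss: TssAnnotation) -> list[pd.DataFrame]:
    """Per-sample knockdown DE tables realizing the planted gene classes.

    Dependent genes get log2FC ~ -de_effect (FDR << 0.05), nonregulated
    genes small fold changes with large FDR, buffer genes fall in the gap
    between the class windows, the rest are up-regulated.
    """
    classes = gene_classes(cfg, tss)
    tables = []
    for i in range(cfg.n_samples):
        rng = _rng(cfg, 4, i)
        n = len(classes)
        lfc = np.empty(n)
        fdr = np.empty(n)
        for j, true_class in enumerate(classes["true_class"]):
            if true_class == "dependent":
                lfc[j] = -cfg.de_effect + rng.uniform(-0.1, 0.1)
                fdr[j] = rng.uniform(1e-8, 0.01)
            elif true_class == "nonregulated":
                lfc[j] = rng.uniform(-0.12, 0.12)
                fdr[j] = rng.uniform(0.3, 0.99)
            elif true_class == "buffer":
                lfc[j] = rng.uniform(-0.23, -0.17)
                fdr[j] = rng.uniform(0.08, 0.2)
            else:
                lfc[j] = rng.uniform(0.3, 1.0)
                fdr[j] = rng.uniform(1e-6, 0.04)
        tables.append(
            pd.DataFrame(
                {"gene_id": classes["gene_id"].to_numpy(), "log2fc": lfc, "fdr": fdr}
            )
        )
    return tables


# ---------------------------------------------------------------------------
# expression / intensities / confluency


def generate_expression(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, SignatureSets]:
    """Single-cell-like expression with three planted populations.

    Classical-committed cells express the classical signature at
    ``state_effect`` SD above baseline, basal-committed cells the basal
    signature, coexpressors both. Returns (genes x cells matrix, truth
    labels per cell, signature sets).
    """
    rng = _rng(cfg, 5)
    n_sig, n_bg = cfg.n_signature_genes, cfg.n_background_genes
    classical_genes = [f"CLA{i + 1:03d}" for i in range(n_sig)]
    basal_genes = [f"BAS{i + 1:03d}" for i in range(n_sig)]
    bg_genes = [f"BGD{i + 1:03d}" for i in range(n_bg)]
    genes = classical_genes + basal_genes + bg_genes

    n_c, n_b, n_x = cfg.state_populations
    labels = ["classical"] * n_c + ["basal"] * n_b + ["coexpressor"] * n_x
    n_cells = len(labels)
    x = rng.normal(0.0, 1.0, size=(len(genes), n_cells))
    col = 0
    for pop, size in (("classical", n_c), ("basal", n_b), ("coexpressor", n_x)):
        sl = slice(col, col + size)
        if pop in ("classical", "coexpressor"):
            x[:n_sig, sl] += cfg.state_effect
        if pop in ("basal", "coexpressor"):
            x[n_sig : 2 * n_sig, sl] += cfg.state_effect
        col += size
    cells = [f"cell{i + 1:04d}" for i in range(n_cells)]
    expr = pd.DataFrame(x, index=genes, columns=cells)
    return expr, pd.Series(labels, index=cells, name="population"), SignatureSets(
        frozenset(classical_genes), frozenset(basal_genes)
    )


def generate_intensities(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Bimodal marker intensities (raw scale) plus truth component labels."""
    rng = _rng(cfg, 6)
    n = cfg.n_intensity_cells
    comp = (rng.random(n) >= cfg.intensity_weight_negative).astype(int)
    mus = np.asarray(cfg.intensity_log_means)
    sds = np.asarray(cfg.intensity_log_sds)
    log_int = rng.normal(mus[comp], sds[comp])
    return np.exp(log_int), comp


def generate_marker_calls(cfg: SimConfig, n_cells: int = 500) -> pd.DataFrame:
    """Boolean positivity table with planted subtype classes.

    Columns: panCK, HNF4A, KRT5/6, KLF5, BclxL. Most cells are tumor
    (panCK+); among them classical (HNF4A+/KRT5/6-), basal
    (HNF4A-/KRT5/6+) and double-negative cells appear in fixed
    proportions, with class-specific KLF5/Bcl-xL positivity rates.
    """
    rng = _rng(cfg, 7)
    panck = rng.random(n_cells) < 0.95
    u = rng.random(n_cells)
    hnf4a = panck & (u < 0.4)
    krt56 = panck & (u >= 0.4) & (u < 0.8)
    klf5_p = np.where(hnf4a, 0.8, np.where(krt56, 0.75, 0.5))
    bclxl_p = np.where(hnf4a, 0.7, np.where(krt56, 0.65, 0.4))
    return pd.DataFrame(
        {
            "panCK": panck,
            "HNF4A": hnf4a,
            "KRT5/6": krt56,
            "KLF5": rng.random(n_cells) < klf5_p,
            "BclxL": rng.random(n_cells) < bclxl_p,
        },
        index=[f"cell{i + 1:04d}" for i in range(n_cells)],
    )


def generate_confluency(
    cfg: SimConfig, synergy_offset: float = 0.0
) -> dict[str, ConfluencyCurve]:
    """Control / drug A / drug B / combination confluency curves.

    Treated curves are the control scaled by (1 - E); the combination
    realizes the Bliss independence surface plus `synergy_offset`, so the
    recovered synergy score equals the offset by construction.
    """
    t = np.arange(0.0, 97.0, 6.0)
    control = 80.0 / (1.0 + np.exp(-(t - 48.0) / 12.0))
    e_ind = cfg.effect_a + cfg.effect_b - cfg.effect_a * cfg.effect_b
    e_combo = e_ind + synergy_offset
    if not 0.0 <= e_combo <= 1.0:
        raise ValueError("synergy_offset pushes the combination effect outside [0, 1]")
    return {
        "control": ConfluencyCurve("control", t, control),
        "drug_a": ConfluencyCurve("drug_a", t, control * (1 - cfg.effect_a)),
        "drug_b": ConfluencyCurve("drug_b", t, control * (1 - cfg.effect_b)),
        "combo": ConfluencyCurve("combo", t, control * (1 - e_combo)),
    }


# ---------------------------------------------------------------------------
# file export


def _write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.df.itertuples(index=False)):
            name = row.name if row.name is not None else f"peak{i + 1}"
            summit = int(row.summit) if not pd.isna(row.summit) else -1
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t.\t0\t-1\t-1\t{summit}\n"
            )


def write_simulation(cfg: SimConfig, outdir) -> dict:
    """Write every pipeline input (and truth tables) as plain-text files.

    Produces per-sample narrowPeak/BED/bedpe/TSV files in the dialects
    the other modules read, a depth sidecar table, the CTCF signal
    matrix, and ``truth/`` tables. Returns a manifest of paths.
    """
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    tss, chrom_sizes = generate_genome_and_tss(cfg)
    peaksets, signal, truth = generate_peak_sets(cfg, tss)
    loopsets, truth_keys, links = generate_loops(cfg, tss, truth)
    de_tables = generate_de_tables(cfg, tss)

    manifest: dict = {"samples": {}, "seed": cfg.seed}
    write_tss(tss, outdir / "tss.tsv")
    manifest["tss"] = str(outdir / "tss.tsv")

    sig_df = signal.regions[["chrom", "start", "end"]].copy()
    for j, sid in enumerate(signal.samples):
        sig_df[sid] = signal.values[:, j]
    sig_df.to_csv(outdir / "ctcf_signal.tsv", sep="\t", index=False)
    manifest["ctcf_signal"] = str(outdir / "ctcf_signal.tsv")

    depth_rows = []
    for ls, sid, de in zip(loopsets, cfg.sample_ids, de_tables):
        paths = {}
        p = outdir / f"{sid}_atac.narrowPeak"
        _write_narrowpeak(peaksets[sid]["atac"], p)
        paths["atac"] = str(p)
        for track in ("h3k27ac", "h3k4me3", "tf"):
            p = outdir / f"{sid}_{track}.bed"
            write_bed(peaksets[sid][track], p)
            paths[track] = str(p)
        p = outdir / f"{sid}.bedpe"
        write_bedpe(ls, p)
        paths["bedpe"] = str(p)
        paths["depth"] = ls.valid_pairs_depth
        depth_rows.append((sid, ls.valid_pairs_depth))
        p = outdir / f"{sid}_de.tsv"
        de.to_csv(p, sep="\t", index=False)
        paths["de"] = str(p)
        manifest["samples"][sid] = paths
    pd.DataFrame(depth_rows, columns=["sample_id", "valid_interaction_rmdup"]).to_csv(
        outdir / "depths.tsv", sep="\t", index=False
    )
    manifest["depths"] = str(outdir / "depths.tsv")

    links.to_csv(outdir / "truth" / "links.tsv", sep="\t", index=False)
    write_bed(truth.enhancers, outdir / "truth" / "enhancers.bed")
    gene_classes(cfg, tss).to_csv(outdir / "truth" / "gene_classes.tsv", sep="\t", index=False)
    manifest["truth"] = {
        "links": str(outdir / "truth" / "links.tsv"),
        "enhancers": str(outdir / "truth" / "enhancers.bed"),
        "gene_classes": str(outdir / "truth" / "gene_classes.tsv"),
    }
    return manifest
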