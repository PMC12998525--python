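"""End-to-end discovery of subtype-independent highly interactive enhancers.

Given per-sample peak catalogs, loop catalogs with depths, a TSS
annotation, a CTCF signal matrix and DE tables, :func:`run_discovery`
executes the full cascade:

    extend ATAC summits -> subtract promoter windows -> intersect
    H3K27ac -> subtract CTCF-high -> multi-sample consensus ->
    A2A loop filtering -> depth normalization -> per-sample knee
    threshold -> cross-sample pair intersection -> hub counting ->
    dependent-vs-nonregulated comparison

writing every intermediate as BED/TSV plus a JSON report whose stage
counts are asserted to be monotonically non-increasing through each
filtering arm. The consensus enhancer BED is exported for external
motif tools; motif analysis itself is an export boundary, not a stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .intervals import (
    PeakSet,
    SignalMatrix,
    consensus_regions,
    ctcf_high_regions,
    extend_summits,
    intersect_overlapping,
    read_bed,
    read_tss,
    subtract_overlapping,
    tss_windows,
    write_bed,
)
from .kneepoint import RankedDistribution, knee_point
from .loops import (
    active_tss,
    filter_a2a_loops,
    intersect_epi_pairs,
    normalize_depth,
    read_bedpe,
    threshold_high_interactions,
)
from .hubs import (
    DEFAULT_THRESHOLDS,
    classify_genes,
    common_class_genes,
    common_dependent_genes,
    compare_hub_groups,
    count_connected_peaks,
    read_de_table,
)

__all__ = ["PipelineConfig", "RunReport", "PipelineStageError", "run_discovery"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class PipelineConfig:
    """File paths and parameters of one discovery run.

    `samples` maps a sample id to a dict with keys ``atac`` (summit
    narrowPeak/BED), ``h3k27ac``, ``h3k4me3``, ``tf`` (BED), ``bedpe``,
    ``depth`` (valid-pairs count) and ``de`` (TSV).
    """

    samples: dict
    tss: str
    ctcf_signal: str
    out_dir: str
    atac_flank: int = 100
    tss_flank: int = 2500
    ctcf_k: int = 2
    seed: int = 0
    knee_distance: str = "perpendicular"
    min_cis_distance: int = 10_000
    count_column: int = 7
    consensus_reference: str | None = None
    de_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    @classmethod
    def from_manifest(cls, manifest: dict, out_dir) -> "PipelineConfig":
        """Build a config from a :func:`enhancerhub.synthetic.write_simulation` manifest."""
        return cls(
            samples=manifest["samples"],
            tss=manifest["tss"],
            ctcf_signal=manifest["ctcf_signal"],
            out_dir=str(out_dir),
            seed=manifest.get("seed", 0),
        )

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config lists no samples")
        for sid, paths in self.samples.items():
            for key in ("atac", "h3k27ac", "h3k4me3", "tf", "bedpe", "de"):
                p = paths.get(key)
                if p is None or not Path(p).exists():
                    raise ValueError(f"sample {sid!r}: missing file for {key!r}: {p}")
            if int(paths.get("depth", 0)) <= 0:
                raise ValueError(f"sample {sid!r}: depth must be a positive integer")
        for key in ("tss", "ctcf_signal"):
            if not Path(getattr(self, key)).exists():
                raise ValueError(f"missing {key} file: {getattr(self, key)}")
        if self.atac_flank <= 0 or self.tss_flank <= 0 or self.ctcf_k < 2:
            raise ValueError("invalid parameter ranges")


@dataclass
class RunReport:
    """Per-stage counts, knee thresholds, hub statistics and file manifest."""

    stage_counts: dict
    knee: dict
    hub: dict
    files: dict
    config: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "knee": self.knee,
            "hub": self.hub,
            "files": self.files,
            "config": self.config,
            "version": self.version,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)


def _read_ctcf_signal(path) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t")
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    return SignalMatrix(
        df[["chrom", "start", "end"]], sample_cols, df[sample_cols].to_numpy(dtype=float)
    )


def run_discovery(config: PipelineConfig) -> RunReport:
    """Run the full discovery cascade and write intermediates + report."""

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineStageError(name, str(exc)) from exc

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sids = list(config.samples)
    counts: dict = {sid: {} for sid in sids}
    files: dict = {}

    tss = stage("read_tss", read_tss, config.tss)
    windows = stage("tss_windows", tss_windows, tss, config.tss_flank)
    signal = stage("read_ctcf_signal", _read_ctcf_signal, config.ctcf_signal)
    ctcf_high = stage("ctcf_high_regions", ctcf_high_regions, signal, config.ctcf_k, config.seed)
    write_bed(ctcf_high, out / "ctcf_high.bed")
    files["ctcf_high"] = str(out / "ctcf_high.bed")

    doa_per_sample = []
    for sid in sids:
        paths = config.samples[sid]
        atac = stage(f"{sid}:read_atac", read_bed, paths["atac"], sid)
        peaks = stage(f"{sid}:extend_summits", extend_summits, atac, config.atac_flank)
        counts[sid]["atac_peaks"] = len(peaks)
        distal = stage(f"{sid}:subtract_tss", subtract_overlapping, peaks, windows)
        counts[sid]["distal_open"] = len(distal)
        k27 = read_bed(paths["h3k27ac"], sid)
        doa = stage(f"{sid}:intersect_h3k27ac", intersect_overlapping, distal, k27)
        counts[sid]["distal_open_active"] = len(doa)
        doa_nc = stage(f"{sid}:subtract_ctcf_high", subtract_overlapping, doa, ctcf_high)
        counts[sid]["doa_no_ctcf"] = len(doa_nc)
        write_bed(doa_nc, out / f"{sid}_doa.bed")
        doa_per_sample.append(doa_nc)

    if len(sids) == 1:
        consensus = doa_per_sample[0]  # consensus degenerates to identity
    else:
        consensus = stage(
            "consensus_regions", consensus_regions, doa_per_sample, config.consensus_reference
        )
    n_consensus = len(consensus)
    write_bed(consensus, out / "consensus_enhancers.bed")
    files["consensus_enhancers"] = str(out / "consensus_enhancers.bed")

    loopsets = [
        stage(
            f"{sid}:read_bedpe",
            read_bedpe,
            config.samples[sid]["bedpe"],
            int(config.samples[sid]["depth"]),
            sid,
            config.count_column,
            config.min_cis_distance,
        )
        for sid in sids
    ]
    loopsets = stage("normalize_depth", normalize_depth, loopsets)

    knee_info: dict = {}
    epi_high_tables = []
    for sid, ls in zip(sids, loopsets):
        paths = config.samples[sid]
        k4 = read_bed(paths["h3k4me3"], sid)
        active = stage(f"{sid}:active_tss", active_tss, windows, k4)
        counts[sid]["active_tss"] = len(active)
        epi = stage(f"{sid}:filter_a2a_loops", filter_a2a_loops, ls, active, consensus)
        counts[sid]["epi_pairs"] = len(epi)
        knee = stage(
            f"{sid}:knee_point",
            knee_point,
            RankedDistribution(epi.df["contact_count"].to_numpy()),
            config.knee_distance,
        )
        knee_info[sid] = {
            "knee_rank": knee.knee_rank,
            "knee_value": knee.knee_value,
            "fit_a": knee.fit_params.a,
            "fit_b": knee.fit_params.b,
            "norm_factor": ls.norm_factor,
        }
        epi_high = stage(
            f"{sid}:threshold", threshold_high_interactions, epi, knee.knee_value
        )
        counts[sid]["epi_pairs_high"] = len(epi_high)
        epi_high.df.to_csv(out / f"{sid}_epi_high.tsv", sep="\t", index=False)
        epi_high_tables.append(epi_high)

    if len(epi_high_tables) == 1:
        final = epi_high_tables[0]
    else:
        final = stage("intersect_epi_pairs", intersect_epi_pairs, epi_high_tables)
    n_final = len(final)
    final.df.to_csv(out / "epi_intersection.tsv", sep="\t", index=False)
    files["epi_intersection"] = str(out / "epi_intersection.tsv")
    # candidate enhancer regions for external motif tools
    enh_keys = set(final.df["enhancer_id"])
    candidate = consensus.with_df(
        consensus.df[
            [
                f"{r.chrom}:{r.start}-{r.end}" in enh_keys
                for r in consensus.df.itertuples(index=False)
            ]
        ]
    )
    write_bed(candidate, out / "candidate_enhancers.bed")
    files["candidate_enhancers"] = str(out / "candidate_enhancers.bed")

    # hub connectivity: dependent vs nonregulated genes
    classifications = []
    for sid in sids:
        de = stage(f"{sid}:read_de", read_de_table, config.samples[sid]["de"])
        cls = stage(f"{sid}:classify_genes", classify_genes, de, **config.de_thresholds)
        counts[sid]["genes_down"] = int((cls["cls"] == "down").sum())
        counts[sid]["genes_nonregulated"] = int((cls["cls"] == "nonregulated").sum())
        classifications.append(cls)
    if len(classifications) >= 2:
        dep = stage("common_dependent_genes", common_dependent_genes, classifications)
        nonreg = common_class_genes(classifications, "nonregulated")
    else:
        dep = set(classifications[0].loc[classifications[0]["cls"] == "down", "gene_id"])
        nonreg = set(
            classifications[0].loc[classifications[0]["cls"] == "nonregulated", "gene_id"]
        )
    tf_peaks = read_bed(config.samples[sids[0]]["tf"], sids[0])
    hub_counts = stage(
        "count_connected_peaks",
        count_connected_peaks,
        sorted(dep | nonreg),
        final,
        tf_peaks,
        windows,
    )
    hub_counts["cls"] = [
        "down" if g in dep else "nonregulated" for g in hub_counts["gene_id"]
    ]
    hub_counts.to_csv(out / "hub_counts.tsv", sep="\t", index=False)
    files["hub_counts"] = str(out / "hub_counts.tsv")
    cmp_res = stage(
        "compare_hub_groups",
        compare_hub_groups,
        hub_counts.loc[hub_counts["cls"] == "down", "n_peaks"],
        hub_counts.loc[hub_counts["cls"] == "nonregulated", "n_peaks"],
    )
    hub_info = {
        "n_common_dependent": len(dep),
        "n_common_nonregulated": len(nonreg),
        "t_statistic": cmp_res.t_statistic,
        "p_value": cmp_res.p_value,
        "mean_down": cmp_res.mean_down,
        "mean_nonregulated": cmp_res.mean_nonregulated,
    }

    # cascade monotonicity: every filtering stage shrinks or keeps its input
    for sid in sids:
        c = counts[sid]
        arm = [c["atac_peaks"], c["distal_open"], c["distal_open_active"], c["doa_no_ctcf"]]
        if any(a < b for a, b in zip(arm, arm[1:])):
            raise PipelineStageError("cascade_check", f"{sid}: region counts increased")
        if not (c["epi_pairs"] >= c["epi_pairs_high"] >= n_final):
            raise PipelineStageError("cascade_check", f"{sid}: pair counts increased")
        if n_consensus > min(len(d) for d in doa_per_sample):
            raise PipelineStageError("cascade_check", "consensus exceeds a member set")

    stage_counts = {
        "per_sample": counts,
        "consensus_enhancers": n_consensus,
        "epi_intersection": n_final,
        "candidate_enhancers": len(candidate),
    }
    cfg_echo = {
        "samples": {sid: dict(p) for sid, p in config.samples.items()},
        "tss": config.tss,
        "ctcf_signal": config.ctcf_signal,
        "atac_flank": config.atac_flank,
        "tss_flank": config.tss_flank,
        "ctcf_k": config.ctcf_k,
        "seed": config.seed,
        "knee_distance": config.knee_distance,
        "min_cis_distance": config.min_cis_distance,
        "de_thresholds": dict(config.de_thresholds),
    }
    report = RunReport(
        stage_counts=stage_counts,
        knee=knee_info,
        hub=hub_info,
        files=files,
        config=cfg_echo,
    )
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(_report_text(report))
    return report


def _report_text(report: RunReport) -> str:
    lines = [f"enhancerhub discovery report (v{report.version})", ""]
    for sid, c in report.stage_counts["per_sample"].items():
        lines.append(
            f"{sid}: ATAC {c['atac_peaks']} -> distal {c['distal_open']} -> "
            f"DOA {c['distal_open_active']} -> no-CTCF {c['doa_no_ctcf']}; "
            f"EPI {c['epi_pairs']} -> high {c['epi_pairs_high']} "
            f"(knee {report.knee[sid]['knee_value']:.2f})"
        )
    lines.append("")
    lines.append(f"consensus enhancers: {report.stage_counts['consensus_enhancers']}")
    lines.append(f"EPI pairs in all samples: {report.stage_counts['epi_intersection']}")
    lines.append(f"candidate enhancers exported: {report.stage_counts['candidate_enhancers']}")
    h = report.hub
    lines.append(
        f"hub comparison: {h['n_common_dependent']} dependent vs "
        f"{h['n_common_nonregulated']} nonregulated genes; "
        f"mean peaks {h['mean_down']:.2f} vs {h['mean_nonregulated']:.2f}; "
        f"t = {h['t_statistic']:.3f}, p = {h['p_value']:.3g}"
    )
    return "\n".join(lines) + "\n"
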