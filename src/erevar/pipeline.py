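"""End-to-end orchestration: scan -> consensus -> select -> QC -> association.

A single configuration names every input; the run writes all intermediate
artifacts as plain text plus a JSON manifest recording input checksums,
thresholds and the count flow through each stage (candidates found,
genotyped, proxied, post-QC, tested).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .association import Stratum, run_stratified, write_results_full, write_results_tsv
from .ere_scan import filter_snp_disrupting, read_masked_fasta, scan_halfsites, write_hits_offsets_tsv
from .genotype_qc import QcThresholds, read_ped_map
from .intervals import intersect_all, read_bed, union_any, whole_region_consensus, write_bed
from .snp_select import (
    DEFAULT_R2_MIN,
    assemble_candidates,
    find_proxies,
    read_ld_table,
    read_map,
    snps_in_regions,
    write_candidates_tsv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage's name attached."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    fasta: str
    chip_beds: list[str]
    snp_map: str
    ld_table: str
    ped: Mapping[str, str]  # disease -> PED path
    ped_map: Mapping[str, str]  # disease -> MAP path
    out_dir: str
    genes_bed: str | None = None
    consensus_mode: str = "intersect"  # or "whole-region"
    r2_min: float = DEFAULT_R2_MIN
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    multiplier: int | str = "auto"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = QcThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def input_paths(self) -> dict[str, Path]:
        paths = {"fasta": Path(self.fasta), "snp_map": Path(self.snp_map), "ld_table": Path(self.ld_table)}
        for i, bed in enumerate(self.chip_beds):
            paths[f"chip_bed_{i}"] = Path(bed)
        for disease in self.ped:
            paths[f"ped_{disease}"] = Path(self.ped[disease])
            paths[f"map_{disease}"] = Path(self.ped_map[disease])
        if self.genes_bed:
            paths["genes_bed"] = Path(self.genes_bed)
        return paths


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns the run manifest.

    Missing inputs raise before any computation; a stage failure leaves
    earlier outputs in place and the manifest names the failure point.
    """
    inputs = cfg.input_paths()
    missing = [str(p) for p in inputs.values() if not p.exists()]
    if missing:
        raise PipelineError("config", f"missing input file(s): {', '.join(missing)}")
    if len(cfg.chip_beds) < 2:
        raise PipelineError("config", "need at least two ChIP region files")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "inputs": {k: {"path": str(p), "md5": _md5(p)} for k, p in inputs.items()},
        "thresholds": asdict(cfg.thresholds),
        "r2_min": cfg.r2_min,
        "consensus_mode": cfg.consensus_mode,
        "seed": cfg.seed,
        "counts": {},
        "stages_completed": [],
        "failed_stage": None,
    }
    counts = manifest["counts"]

    def checkpoint(stage: str) -> None:
        manifest["stages_completed"].append(stage)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    stage = "scan"
    try:
        seqs = read_masked_fasta(cfg.fasta)
        hits = [h for seq in seqs for h in scan_halfsites(seq)]
        disrupting = [
            h
            for seq in seqs
            for h in filter_snp_disrupting(scan_halfsites(seq), seq)
        ]
        counts["motif_hits"] = len(hits)
        counts["disrupting_hits"] = len(disrupting)
        write_hits_offsets_tsv(disrupting, out / "hits.tsv")
        checkpoint(stage)

        stage = "consensus"
        chip = [read_bed(p) for p in cfg.chip_beds]
        consensus = (
            intersect_all(chip)
            if cfg.consensus_mode == "intersect"
            else whole_region_consensus(chip)
        )
        union = union_any(chip)
        counts["consensus_regions"] = len(consensus)
        write_bed(consensus, out / "consensus.bed")
        write_bed(union, out / "union.bed")
        checkpoint(stage)

        stage = "select"
        snps = read_map(cfg.snp_map)
        group_a = snps_in_regions(snps, consensus, "consensus_region")
        disrupting_pos = {
            (h.chrom, h.start + off)
            for h in disrupting
            for off in h.masked_positions
        }
        ere_snps = [s for s in snps if (s.chrom, s.pos_1based - 1) in disrupting_pos]
        group_b = snps_in_regions(ere_snps, union, "ere_halfsite")
        candidates = assemble_candidates(group_a, group_b)
        counts["consensus_snps"] = len(group_a)
        counts["ere_snps"] = len(group_b)
        counts["candidates"] = len(candidates)
        write_candidates_tsv(candidates, out / "candidates.tsv")
        checkpoint(stage)

        stage = "proxies"
        ld = read_ld_table(cfg.ld_table)
        datasets = {}
        panels = {}
        for disease in sorted(cfg.ped):
            ds = read_ped_map(cfg.ped[disease], cfg.ped_map[disease])
            datasets[disease] = ds
            genotyped = {s.rsid for s in ds.snps}
            panel = find_proxies(candidates, genotyped, ld, cfg.r2_min)
            panels[disease] = panel
            counts[f"{disease}_genotyped_candidates"] = sum(
                1 for c in panel if c.provenance != "ld_proxy"
            )
            counts[f"{disease}_proxies"] = sum(
                1 for c in panel if c.provenance == "ld_proxy"
            )
            counts[f"{disease}_panel"] = len(panel)
            write_candidates_tsv(panel, out / f"panel_{disease}.tsv")
        checkpoint(stage)

        stage = "association"
        results_all = []
        mult_used = None
        # one shared multiplier across diseases: run jointly
        panel_rsids = sorted({c.snp.rsid for p in panels.values() for c in p})
        results_all, qc_reports, mult_used = run_stratified(
            datasets,
            candidate_rsids=panel_rsids,
            thresholds=cfg.thresholds,
            multiplier=cfg.multiplier,
        )
        for st, report in qc_reports.items():
            counts[f"{st.disease}_{st.sex}_post_qc"] = report.n_snps_after
            report.write_tsv(out / f"qc_{st.disease}_{st.sex}.tsv")
        counts["multiplier"] = mult_used
        counts["tested"] = len(results_all)
        write_results_tsv(results_all, out / "results.tsv")
        write_results_full(results_all, out / "results_full.tsv")
        checkpoint(stage)
    except PipelineError:
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise PipelineError(stage, str(exc)) from exc

    return manifest
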