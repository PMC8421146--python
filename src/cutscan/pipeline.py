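"""End-to-end orchestration: scan -> call-offtargets -> classify -> consensus.

Stages run in order from a single structured config, each filter logs record
counts in/out, every output file is checksummed into a manifest, and reruns
with an identical config + seed reproduce byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from pyfaidx import Fasta

from cutscan import __version__
from cutscan import consensus_analysis, editing_outcomes, offtarget_calling
from cutscan.genome_scan import (
    GuideTarget,
    enumerate_candidates,
    write_candidates,
)
from cutscan.synthetic_data import PLASMID_NAME, read_junctions

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, guide definition and thresholds for one end-to-end run."""

    genome: str
    junctions: str
    outdir: str
    guide: GuideTarget
    plasmid: str | None = None
    max_mismatches: int = 7
    min_junctions: int = 4
    proximal_radius: int = 20_000
    ot_radius: int = 100
    ld_threshold: int = 100
    cut_window: int = offtarget_calling.DEFAULT_CUT_WINDOW
    region_window: int = offtarget_calling.DEFAULT_REGION_WINDOW
    binsize: int = 100
    denominator: str = "editing_events"
    pam_pattern: str | None = None  # scan pattern; default NNN (unconstrained)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_mismatches",
            "min_junctions",
            "proximal_radius",
            "ot_radius",
            "ld_threshold",
            "cut_window",
            "region_window",
            "binsize",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["guide"] = GuideTarget.from_dict(d["guide"])
        return cls(**d)


def _load_fasta(path) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, rebuild=False)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the report dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "max_mismatches": config.max_mismatches,
            "min_junctions": config.min_junctions,
            "proximal_radius": config.proximal_radius,
            "ot_radius": config.ot_radius,
            "ld_threshold": config.ld_threshold,
            "cut_window": config.cut_window,
            "region_window": config.region_window,
            "binsize": config.binsize,
        },
        "stages": {},
        "checksums": {},
    }
    outputs: list[Path] = []

    # --- scan ---
    try:
        genome = _load_fasta(config.genome)
        pattern = config.pam_pattern or "NNN"
        candidates = enumerate_candidates(
            genome, config.guide, config.max_mismatches, pattern
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("scan", str(exc)) from exc
    cand_path = outdir / "candidates.tsv"
    write_candidates(candidates, cand_path)
    outputs.append(cand_path)
    manifest["stages"]["scan"] = {"candidates": len(candidates)}
    logger.info("scan: %d candidate sites", len(candidates))

    # --- call-offtargets ---
    try:
        junctions = read_junctions(config.junctions)
        distal = offtarget_calling.exclude_proximal(
            junctions, config.guide, config.proximal_radius
        )
        regions = offtarget_calling.find_enriched_regions(
            distal, window=config.region_window
        )
        calls = offtarget_calling.call_hotspots(
            regions,
            candidates,
            config.guide,
            cut_window=config.cut_window,
            proximal_radius=config.proximal_radius,
        )
    except FileNotFoundError as exc:
        raise StageError("call-offtargets", str(exc)) from exc
    except Exception as exc:  # noqa: BLE001
        raise StageError("call-offtargets", str(exc)) from exc
    calls_path = outdir / "offtargets.tsv"
    offtarget_calling.write_calls(calls, calls_path)
    outputs.append(calls_path)
    manifest["stages"]["call-offtargets"] = {
        "junctions_in": int(len(junctions)),
        "junctions_distal": int(len(distal)),
        "regions": len(regions),
        "calls": len(calls),
    }
    logger.info(
        "call-offtargets: %d junctions -> %d distal -> %d regions -> %d calls",
        len(junctions), len(distal), len(regions), len(calls),
    )

    # --- classify ---
    try:
        known = set(genome) | {PLASMID_NAME}
        classified = editing_outcomes.classify_table(
            junctions,
            config.guide,
            calls,
            known_refs=known,
            ld_threshold=config.ld_threshold,
            proximal_radius=config.proximal_radius,
            ot_radius=config.ot_radius,
        )
        summary = editing_outcomes.summarize(classified)
        if config.plasmid and summary.counts["plasmid_insertion"] > 0:
            plasmid = _load_fasta(config.plasmid)
            plasmid_length = len(next(iter(plasmid.values())))
            try:
                rate, profile = editing_outcomes.plasmid_profile(
                    classified,
                    plasmid_length,
                    denominator=config.denominator,
                    binsize=config.binsize,
                )
                summary.plasmid_junctions_per_100k = rate
                summary.plasmid_bin_profile = [int(x) for x in profile]
                prof_path = outdir / "plasmid_profile.tsv"
                editing_outcomes.profile_to_frame(profile, config.binsize).to_csv(
                    prof_path, sep="\t", index=False
                )
                outputs.append(prof_path)
            except ZeroDivisionError:
                logger.warning("plasmid profile skipped: empty denominator")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", str(exc)) from exc
    classified_path = outdir / "classified.tsv"
    classified.to_csv(classified_path, sep="\t", index=False)
    summary_path = outdir / "summary.json"
    summary.save(summary_path)
    outputs += [classified_path, summary_path]
    manifest["stages"]["classify"] = {"events": summary.total_events}
    logger.info("classify: %d events, efficiency %.2f%%",
                summary.total_events, summary.editing_efficiency)

    # --- consensus ---
    try:
        consensus: dict = {"off_target_count": len(calls)}
        if calls:
            sites = [c.site for c in calls]
            pfm = consensus_analysis.build_pfm(sites)
            pfm_path = outdir / "pfm.tsv"
            pfm.to_frame().to_csv(pfm_path, sep="\t", index=False)
            outputs.append(pfm_path)
            consensus["pam_stats"] = consensus_analysis.pam_position_stats(sites)
            consensus["mismatch_distribution"] = {
                str(k): v
                for k, v in consensus_analysis.mismatch_distribution(sites).items()
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("consensus", str(exc)) from exc
    consensus_path = outdir / "consensus.json"
    consensus_path.write_text(json.dumps(consensus, indent=1) + "\n")
    outputs.append(consensus_path)
    manifest["stages"]["consensus"] = {"off_target_count": len(calls)}

    report = make_report(summary, calls, consensus)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1) + "\n")
    text_path = outdir / "report.txt"
    text_path.write_text(_report_text(report))
    outputs += [report_path, text_path]

    for path in outputs:
        manifest["checksums"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return report


def make_report(
    summary: editing_outcomes.EditingSummary,
    calls,
    consensus: Mapping,
    reference: editing_outcomes.EditingSummary | None = None,
) -> dict:
    """Assemble the run summary; adds fold-change fields when a reference
    library summary is supplied."""
    report = {
        "editing_efficiency": summary.editing_efficiency,
        "total_events": summary.total_events,
        "off_target_count": len(calls),
        "class_rates": {
            "indel": summary.indel_rate,
            "large_deletion": summary.large_deletion_rate,
            "offtarget_translocation": summary.offtarget_translocation_rate,
            "general_translocation": summary.general_translocation_rate,
            "plasmid_insertion": summary.plasmid_insertion_rate,
        },
        "counts": dict(summary.counts),
    }
    if summary.plasmid_junctions_per_100k is not None:
        report["plasmid_junctions_per_100k"] = summary.plasmid_junctions_per_100k
    if "pam_stats" in consensus:
        report["pam_composition"] = consensus["pam_stats"]
    if reference is not None:
        report["fold_change_vs_reference"] = {}
        for metric in (
            "large_deletion_rate",
            "general_translocation_rate",
            "offtarget_translocation_rate",
            "editing_efficiency",
        ):
            try:
                report["fold_change_vs_reference"][metric] = (
                    editing_outcomes.fold_change(summary, reference, metric)
                )
            except ZeroDivisionError:
                report["fold_change_vs_reference"][metric] = None
    return report


def _report_text(report: Mapping) -> str:
    lines = [
        "cutscan run report",
        "==================",
        f"total events:            {report['total_events']}",
        f"editing efficiency:      {report['editing_efficiency']:.2f}%",
        f"off-target calls:        {report['off_target_count']}",
    ]
    for name, value in report["class_rates"].items():
        lines.append(f"  {name + ':':<24} {value:.2f}%")
    if "plasmid_junctions_per_100k" in report:
        lines.append(
            f"plasmid junctions/100k:  {report['plasmid_junctions_per_100k']:.1f}"
        )
    if "fold_change_vs_reference" in report:
        lines.append("fold change vs reference:")
        for metric, ratio in report["fold_change_vs_reference"].items():
            shown = "n/a" if ratio is None else f"{ratio:.3f}"
            lines.append(f"  {metric + ':':<24} {shown}")
    return "\n".join(lines) + "\n"
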