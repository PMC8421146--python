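"""Classification of junctions into editing-outcome classes and summary metrics.

Each deduplicated junction record is assigned exactly one class: uncut,
indel, large deletion (> 100 bp on the bait chromosome), off-target
translocation (within ±100 bp of a called off-target cut), general
translocation, or plasmid insertion.  Summaries report editing efficiency,
per-class rates, fold changes between libraries, and plasmid-integration
metrics normalized per 100k events with a 100-bp binned profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cutscan.genome_scan import GuideTarget
from cutscan.offtarget_calling import OffTargetCall
from cutscan.synthetic_data import OUTCOME_CLASSES, PLASMID_NAME

DEFAULT_LD_THRESHOLD = 100
DEFAULT_PROXIMAL_RADIUS = 20_000
DEFAULT_OT_RADIUS = 100
DEFAULT_BINSIZE = 100

EDITED_CLASSES = (
    "indel",
    "large_deletion",
    "offtarget_translocation",
    "general_translocation",
    "plasmid_insertion",
)


@dataclass
class EditingSummary:
    """Per-library outcome counts and rates (percent scale)."""

    counts: dict[str, int]
    total_events: int
    editing_efficiency: float
    large_deletion_rate: float
    offtarget_translocation_rate: float
    general_translocation_rate: float
    indel_rate: float
    plasmid_insertion_rate: float
    plasmid_junctions_per_100k: float | None = None
    plasmid_bin_profile: list[int] | None = None

    def metric(self, name: str) -> float:
        try:
            return float(getattr(self, name))
        except AttributeError:
            raise KeyError(f"unknown metric {name!r}") from None

    def to_dict(self) -> dict:
        d = {
            "counts": dict(self.counts),
            "total_events": self.total_events,
            "editing_efficiency": self.editing_efficiency,
            "indel_rate": self.indel_rate,
            "large_deletion_rate": self.large_deletion_rate,
            "offtarget_translocation_rate": self.offtarget_translocation_rate,
            "general_translocation_rate": self.general_translocation_rate,
            "plasmid_insertion_rate": self.plasmid_insertion_rate,
        }
        if self.plasmid_junctions_per_100k is not None:
            d["plasmid_junctions_per_100k"] = self.plasmid_junctions_per_100k
        if self.plasmid_bin_profile is not None:
            d["plasmid_bin_profile"] = list(self.plasmid_bin_profile)
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def _offtarget_cut_positions(
    offtargets: Sequence[OffTargetCall] | pd.DataFrame,
) -> list[tuple[str, int]]:
    """Accepts OffTargetCall objects or a calls BED frame."""
    if isinstance(offtargets, pd.DataFrame):
        out = []
        for _, row in offtargets.iterrows():
            start = int(row["start"])
            cut = start + 17 if str(row["strand"]) == "+" else start + 6
            out.append((str(row["chrom"]), cut))
        return out
    return [(c.site.chrom, c.cut_position) for c in offtargets]


def classify_junction(
    prey_ref: str,
    prey_pos: int,
    junction_present: int,
    guide: GuideTarget,
    offtarget_cuts: Sequence[tuple[str, int]],
    ld_threshold: int = DEFAULT_LD_THRESHOLD,
    proximal_radius: int = DEFAULT_PROXIMAL_RADIUS,
    ot_radius: int = DEFAULT_OT_RADIUS,
) -> str:
    """Assign one outcome class to a single junction record.

    Rule order: no junction -> uncut; plasmid prey -> plasmid_insertion;
    bait-chromosome prey within ``ld_threshold`` of the cut -> indel; within
    ``proximal_radius`` -> large_deletion; within ``ot_radius`` of a called
    off-target cut (any chromosome) -> offtarget_translocation; everything
    else -> general_translocation.
    """
    if not junction_present:
        return "uncut"
    if prey_ref == PLASMID_NAME:
        return "plasmid_insertion"
    if prey_ref == guide.chrom:
        d = abs(int(prey_pos) - guide.cut_position)
        if d <= ld_threshold:
            return "indel"
        if d <= proximal_radius:
            return "large_deletion"
    for chrom, cut in offtarget_cuts:
        if prey_ref == chrom and abs(int(prey_pos) - cut) <= ot_radius:
            return "offtarget_translocation"
    return "general_translocation"


def classify_table(
    junctions: pd.DataFrame,
    guide: GuideTarget,
    offtargets: Sequence[OffTargetCall] | pd.DataFrame = (),
    known_refs: Iterable[str] | None = None,
    ld_threshold: int = DEFAULT_LD_THRESHOLD,
    proximal_radius: int = DEFAULT_PROXIMAL_RADIUS,
    ot_radius: int = DEFAULT_OT_RADIUS,
) -> pd.DataFrame:
    """Classify every row; returns a copy with an ``outcome`` column appended.

    ``known_refs``, when given, is the set of valid prey references (genome
    contigs plus the plasmid); an unknown contig raises with its name.
    """
    cuts = _offtarget_cut_positions(offtargets)
    if known_refs is not None:
        valid = set(known_refs) | {PLASMID_NAME}
        bad = set(junctions["prey_ref"].astype(str)) - valid
        if bad:
            raise ValueError(f"prey reference(s) not in genome/plasmid: {sorted(bad)}")
    out = junctions.copy()
    out["outcome"] = [
        classify_junction(
            str(r.prey_ref),
            int(r.prey_pos),
            int(r.junction_present),
            guide,
            cuts,
            ld_threshold=ld_threshold,
            proximal_radius=proximal_radius,
            ot_radius=ot_radius,
        )
        for r in junctions.itertuples(index=False)
    ]
    return out


def summarize(classified: pd.DataFrame) -> EditingSummary:
    """Aggregate a classified table into counts and percent rates.

    Editing efficiency is the total percentage of edited alleles (indels,
    large deletions, translocations and plasmid insertions) over all events.
    """
    total = int(len(classified))
    if total == 0:
        raise ValueError("cannot summarize an empty table (total_events = 0)")
    counts = {c: 0 for c in OUTCOME_CLASSES}
    for c, n in classified["outcome"].value_counts().items():
        if c not in counts:
            raise ValueError(f"unknown outcome class {c!r}")
        counts[c] = int(n)
    edited = sum(counts[c] for c in EDITED_CLASSES)

    def rate(c: str) -> float:
        return 100.0 * counts[c] / total

    return EditingSummary(
        counts=counts,
        total_events=total,
        editing_efficiency=100.0 * edited / total,
        indel_rate=rate("indel"),
        large_deletion_rate=rate("large_deletion"),
        offtarget_translocation_rate=rate("offtarget_translocation"),
        general_translocation_rate=rate("general_translocation"),
        plasmid_insertion_rate=rate("plasmid_insertion"),
    )


def fold_change(summary: EditingSummary, reference: EditingSummary, metric: str) -> float:
    """Ratio of a metric between a library and a reference library."""
    ref = reference.metric(metric)
    if ref == 0:
        raise ZeroDivisionError(f"reference metric {metric!r} is zero")
    return summary.metric(metric) / ref


def plasmid_profile(
    classified: pd.DataFrame,
    plasmid_length: int,
    denominator: str = "editing_events",
    binsize: int = DEFAULT_BINSIZE,
) -> tuple[float, np.ndarray]:
    """Plasmid-junction rate per 100k and a binned positional profile.

    ``denominator`` selects the normalizer: ``editing_events`` (all edited
    alleles) or ``on_target_indels`` (indel class only).
    """
    if denominator not in ("editing_events", "on_target_indels"):
        raise ValueError(f"unknown denominator {denominator!r}")
    outcome = classified["outcome"]
    n_plasmid = int((outcome == "plasmid_insertion").sum())
    if denominator == "editing_events":
        denom = int(outcome.isin(EDITED_CLASSES).sum())
    else:
        denom = int((outcome == "indel").sum())
    if denom == 0:
        raise ZeroDivisionError(f"denominator {denominator!r} count is zero")
    rate = n_plasmid / denom * 100_000.0

    n_bins = int(np.ceil(plasmid_length / binsize))
    profile = np.zeros(n_bins, dtype=np.int64)
    mask = (outcome == "plasmid_insertion").to_numpy()
    if mask.any():
        pos = classified.loc[mask, "prey_pos"].to_numpy(dtype=np.int64)
        bins = np.clip(pos // binsize, 0, n_bins - 1)
        np.add.at(profile, bins, 1)
    return rate, profile


def profile_to_frame(profile: np.ndarray, binsize: int = DEFAULT_BINSIZE) -> pd.DataFrame:
    starts = np.arange(len(profile)) * binsize
    return pd.DataFrame(
        {"bin_start": starts, "bin_end": starts + binsize, "count": profile}
    )
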