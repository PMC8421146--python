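"""Off-target hotspot calling from translocation junction tables.

Junctions proximal to the on-target break (±20 kb by default) are excluded,
remaining prey positions are clustered into junction-enriched regions
(a deterministic gap-clustering stand-in for a peak caller), and regions are
matched to homologous candidate sites.  A candidate becomes a hotspot call
when it has fewer than 8 protospacer mismatches and more than 3 junctions
within a window around its presumable cut site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cutscan.genome_scan import CandidateSite, GuideTarget

DEFAULT_PROXIMAL_RADIUS = 20_000
DEFAULT_REGION_WINDOW = 100
DEFAULT_REGION_MIN_JUNCTIONS = 2
DEFAULT_CUT_WINDOW = 25
MAX_MISMATCHES_CALLED = 7  # "< 8 mismatches"
MIN_JUNCTIONS_CALLED = 4  # "> 3 junctions"


@dataclass
class EnrichedRegion:
    """A cluster of junction prey positions on one chromosome."""

    chrom: str
    start: int
    end: int
    junction_count: int
    summit: int
    positions: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.junction_count < 1:
            raise ValueError("junction_count must be >= 1")
        if not self.start < self.end:
            raise ValueError("start must be < end")


@dataclass
class OffTargetCall:
    """A candidate site with junction support at its presumable cut site."""

    site: CandidateSite
    junction_count: int
    region: EnrichedRegion
    ambiguous: bool = False

    @property
    def cut_position(self) -> int:
        return self.site.cut_position

    def validate(self, guide: GuideTarget, proximal_radius: int = DEFAULT_PROXIMAL_RADIUS) -> None:
        if not self.site.mismatch_count < 8:
            raise ValueError("off-target call with >= 8 mismatches")
        if not self.junction_count > 3:
            raise ValueError("off-target call with <= 3 junctions")
        if (
            self.site.chrom == guide.chrom
            and abs(self.cut_position - guide.cut_position) <= proximal_radius
        ):
            raise ValueError("off-target call within the proximal exclusion zone")


def exclude_proximal(
    junctions: pd.DataFrame,
    guide: GuideTarget,
    radius: int = DEFAULT_PROXIMAL_RADIUS,
) -> pd.DataFrame:
    """Drop rows whose prey lies within ±radius of the on-target cut.

    Rows without a junction (germline records) are dropped too, since they
    carry no prey.  Prey on other chromosomes or on the plasmid are kept.
    """
    if junctions.empty:
        return junctions.copy()
    has_junction = junctions["junction_present"].astype(int) == 1
    same_chrom = junctions["prey_ref"].astype(str) == guide.chrom
    proximal = same_chrom & (
        (junctions["prey_pos"] - guide.cut_position).abs() <= radius
    )
    return junctions.loc[has_junction & ~proximal].copy()


def find_enriched_regions(
    junctions: pd.DataFrame,
    window: int = DEFAULT_REGION_WINDOW,
    min_junctions: int = DEFAULT_REGION_MIN_JUNCTIONS,
) -> list[EnrichedRegion]:
    """Single-linkage clustering of genomic prey positions per chromosome.

    Consecutive sorted positions with gap <= ``window`` join one cluster;
    clusters with >= ``min_junctions`` members become regions.  The summit is
    the modal prey position (leftmost on ties).  Plasmid prey are ignored
    here (they are handled by the outcome classifier).
    """
    regions: list[EnrichedRegion] = []
    if junctions.empty:
        return regions
    genomic = junctions.loc[
        (junctions["junction_present"].astype(int) == 1)
        & (junctions["prey_ref"].astype(str) != "plasmid")
    ]
    for chrom, grp in sorted(genomic.groupby("prey_ref", sort=True)):
        pos = np.sort(grp["prey_pos"].to_numpy(dtype=np.int64))
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > window)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for a, b in zip(starts, ends):
            members = pos[a:b]
            if len(members) < min_junctions:
                continue
            vals, counts = np.unique(members, return_counts=True)
            summit = int(vals[np.argmax(counts)])
            regions.append(
                EnrichedRegion(
                    chrom=str(chrom),
                    start=int(members[0]),
                    end=int(members[-1]) + 1,
                    junction_count=int(len(members)),
                    summit=summit,
                    positions=members,
                )
            )
    return regions


def call_hotspots(
    regions: Sequence[EnrichedRegion],
    candidates: Sequence[CandidateSite],
    guide: GuideTarget,
    cut_window: int = DEFAULT_CUT_WINDOW,
    proximal_radius: int = DEFAULT_PROXIMAL_RADIUS,
) -> list[OffTargetCall]:
    """Match enriched regions to candidate sites and apply the hotspot rules.

    A candidate is called iff it has < 8 protospacer mismatches, is not the
    on-target site (or within the proximal exclusion zone), and more than 3
    junctions fall within ± ``cut_window`` of its presumable cut position.
    Candidates sharing supporting junctions with another called candidate are
    flagged ambiguous.  Output is sorted by descending junction count, then
    (chrom, start, strand).
    """
    calls: list[OffTargetCall] = []
    by_chrom: dict[str, list[EnrichedRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    for cand in candidates:
        if cand.mismatch_count >= 8:
            continue
        cut = cand.cut_position
        if (
            cand.chrom == guide.chrom
            and abs(cut - guide.cut_position) <= proximal_radius
        ):
            continue
        best: tuple[int, EnrichedRegion] | None = None
        for region in by_chrom.get(cand.chrom, []):
            n = int(
                np.count_nonzero(np.abs(region.positions - cut) <= cut_window)
            )
            if n >= MIN_JUNCTIONS_CALLED and (best is None or n > best[0]):
                best = (n, region)
        if best is not None:
            calls.append(
                OffTargetCall(site=cand, junction_count=best[0], region=best[1])
            )

    # flag candidates competing for the same region
    region_users: dict[int, list[OffTargetCall]] = {}
    for call in calls:
        region_users.setdefault(id(call.region), []).append(call)
    for users in region_users.values():
        if len(users) > 1:
            for call in users:
                call.ambiguous = True

    for call in calls:
        call.validate(guide, proximal_radius)
    calls.sort(
        key=lambda c: (
            -c.junction_count,
            c.site.chrom,
            c.site.start,
            c.site.strand,
        )
    )
    return calls


def calls_to_frame(calls: Iterable[OffTargetCall]) -> pd.DataFrame:
    """BED6+ layout with mismatch count, PAM and ambiguity flag appended."""
    rows = [
        {
            "chrom": c.site.chrom,
            "start": c.site.start,
            "end": c.site.end,
            "name": c.site.sequence_23,
            "score": c.junction_count,
            "strand": c.site.strand,
            "mismatch_count": c.site.mismatch_count,
            "pam": c.site.pam,
            "ambiguous": int(c.ambiguous),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "name",
            "score",
            "strand",
            "mismatch_count",
            "pam",
            "ambiguous",
        ],
    )


def write_calls(calls: Iterable[OffTargetCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
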