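"""Synthetic genomes and junction tables with known ground truth.

Generates toy multi-contig genomes carrying a planted on-target site plus
configurable homologous off-target sites (controlled mismatch counts and PAM
composition), a plasmid with a U6-sgRNA-like cassette, and junction tables
drawn from configurable outcome proportions.  Every emitted junction row is
traceable to a truth record, so downstream callers and classifiers can be
tested without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cutscan.genome_scan import (
    PAM_LEN,
    PROTOSPACER_LEN,
    SITE_LEN,
    GuideTarget,
    decode_seq,
    encode_seq,
)

OUTCOME_CLASSES = (
    "uncut",
    "indel",
    "large_deletion",
    "offtarget_translocation",
    "general_translocation",
    "plasmid_insertion",
)

JUNCTION_COLUMNS = (
    "read_id",
    "bait_chrom",
    "bait_pos",
    "bait_strand",
    "prey_ref",
    "prey_pos",
    "prey_strand",
    "junction_present",
)

PLASMID_NAME = "plasmid"

#: ±jitter (bp) of simulated junctions around a planted off-target cut site.
#: Stand-in for resection scatter; must stay well inside the hotspot-calling
#: cut window.
OFFTARGET_JITTER = 10

#: Exclusion radius around the on-target cut for general-translocation prey.
GENERAL_EXCLUSION_ON_TARGET = 20_000
#: Exclusion radius around planted off-target cuts for general prey.
GENERAL_EXCLUSION_OFF_TARGET = 100


@dataclass(frozen=True)
class PlantedSite:
    """Requested homologous site: mismatch count, PAM and location."""

    mismatch_count: int
    pam: str
    chrom: str
    position: int  # 0-based start of the 23-nt site, plus strand

    def __post_init__(self) -> None:
        if not 0 <= self.mismatch_count <= 12:
            raise ValueError("mismatch_count must be in 0..12")
        if len(self.pam) != PAM_LEN:
            raise ValueError("pam must be 3 nt")


@dataclass
class SyntheticConfig:
    """Parameters for one synthetic library."""

    genome_length: int = 100_000
    chrom_count: int = 2
    planted_sites: Sequence[PlantedSite] = ()
    outcome_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "uncut": 0.4,
            "indel": 0.35,
            "large_deletion": 0.08,
            "offtarget_translocation": 0.1,
            "general_translocation": 0.05,
            "plasmid_insertion": 0.02,
        }
    )
    n_events: int = 10_000
    resection_length_distribution: tuple[int, int] = (200, 5_000)
    seed: int = 0
    # plumbing knobs (defaulted, not part of the core contract)
    protospacer: str | None = None  # random if None
    canonical_pam: str = "AGG"
    on_target_position: int | None = None  # mid chrom1 if None
    plasmid_length: int = 3_000

    def __post_init__(self) -> None:
        self.planted_sites = [
            s if isinstance(s, PlantedSite) else PlantedSite(*s)
            for s in self.planted_sites
        ]
        self.validate()

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.chrom_count

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.chrom_count)]

    def validate(self) -> None:
        props = dict(self.outcome_proportions)
        unknown = set(props) - set(OUTCOME_CLASSES)
        if unknown:
            raise ValueError(f"unknown outcome classes: {sorted(unknown)}")
        if any(v < 0 for v in props.values()):
            raise ValueError("outcome proportions must be >= 0")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome proportions must sum to 1, got {total}")
        lo, hi = self.resection_length_distribution
        if not (100 < lo <= hi):
            raise ValueError("resection lengths must satisfy 100 < min <= max")
        names = set(self.chrom_names())
        for s in self.planted_sites:
            if s.chrom not in names:
                raise ValueError(f"planted site on unknown contig {s.chrom}")
            if not (SITE_LEN <= s.position <= self.chrom_length - 2 * SITE_LEN):
                raise ValueError(
                    f"planted site at {s.chrom}:{s.position} lacks 23-nt margin"
                )

    def proportions_vector(self) -> np.ndarray:
        return np.array(
            [self.outcome_proportions.get(c, 0.0) for c in OUTCOME_CLASSES]
        )

    def to_dict(self) -> dict:
        return {
            "genome_length": self.genome_length,
            "chrom_count": self.chrom_count,
            "planted_sites": [
                [s.mismatch_count, s.pam, s.chrom, s.position]
                for s in self.planted_sites
            ],
            "outcome_proportions": dict(self.outcome_proportions),
            "n_events": self.n_events,
            "resection_length_distribution": list(self.resection_length_distribution),
            "seed": self.seed,
            "protospacer": self.protospacer,
            "canonical_pam": self.canonical_pam,
            "on_target_position": self.on_target_position,
            "plasmid_length": self.plasmid_length,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "planted_sites" in d:
            d["planted_sites"] = [PlantedSite(*s) for s in d["planted_sites"]]
        if "resection_length_distribution" in d:
            d["resection_length_distribution"] = tuple(
                d["resection_length_distribution"]
            )
        return cls(**d)


@dataclass
class TruthSite:
    """A planted homologous site with its realized sequence."""

    chrom: str
    start: int  # 0-based start of the 23-nt site
    strand: str
    sequence_23: str
    mismatch_count: int
    pam: str

    @property
    def cut_position(self) -> int:
        return self.start + 17 if self.strand == "+" else self.start + 6


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic library."""

    guide: GuideTarget
    on_target: TruthSite
    off_targets: list[TruthSite]
    event_classes: list[str] = field(default_factory=list)
    offtarget_junction_counts: dict[int, int] = field(default_factory=dict)
    event_offtarget_index: list[int | None] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in OUTCOME_CLASSES}
        for c in self.event_classes:
            counts[c] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "guide": self.guide.to_dict(),
            "on_target": vars(self.on_target),
            "off_targets": [vars(s) for s in self.off_targets],
            "event_classes": self.event_classes,
            "offtarget_junction_counts": {
                str(k): v for k, v in self.offtarget_junction_counts.items()
            },
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def _random_protospacer(rng: np.random.Generator) -> str:
    return decode_seq(rng.integers(0, 4, PROTOSPACER_LEN))


def _mutate_protospacer(
    proto: str, n_mismatches: int, rng: np.random.Generator
) -> str:
    codes = encode_seq(proto).copy()
    pos = rng.choice(PROTOSPACER_LEN, size=n_mismatches, replace=False)
    for p in pos:
        codes[p] = (codes[p] + rng.integers(1, 4)) % 4
    return decode_seq(codes)


def generate_reference(
    config: SyntheticConfig,
) -> tuple[dict[str, str], str, GuideTarget, SyntheticTruth]:
    """Build the toy genome, plasmid, guide and truth records.

    The background is i.i.d. uniform over A/C/G/T from the seed.  Each
    planted site differs from the on-target protospacer at exactly its
    requested mismatch count (positions chosen uniformly without
    replacement) and carries its requested PAM.  The on-target site is
    planted with 0 mismatches and the canonical PAM.  The plasmid carries a
    U6-sgRNA-like cassette whose spacer matches the protospacer.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    protospacer = (config.protospacer or _random_protospacer(rng)).upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError("protospacer must be 20 nt")

    chrom_len = config.chrom_length
    genome = {
        name: decode_seq(rng.integers(0, 4, chrom_len))
        for name in config.chrom_names()
    }

    on_chrom = config.chrom_names()[0]
    on_pos = (
        config.on_target_position
        if config.on_target_position is not None
        else chrom_len // 2
    )
    guide = GuideTarget(
        protospacer=protospacer,
        pam_pattern=config.canonical_pam,
        chrom=on_chrom,
        protospacer_start=on_pos,
        strand="+",
    )

    # collision check over all planted intervals (incl. on-target)
    intervals = [(on_chrom, on_pos, on_pos + SITE_LEN, "on-target")]
    for i, s in enumerate(config.planted_sites):
        intervals.append((s.chrom, s.position, s.position + SITE_LEN, f"site{i}"))
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv[0], []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda x: x[1])
        for a, b in zip(ivs, ivs[1:]):
            if b[1] < a[2]:
                raise ValueError(
                    f"planted sites overlap on {chrom}: {a[3]} and {b[3]}"
                )

    def plant(chrom: str, pos: int, site_seq: str) -> None:
        s = genome[chrom]
        genome[chrom] = s[:pos] + site_seq + s[pos + SITE_LEN :]

    on_seq = protospacer + config.canonical_pam.upper()
    plant(on_chrom, on_pos, on_seq)
    on_target = TruthSite(
        chrom=on_chrom,
        start=on_pos,
        strand="+",
        sequence_23=on_seq,
        mismatch_count=0,
        pam=config.canonical_pam.upper(),
    )

    off_targets: list[TruthSite] = []
    for s in config.planted_sites:
        mutated = _mutate_protospacer(protospacer, s.mismatch_count, rng)
        site_seq = mutated + s.pam.upper()
        plant(s.chrom, s.position, site_seq)
        off_targets.append(
            TruthSite(
                chrom=s.chrom,
                start=s.position,
                strand="+",
                sequence_23=site_seq,
                mismatch_count=s.mismatch_count,
                pam=s.pam.upper(),
            )
        )

    # plasmid with a U6-sgRNA-like cassette: CACC + spacer + GTTT
    cassette = "CACC" + protospacer + "GTTT"
    backbone = decode_seq(rng.integers(0, 4, config.plasmid_length))
    ins = config.plasmid_length // 3
    plasmid = backbone[:ins] + cassette + backbone[ins + len(cassette) :]

    truth = SyntheticTruth(guide=guide, on_target=on_target, off_targets=off_targets)
    return genome, plasmid, guide, truth


def simulate_junctions(
    truth: SyntheticTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Draw ``n_events`` junction records i.i.d. from the outcome proportions.

    Prey placement per class:

    - ``uncut``: no-junction germline record (prey = bait, junction_present 0)
    - ``indel``: same chromosome within 100 bp of the cut
    - ``large_deletion``: same chromosome at a resection distance drawn from
      ``resection_length_distribution`` (always > 100 bp)
    - ``offtarget_translocation``: a planted site's cut position ± 0-10 bp
    - ``general_translocation``: uniform over the genome excluding ±20 kb of
      the on-target and ±100 bp of planted sites
    - ``plasmid_insertion``: uniform over the plasmid

    Truth is updated in place with per-event classes and per-off-target
    junction counts.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    probs = config.proportions_vector()
    if truth.off_targets == [] and probs[OUTCOME_CLASSES.index("offtarget_translocation")] > 0:
        raise ValueError(
            "offtarget_translocation proportion > 0 but no planted off-targets"
        )

    guide = truth.guide
    cut = guide.cut_position
    chrom_len = config.chrom_length
    chroms = config.chrom_names()
    lo, hi = config.resection_length_distribution

    classes = rng.choice(len(OUTCOME_CLASSES), size=config.n_events, p=probs)

    # precompute exclusion zones for general translocations
    exclusions: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    exclusions[guide.chrom].append(
        (cut - GENERAL_EXCLUSION_ON_TARGET, cut + GENERAL_EXCLUSION_ON_TARGET)
    )
    for ot in truth.off_targets:
        exclusions[ot.chrom].append(
            (
                ot.cut_position - GENERAL_EXCLUSION_OFF_TARGET,
                ot.cut_position + GENERAL_EXCLUSION_OFF_TARGET,
            )
        )

    def general_prey() -> tuple[str, int]:
        for _ in range(10_000):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(chrom_len))
            if all(not (a <= pos <= b) for a, b in exclusions[chrom]):
                return chrom, pos
        raise RuntimeError("could not place a general-translocation prey")

    rows = []
    truth.event_classes = []
    truth.event_offtarget_index = []
    counts: dict[int, int] = {i: 0 for i in range(len(truth.off_targets))}
    for i, ci in enumerate(classes):
        cls = OUTCOME_CLASSES[ci]
        ot_index: int | None = None
        strand = "+" if rng.random() < 0.5 else "-"
        if cls == "uncut":
            prey_ref, prey_pos, present = guide.chrom, cut, 0
            strand = "+"
        elif cls == "indel":
            prey_ref = guide.chrom
            prey_pos = cut + int(rng.integers(-100, 101))
            present = 1
        elif cls == "large_deletion":
            dist = int(rng.integers(lo, hi + 1))
            sign = 1 if rng.random() < 0.5 else -1
            pos = cut + sign * dist
            if not 0 <= pos < chrom_len:
                pos = cut - sign * dist
            prey_ref, prey_pos, present = guide.chrom, pos, 1
        elif cls == "offtarget_translocation":
            ot_index = int(rng.integers(len(truth.off_targets)))
            ot = truth.off_targets[ot_index]
            prey_ref = ot.chrom
            prey_pos = ot.cut_position + int(
                rng.integers(-OFFTARGET_JITTER, OFFTARGET_JITTER + 1)
            )
            present = 1
            counts[ot_index] += 1
        elif cls == "general_translocation":
            prey_ref, prey_pos = general_prey()
            present = 1
        else:  # plasmid_insertion
            prey_ref = PLASMID_NAME
            prey_pos = int(rng.integers(config.plasmid_length))
            present = 1
        rows.append(
            (
                f"evt{i:06d}",
                guide.chrom,
                cut,
                "+",
                prey_ref,
                int(prey_pos),
                strand,
                present,
            )
        )
        truth.event_classes.append(cls)
        truth.event_offtarget_index.append(ot_index)

    truth.offtarget_junction_counts = {k: v for k, v in counts.items() if v > 0}
    return pd.DataFrame(rows, columns=list(JUNCTION_COLUMNS))


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_junctions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"bait_chrom": str, "prey_ref": str})
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction table missing columns: {sorted(missing)}")
    return df


def write_junctions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
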