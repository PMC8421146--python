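"""Genome-wide enumeration and scoring of guide-homologous sites.

A *candidate site* is a 23-nt genomic window (20-nt protospacer + 3-nt PAM,
reported in guide orientation) whose protospacer portion lies within a
mismatch budget of the on-target protospacer and whose PAM matches a
(possibly degenerate) pattern.  Candidates feed both the hotspot caller and
the CNN ranker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_LEN = 23
PROTOSPACER_LEN = 20
PAM_LEN = 3

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = "ACGT"

# IUPAC subset used for PAM patterns.
_IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode A/C/G/T as int8 codes 0..3; any other character becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_seq(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[c] for c in codes)


def _pam_allowed_table(pam_pattern: str) -> np.ndarray:
    """(3, 4) boolean table: allowed[i, code] for PAM position i."""
    if len(pam_pattern) != PAM_LEN:
        raise ValueError(f"PAM pattern must be {PAM_LEN} characters, got {pam_pattern!r}")
    table = np.zeros((PAM_LEN, 4), dtype=bool)
    for i, ch in enumerate(pam_pattern.upper()):
        try:
            allowed = _IUPAC_SETS[ch]
        except KeyError:
            raise ValueError(
                f"unsupported PAM pattern character {ch!r} (allowed: N,R,Y,A,C,G,T)"
            ) from None
        for b in allowed:
            table[i, _BASE_TO_CODE[b]] = True
    return table


def count_mismatches(a: str, b: str) -> int:
    """Hamming distance between two equal-length ACGT protospacers.

    No gaps are considered; comparison is position by position.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences have unequal lengths ({len(a)} vs {len(b)})")
    au, bu = a.upper(), b.upper()
    for s in (au, bu):
        if any(ch not in _BASE_TO_CODE for ch in s):
            raise ValueError(f"non-ACGT character in sequence {s!r}")
    return sum(x != y for x, y in zip(au, bu))


def classify_pam(pam: str) -> dict:
    """Classify a 3-nt PAM by its second/third nucleotides.

    Category is NRN when the second nucleotide is a purine (A/G) and NYN
    when it is a pyrimidine (C/T).
    """
    pam = pam.upper()
    if len(pam) != PAM_LEN or any(ch not in _BASE_TO_CODE for ch in pam):
        raise ValueError(f"PAM must be 3 characters over ACGT, got {pam!r}")
    second, third = pam[1], pam[2]
    category = "NRN" if second in "AG" else "NYN"
    return {"second_nt": second, "third_nt": third, "category": category}


@dataclass(frozen=True)
class GuideTarget:
    """A protospacer + PAM definition anchored to a genome coordinate.

    ``protospacer_start`` is the 0-based genomic start of the 20-nt
    protospacer.  The cut position is the blunt cleavage point between
    protospacer positions 17 and 18 (3 bp 5' of the PAM), expressed as a
    genomic insertion coordinate.
    """

    protospacer: str
    pam_pattern: str
    chrom: str
    protospacer_start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"protospacer must be {PROTOSPACER_LEN} nt, got {len(self.protospacer)}"
            )
        if any(ch not in _BASE_TO_CODE for ch in self.protospacer.upper()):
            raise ValueError("protospacer contains non-ACGT characters")
        if len(self.pam_pattern) != PAM_LEN:
            raise ValueError("pam_pattern must be 3 characters")
        _pam_allowed_table(self.pam_pattern)  # validates alphabet
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def cut_position(self) -> int:
        if self.strand == "+":
            return self.protospacer_start + 17
        return self.protospacer_start + 3

    @property
    def site_start(self) -> int:
        """Genomic start of the full 23-nt site (protospacer + PAM)."""
        if self.strand == "+":
            return self.protospacer_start
        return self.protospacer_start - PAM_LEN

    def to_dict(self) -> dict:
        return {
            "protospacer": self.protospacer.upper(),
            "pam_pattern": self.pam_pattern.upper(),
            "chrom": self.chrom,
            "protospacer_start": self.protospacer_start,
            "strand": self.strand,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GuideTarget":
        return cls(
            protospacer=d["protospacer"],
            pam_pattern=d["pam_pattern"],
            chrom=d["chrom"],
            protospacer_start=int(d["protospacer_start"]),
            strand=d.get("strand", "+"),
        )


@dataclass(frozen=True)
class CandidateSite:
    """A 23-nt genomic site homologous to the guide.

    ``start``/``end`` are 0-based half-open over the full 23-nt window.
    ``sequence_23`` is protospacer(20) + PAM(3) in guide orientation;
    ``mismatch_count`` covers the protospacer only (PAM excluded).
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence_23: str
    mismatch_count: int
    pam: str

    def __post_init__(self) -> None:
        if self.end - self.start != SITE_LEN:
            raise ValueError("candidate site must span exactly 23 nt")

    @property
    def protospacer(self) -> str:
        return self.sequence_23[:PROTOSPACER_LEN]

    @property
    def cut_position(self) -> int:
        """Genomic insertion coordinate of the blunt 17|18 cut."""
        if self.strand == "+":
            return self.start + 17
        return self.start + 6

    def key(self) -> tuple:
        return (self.chrom, self.start, self.strand)


def enumerate_candidates(
    genome: Mapping[str, str],
    guide: GuideTarget,
    max_mismatches: int,
    pam_pattern: str | None = None,
) -> list[CandidateSite]:
    """Enumerate every 23-nt window, both strands, within the mismatch budget.

    Parameters
    ----------
    genome
        Mapping of contig name to sequence (e.g. a :class:`pyfaidx.Fasta`
        wrapped with ``{name: str(rec)}`` or a plain dict).
    guide
        On-target definition; mismatches are counted against its protospacer.
    max_mismatches
        Inclusive protospacer mismatch budget.
    pam_pattern
        IUPAC pattern (N/R/Y + literals) the PAM must match; defaults to the
        guide's own pattern.  ``NNN`` matches everything.

    Returns
    -------
    Candidates sorted by (chrom, start, strand).  Windows containing
    non-ACGT characters are skipped.  Contigs shorter than 23 nt are skipped
    with a logged warning.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    pattern = (pam_pattern or guide.pam_pattern).upper()
    pam_table = _pam_allowed_table(pattern)
    proto = encode_seq(guide.protospacer)

    sites: list[CandidateSite] = []
    for chrom in sorted(genome):
        seq = str(genome[chrom]).upper()
        if len(seq) < SITE_LEN:
            logger.warning("contig %s shorter than %d nt, skipped", chrom, SITE_LEN)
            continue
        arr = encode_seq(seq)
        sites.extend(_scan_strand(arr, chrom, "+", proto, pam_table, max_mismatches))
        # minus strand: scan the reverse complement and map coordinates back
        rc = np.where(arr >= 0, 3 - arr, np.int8(-1))[::-1]
        for site in _scan_strand(rc, chrom, "-", proto, pam_table, max_mismatches):
            start = len(seq) - site.end
            sites.append(
                CandidateSite(
                    chrom=chrom,
                    start=start,
                    end=start + SITE_LEN,
                    strand="-",
                    sequence_23=site.sequence_23,
                    mismatch_count=site.mismatch_count,
                    pam=site.pam,
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def _scan_strand(
    arr: np.ndarray,
    chrom: str,
    strand: str,
    proto: np.ndarray,
    pam_table: np.ndarray,
    max_mismatches: int,
) -> list[CandidateSite]:
    windows = np.lib.stride_tricks.sliding_window_view(arr, SITE_LEN)
    valid = (windows >= 0).all(axis=1)
    mm = (windows[:, :PROTOSPACER_LEN] != proto[None, :]).sum(axis=1)
    pam_codes = windows[:, PROTOSPACER_LEN:]
    pam_ok = np.ones(len(windows), dtype=bool)
    for i in range(PAM_LEN):
        codes = np.clip(pam_codes[:, i], 0, 3)
        pam_ok &= pam_table[i][codes]
    hits = np.flatnonzero(valid & pam_ok & (mm <= max_mismatches))
    out = []
    for idx in hits:
        w = windows[idx]
        out.append(
            CandidateSite(
                chrom=chrom,
                start=int(idx),
                end=int(idx) + SITE_LEN,
                strand=strand,
                sequence_23=decode_seq(w),
                mismatch_count=int(mm[idx]),
                pam=decode_seq(w[PROTOSPACER_LEN:]),
            )
        )
    return out


def candidates_to_frame(sites: Iterable[CandidateSite]) -> pd.DataFrame:
    """BED6+ layout: chrom, start, end, name=sequence_23, score=mismatches, strand, pam."""
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "name": s.sequence_23,
            "score": s.mismatch_count,
            "strand": s.strand,
            "pam": s.pam,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand", "pam"]
    )


def candidates_from_frame(df: pd.DataFrame) -> list[CandidateSite]:
    return [
        CandidateSite(
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
            sequence_23=str(row["name"]),
            mismatch_count=int(row["score"]),
            pam=str(row["pam"]),
        )
        for _, row in df.iterrows()
    ]


def write_candidates(sites: Iterable[CandidateSite], path) -> None:
    candidates_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_candidates(path) -> list[CandidateSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CandidateSite(
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
            sequence_23=str(row["name"]),
            mismatch_count=int(row["score"]),
            pam=str(row["pam"]),
        )
        for _, row in df.iterrows()
    ]
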