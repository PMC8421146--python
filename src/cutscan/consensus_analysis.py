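"""Descriptive statistics over off-target site sets.

Position frequency matrices (logo input), PAM second/third nucleotide
tallies with the purine/pyrimidine (NRN/NYN) split, mismatch-number
histograms, cross-variant overlap partitions, and a paired Wilcoxon
signed-rank comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cutscan.genome_scan import SITE_LEN, CandidateSite, classify_pam, encode_seq

BASES = "ACGT"
DEFAULT_MATCH_RADIUS = 100
EXACT_WILCOXON_MAX_N = 25


@dataclass
class PositionFrequencyMatrix:
    """23 x 4 relative base frequencies (rows: 20 protospacer + 3 PAM)."""

    frequencies: np.ndarray  # (23, 4) over A, C, G, T
    site_count: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(BASES))
        df.insert(0, "position", np.arange(1, SITE_LEN + 1))
        return df


def build_pfm(sites: Sequence[CandidateSite | str]) -> PositionFrequencyMatrix:
    """Column-wise base frequencies over 23-nt sites in guide orientation."""
    seqs = [s.sequence_23 if isinstance(s, CandidateSite) else s for s in sites]
    if not seqs:
        raise ValueError("cannot build a PFM from an empty site list")
    counts = np.zeros((SITE_LEN, 4), dtype=np.int64)
    for seq in seqs:
        codes = encode_seq(seq)
        if len(codes) != SITE_LEN or (codes < 0).any():
            raise ValueError(f"site must be 23 nt over ACGT, got {seq!r}")
        counts[np.arange(SITE_LEN), codes] += 1
    return PositionFrequencyMatrix(
        frequencies=counts / len(seqs), site_count=len(seqs)
    )


def pam_position_stats(sites: Sequence[CandidateSite | str]) -> dict:
    """Tallies of PAM second/third nucleotides and the NRN/NYN split."""
    pams = [s.pam if isinstance(s, CandidateSite) else s[-3:] for s in sites]
    second = {b: 0 for b in BASES}
    third = {b: 0 for b in BASES}
    nrn = nyn = 0
    for pam in pams:
        info = classify_pam(pam)
        second[info["second_nt"]] += 1
        third[info["third_nt"]] += 1
        if info["category"] == "NRN":
            nrn += 1
        else:
            nyn += 1
    return {
        "second_nt_counts": second,
        "third_nt_counts": third,
        "NRN": nrn,
        "NYN": nyn,
        "site_count": len(pams),
    }


def mismatch_distribution(
    sites: Sequence[CandidateSite], max_mismatches: int = 7
) -> dict[int, int]:
    """Histogram of protospacer mismatch counts over 0..max_mismatches."""
    hist = {k: 0 for k in range(max_mismatches + 1)}
    for s in sites:
        hist[s.mismatch_count] = hist.get(s.mismatch_count, 0) + 1
    return hist


def overlap_sets(
    site_lists: Mapping[str, Sequence[CandidateSite]],
    match_radius: int = DEFAULT_MATCH_RADIUS,
) -> dict[frozenset[str], int]:
    """Exclusive overlap partition (Venn cells) across variants.

    Two sites match iff they share chromosome and strand and their cut
    positions lie within ``match_radius``.  Matching is closed transitively
    (connected components of the match graph); each component contributes 1
    to the cell keyed by the set of variants it contains.  Cell counts
    therefore sum to the size of the union under the matching relation.
    """
    if len(site_lists) < 2:
        raise ValueError("overlap_sets requires at least two variants")
    nodes: list[tuple[str, CandidateSite]] = []
    for variant in sorted(site_lists):
        for s in site_lists[variant]:
            nodes.append((variant, s))
    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i, j in combinations(range(len(nodes)), 2):
        a, b = nodes[i][1], nodes[j][1]
        if (
            a.chrom == b.chrom
            and a.strand == b.strand
            and abs(a.cut_position - b.cut_position) <= match_radius
        ):
            union(i, j)

    components: dict[int, set[str]] = {}
    for i, (variant, _) in enumerate(nodes):
        components.setdefault(find(i), set()).add(variant)
    cells: dict[frozenset[str], int] = {}
    for members in components.values():
        key = frozenset(members)
        cells[key] = cells.get(key, 0) + 1
    return cells


def overlap_cells_to_json(cells: Mapping[frozenset[str], int]) -> dict[str, int]:
    return {"&".join(sorted(k)): v for k, v in sorted(cells.items(), key=lambda kv: "&".join(sorted(kv[0])))}


def paired_compare(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
    alpha: float = 0.05,
) -> dict:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Pairs with zero difference are dropped.  The exact null distribution is
    used for n <= 25 remaining pairs (when free of rank ties); the normal
    approximation with continuity correction otherwise.  When every
    difference is zero the test is undefined and reported non-significant
    with ``undefined = True``.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return {
            "statistic": float("nan"),
            "p_value": float("nan"),
            "significant": False,
            "undefined": True,
            "n_used": 0,
        }
    method = "exact" if len(nonzero) <= EXACT_WILCOXON_MAX_N else "approx"
    try:
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", alternative="two-sided", method=method
        )
    except ValueError:
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", alternative="two-sided", method="approx",
            correction=True,
        )
    p = float(res.pvalue)
    return {
        "statistic": float(res.statistic),
        "p_value": p,
        "significant": bool(p < alpha),
        "undefined": False,
        "n_used": int(len(nonzero)),
    }
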