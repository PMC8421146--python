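"""Independent brute-force oracles used by the test suite.

Everything here is written against the problem statements, not against the
package internals: pure-python string scans, naive clustering, exhaustive
signed-rank enumeration.  Oracles are intentionally slow and simple.
"""

from itertools import product

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "N": "ACGT",
}


def revcomp(seq):
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def hamming(a, b):
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def pam_matches(pam, pattern):
    return all(b in IUPAC[p] for b, p in zip(pam, pattern))


def brute_force_candidates(genome, protospacer, max_mm, pam_pattern):
    """Every 23-nt window on both strands within the mismatch/PAM rules.

    Returns a set of (chrom, start, strand, sequence_23, mismatches, pam).
    """
    hits = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        for start in range(len(seq) - 22):
            window = seq[start : start + 23]
            if any(b not in "ACGT" for b in window):
                continue
            for strand in "+-":
                oriented = window if strand == "+" else revcomp(window)
                mm = hamming(oriented[:20], protospacer)
                pam = oriented[20:]
                if mm <= max_mm and pam_matches(pam, pam_pattern):
                    hits.add((chrom, start, strand, oriented, mm, pam))
    return hits


def brute_force_clusters(positions, window):
    """Single-linkage clustering of sorted integer positions at gap <= window."""
    clusters = []
    for pos in sorted(positions):
        if clusters and pos - clusters[-1][-1] <= window:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    return clusters


def exact_signed_rank_p(diffs):
    """Two-sided exact Wilcoxon signed-rank p-value by full enumeration.

    Zero differences are dropped; ranks are midranks of |d|.  Enumerates all
    2^m sign assignments of the null and returns P(W+ as or more extreme).
    """
    d = [x for x in diffs if x != 0]
    m = len(d)
    if m == 0:
        return None
    absd = sorted((abs(x), i) for i, x in enumerate(d))
    ranks = [0.0] * m
    i = 0
    while i < m:
        j = i
        while j + 1 < m and absd[j + 1][0] == absd[i][0]:
            j += 1
        midrank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[absd[k][1]] = midrank
        i = j + 1
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    mean = sum(ranks) / 2
    dev_obs = abs(w_obs - mean)
    count = 0
    for signs in product((0, 1), repeat=m):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mean) >= dev_obs - 1e-12:
            count += 1
    return count / 2**m
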