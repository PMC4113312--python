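"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (pure Python, no shared code paths
with the package internals beyond calling the public aligner where the
oracle checks higher-level logic, never the same routine it verifies).
"""

from __future__ import annotations

import re


def sw_score(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Plain-Python affine-gap local alignment score (Gotoh), O(n*m)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = match if a[i - 1] == b[j - 1] and a[i - 1] in "ACGT" else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def brute_best_hits(align, set_a, set_b, min_aligned=100, min_score=40,
                    within=False):
    """Exhaustive argmax over all subject alignments, same filters/tiebreak."""
    out = {}
    for q, qs in set_a.items():
        best = None
        for s in sorted(set_b):
            if within and s == q:
                continue
            r = align(qs, set_b[s])
            if r.aligned_columns < min_aligned or r.score < min_score:
                continue
            key = (-r.score, -r.percent_identity, s)
            if best is None or key < best[0]:
                best = (key, s, r)
        if best is not None:
            out[q] = (best[1], best[2].score)
    return out


def brute_rbh(align, set_a, set_b, min_aligned=100, min_score=40,
              within=False):
    fwd = brute_best_hits(align, set_a, set_b, min_aligned, min_score, within)
    rev = brute_best_hits(align, set_b, set_a, min_aligned, min_score, within)
    pairs = set()
    for q, (s, _) in fwd.items():
        if s in rev and rev[s][0] == q:
            pairs.add(tuple(sorted((q, s))) if within else (q, s))
    return pairs


def transitive_closure_clusters(items, related):
    """Clusters under the transitive closure of a pairwise predicate."""
    items = list(items)
    clusters = []
    for it in items:
        merged = [c for c in clusters if any(related(it, o) for o in c)]
        rest = [c for c in clusters if c not in merged]
        new = {it}
        for c in merged:
            new |= c
        clusters = rest + [new]
    # keep merging until stable (closure)
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(related(x, y) for x in clusters[i] for y in clusters[j]):
                    clusters[i] |= clusters.pop(j)
                    changed = True
                    break
            if changed:
                break
    return {frozenset(c) for c in clusters}


_COMP = str.maketrans("ACGT", "TGCA")


def longest_orf_regex(seq: str) -> int:
    """Six-frame ORF scan via regex, independent of the codon walker."""
    best = 0
    for s in (seq.upper(), seq.upper().translate(_COMP)[::-1]):
        for frame in range(3):
            codons = re.findall("...", s[frame:])
            joined = "".join(codons)
            for m in re.finditer(r"(?=((?:ATG)(?:(?!TAA|TAG|TGA)...)*(?:TAA|TAG|TGA)))",
                                 joined):
                start = m.start(1)
                if start % 3 == 0:
                    best = max(best, len(m.group(1)))
    return best


def brute_specialized(fpkm_rows, k=3.0, ddof=1):
    """Per-row mean/SD flagging, computed with the statistics module."""
    import statistics

    flags = []
    for row in fpkm_rows:
        mu = statistics.fmean(row)
        sd = (statistics.stdev(row) if ddof == 1 else statistics.pstdev(row))
        flags.append([v > mu + k * sd for v in row])
    return flags


def binomial_lod(x: int, n: int) -> float:
    """log10 likelihood ratio at the phase-minimized recombinant count,
    evaluated through the binomial likelihood itself."""
    import math

    r = min(x, n - x)
    p = r / n
    if r == 0:
        return n * math.log10(2)
    like = (p ** r) * ((1 - p) ** (n - r))
    null = 0.5 ** n
    return math.log10(like / null)
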