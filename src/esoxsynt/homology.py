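"""Pairwise alignment, reciprocal-best-hit homology and redundancy collapse.

This is the computational stand-in for an all-vs-all BLASTN screen: an exact
Smith-Waterman/Gotoh local aligner, best-hit and reciprocal-best-hit (RBH)
search within or between transcript sets, non-overlapping HSP tiling for
coverage, single-linkage redundancy collapse, and an ORF length filter.

The statistical E-value of BLAST is replaced by a raw score threshold
(default ``min_score=40`` under +1/-1/-2/-1 scoring) because database-size
dependent statistics are not modelled here; the 100-column minimum
alignment length filter dominates in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from ._align import encode, sw_align

DEFAULT_SCORING = {"match": 1, "mismatch": -1, "gap_open": -2, "gap_extend": -1}

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class AlignmentResult:
    """One local alignment between a query and a subject sequence."""

    query: str
    subject: str
    score: int
    matches: int
    aligned_columns: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    query_coverage: float
    subject_coverage: float

    @property
    def percent_identity(self) -> float:
        if self.aligned_columns == 0:
            return 0.0
        return 100.0 * self.matches / self.aligned_columns


@dataclass
class HomologyPair:
    """A reciprocal-best-hit pair, stored once in canonical (sorted-id) order."""

    id_a: str
    id_b: str
    relation: str  # "within_species" | "between_species"
    alignment: AlignmentResult

    def __post_init__(self):
        if self.relation == "within_species" and self.id_a == self.id_b:
            raise ValueError("within-species pair cannot be a self pair")


def _scoring_tuple(scoring: Mapping[str, int] | None):
    s = dict(DEFAULT_SCORING)
    if scoring:
        s.update(scoring)
    return s["match"], s["mismatch"], s["gap_open"], s["gap_extend"]


def align_pair(seq_a: str, seq_b: str, scoring: Mapping[str, int] | None = None,
               band: int | None = None, qid: str = "a", sid: str = "b") -> AlignmentResult:
    """Best local alignment of two nucleotide sequences.

    ``band`` restricts the dynamic programme to a diagonal band (for long,
    near-collinear homologues); the default is the full O(n*m) matrix.
    Percent identity counts internal gap columns in the denominator.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    ea, eb = encode(seq_a), encode(seq_b)
    return _align_encoded(ea, eb, _scoring_tuple(scoring), band, qid, sid)


def _align_encoded(ea, eb, sc, band, qid, sid) -> AlignmentResult:
    m_, mm, go, ge = sc
    score, qs, qe, ss, se, matches, cols = sw_align(
        ea, eb, m_, mm, go, ge, -1 if band is None else int(band))
    return AlignmentResult(
        query=qid, subject=sid, score=int(score), matches=int(matches),
        aligned_columns=int(cols),
        query_start=int(qs), query_end=int(qe),
        subject_start=int(ss), subject_end=int(se),
        query_coverage=(qe - qs) / len(ea),
        subject_coverage=(se - ss) / len(eb),
    )


def hsp_tiling(seq_a: str, seq_b: str, scoring: Mapping[str, int] | None = None,
               min_score: int = 20, max_hsps: int = 8) -> list[AlignmentResult]:
    """Greedy best-first selection of non-overlapping local alignments (HSPs).

    The top-scoring alignment is taken, its footprint masked on both
    sequences, and the search repeated; this mirrors the usual HSP-tiling
    practice for coverage computation rather than optimal interval
    scheduling.
    """
    sc = _scoring_tuple(scoring)
    ea, eb = encode(seq_a).copy(), encode(seq_b).copy()
    out: list[AlignmentResult] = []
    for _ in range(max_hsps):
        res = _align_encoded(ea, eb, sc, None, "a", "b")
        if res.score < min_score or res.aligned_columns == 0:
            break
        out.append(res)
        ea[res.query_start:res.query_end] = 255
        eb[res.subject_start:res.subject_end] = 255
    return out


def pair_coverage(seq_a: str, seq_b: str, scoring=None, min_score: int = 20):
    """(coverage_a, coverage_b) from greedily tiled non-overlapping HSPs."""
    hsps = hsp_tiling(seq_a, seq_b, scoring, min_score)
    cov_a = sum(h.query_end - h.query_start for h in hsps) / len(seq_a)
    cov_b = sum(h.subject_end - h.subject_start for h in hsps) / len(seq_b)
    return cov_a, cov_b


def _seed_index(seqs: Mapping[str, str], k: int):
    idx: dict[str, set[str]] = {}
    for name, s in seqs.items():
        for i in range(len(s) - k + 1):
            idx.setdefault(s[i:i + k], set()).add(name)
    return idx


def _candidates(query: str, subject_index, k: int) -> set[str]:
    out: set[str] = set()
    for i in range(len(query) - k + 1):
        hit = subject_index.get(query[i:i + k])
        if hit:
            out |= hit
    return out


def best_hits(set_a: Mapping[str, str], set_b: Mapping[str, str],
              min_aligned: int = 100, min_score: int = 40,
              scoring: Mapping[str, int] | None = None,
              within: bool = False, seed_k: int | None = None,
              band: int | None = None) -> dict[str, AlignmentResult]:
    """Single best passing hit per query of ``set_a`` against ``set_b``.

    A hit passes if it spans at least ``min_aligned`` alignment columns and
    scores at least ``min_score``.  Ties break by score, then percent
    identity, then lexicographic subject id.  ``within=True`` excludes
    self-pairs.  ``seed_k`` enables a shared-k-mer candidate prefilter
    (heuristic, used by the pipeline for speed); the default is an
    exhaustive, oracle-equivalent scan.
    """
    if not set_a or not set_b:
        raise ValueError("best_hits requires non-empty sequence sets")
    sc = _scoring_tuple(scoring)
    enc_b = {n: encode(s) for n, s in set_b.items()}
    sidx = _seed_index(set_b, seed_k) if seed_k else None
    out: dict[str, AlignmentResult] = {}
    for qname, qseq in set_a.items():
        eq = encode(qseq)
        if sidx is None:
            cand: Iterable[str] = set_b.keys()
        else:
            cand = sorted(_candidates(qseq, sidx, seed_k))
        best: AlignmentResult | None = None
        for sname in cand:
            if within and sname == qname:
                continue
            res = _align_encoded(eq, enc_b[sname], sc, band, qname, sname)
            if res.aligned_columns < min_aligned or res.score < min_score:
                continue
            if best is None or (res.score, res.percent_identity, ) > (
                    best.score, best.percent_identity) or (
                    res.score == best.score
                    and res.percent_identity == best.percent_identity
                    and res.subject < best.subject):
                best = res
        if best is not None:
            out[qname] = best
    return out


def reciprocal_best_hits(set_a: Mapping[str, str], set_b: Mapping[str, str],
                         min_aligned: int = 100, min_score: int = 40,
                         scoring=None, within: bool = False,
                         seed_k: int | None = None,
                         band: int | None = None) -> list[HomologyPair]:
    """RBH pairs: (a, b) is reported iff b is a's best hit and a is b's.

    In within-species mode both directions run over the same set with
    self-hits excluded, and each pair is reported once in canonical order;
    the output is always a partial matching (each id in at most one pair).
    """
    fwd = best_hits(set_a, set_b, min_aligned, min_score, scoring, within,
                    seed_k, band)
    rev = best_hits(set_b, set_a, min_aligned, min_score, scoring, within,
                    seed_k, band)
    relation = "within_species" if within else "between_species"
    pairs = []
    for qname, res in sorted(fwd.items()):
        back = rev.get(res.subject)
        if back is None or back.subject != qname:
            continue
        if within and res.subject < qname:
            continue  # canonical order: report once
        pairs.append(HomologyPair(qname, res.subject, relation, res))
    return pairs


def rbh_with_coverage(set_a: Mapping[str, str], set_b: Mapping[str, str],
                      min_cov: float = 0.5, min_aligned: int = 100,
                      min_score: int = 40, scoring=None,
                      within: bool = False, seed_k: int | None = None,
                      band: int | None = None) -> list[HomologyPair]:
    """RBH pairs where >= ``min_cov`` of *each* sequence is covered by
    greedily selected non-overlapping HSPs (the synteny-grade filter)."""
    pairs = reciprocal_best_hits(set_a, set_b, min_aligned, min_score,
                                 scoring, within, seed_k, band)
    sets = (set_a, set_a if within else set_b)
    kept = []
    for p in pairs:
        cov_a, cov_b = pair_coverage(sets[0][p.id_a], sets[1][p.id_b],
                                     scoring)
        if cov_a >= min_cov and cov_b >= min_cov:
            p.alignment.query_coverage = cov_a
            p.alignment.subject_coverage = cov_b
            kept.append(p)
    return kept


def collapse_redundancy(transcripts: Mapping[str, str], min_identity: float = 98.0,
                        min_len: int = 300, scoring=None,
                        seed_k: int | None = None):
    """Collapse near-identical transcripts to one representative each.

    Two transcripts are redundant when they share a local alignment of at
    least ``min_len`` columns at >= ``min_identity`` percent identity;
    clusters are the single-linkage (transitive) closure of that relation.
    The representative is the longest member, ties broken by lexicographic
    id.  Returns ``(representatives, cluster_map)`` where ``cluster_map``
    sends every input id to its representative.  Idempotent.
    """
    sc = _scoring_tuple(scoring)
    names = sorted(transcripts)
    enc = {n: encode(transcripts[n]) for n in names}
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sidx = _seed_index(transcripts, seed_k) if seed_k else None
    for i, na in enumerate(names):
        if sidx is None:
            cand = names[i + 1:]
        else:
            cand = [c for c in sorted(_candidates(transcripts[na], sidx, seed_k))
                    if c > na]
        for nb in cand:
            if find(na) == find(nb):
                continue
            res = _align_encoded(enc[na], enc[nb], sc, None, na, nb)
            if res.aligned_columns >= min_len and res.percent_identity >= min_identity:
                parent[find(nb)] = find(na)
    clusters: dict[str, list[str]] = {}
    for n in names:
        clusters.setdefault(find(n), []).append(n)
    cluster_map: dict[str, str] = {}
    reps: dict[str, str] = {}
    for members in clusters.values():
        rep = min(members, key=lambda n: (-len(transcripts[n]), n))
        for m in members:
            cluster_map[m] = rep
        reps[rep] = transcripts[rep]
    return reps, cluster_map


def longest_orf(seq: str) -> int:
    """Length in bp of the longest start-to-stop ORF over all six frames."""
    best = 0
    for strand in (seq.upper(), seq.upper().translate(_COMP)[::-1]):
        for frame in range(3):
            start = None
            for pos in range(frame, len(strand) - 2, 3):
                codon = strand[pos:pos + 3]
                if start is None:
                    if codon == "ATG":
                        start = pos
                elif codon in _STOPS:
                    best = max(best, pos + 3 - start)
                    start = None
    return best


def orf_filter(transcripts: Mapping[str, str], min_orf: int = 300) -> dict[str, str]:
    """Retain transcripts whose longest ORF is at least ``min_orf`` bp."""
    return {n: s for n, s in transcripts.items() if longest_orf(s) >= min_orf}
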