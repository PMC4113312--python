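"""Conserved-synteny matrices and scaffold diagnosis.

Orthologue pairs are cross-tabulated as an Oxford-grid style contingency
matrix of focal linkage group (LG) x comparator chromosome.  Patterns in
those matrices are classified into comparator-lineage fusions,
focal-lineage fissions and whole-genome-duplication (2 chromosomes per LG)
signatures.  Individual scaffolds whose orthologue hits split across two
chromosomes are diagnosed as genuine translocations (when flanking
scaffolds in the linkage group corroborate the breakpoint), as part of a
reorganized linkage-group context, or as chimera suspects (mis-joined
assembly scaffolds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def point_position(start: float, end: float) -> float:
    """Represent a located feature by the midpoint (start + end) / 2."""
    if start > end:
        raise ValueError("start must not exceed end")
    return (start + end) / 2.0


def anchor_transcripts(locations: pd.DataFrame,
                       anchors: pd.DataFrame) -> pd.Series:
    """Map transcripts to linkage groups via their host scaffold.

    ``locations`` needs columns (id, chrom) where chrom is the scaffold;
    ``anchors`` needs (scaffold, linkage_group).  Transcripts on scaffolds
    without an anchor are excluded, with the count logged.
    """
    amap = anchors.set_index("scaffold")["linkage_group"]
    on_known = locations["chrom"].isin(amap.index)
    n_dropped = int((~on_known).sum())
    if n_dropped:
        logger.warning("excluded %d transcripts on unanchored scaffolds",
                       n_dropped)
    sub = locations[on_known]
    return pd.Series(amap[sub["chrom"]].to_numpy(), index=sub["id"].to_numpy(),
                     name="linkage_group")


@dataclass
class SyntenyMatrix:
    """Orthologue-pair counts: focal linkage groups x comparator chromosomes."""

    counts: pd.DataFrame  # rows LG, columns comparator chromosome
    comparator: str = "comparator"
    display_min: int = 3

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def masked(self) -> pd.DataFrame:
        """Export view: cells below ``display_min`` blanked (kept internally)."""
        m = self.counts.copy().astype(object)
        m[self.counts < self.display_min] = ""
        return m

    def dominant(self, frac: float = 0.5) -> dict[str, list[str]]:
        """Per LG, the chromosomes holding at least ``frac`` of the row mass
        (ties all reported)."""
        out = {}
        for lg, row in self.counts.iterrows():
            tot = row.sum()
            if tot == 0:
                out[lg] = []
                continue
            out[lg] = sorted(row.index[row >= frac * tot])
        return out

    def argmax_dominant(self) -> dict[str, list[str]]:
        out = {}
        for lg, row in self.counts.iterrows():
            if row.sum() == 0:
                out[lg] = []
            else:
                out[lg] = sorted(row.index[row == row.max()])
        return out


def build_synteny_matrix(pairs, transcript_lg: pd.Series,
                         comparator_locations: pd.DataFrame,
                         comparator: str = "comparator",
                         display_min: int = 3) -> SyntenyMatrix:
    """Cross-tabulate RBH orthologue pairs by focal LG x comparator chromosome.

    ``pairs`` are HomologyPair objects with the focal transcript as
    ``id_a``; pairs whose focal transcript has no linkage-group anchor or
    whose comparator orthologue has no location are skipped.
    """
    comp_chrom = comparator_locations.set_index("id")["chrom"]
    rows = []
    for p in pairs:
        lg = transcript_lg.get(p.id_a)
        chrom = comp_chrom.get(p.id_b)
        if lg is None or chrom is None or (isinstance(lg, float) and np.isnan(lg)):
            continue
        rows.append((lg, chrom))
    df = pd.DataFrame(rows, columns=["lg", "chrom"])
    counts = pd.crosstab(df["lg"], df["chrom"]) if len(df) else pd.DataFrame()
    counts = counts.sort_index().sort_index(axis=1)
    return SyntenyMatrix(counts=counts, comparator=comparator,
                         display_min=display_min)


def classify_patterns(matrices: dict[str, SyntenyMatrix],
                      dominance_frac: float = 0.5,
                      duplication_frac: float = 0.2) -> pd.DataFrame:
    """Call fusion / fission / duplication signatures across comparators.

    * comparator-lineage fusion: one comparator chromosome is dominant
      (>= ``dominance_frac`` of row mass) in >= 2 LG rows of ONE comparator
      only;
    * focal-lineage fission: two LGs share a dominant chromosome in ALL
      comparators;
    * duplication signature (per comparator): an LG row with exactly two
      chromosomes each >= ``duplication_frac`` of row mass.

    Fusion/fission calls require at least two comparators.
    """
    if len(matrices) < 2:
        raise ValueError("fusion/fission classification needs >= 2 comparators")
    lg_sets = {frozenset(m.counts.index) for m in matrices.values()}
    if len(lg_sets) > 1:
        raise ValueError("matrices must share the focal linkage-group set")
    lgs = sorted(next(iter(lg_sets)))
    dom = {name: m.dominant(dominance_frac) for name, m in matrices.items()}
    calls = []
    for i, g1 in enumerate(lgs):
        for g2 in lgs[i + 1:]:
            shared_by = {}
            for name in matrices:
                shared = set(dom[name].get(g1, [])) & set(dom[name].get(g2, []))
                if shared:
                    shared_by[name] = sorted(shared)
            if len(shared_by) == len(matrices) and shared_by:
                calls.append(("fission", f"{g1}+{g2}", "all",
                              ";".join(";".join(v) for v in shared_by.values())))
            elif len(shared_by) == 1:
                name, chroms = next(iter(shared_by.items()))
                calls.append(("fusion", f"{g1}+{g2}", name, ";".join(chroms)))
    for name, m in matrices.items():
        for lg, row in m.counts.iterrows():
            tot = row.sum()
            if tot == 0:
                continue
            big = row.index[row >= duplication_frac * tot]
            if len(big) == 2:
                calls.append(("duplication", lg, name, ";".join(sorted(big))))
    return pd.DataFrame(calls, columns=["pattern", "linkage_groups",
                                        "comparator", "chromosomes"])


@dataclass
class ScaffoldDiagnosis:
    scaffold: str
    dominant: dict[str, str] = field(default_factory=dict)
    breakpoint: float | None = None
    halves: tuple[str, str] | None = None
    verdict: str | None = None  # consistent|translocation|reorganized_context|chimera_suspect
    evidence: dict = field(default_factory=dict)


def _majority(chroms: pd.Series):
    if len(chroms) == 0:
        return None, 0
    vc = chroms.value_counts()
    return vc.index[0], int(vc.iloc[0])


def _best_breakpoint(hits: pd.DataFrame):
    """Best single split of positionally ordered hits into two
    chromosome-pure halves; returns (purity, pos, left_chrom, right_chrom)."""
    h = hits.sort_values("pos")
    n = len(h)
    chroms = h["chrom"].to_numpy()
    pos = h["pos"].to_numpy()
    best = (0.0, None, None, None)
    for k in range(1, n):
        lc, lcount = _majority(pd.Series(chroms[:k]))
        rc, rcount = _majority(pd.Series(chroms[k:]))
        if lc == rc:
            continue
        purity = (lcount + rcount) / n
        if purity > best[0]:
            best = (purity, (pos[k - 1] + pos[k]) / 2.0, lc, rc)
    return best


def _lg_dominants(hits: pd.DataFrame, lg_order: list[str], comparator: str):
    """Dominant chromosome for every scaffold along the LG, in order."""
    sub = hits[hits["comparator"] == comparator]
    out = []
    for sc in lg_order:
        c, _ = _majority(sub.loc[sub["scaffold"] == sc, "chrom"])
        out.append(c)
    return out


def _is_reorganized(dominants: list) -> bool:
    seq = [c for c in dominants if c is not None]
    distinct = set(seq)
    if len(distinct) < 4:
        return False
    runs = 1 + sum(1 for a, b in zip(seq, seq[1:]) if a != b)
    return runs > len(distinct)


def diagnose_scaffold(scaffold: str, hits: pd.DataFrame,
                      lg_order: list[str], min_hits: int = 5,
                      purity: float = 0.8) -> ScaffoldDiagnosis:
    """Classify one scaffold from its positionally ordered orthologue hits.

    ``hits`` covers the whole linkage group, with columns
    (scaffold, pos, comparator, chrom); ``lg_order`` is the ordered list of
    scaffolds along the linkage group hosting ``scaffold``.

    Verdicts: *consistent* when one chromosome holds >= ``purity`` of the
    hits in every comparator; otherwise the best single breakpoint is
    sought and the verdict is *translocation* when the flanking scaffolds
    side-match the two halves, *reorganized_context* when the linkage
    group's scaffolds collectively hit >= 4 chromosomes interleaved, else
    *chimera_suspect*.
    """
    diag = ScaffoldDiagnosis(scaffold=scaffold)
    own = hits[hits["scaffold"] == scaffold]
    per_comp = {c: sub for c, sub in own.groupby("comparator")}
    sizes = {c: len(sub) for c, sub in per_comp.items()}
    if not sizes or max(sizes.values()) < min_hits:
        diag.evidence["reason"] = "insufficient hits"
        return diag
    consistent = True
    for comp, sub in per_comp.items():
        c, n = _majority(sub["chrom"])
        diag.dominant[comp] = c
        if n < purity * len(sub):
            consistent = False
    if consistent:
        diag.verdict = "consistent"
        return diag
    # breakpoint search in the comparator with most hits
    comp = max(sizes, key=lambda c: (sizes[c], c))
    pur, bp, lc, rc = _best_breakpoint(per_comp[comp])
    diag.breakpoint = bp
    diag.halves = (lc, rc)
    diag.evidence["breakpoint_purity"] = pur
    # flanking scaffolds along the LG
    dominants = _lg_dominants(hits, lg_order, comp)
    idx = lg_order.index(scaffold) if scaffold in lg_order else -1
    left = dominants[idx - 1] if idx > 0 else None
    right = dominants[idx + 1] if 0 <= idx < len(lg_order) - 1 else None
    diag.evidence["flanks"] = (left, right)
    if pur >= purity and lc is not None and (
            (left == lc and right == rc) or (left == rc and right == lc)):
        diag.verdict = "translocation"
        return diag
    if _is_reorganized(dominants):
        diag.verdict = "reorganized_context"
        return diag
    diag.verdict = "chimera_suspect"
    return diag


def hits_table(pairs, focal_locations: pd.DataFrame,
               comparator_locations: pd.DataFrame,
               comparator: str) -> pd.DataFrame:
    """Per-transcript comparator hits for scaffold diagnosis.

    Focal positions collapse to :func:`point_position` midpoints on the
    host scaffold; strand is ignored throughout.
    """
    floc = focal_locations.set_index("id")
    cloc = comparator_locations.set_index("id")
    rows = []
    for p in pairs:
        if p.id_a not in floc.index or p.id_b not in cloc.index:
            continue
        fr = floc.loc[p.id_a]
        cr = cloc.loc[p.id_b]
        rows.append((p.id_a, fr["chrom"], point_position(fr["start"], fr["end"]),
                     comparator, cr["chrom"],
                     point_position(cr["start"], cr["end"])))
    return pd.DataFrame(rows, columns=["transcript", "scaffold", "pos",
                                       "comparator", "chrom", "comp_pos"])
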