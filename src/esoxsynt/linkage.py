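"""Half-sib (pseudo-testcross) two-point linkage mapping.

Each heterozygous parent of a half-sib family is analysed as a backcross:
per marker pair and parent, the recombinant count over informative meioses
gives a recombination fraction and a LOD score (phase unknown, so the
minority count is taken over the two phase assignments).  Markers are
grouped by single-linkage clustering at a LOD threshold, ordered by a
greedy nearest-neighbour chain on the recombination fractions, placed in
centiMorgans through a map function (Kosambi by default, Haldane
available), and the sex-specific maps are merged on shared markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import GenotypeTable

logger = logging.getLogger(__name__)

LOG2 = np.log10(2.0)


# --------------------------------------------------------------------------
# genotype parsing and informativeness


def parse_gt(gt: str) -> tuple[str, str] | None:
    if gt is None or gt == "-" or (isinstance(gt, float) and np.isnan(gt)):
        return None
    parts = str(gt).split("/")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"malformed genotype string: {gt!r}")
    return (parts[0], parts[1])


def classify_informativeness(mother_gt: str, father_gt: str) -> str:
    """mother_only / father_only / both / neither for one marker.

    A parent is informative when heterozygous (its transmitted allele is
    then recoverable in at least part of the progeny given the other
    parent's genotype); homozygous-in-both markers carry no meiotic
    information and are excluded.
    """
    m = parse_gt(mother_gt)
    f = parse_gt(father_gt)
    if m is None or f is None:
        return "neither"
    m_het = m[0] != m[1]
    f_het = f[0] != f[1]
    if m_het and f_het:
        return "both"
    if m_het:
        return "mother_only"
    if f_het:
        return "father_only"
    return "neither"


def transmitted_allele(progeny_gt, parent_gt, other_gt):
    """The allele ``parent`` transmitted, or None when ambiguous/missing.

    Enumerates the two assignments of the progeny's alleles to the parents
    and keeps the parent allele when it is uniquely determined; progeny
    genotypes inconsistent with the parents resolve to None (treated as
    missing, the Mendelian-error policy).
    """
    p = parse_gt(progeny_gt)
    par = parse_gt(parent_gt)
    oth = parse_gt(other_gt)
    if p is None or par is None or oth is None:
        return None
    found = set()
    for a, b in (p, p[::-1]):
        if a in par and b in oth:
            found.add(a)
    if len(found) == 1:
        return found.pop()
    return None


# --------------------------------------------------------------------------
# filtering


def missing_filter(table: GenotypeTable, max_missing: float = 0.15,
                   keep_list: list[str] | None = None) -> GenotypeTable:
    """Drop markers with missing fraction strictly above ``max_missing``
    unless they are on ``keep_list`` (kept and flagged)."""
    keep_list = set(keep_list or [])
    frac = table.missing_fraction()
    drop = [m for m in table.markers
            if frac[m] > max_missing and m not in keep_list]
    kept_flagged = [m for m in keep_list if m in frac.index
                    and frac[m] > max_missing]
    if drop:
        logger.info("missing_filter dropped %d markers: %s", len(drop),
                    ",".join(drop[:10]))
    if kept_flagged:
        logger.warning("keep_list retained high-missing markers: %s",
                       ",".join(kept_flagged))
    data = table.data.drop(index=drop)
    return GenotypeTable(data=data, mother=table.mother, fathers=table.fathers,
                         progeny_father=dict(table.progeny_father),
                         missing_code=table.missing_code)


# --------------------------------------------------------------------------
# two-point statistics


@dataclass
class MarkerPairStat:
    parent: str
    marker_i: str
    marker_j: str
    n: int
    r: int
    r_hat: float
    lod: float


def lod_score(r: int, n: int) -> float:
    """Pseudo-testcross two-point LOD at the phase-maximized count."""
    if n == 0:
        return float("nan")
    r = min(r, n - r)
    if r == 0:
        return n * LOG2
    rh = r / n
    return r * np.log10(rh) + (n - r) * np.log10(1 - rh) + n * LOG2


class TwoPointAnalysis:
    """All pairwise recombination/LOD statistics, one block per parent.

    For each parent, ``markers`` lists the markers heterozygous in that
    parent, and the matrices ``n`` (informative meioses), ``x`` (phase-0
    discordant count), ``rhat`` and ``lod`` are aligned to that list.
    """

    def __init__(self, table: GenotypeTable):
        self.table = table
        self.parents = [table.mother] + table.fathers
        self.markers_by_parent: dict[str, list[str]] = {}
        self.n: dict[str, np.ndarray] = {}
        self.x: dict[str, np.ndarray] = {}
        self.rhat: dict[str, np.ndarray] = {}
        self.lod: dict[str, np.ndarray] = {}
        for parent in self.parents:
            self._compute_parent(parent)

    def _meioses(self, parent: str) -> list[str]:
        if parent == self.table.mother:
            return self.table.progeny
        return [p for p, f in self.table.progeny_father.items() if f == parent]

    def _compute_parent(self, parent: str):
        t = self.table
        prog = self._meioses(parent)
        inf_markers = []
        rows = []
        for m in t.markers:
            par_gt = t.data.at[m, parent]
            pg = parse_gt(par_gt)
            if pg is None or pg[0] == pg[1]:
                continue
            inf_markers.append(m)
            ordered = sorted(pg)
            vals = np.full(len(prog), np.nan)
            for k, p in enumerate(prog):
                other = (t.progeny_father[p] if parent == t.mother
                         else t.mother)
                al = transmitted_allele(t.data.at[m, p], par_gt,
                                        t.data.at[m, other])
                if al is not None:
                    vals[k] = ordered.index(al)
            rows.append(vals)
        self.markers_by_parent[parent] = inf_markers
        if not rows:
            z = np.zeros((0, 0))
            self.n[parent] = self.x[parent] = z
            self.rhat[parent] = self.lod[parent] = z
            return
        A = np.vstack(rows)
        V = ~np.isnan(A)
        A0 = ((A == 0) & V).astype(np.float64)
        A1 = ((A == 1) & V).astype(np.float64)
        n = (V.astype(np.float64) @ V.T.astype(np.float64))
        x = A0 @ A1.T + A1 @ A0.T
        r = np.minimum(x, n - x)
        with np.errstate(divide="ignore", invalid="ignore"):
            rh = np.where(n > 0, r / np.maximum(n, 1), np.nan)
            lod = np.where(
                r == 0, n * LOG2,
                r * np.log10(np.where(rh > 0, rh, 1))
                + (n - r) * np.log10(np.where(rh < 1, 1 - rh, 1)) + n * LOG2)
        lod = np.where(n > 0, lod, np.nan)
        self.n[parent] = n
        self.x[parent] = x
        self.rhat[parent] = np.where(n > 0, rh, np.nan)
        self.lod[parent] = lod

    def pair(self, marker_i: str, marker_j: str, parent: str) -> MarkerPairStat:
        mk = self.markers_by_parent[parent]
        if marker_i not in mk or marker_j not in mk:
            raise KeyError(f"{marker_i}/{marker_j} not informative in {parent}")
        i, j = mk.index(marker_i), mk.index(marker_j)
        n = int(self.n[parent][i, j])
        x = int(self.x[parent][i, j])
        r = min(x, n - x) if n else 0
        return MarkerPairStat(parent, marker_i, marker_j, n, r,
                              r / n if n else float("nan"),
                              lod_score(r, n) if n else float("nan"))


def two_point(table_or_analysis, marker_i: str, marker_j: str,
              parent: str) -> MarkerPairStat:
    """Two-point recombination and LOD for one marker pair and parent."""
    an = (table_or_analysis if isinstance(table_or_analysis, TwoPointAnalysis)
          else TwoPointAnalysis(table_or_analysis))
    return an.pair(marker_i, marker_j, parent)


# --------------------------------------------------------------------------
# grouping


class _UnionFind(dict):
    def find(self, x):
        while self[x] != x:
            self[x] = self[self[x]]
            x = self[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self[rb] = ra


@dataclass
class GroupingResult:
    groups: list[list[str]]
    unlinked: list[str]
    per_parent: dict[str, list[list[str]]]


def group_markers(analysis: TwoPointAnalysis, lod_form: float = 4.0,
                  lod_join: float = 3.0,
                  cross_parent_support: bool = True) -> GroupingResult:
    """Single-linkage grouping at ``lod_form`` per parent; cluster pairs
    bridged at ``lod_join <= LOD < lod_form`` in one parent are merged only
    when another parent links the same markers at >= ``lod_form``.

    Returns combined groups (across parents, shared markers unify them),
    sorted by decreasing size, plus markers that stay unlinked.
    """
    all_markers = sorted({m for p in analysis.parents
                          for m in analysis.markers_by_parent[p]})
    uf = _UnionFind({m: m for m in all_markers})
    strong: dict[str, set[tuple[str, str]]] = {}
    weak: dict[str, list[tuple[str, str, float]]] = {}
    for parent in analysis.parents:
        mk = analysis.markers_by_parent[parent]
        lod = analysis.lod[parent]
        strong[parent] = set()
        weak[parent] = []
        for i in range(len(mk)):
            for j in range(i + 1, len(mk)):
                lv = lod[i, j]
                if np.isnan(lv):
                    continue
                if lv >= lod_form:
                    strong[parent].add((mk[i], mk[j]))
                elif lv >= lod_join:
                    weak[parent].append((mk[i], mk[j], lv))
    per_parent: dict[str, list[list[str]]] = {}
    for parent in analysis.parents:
        puf = _UnionFind({m: m for m in analysis.markers_by_parent[parent]})
        for a, b in strong[parent]:
            puf.union(a, b)
        if cross_parent_support:
            for a, b, lv in weak[parent]:
                supported = any((a, b) in strong[q] or (b, a) in strong[q]
                                for q in analysis.parents if q != parent)
                if supported:
                    puf.union(a, b)
        clusters: dict[str, list[str]] = {}
        for m in analysis.markers_by_parent[parent]:
            clusters.setdefault(puf.find(m), []).append(m)
        per_parent[parent] = sorted((sorted(c) for c in clusters.values()),
                                    key=lambda c: (-len(c), c[0]))
        for c in per_parent[parent]:
            for m in c[1:]:
                uf.union(c[0], m)
    combined: dict[str, list[str]] = {}
    for m in all_markers:
        combined.setdefault(uf.find(m), []).append(m)
    groups = [sorted(c) for c in combined.values() if len(c) > 1]
    groups.sort(key=lambda c: (-len(c), c[0]))
    unlinked = sorted(m for c in combined.values() if len(c) == 1 for m in c)
    return GroupingResult(groups=groups, unlinked=unlinked,
                          per_parent=per_parent)


# --------------------------------------------------------------------------
# ordering and map distance


def order_group(group: list[str], analysis: TwoPointAnalysis,
                parent: str) -> list[str]:
    """Greedy nearest-neighbour chain over r-hat.

    Starts from the tightest pair and extends at both ends with the
    unplaced marker closest to a terminal; deterministic under marker-id
    tie-breaks, orientation canonicalized so the lexicographically smaller
    terminal comes first.  Only markers informative in ``parent`` are
    placed.
    """
    mk = analysis.markers_by_parent[parent]
    members = [m for m in group if m in mk]
    if len(members) < 2:
        return members
    idx = {m: mk.index(m) for m in members}
    rh = analysis.rhat[parent]

    def r(a, b):
        v = rh[idx[a], idx[b]]
        return 0.5 if np.isnan(v) else float(v)

    pairs = sorted(((r(a, b), a, b) for i, a in enumerate(members)
                    for b in members[i + 1:]), key=lambda t: (t[0], t[1], t[2]))
    chain = [pairs[0][1], pairs[0][2]]
    rest = set(members) - set(chain)
    while rest:
        head, tail = chain[0], chain[-1]
        cand = sorted(((min(r(m, head), r(m, tail)), m) for m in rest),
                      key=lambda t: (t[0], t[1]))
        _, m = cand[0]
        if r(m, head) < r(m, tail) or (r(m, head) == r(m, tail)
                                       and head < tail):
            chain.insert(0, m)
        else:
            chain.append(m)
        rest.remove(m)
    if chain[0] > chain[-1]:
        chain.reverse()
    return chain


def map_distance(r_hat: float, function: str = "kosambi") -> float:
    """cM from a recombination fraction (Kosambi default, Haldane option)."""
    if not 0 <= r_hat < 0.5:
        raise ValueError("r_hat must be in [0, 0.5)")
    if function == "haldane":
        return -50.0 * np.log(1.0 - 2.0 * r_hat)
    if function == "kosambi":
        return 25.0 * np.log((1.0 + 2.0 * r_hat) / (1.0 - 2.0 * r_hat))
    raise ValueError(f"unknown map function {function!r}")


@dataclass
class LinkageMap:
    sex: str
    groups: dict[str, pd.DataFrame] = field(default_factory=dict)
    unmerged: list[str] = field(default_factory=list)

    @property
    def total_cM(self) -> float:
        tot = 0.0
        for df in self.groups.values():
            if len(df) >= 2:
                tot += df["pos_cM"].max() - df["pos_cM"].min()
        return tot

    def marker_positions(self) -> pd.DataFrame:
        frames = []
        for gid, df in self.groups.items():
            d = df.copy()
            d.insert(0, "group", gid)
            frames.append(d)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def build_parent_map(analysis: TwoPointAnalysis, grouping: GroupingResult,
                     parent: str, map_function: str = "kosambi",
                     sex: str | None = None) -> LinkageMap:
    """Per-parent map: order each group's parent-informative markers and
    accumulate adjacent map distances."""
    mk = analysis.markers_by_parent[parent]
    idx = {m: i for i, m in enumerate(mk)}
    rh = analysis.rhat[parent]
    lm = LinkageMap(sex=sex or parent)
    for g, members in enumerate(grouping.groups, start=1):
        chain = order_group(members, analysis, parent)
        if len(chain) < 2:
            continue
        pos = [0.0]
        for a, b in zip(chain, chain[1:]):
            rv = rh[idx[a], idx[b]]
            rv = 0.0 if np.isnan(rv) else min(float(rv), 0.4999)
            pos.append(pos[-1] + map_distance(rv, map_function))
        lm.groups[f"LG{g:02d}"] = pd.DataFrame(
            {"marker": chain, "pos_cM": pos})
    return lm


# --------------------------------------------------------------------------
# map merging and statistics


def _orient(base_pos: pd.Series, other: pd.DataFrame) -> pd.DataFrame:
    shared = [m for m in other["marker"] if m in base_pos.index]
    if len(shared) >= 2:
        op = other.set_index("marker")["pos_cM"]
        bp = base_pos[shared]
        fwd = sum(1 for i, a in enumerate(shared) for b in shared[i + 1:]
                  if (op[a] < op[b]) == (bp[a] < bp[b]))
        rev = sum(1 for i, a in enumerate(shared) for b in shared[i + 1:]
                  if (op[a] < op[b]) != (bp[a] < bp[b]))
        if rev > fwd:
            flipped = other.copy()
            flipped["pos_cM"] = other["pos_cM"].max() - other["pos_cM"]
            return flipped.sort_values("pos_cM").reset_index(drop=True)
    return other


def merge_maps(female: LinkageMap, males: list[LinkageMap] | LinkageMap
               ) -> tuple[LinkageMap, pd.DataFrame]:
    """Merge sex-specific maps on shared anchor markers.

    The female map is the frame; each male group that shares >= 1 marker
    with a female group is oriented to maximize shared-marker order
    agreement and its private markers are interpolated proportionally
    between the nearest anchors (offset past terminal anchors).  Groups
    sharing no markers are reported unmerged.  Returns (merged map,
    anchor report).
    """
    if isinstance(males, LinkageMap):
        males = [males]
    merged = LinkageMap(sex="merged")
    report_rows = []
    used_other: set[tuple[int, str]] = set()
    for gid, fdf in female.groups.items():
        pos = fdf.set_index("marker")["pos_cM"].copy()
        for mi, male in enumerate(males):
            for ogid, odf in male.groups.items():
                shared = [m for m in odf["marker"] if m in pos.index]
                if not shared:
                    continue
                used_other.add((mi, ogid))
                odf = _orient(pos, odf)
                op = odf.set_index("marker")["pos_cM"]
                anchors = sorted(shared, key=lambda m: op[m])
                report_rows.append((gid, f"{male.sex}:{ogid}", len(shared)))
                for m in odf["marker"]:
                    if m in pos.index:
                        continue
                    pm = op[m]
                    lo = [a for a in anchors if op[a] <= pm]
                    hi = [a for a in anchors if op[a] > pm]
                    if lo and hi:
                        a1, a2 = lo[-1], hi[0]
                        span_o = op[a2] - op[a1]
                        f = (pm - op[a1]) / span_o if span_o > 0 else 0.5
                        pos[m] = pos[a1] + f * (pos[a2] - pos[a1])
                    elif lo:
                        a1 = lo[-1]
                        pos[m] = pos[a1] + (pm - op[a1])
                    else:
                        a2 = hi[0]
                        pos[m] = pos[a2] - (op[a2] - pm)
        out = pos.sort_values().reset_index()
        out.columns = ["marker", "pos_cM"]
        out["pos_cM"] -= out["pos_cM"].min()
        merged.groups[gid] = out
    for mi, male in enumerate(males):
        for ogid in male.groups:
            if (mi, ogid) not in used_other:
                merged.unmerged.append(f"{male.sex}:{ogid}")
    report = pd.DataFrame(report_rows,
                          columns=["female_group", "male_group", "n_shared"])
    return merged, report


def map_stats(maps: dict[str, LinkageMap]) -> dict:
    """Totals per map, the female:male recombination ratio (2 dp), and a
    per-group ratio table for region-level comparisons.

    The per-group table also yields a median ratio, which is robust to a
    single anomalous group (e.g. one inflated by a spurious join).
    """
    totals = {sex: round(m.total_cM, 1) for sex, m in maps.items()}
    out = {"total_cM": totals}
    if "female" in maps and "male" in maps:
        f, m = maps["female"], maps["male"]
        male_tot = m.total_cM
        out["female_male_ratio"] = (round(f.total_cM / male_tot, 2)
                                    if male_tot > 0 else float("nan"))
        rows = []
        for gid in f.groups:
            if gid not in m.groups:
                continue
            fl = f.groups[gid]["pos_cM"].max() - f.groups[gid]["pos_cM"].min()
            ml = m.groups[gid]["pos_cM"].max() - m.groups[gid]["pos_cM"].min()
            rows.append((gid, round(float(fl), 2), round(float(ml), 2),
                         round(fl / ml, 2) if ml > 0 else float("nan")))
        table = pd.DataFrame(rows, columns=["group", "female_cM", "male_cM",
                                            "ratio"])
        out["per_group"] = table
        valid = table["ratio"].dropna()
        if len(valid):
            out["female_male_ratio_median"] = round(float(valid.median()), 2)
    return out


def write_mapchart(lm: LinkageMap, path) -> None:
    """MAPCHART-style text export: group header then marker<TAB>position."""
    with open(path, "w") as fh:
        for gid, df in lm.groups.items():
            fh.write(f"group {gid}\n")
            for _, row in df.iterrows():
                fh.write(f"{row['marker']}\t{row['pos_cM']:.2f}\n")
            fh.write("\n")
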