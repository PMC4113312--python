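"""Genome-evolution simulator with full ground truth.

Generates the inputs the comparative analyses consume: transcript sets with
genomic locations, whole-genome duplications (WGD) at controlled pairwise
divergence, chromosome fissions/fusions/translocations, scaffold
fragmentation with optional chimera injection, half-sib meioses on a known
genetic map, and tissue expression matrices with planted specialized
transcripts.  Every emitted object is recorded in a :class:`SimTruth` so
downstream recovery tests have an oracle.

Divergence model
----------------
A divergence event of size ``d`` places exactly ``round(d * L)``
substitutions at distinct interior sites of each gene, each to a different
base, and splits the sites at random between the two descendant copies;
the two copies therefore differ at exactly ``round(d * L)`` sites, i.e.
their ungapped identity is exactly ``1 - d`` (gene lengths are multiples
of 100 so the product is integral for two-decimal ``d``).  The terminal
``end_protect`` bases are never mutated, which keeps local alignments
full-length and identity bookkeeping exact.  Indels are off by default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# --------------------------------------------------------------------------
# configuration and truth records


@dataclass
class FamilyConfig:
    n_progeny_per_father: list[int] = field(default_factory=lambda: [48, 44])
    missing_rate: float = 0.05
    mother_het: float = 0.45
    father_het: float = 0.45
    female_map_expansion: float = 1.0  # female cM per male cM


@dataclass
class ExpressionConfig:
    n_tissues: int = 13
    n_specialized_per_tissue: int = 10
    baseline_dispersion: float = 1.0  # sigma of the log-normal tissue mean
    baseline_mean: float = 50.0      # median baseline count
    boost: float = 100.0             # fold boost of a planted specialization


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    seed: int = 0
    n_chromosomes_ancestral: int = 24
    genes_per_chromosome: int = 10
    gene_length_range: tuple[int, int] = (300, 600)  # multiples of 100 used
    intergenic_range: tuple[int, int] = (200, 500)
    per_site_divergence: float = 0.18
    indel_rate: float = 0.0
    end_protect: int = 16
    wgd_rounds: list[float] = field(default_factory=list)
    loss_fraction: float = 0.0
    scaffold_n: int = 48
    chimera_inject: bool = False
    family: FamilyConfig = field(default_factory=FamilyConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def __post_init__(self):
        for frac in (self.per_site_divergence, self.indel_rate,
                     self.loss_fraction, self.family.missing_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0, 1]: {frac}")
        if self.n_chromosomes_ancestral < 1:
            raise ValueError("need at least one chromosome")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimTruth:
    """Ground-truth record: ancestry, events, maps and plantings."""

    ancestry: dict[str, tuple[str | None, str]] = field(default_factory=dict)
    roots: dict[str, str] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str, str, float]] = field(default_factory=list)
    chrom_ancestors: dict[str, list[str]] = field(default_factory=dict)
    chrom_events: list[dict] = field(default_factory=list)
    marker_map: pd.DataFrame | None = None
    specialized: set[tuple[str, str]] = field(default_factory=set)
    chimeric_scaffolds: set[str] = field(default_factory=set)
    scaffold_origin: dict[str, str] = field(default_factory=dict)

    def copy(self) -> "SimTruth":
        return copy.deepcopy(self)


@dataclass
class Genome:
    """Transcripts with ordered positions on named chromosomes.

    ``chromosomes`` maps chromosome id to the ordered list of gene ids;
    ``gaps`` holds the intergenic gap preceding each gene.  Coordinates are
    0-based half-open and derived from lengths + gaps on demand.
    """

    sequences: dict[str, str] = field(default_factory=dict)
    chromosomes: dict[str, list[str]] = field(default_factory=dict)
    gaps: dict[str, list[int]] = field(default_factory=dict)

    def copy(self) -> "Genome":
        return Genome(dict(self.sequences),
                      {c: list(g) for c, g in self.chromosomes.items()},
                      {c: list(g) for c, g in self.gaps.items()})

    @property
    def n_genes(self) -> int:
        return len(self.sequences)

    def locations(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.chromosomes):
            pos = 0
            for gid, gap in zip(self.chromosomes[chrom], self.gaps[chrom]):
                pos += gap
                L = len(self.sequences[gid])
                rows.append((gid, chrom, pos, pos + L, "+"))
                pos += L
        return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand"])

    def gene_chrom(self) -> dict[str, str]:
        return {g: c for c, genes in self.chromosomes.items() for g in genes}


# --------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, length)].tobytes().decode()


def _mutate(seq: str, sites: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for i in sites:
        old = arr[i]
        choices = BASES[BASES != old]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _divergence_sites(length: int, d: float, end_protect: int,
                      rng: np.random.Generator) -> np.ndarray:
    k = int(round(d * length))
    interior = np.arange(end_protect, length - end_protect)
    if k > interior.size:
        raise ValueError("divergence too high for protected gene ends")
    return rng.choice(interior, size=k, replace=False)


def diverge_pair(seq: str, d: float, end_protect: int,
                 rng: np.random.Generator) -> tuple[str, str]:
    """Two descendants of ``seq`` differing at exactly round(d*L) sites,
    split at random between the copies."""
    sites = _divergence_sites(len(seq), d, end_protect, rng)
    pick = rng.random(sites.size) < 0.5
    a = _mutate(seq, sites[pick], rng)
    b = _mutate(seq, sites[~pick], rng)
    return a, b


# --------------------------------------------------------------------------
# core operations


def simulate_ancestral_genome(config: SimConfig,
                              rng: np.random.Generator | None = None
                              ) -> tuple[Genome, SimTruth]:
    """Root genome: non-overlapping genes laid along ancestral chromosomes."""
    rng = config.rng() if rng is None else rng
    lo, hi = config.gene_length_range
    lengths = np.arange((lo + 99) // 100 * 100, hi + 1, 100)
    if lengths.size == 0:
        raise ValueError("gene_length_range admits no multiple of 100")
    genome = Genome()
    truth = SimTruth()
    counter = 0
    for c in range(1, config.n_chromosomes_ancestral + 1):
        chrom = f"chr{c:02d}"
        genome.chromosomes[chrom] = []
        genome.gaps[chrom] = []
        truth.chrom_ancestors[chrom] = [chrom]
        for _ in range(config.genes_per_chromosome):
            counter += 1
            gid = f"g{counter:05d}"
            L = int(rng.choice(lengths))
            genome.sequences[gid] = _random_seq(rng, L)
            genome.chromosomes[chrom].append(gid)
            genome.gaps[chrom].append(int(rng.integers(*config.intergenic_range)))
            truth.ancestry[gid] = (None, "none")
            truth.roots[gid] = gid
    return genome, truth


def apply_wgd(genome: Genome, truth: SimTruth, divergence_d: float,
              rng: np.random.Generator, label: str = "wgd",
              end_protect: int = 16) -> tuple[Genome, SimTruth]:
    """Whole-genome duplication: chromosome and gene counts double and each
    duplicate pair ends up at exactly ``1 - divergence_d`` ungapped identity."""
    if genome.n_genes == 0:
        raise ValueError("cannot duplicate an empty genome")
    new = Genome()
    t = truth.copy()
    for chrom in sorted(genome.chromosomes):
        for copy_tag in ("1", "2"):
            cc = f"{chrom}-{copy_tag}"
            new.chromosomes[cc] = []
            new.gaps[cc] = list(genome.gaps[chrom])
            t.chrom_ancestors[cc] = list(t.chrom_ancestors.get(chrom, [chrom]))
        t.chrom_events.append({"event": label, "chrom": chrom,
                               "products": [f"{chrom}-1", f"{chrom}-2"]})
        for gid in genome.chromosomes[chrom]:
            a, b = diverge_pair(genome.sequences[gid], divergence_d,
                                end_protect, rng)
            ga, gb = f"{gid}.1", f"{gid}.2"
            new.sequences[ga] = a
            new.sequences[gb] = b
            new.chromosomes[f"{chrom}-1"].append(ga)
            new.chromosomes[f"{chrom}-2"].append(gb)
            root = t.roots.get(gid, gid)
            t.ancestry[ga] = (gid, label)
            t.ancestry[gb] = (gid, label)
            t.roots[ga] = root
            t.roots[gb] = root
            t.duplicate_pairs.append((ga, gb, label, divergence_d))
        for key in (chrom,):
            t.chrom_ancestors.pop(key, None)
    return new, t


def apply_loss(genome: Genome, truth: SimTruth, loss_fraction: float,
               rng: np.random.Generator) -> tuple[Genome, SimTruth]:
    """Delete a fraction of post-WGD duplicate copies (one per chosen pair)."""
    new = genome.copy()
    t = truth.copy()
    pairs = [p for p in t.duplicate_pairs
             if p[0] in new.sequences and p[1] in new.sequences]
    n_lose = int(round(loss_fraction * len(pairs)))
    idx = rng.choice(len(pairs), size=n_lose, replace=False) if n_lose else []
    for i in idx:
        ga, gb = pairs[i][0], pairs[i][1]
        victim = ga if rng.random() < 0.5 else gb
        del new.sequences[victim]
        for chrom, genes in new.chromosomes.items():
            if victim in genes:
                k = genes.index(victim)
                genes.pop(k)
                new.gaps[chrom].pop(k)
                break
    return new, t


def speciate(genome: Genome, truth: SimTruth, divergence_d: float,
             rng: np.random.Generator, prefix: str = "sp2",
             end_protect: int = 16):
    """Split one lineage into two species at pairwise divergence ``d``.

    Returns ``((genome_a, truth_a), (genome_b, truth_b))``; orthologues keep
    equal root ids across the two truths.  Chromosome names in the second
    species keep their ancestral labels, gene ids get ``prefix|``.
    """
    ga = genome.copy()
    ta = truth.copy()
    gb = Genome(chromosomes={c: [f"{prefix}|{g}" for g in genes]
                             for c, genes in genome.chromosomes.items()},
                gaps={c: list(g) for c, g in genome.gaps.items()})
    tb = truth.copy()
    tb.ancestry = {}
    tb.roots = {}
    tb.duplicate_pairs = []
    for gid in sorted(genome.sequences):
        sa, sb = diverge_pair(genome.sequences[gid], divergence_d,
                              end_protect, rng)
        ga.sequences[gid] = sa
        bid = f"{prefix}|{gid}"
        gb.sequences[bid] = sb
        tb.ancestry[bid] = (gid, "speciation")
        tb.roots[bid] = truth.roots.get(gid, gid)
    return (ga, ta), (gb, tb)


# --------------------------------------------------------------------------
# rearrangements


@dataclass
class Fission:
    chrom: str
    after_gene: int  # break after this many genes (1 .. n-1)


@dataclass
class Fusion:
    chrom_a: str
    chrom_b: str


@dataclass
class Translocation:
    src: str
    start_gene: int
    n_genes: int
    dest: str
    insert_after: int  # gene index on dest; -1 -> prepend, len -> append


def apply_rearrangement(genome: Genome, truth: SimTruth, directive,
                        rng: np.random.Generator | None = None
                        ) -> tuple[Genome, SimTruth]:
    """Apply a fission/fusion/translocation; gene content is conserved."""
    new = genome.copy()
    t = truth.copy()
    if isinstance(directive, Fission):
        genes = new.chromosomes.pop(directive.chrom)
        gaps = new.gaps.pop(directive.chrom)
        k = directive.after_gene
        if not 0 < k < len(genes):
            raise ValueError("fission breakpoint must fall between genes")
        for tag, sl in (("a", slice(None, k)), ("b", slice(k, None))):
            cc = f"{directive.chrom}{tag}"
            new.chromosomes[cc] = genes[sl]
            new.gaps[cc] = gaps[sl]
            t.chrom_ancestors[cc] = list(t.chrom_ancestors.get(directive.chrom,
                                                               [directive.chrom]))
        t.chrom_ancestors.pop(directive.chrom, None)
        t.chrom_events.append({"event": "fission", "chrom": directive.chrom,
                               "products": [f"{directive.chrom}a",
                                            f"{directive.chrom}b"]})
    elif isinstance(directive, Fusion):
        a, b = directive.chrom_a, directive.chrom_b
        cc = f"{a}+{b}"
        new.chromosomes[cc] = new.chromosomes.pop(a) + new.chromosomes.pop(b)
        new.gaps[cc] = new.gaps.pop(a) + new.gaps.pop(b)
        t.chrom_ancestors[cc] = (t.chrom_ancestors.get(a, [a])
                                 + t.chrom_ancestors.get(b, [b]))
        t.chrom_ancestors.pop(a, None)
        t.chrom_ancestors.pop(b, None)
        t.chrom_events.append({"event": "fusion", "chroms": [a, b],
                               "product": cc})
    elif isinstance(directive, Translocation):
        src, dest = directive.src, directive.dest
        i, k = directive.start_gene, directive.n_genes
        seg = new.chromosomes[src][i:i + k]
        seg_gaps = new.gaps[src][i:i + k]
        if len(seg) != k:
            raise ValueError("translocation segment out of range")
        new.chromosomes[src] = (new.chromosomes[src][:i]
                                + new.chromosomes[src][i + k:])
        new.gaps[src] = new.gaps[src][:i] + new.gaps[src][i + k:]
        j = directive.insert_after + 1
        new.chromosomes[dest] = (new.chromosomes[dest][:j] + seg
                                 + new.chromosomes[dest][j:])
        new.gaps[dest] = new.gaps[dest][:j] + seg_gaps + new.gaps[dest][j:]
        t.chrom_ancestors[dest] = sorted(set(t.chrom_ancestors.get(dest, [dest])
                                             + t.chrom_ancestors.get(src, [src])))
        t.chrom_events.append({"event": "translocation", "src": src,
                               "dest": dest, "genes": seg,
                               "junction_after": j - 1})
    else:
        raise TypeError(f"unknown directive {directive!r}")
    return new, t


# --------------------------------------------------------------------------
# scaffolding


def fragment_into_scaffolds(genome: Genome, truth: SimTruth, scaffold_n: int,
                            chimera_inject: int | bool, rng: np.random.Generator,
                            protected_gaps: set[tuple[str, int]] | None = None,
                            forced_cuts: set[tuple[str, int]] | None = None,
                            chimera_exclude: set[str] | None = None
                            ) -> tuple[Genome, pd.DataFrame, SimTruth]:
    """Cut chromosomes at random inter-gene points into scaffolds.

    Returns ``(scaffolds, anchors, truth')`` where ``anchors`` maps each
    scaffold to its linkage group (source chromosome) with its rank along
    the group.  ``chimera_inject`` joins that many scaffold pairs from
    *different* chromosomes into single mis-assembled scaffolds, flagged in
    the truth record.  ``protected_gaps`` are (chrom, gap_index) inter-gene
    points that must not be cut at random and ``forced_cuts`` are points
    that are always cut, so a planted junction can be kept mid-scaffold
    with intact flanking scaffolds; ``chimera_exclude`` chromosomes never
    contribute scaffolds to chimera joins.
    """
    n_chrom = len(genome.chromosomes)
    if scaffold_n < n_chrom:
        raise ValueError("need at least one scaffold per chromosome")
    protected = protected_gaps or set()
    forced = forced_cuts or set()
    all_gaps = [(c, i) for c in sorted(genome.chromosomes)
                for i in range(1, len(genome.chromosomes[c]))
                if (c, i) not in protected and (c, i) not in forced]
    n_cuts = min(max(scaffold_n - n_chrom - len(forced), 0), len(all_gaps))
    cut_idx = rng.choice(len(all_gaps), size=n_cuts, replace=False) if n_cuts else []
    cuts: dict[str, list[int]] = {}
    for c, i in forced:
        cuts.setdefault(c, []).append(i)
    for j in cut_idx:
        c, i = all_gaps[j]
        cuts.setdefault(c, []).append(i)
    scaffolds = Genome(sequences=genome.sequences)
    t = truth.copy()
    rows = []
    sid = 0
    for chrom in sorted(genome.chromosomes):
        genes = genome.chromosomes[chrom]
        gaps = genome.gaps[chrom]
        bounds = [0] + sorted(cuts.get(chrom, [])) + [len(genes)]
        for order, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            sid += 1
            name = f"sc{sid:04d}"
            scaffolds.chromosomes[name] = genes[a:b]
            scaffolds.gaps[name] = gaps[a:b]
            t.scaffold_origin[name] = chrom
            rows.append((name, chrom, order))
    anchors = pd.DataFrame(rows, columns=["scaffold", "linkage_group", "lg_order"])
    n_chim = int(chimera_inject)
    excl = chimera_exclude or set()
    for _ in range(n_chim):
        # join two scaffolds from different chromosomes into one artefact
        cand = [s for s in anchors["scaffold"]
                if t.scaffold_origin[s] not in excl]
        while True:
            s1, s2 = (cand[i] for i in rng.choice(len(cand), 2, replace=False))
            if (t.scaffold_origin[s1] != t.scaffold_origin[s2]
                    and s1 not in t.chimeric_scaffolds
                    and s2 not in t.chimeric_scaffolds):
                break
        scaffolds.chromosomes[s1] = (scaffolds.chromosomes[s1]
                                     + scaffolds.chromosomes.pop(s2))
        scaffolds.gaps[s1] = scaffolds.gaps[s1] + scaffolds.gaps.pop(s2)
        t.chimeric_scaffolds.add(s1)
        anchors = anchors[anchors["scaffold"] != s2].reset_index(drop=True)
    return scaffolds, anchors, t


# --------------------------------------------------------------------------
# genetic map + half-sib meioses


def make_marker_map(n_groups: int = 25, markers_per_group: int = 20,
                    spacing_cM: float = 2.7) -> pd.DataFrame:
    """Evenly spaced true marker map: columns marker, lg, pos_cM."""
    rows = []
    for g in range(1, n_groups + 1):
        for m in range(markers_per_group):
            rows.append((f"m{g:02d}_{m:02d}", f"LG{g:02d}", m * spacing_cM))
    return pd.DataFrame(rows, columns=["marker", "lg", "pos_cM"])


def haldane_r(d_cM: float) -> float:
    """Recombination fraction of a ``d`` cM interval under Haldane."""
    if d_cM < 0:
        raise ValueError("negative map interval")
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


@dataclass
class GenotypeTable:
    """Marker x individual allele calls for a half-sib family.

    ``data`` holds "a/b" strings (missing ``-``); columns are ``mother``,
    one column per father, then progeny.  ``progeny_father`` maps each
    progeny to its father column.
    """

    data: pd.DataFrame
    mother: str
    fathers: list[str]
    progeny_father: dict[str, str]
    missing_code: str = "-"

    @property
    def markers(self) -> list[str]:
        return list(self.data.index)

    @property
    def progeny(self) -> list[str]:
        return list(self.progeny_father)

    def missing_fraction(self) -> pd.Series:
        prog = self.data[self.progeny]
        return (prog == self.missing_code).sum(axis=1) / prog.shape[1]


def simulate_half_sib_family(true_map: pd.DataFrame, config: FamilyConfig,
                             rng: np.random.Generator) -> GenotypeTable:
    """Simulate meioses for a two-father/one-mother half-sib family.

    Parents are heterozygous at a marker with the configured probabilities;
    allele labels are parent-specific so the transmitted allele is always
    recoverable when the parent is heterozygous.  Crossovers follow the
    inverse-Haldane probability of each cM interval, without interference;
    the female map is scaled by ``female_map_expansion``.  Missing calls
    are injected completely at random.
    """
    markers = true_map["marker"].tolist()
    fathers = [f"father{i+1}" for i in range(len(config.n_progeny_per_father))]
    progeny = []
    progeny_father = {}
    for fa, n in zip(fathers, config.n_progeny_per_father):
        for i in range(n):
            pid = f"{fa}_o{i+1:03d}"
            progeny.append(pid)
            progeny_father[pid] = fa
    # parent genotypes: mother alleles {101,102}, father_k alleles {201+2k, ...}
    het = {"mother": rng.random(len(markers)) < config.mother_het}
    for fa in fathers:
        het[fa] = rng.random(len(markers)) < config.father_het
    par_alleles = {}
    for pi, par in enumerate(["mother"] + fathers):
        base = 101 + 10 * pi
        par_alleles[par] = [(str(base), str(base + 1)) if h else (str(base), str(base))
                            for h in het[par]]

    def meiosis(parent: str, expansion: float) -> np.ndarray:
        """Transmitted allele index (0/1) at every marker for one gamete."""
        out = np.zeros(len(markers), dtype=np.int8)
        pos = true_map["pos_cM"].to_numpy()
        lgs = true_map["lg"].to_numpy()
        cur = rng.integers(0, 2)
        for i in range(len(markers)):
            if i == 0 or lgs[i] != lgs[i - 1]:
                cur = rng.integers(0, 2)
            else:
                d = (pos[i] - pos[i - 1]) * expansion
                if rng.random() < haldane_r(d):
                    cur = 1 - cur
            out[i] = cur
        return out

    fexp = config.female_map_expansion
    cols = {}
    cols["mother"] = ["/".join(sorted(a)) for a in par_alleles["mother"]]
    for fa in fathers:
        cols[fa] = ["/".join(sorted(a)) for a in par_alleles[fa]]
    for pid in progeny:
        fa = progeny_father[pid]
        mg = meiosis("mother", fexp)
        fg = meiosis(fa, 1.0)
        calls = []
        for i in range(len(markers)):
            am = par_alleles["mother"][i][mg[i]]
            af = par_alleles[fa][i][fg[i]]
            if rng.random() < config.missing_rate:
                calls.append("-")
            else:
                calls.append("/".join(sorted([am, af])))
        cols[pid] = calls
    data = pd.DataFrame(cols, index=markers)
    return GenotypeTable(data=data, mother="mother", fathers=fathers,
                         progeny_father=progeny_father)


# --------------------------------------------------------------------------
# expression


def simulate_expression(n_transcripts: int, config: ExpressionConfig,
                        rng: np.random.Generator,
                        lengths: np.ndarray | None = None):
    """Overdispersed count matrix with planted tissue specializations.

    Baseline: per-transcript log-normal mean, i.i.d. Poisson counts per
    tissue.  Each planted (transcript, tissue) gets its Poisson mean
    multiplied by ``boost`` in exactly one tissue, which exceeds the
    mean + 3 SD rule in expectation.  Returns (counts DataFrame, lengths
    Series, truth).
    """
    nt = config.n_tissues
    n_spec = config.n_specialized_per_tissue * nt
    if n_spec > n_transcripts:
        raise ValueError("more planted specializations than transcripts")
    tissues = [f"tissue{i+1:02d}" for i in range(nt)]
    tids = [f"t{i+1:05d}" for i in range(n_transcripts)]
    if lengths is None:
        lengths = rng.integers(3, 31, n_transcripts) * 100
    lengths = pd.Series(np.asarray(lengths), index=tids, name="length")
    mu = config.baseline_mean * rng.lognormal(0.0, config.baseline_dispersion,
                                              n_transcripts)
    lam = np.tile(mu[:, None], (1, nt))
    truth = SimTruth()
    chosen = rng.choice(n_transcripts, size=n_spec, replace=False)
    for j, tr in enumerate(chosen):
        tissue = j % nt
        lam[tr, tissue] *= config.boost
        truth.specialized.add((tids[tr], tissues[tissue]))
    counts = rng.poisson(lam)
    counts = np.maximum(counts, 0)
    # generator contract: no all-zero tissue library
    for j in range(nt):
        if counts[:, j].sum() == 0:
            counts[0, j] = 1
    df = pd.DataFrame(counts, index=tids, columns=tissues)
    return df, lengths, truth
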