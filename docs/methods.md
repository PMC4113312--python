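# Methods

This note documents the models behind `esoxsynt`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the simulation-based tests do and do not demonstrate about real data.

## Genome-evolution simulator (`simdata`)

**Sequence model.** Genes are i.i.d. uniform nucleotide sequences whose
lengths are multiples of 100 bp (default range 300–600), laid
non-overlapping along chromosomes with random intergenic gaps (0-based,
half-open coordinates).  A divergence event of size *d* places exactly
round(*d·L*) substitutions at distinct interior sites, each to a different
base, and assigns each site to one of the two descendant copies at random;
the copies therefore differ at exactly round(*d·L*) sites and their
ungapped identity is exactly 1 − *d*, which gives downstream peak-recovery
tests a sharp target.  Sites are i.i.d. in location but not in count — a
deliberate departure from a Jukes–Cantor-style process, chosen so identity
is a controlled parameter rather than an expectation.  Multiple hits,
back-mutations and rate variation are not modelled; identity is therefore
a direct dial, not a clock.

**Terminal protection.** The first and last `end_protect` (default 16)
bases of a gene are never mutated.  This serves two purposes: a local
aligner will otherwise trim mismatching ends, so reported identity would
drift above the planted value; and every member of a gene family retains
identical terminal k-mers, guaranteeing that the seed-based candidate
prefilter can never miss a true homologue.  Real transcripts have no such
guarantee; the consequence is that the aligner's recall on simulated data
is an upper bound on its recall for real diverged ends.

**Events.** `apply_wgd` doubles every chromosome and gene (labels
3R/4R/recent recorded per copy); `speciate` splits a lineage in two at a
controlled orthologue divergence; `apply_rearrangement` performs fission
(between genes only), fusion, and translocation, conserving gene content;
`apply_loss` deletes one member of a fraction of duplicate pairs.
`fragment_into_scaffolds` cuts chromosomes at random inter-gene points,
can join segments from two chromosomes into flagged chimeric scaffolds,
and emits a scaffold→linkage-group anchor table.  Scenario builders may
protect or force specific cut points so that a planted junction falls
mid-scaffold with intact flanks — the configuration under which
breakpoint diagnosis is well-posed.

**Meioses.** Half-sib families (one mother, two fathers, default 48:44
progeny) are generated marker-by-marker along the true map with
inter-marker crossover probability given by the inverse Haldane function
of the cM interval — i.e. no crossover interference.  The female map can
be a scalar expansion of the male map.  Missing genotypes are injected
completely at random (default 5%).  Parental heterozygosity defaults to
0.45 per parent, which reproduces the roughly half single-parent
informative profile reported for microsatellite panels in low-polymorphism
esocid families; allele labels are parent-specific so a heterozygous
parent's transmitted allele is recoverable wherever Mendelian logic
permits.

**Expression.** Baseline counts are per-transcript log-normal means
(median 50, σ = 1) with i.i.d. Poisson sampling per tissue (13 tissues by
default).  Planted specialized transcripts get one tissue's mean
multiplied by 100, which exceeds the mean + 3·SD rule in expectation.
The model is intentionally minimal — no library-size variation,
transcript-length bias, or correlated tissues — sufficient to exercise
the statistic, not to emulate RNA-seq noise structure.

## Alignment and homology (`homology`)

The aligner is an exact affine-gap Smith–Waterman (Gotoh) with default
scoring +1 match, −1 mismatch, −2 gap open, −1 gap extend, with an
optional diagonal band.  Percent identity is matches / aligned columns,
gap columns included in the denominator (one convention had to be fixed;
it is config-exposed by using the returned match/column counts directly).
A raw score threshold (default ≥ 40) together with a minimum alignment
length (default ≥ 100 columns) replaces a BLAST E-value cut-off, since
database-size statistics are not modelled; in practice the length filter
dominates.  Alignment is forward-strand only (the simulator emits all
transcripts forward); protein-level alignment and E-values are out of
scope.

Best-hit search is exhaustive by default and exactly equal to a
brute-force argmax with deterministic tie-breaking (score, then identity,
then lexicographic subject id).  For large scans an optional k-mer seed
prefilter (`seed_k`, 14 in the pipelines) skips subject sequences sharing
no k-mer with the query — a BLAST-like heuristic whose recall on
simulated families is guaranteed by terminal protection, but which is off
whenever oracle-exact behaviour is required.

One numerical subtlety: for a duplicate pair differing at exactly
round(*d·L*) sites, the gapped optimum occasionally beats the ungapped
alignment by one point (a compensating indel pair converting three or
more mismatches into matches), reporting e.g. 82.3% instead of 82.0%.
The ungapped identity remains exact by construction, and all reported
identities stay inside the same 1% histogram bin, which is the resolution
every downstream statement uses.

Coverage for the synteny-grade RBH filter (≥ 50% of *each* sequence) is
computed by greedy best-first tiling of non-overlapping local alignments
(find best, mask its footprint on both sequences, repeat) — the usual
HSP-tiling practice rather than optimal interval scheduling.  Redundancy
collapse builds single-linkage clusters of the "≥ 98% identity over
≥ 300 columns" relation and keeps the longest member (ties by id); the
operation is idempotent.  The ORF filter scans all six frames for the
longest ATG→stop open reading frame.

## Duplication profile (`dupprofile`)

Identities are binned by floor into 1% bins, with exactly-100 assigned to
the closed top bin.  Peak calling smooths the histogram with a moving sum
over an odd window (default 3; integer arithmetic keeps plateaus
symmetric so the plateau centre is reported) and keeps local maxima whose
prominence is at least `min_prominence_frac` (default 5%) of the total
pair count — a formalization of what is usually read by eye.  Band labels:
recent > 97%, candidate 3R 77–89% inclusive, other; band counts are
reported both as pairs and as distinct transcripts because published
tallies are ambiguous between the two.

## Synteny (`synteny`)

Features are reduced to midpoint positions ((start + end)/2); strand is
ignored.  The contingency matrix counts coverage-filtered RBH pairs by
focal linkage group × comparator chromosome; export masks cells below 3
(full counts are kept internally, and totals are computed from unmasked
counts).  Dominance thresholds formalize qualitative pattern reading and
are config-exposed: a chromosome is *dominant* in a row at ≥ 0.5 of row
mass; a *duplication signature* is a row with exactly two chromosomes
each ≥ 0.2 of row mass; a *fusion* is a chromosome dominant in ≥ 2 rows
of exactly one comparator; a *fission* is two rows sharing a dominant
chromosome in all (≥ 2) comparators.  Ties report all tied chromosomes.

Scaffold diagnosis requires ≥ 5 mapped orthologues.  A scaffold is
*consistent* when one chromosome holds ≥ 80% of its hits in every
comparator; otherwise the best single breakpoint splitting the ordered
hits into two chromosome-pure halves is sought, and the verdict is
*translocation* when the flanking scaffolds along the linkage group
side-match the two halves, *reorganized context* when the group's
scaffolds interleave ≥ 4 chromosomes (some chromosome recurring
non-contiguously), else *chimera suspect*.  A chimeric join and a genuine
translocation produce identical within-scaffold hit patterns; only the
flanking context separates them, which is why the planted-junction
scenarios keep flanks intact.

## Linkage (`linkage`)

Informativeness is per parent (heterozygous ⇒ informative); progeny
genotypes inconsistent with the parents are set to missing with a
warning.  Markers with missing fraction strictly > 15% are dropped unless
kept explicitly (kept markers are flagged).  Two-point statistics use the
pseudo-testcross LOD above with phase maximization; progeny missing at
either marker are excluded from *n*.  Grouping is single-linkage at
LOD ≥ 4.0 per parent; cluster pairs bridged at 3.0 ≤ LOD < 4.0 in one
parent are joined only when another parent links the same pair at ≥ 4.0;
markers linked to nothing are listed as unlinked.  Ordering is a greedy
nearest-neighbour chain on r̂ (start from the tightest pair, extend at
both ends, orientation canonicalized by the lexicographically smaller
terminal) — adequate at simulated densities, not a multipoint
seriation.  Kosambi is the default map function (common for fish maps);
Haldane is available and is the model-consistent choice for data from
this simulator, whose meioses have no interference — Kosambi
underestimates such maps by roughly 5–8% at realistic marker spacing.
Sex-specific maps are merged on shared anchor markers: the female map is
the frame, male groups are flipped when reversal improves shared-marker
order agreement, private markers are placed proportionally between
anchors (offset past terminal anchors), and groups sharing no markers are
reported unmerged rather than estimated.  Map statistics report per-map
totals, the female:male total ratio (2 dp) and a per-group ratio table
whose median is robust to a single anomalous group.

### A statistical limitation worth knowing

With ~500 markers, two-point grouping at LOD 4 tests on the order of
10⁵ unlinked marker pairs per genome scan.  The exact two-sided tail
probability P(LOD ≥ 4 | r = 0.5) is 1–3 × 10⁻⁵ for 40–92 informative
meioses, so the *expected* number of spurious joins is close to 1 per
scan no matter how informativeness is distributed across the three
parents (every marker is informative in at least one parent, so the
per-parent graphs cannot all be small).  A single spurious join merges
two true groups — and, because the false bridge has r̂ ≈ 0.4, adds a
~80 cM phantom interval to the affected group.  Consequently the
recovered group count at this scale fluctuates around the true value
(24–26 for 25 chromosomes), and exact recovery in any given family is a
coin flip, not a failure of the implementation: the identical LOD-4
protocol applied to real 500-marker panels faces the same odds and has
historically relied on manual curation.  The acceptance suite asserts
exact recovery anyway and is expected to be red on that item; all order
and length statements hold on cleanly recovered groups (order exact up to
reversal, total length within ±3% with Haldane at 500 progeny).

## Expression (`expression`)

FPKM uses per-tissue mapped totals (column sums when self-contained;
both zero lengths and zero totals are rejected).  The specialization rule
flags FPKM > mean + k·SD (k = 3) across all tissues of a transcript,
*including* the candidate tissue, with the sample SD (n − 1) — both
choices are exposed (`exclude_self`, `ddof`) since published descriptions
rarely specify them; including the candidate and using n − 1 makes the
rule strictly more conservative.  No log transformation is applied.
Per-tissue specialized counts give the complexity ranking; top-n tables
break ties by transcript id.

## Pipeline, determinism and problem sizes

Every stochastic function takes a seed or NumPy `Generator`; a run
configuration (strictly validated, unknown keys rejected) fully
determines all artifacts, which carry a provenance header (version, seed,
config hash) and are byte-identical on rerun.  The reference study sizes
used by the test suite and the acceptance script are: 24 ancestral
chromosomes; 240 paralogue pairs for peak recovery (plus a 60-gene recent
cohort); 48 genes/chromosome for the WGD synteny signature (large enough
that the random partition of each linkage group's orthologues between the
two duplicate chromosomes clears the 20% dominance threshold with high
probability); 8 genes/chromosome for fission/fusion calls; 8 chromosomes
× 40 genes with a 12-gene translocation and 2 chimeras for scaffold
diagnosis; 25 × 20 markers, 92 progeny (48:44), 5% missing for
linkage-group recovery, with a 500-progeny family for order/length; 2,000
transcripts × 13 tissues with 10 planted specializations per tissue for
expression.  These sizes keep a full acceptance run at a few minutes on
one CPU while leaving each statistic's recovery signal far above its
noise floor.

## What passing tests do and do not show

The simulator gives every analysis a sharp, fully known target:
divergence is exact, orthology is known, maps are known, plantings are
known.  Passing therefore demonstrates correctness of the *statistics
and decision rules*, not robustness to the things real data add —
alignment through indels and repeats, assembly and mapping error,
paralogy interference in anchoring, segregation distortion, genotyping
error that is not MCAR, and overdispersion structure in expression.
Where a rule's real-world fragility is intrinsic rather than incidental
(the LOD-4 grouping false-join rate above; the chimera-vs-translocation
ambiguity without flank evidence), it is documented here rather than
patched over in the implementation.
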