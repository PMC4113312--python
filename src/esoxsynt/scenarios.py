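"""Canonical simulated study scenarios for parameter-recovery evaluation.

Each function builds one in-silico study at its stated conditions, runs the
relevant analysis modules on it, and returns plain summary numbers checked
against the simulator's ground truth.  The problem sizes are the package's
reference conditions: a 24-chromosome ancestral karyotype, ~18% divergence
for the ancient (3R-like) duplication round, ~6% for a salmonid-like 4R
round, <3% for recent duplicates, ~10% between-species divergence, and a
two-father/one-mother half-sib family split 48:44.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dupprofile, homology, linkage, synteny
from .simdata import (FamilyConfig, Fission, Fusion, SimConfig, Translocation,
                      apply_rearrangement, apply_wgd, fragment_into_scaffolds,
                      make_marker_map, simulate_ancestral_genome,
                      simulate_half_sib_family, speciate)

SEED_K = 14  # k-mer prefilter for the heavier all-vs-all scans


def _ancestor(seed, n_chrom, genes, rng, lengths=(300, 600)):
    cfg = SimConfig(seed=seed, n_chromosomes_ancestral=n_chrom,
                    genes_per_chromosome=genes, gene_length_range=lengths)
    return simulate_ancestral_genome(cfg, rng)


def peak_recovery(seed: int, n_chrom: int = 24, genes: int = 10,
                  d_ancient: float = 0.18, d_recent: float = 0.02,
                  n_recent_genes: int = 60) -> dict:
    """Duplication-peak recovery: paralogue pairs at exact 18% divergence
    plus a recent (<3%) cohort; peaks read from the within-species RBH
    identity histogram."""
    rng = np.random.default_rng(seed)
    genome, truth = _ancestor(seed, n_chrom, genes, rng)
    genome, truth = apply_wgd(genome, truth, d_ancient, rng, label="3R")
    pairs = homology.reciprocal_best_hits(genome.sequences, genome.sequences,
                                          within=True, seed_k=SEED_K)
    hist = dupprofile.similarity_histogram(pairs)
    mode_ancient = hist.modal_bin()

    recent, rtruth = _ancestor(seed + 1, 6, n_recent_genes // 6, rng)
    recent, rtruth = apply_wgd(recent, rtruth, d_recent, rng, label="recent")
    union = dict(genome.sequences)
    union.update({f"r|{k}": v for k, v in recent.sequences.items()})
    pairs2 = homology.reciprocal_best_hits(union, union, within=True,
                                           seed_k=SEED_K)
    hist2 = dupprofile.similarity_histogram(pairs2)
    peaks = dupprofile.detect_peaks(hist2)
    peak_bins = sorted(p.bin for p in peaks)
    return {
        "n_pairs_ancient": len(pairs),
        "mode_bin_ancient": mode_ancient,
        "n_pairs_total": len(pairs2),
        "peak_bins": peak_bins,
        "has_recent_peak": any(b > 97 for b in peak_bins),
        "has_ancient_peak": 82 in peak_bins,
    }


def _species_trio(seed, n_chrom, genes, d_species=0.10, d_wgd=0.06):
    """Focal species plus a plain comparator and a one-round-WGD comparator."""
    rng = np.random.default_rng(seed)
    ancestor, truth0 = _ancestor(seed, n_chrom, genes, rng)
    (focal, ftruth), (comp1, c1truth) = speciate(ancestor, truth0, d_species,
                                                 rng, prefix="cmpA")
    (focal, ftruth), (comp2, c2truth) = speciate(focal, ftruth, d_species,
                                                 rng, prefix="cmpB")
    if d_wgd is not None:
        comp2, c2truth = apply_wgd(comp2, c2truth, d_wgd, rng, label="4R")
    return rng, (focal, ftruth), (comp1, c1truth), (comp2, c2truth)


def _identity_anchors(genome):
    """Anchor table treating each chromosome as its own linkage group."""
    chroms = sorted(genome.chromosomes)
    return pd.DataFrame({"scaffold": chroms, "linkage_group": chroms,
                         "lg_order": 0})


def _matrix(focal, comp, name, min_cov=0.5):
    pairs = homology.rbh_with_coverage(focal.sequences, comp.sequences,
                                       min_cov=min_cov, seed_k=SEED_K)
    tlg = synteny.anchor_transcripts(focal.locations(),
                                     _identity_anchors(focal))
    return synteny.build_synteny_matrix(pairs, tlg, comp.locations(), name)


def wgd_signature(seed: int, n_chrom: int = 24, genes: int = 48) -> dict:
    """Two-dominant-chromosome rows against a one-round-WGD comparator and
    1:1 rows against a plain comparator, for every focal linkage group."""
    rng, (focal, _), (comp1, _), (comp2, _) = _species_trio(seed, n_chrom,
                                                            genes)
    mat_plain = _matrix(focal, comp1, "plain")
    mat_dup = _matrix(focal, comp2, "wgd")
    n_lg = len(mat_dup.counts.index)
    two_dom = 0
    for lg, row in mat_dup.counts.iterrows():
        tot = row.sum()
        if tot and (row >= 0.2 * tot).sum() == 2:
            two_dom += 1
    one_dom = 0
    for lg, row in mat_plain.counts.iterrows():
        tot = row.sum()
        if tot and (row >= 0.2 * tot).sum() == 1 and (row > 0).sum() == 1:
            one_dom += 1
    calls = synteny.classify_patterns({"plain": mat_plain, "wgd": mat_dup})
    dup_calls = calls[(calls["pattern"] == "duplication")
                      & (calls["comparator"] == "wgd")]
    return {
        "n_lg": n_lg,
        "frac_two_dominant": two_dom / n_lg if n_lg else 0.0,
        "frac_one_to_one": one_dom / len(mat_plain.counts.index),
        "n_duplication_calls": int(dup_calls["linkage_groups"].nunique()),
        "grand_total_pairs": mat_dup.grand_total,
    }


def fission_fusion(seed: int, n_chrom: int = 24, genes: int = 8) -> dict:
    """One focal-lineage fission + one comparator-lineage fusion; pattern
    classification must recover both with no false calls."""
    rng, (focal, ftruth), (comp1, c1truth), (comp2, c2truth) = _species_trio(
        seed, n_chrom, genes, d_wgd=None)
    focal, ftruth = apply_rearrangement(
        focal, ftruth, Fission("chr01", after_gene=genes // 2), rng)
    comp1, c1truth = apply_rearrangement(
        comp1, c1truth, Fusion("chr02", "chr03"), rng)
    matrices = {"compA": _matrix(focal, comp1, "compA"),
                "compB": _matrix(focal, comp2, "compB")}
    calls = synteny.classify_patterns(matrices)
    fissions = calls[calls["pattern"] == "fission"]
    fusions = calls[calls["pattern"] == "fusion"]
    fission_ok = (len(fissions) == 1
                  and fissions.iloc[0]["linkage_groups"] == "chr01a+chr01b")
    fusion_ok = (len(fusions) == 1
                 and fusions.iloc[0]["comparator"] == "compA"
                 and set(fusions.iloc[0]["linkage_groups"].split("+"))
                 == {"chr02", "chr03"})
    false_calls = (len(fissions) - int(fission_ok)
                   + len(fusions) - int(fusion_ok))
    return {"fission_recovered": bool(fission_ok),
            "fusion_recovered": bool(fusion_ok),
            "n_false_calls": int(false_calls)}


def chimera_diagnosis(seed: int, n_chrom: int = 8, genes: int = 40,
                      seg_len: int = 12, scaffold_n: int = 40) -> dict:
    """Two injected chimeric scaffolds + one genuine translocation.

    The translocated segment is inserted mid-chromosome and the scaffold
    cutting is constrained so the junction falls mid-scaffold with intact
    flanking scaffolds (the empirically motivating configuration); chimera
    joins avoid the translocation chromosome so the two artefact classes
    stay separable.
    """
    rng, (focal, ftruth), (comp1, _), _ = _species_trio(seed, n_chrom, genes,
                                                        d_wgd=None)
    insert_after = genes // 2  # gene index on the receiving chromosome
    focal, ftruth = apply_rearrangement(
        focal, ftruth,
        Translocation(src="chr02", start_gene=5, n_genes=seg_len,
                      dest="chr05", insert_after=insert_after - 1), rng)
    p = insert_after  # first segment gene sits at index p (0-based)
    forced = {("chr05", p - 2), ("chr05", p + 3), ("chr05", p + seg_len)}
    protected = {("chr05", i) for i in range(p - 1, p + 3)}
    scaffolds, anchors, ftruth = fragment_into_scaffolds(
        focal, ftruth, scaffold_n, chimera_inject=2, rng=rng,
        protected_gaps=protected | forced, forced_cuts=forced,
        chimera_exclude={"chr05"})
    pairs = homology.rbh_with_coverage(focal.sequences, comp1.sequences,
                                       min_cov=0.5, seed_k=SEED_K)
    floc = scaffolds.locations()
    hits = synteny.hits_table(pairs, floc, comp1.locations(), "comp")
    lg_orders = {lg: sub.sort_values("lg_order")["scaffold"].tolist()
                 for lg, sub in anchors.groupby("linkage_group")}
    scaffold_lg = anchors.set_index("scaffold")["linkage_group"]
    seg_genes = set()
    for ev in ftruth.chrom_events:
        if ev.get("event") == "translocation":
            seg_genes = set(ev["genes"])
    # the scaffold spanning the planted junction
    junction_scaffold = None
    for sc in anchors["scaffold"]:
        members = set(scaffolds.chromosomes[sc])
        has_seg = bool(members & seg_genes)
        has_host = bool(members - seg_genes)
        if (ftruth.scaffold_origin[sc] == "chr05" and has_seg and has_host
                and sc not in ftruth.chimeric_scaffolds):
            junction_scaffold = sc
    results = {}
    for sc in anchors["scaffold"]:
        lg = scaffold_lg[sc]
        d = synteny.diagnose_scaffold(sc, hits[hits["scaffold"].isin(
            lg_orders[lg])], lg_orders[lg])
        results[sc] = d.verdict
    chimera_verdicts = [results.get(sc) for sc in ftruth.chimeric_scaffolds]
    translo_verdict = results.get(junction_scaffold)
    mixed = set(ftruth.chimeric_scaffolds) | {junction_scaffold}
    misflagged = [sc for sc, v in results.items()
                  if sc not in mixed and v not in (None, "consistent")]
    return {
        "translocation_recovered": translo_verdict == "translocation",
        "n_chimeras_flagged": sum(v == "chimera_suspect"
                                  for v in chimera_verdicts),
        "n_consistent_misflagged": len(misflagged),
        "junction_scaffold": junction_scaffold,
    }


def sex_ratio_recovery(seed: int, expansion: float = 1.07,
                       n_groups: int = 8, markers: int = 10,
                       spacing_cM: float = 5.0, progeny: int = 500) -> dict:
    """Recover the female:male recombination-rate ratio from a family whose
    true female map is ``expansion`` times the male map.

    Uses a fully informative single-father design (every marker scored in
    both parents over the same meioses) so the two sex maps span identical
    markers and the comparison isolates the recombination-rate difference
    rather than marker-coverage differences.
    """
    tmap = make_marker_map(n_groups, markers, spacing_cM)
    rng = np.random.default_rng(seed)
    fam = FamilyConfig(n_progeny_per_father=[progeny], missing_rate=0.05,
                       mother_het=1.0, father_het=1.0,
                       female_map_expansion=expansion)
    table = simulate_half_sib_family(tmap, fam, rng)
    table = linkage.missing_filter(table, 0.15)
    analysis = linkage.TwoPointAnalysis(table)
    grouping = linkage.group_markers(analysis, 4.0, 3.0)
    female = linkage.build_parent_map(analysis, grouping, table.mother,
                                      "haldane", sex="female")
    male = linkage.build_parent_map(analysis, grouping, table.fathers[0],
                                    "haldane", sex="male")
    stats = linkage.map_stats({"female": female, "male": male})
    return {"true_ratio": expansion,
            "recovered_ratio": float(stats["female_male_ratio_median"]),
            "recovered_ratio_total": float(stats["female_male_ratio"])}


def expression_recovery(seed: int, n_transcripts: int = 2000,
                        per_tissue: int = 10) -> dict:
    """Sensitivity/specificity of the 3-SD specialization rule on planted
    tissue-specific transcripts."""
    from .expression import fpkm, specialized_calls
    from .simdata import ExpressionConfig, simulate_expression

    rng = np.random.default_rng(seed)
    cfg = ExpressionConfig(n_specialized_per_tissue=per_tissue)
    counts, lengths, truth = simulate_expression(n_transcripts, cfg, rng)
    flags, _, _ = specialized_calls(fpkm(counts, lengths))
    planted = truth.specialized
    hit = sum(flags.at[t, tis] for t, tis in planted)
    flagged = {(t, c) for t in flags.index for c in flags.columns
               if flags.at[t, c]}
    false_cells = len(flagged - planted)
    total_neg = flags.size - len(planted)
    return {"sensitivity": hit / len(planted),
            "specificity": 1 - false_cells / total_neg,
            "n_planted": len(planted)}


def linkage_recovery(seed: int, n_groups: int = 25, markers: int = 20,
                     spacing_cM: float = 2.7,
                     progeny: tuple[int, int] = (48, 44),
                     missing: float = 0.05,
                     map_function: str = "haldane") -> dict:
    """Linkage-group recovery for one half-sib family.

    Defaults emulate the reference study's scale: 25 groups x 20 markers
    (true span 25 x 51.3 = 1282.5 cM) and 92 progeny split 48:44.
    """
    tmap = make_marker_map(n_groups, markers, spacing_cM)
    rng = np.random.default_rng(seed)
    fam = FamilyConfig(n_progeny_per_father=list(progeny),
                       missing_rate=missing)
    table = simulate_half_sib_family(tmap, fam, rng)
    table = linkage.missing_filter(table, 0.15)
    analysis = linkage.TwoPointAnalysis(table)
    grouping = linkage.group_markers(analysis, 4.0, 3.0)
    female = linkage.build_parent_map(analysis, grouping, table.mother,
                                      map_function, sex="female")
    truth_pos = tmap.set_index("marker")["pos_cM"]
    truth_lg = tmap.set_index("marker")["lg"]
    ordered_ok = total_groups = 0
    for gid, df in female.groups.items():
        total_groups += 1
        mk = df["marker"].tolist()
        if truth_lg[mk].nunique() > 1:
            continue
        tp = truth_pos[mk].tolist()
        if tp == sorted(tp) or tp == sorted(tp, reverse=True):
            ordered_ok += 1
    est_len = female.total_cM
    true_len = sum(truth_pos[df["marker"]].max() - truth_pos[df["marker"]].min()
                   for df in female.groups.values())
    return {
        "n_groups": len(grouping.groups),
        "n_unlinked": len(grouping.unlinked),
        "frac_groups_ordered": ordered_ok / total_groups if total_groups else 0.0,
        "map_length_cM": float(est_len),
        "map_length_rel_err": float((est_len - true_len) / true_len)
        if true_len else float("nan"),
    }
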