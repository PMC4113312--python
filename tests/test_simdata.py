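"""Simulator contracts: determinism, conservation, exact divergence,
rearrangements, scaffolding, meioses and expression plantings."""

import numpy as np
import pytest

from esoxsynt import io as eio
from esoxsynt.simdata import (ExpressionConfig, FamilyConfig, Fission, Fusion,
                              SimConfig, Translocation, apply_rearrangement,
                              apply_wgd, fragment_into_scaffolds, haldane_r,
                              make_marker_map, simulate_ancestral_genome,
                              simulate_expression, simulate_half_sib_family,
                              speciate)


class TestAncestralGenome:
    def test_counts_forced_by_config(self):
        cfg = SimConfig(seed=5, n_chromosomes_ancestral=24,
                        genes_per_chromosome=10)
        g, t = simulate_ancestral_genome(cfg)
        assert len(g.chromosomes) == 24
        assert g.n_genes == 240
        assert set(t.ancestry) == set(g.sequences)

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        cfg = SimConfig(seed=9, n_chromosomes_ancestral=3,
                        genes_per_chromosome=4)
        for name in ("a.fa", "b.fa"):
            g, _ = simulate_ancestral_genome(cfg)
            eio.write_fasta(g.sequences, tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_single_gene_genome(self):
        cfg = SimConfig(seed=1, n_chromosomes_ancestral=1,
                        genes_per_chromosome=1, gene_length_range=(300, 300))
        g, _ = simulate_ancestral_genome(cfg)
        (seq,) = g.sequences.values()
        assert len(seq) == 300

    def test_locations_non_overlapping_half_open(self):
        cfg = SimConfig(seed=2, n_chromosomes_ancestral=2,
                        genes_per_chromosome=5)
        g, _ = simulate_ancestral_genome(cfg)
        loc = g.locations()
        for _, sub in loc.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["end"] > sub["start"]).all()
            assert (sub["start"].to_numpy()[1:]
                    >= sub["end"].to_numpy()[:-1]).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, per_site_divergence=1.5)


class TestWgd:
    def test_doubles_counts_and_sets_exact_identity(self, rng):
        cfg = SimConfig(seed=3, n_chromosomes_ancestral=4,
                        genes_per_chromosome=5)
        g, t = simulate_ancestral_genome(cfg)
        g2, t2 = apply_wgd(g, t, 0.18, rng)
        assert len(g2.chromosomes) == 8
        assert g2.n_genes == 40
        for ga, gb, _, d in t2.duplicate_pairs:
            sa, sb = g2.sequences[ga], g2.sequences[gb]
            assert len(sa) == len(sb)
            diffs = sum(x != y for x, y in zip(sa, sb))
            assert diffs == round(d * len(sa))

    def test_zero_divergence_identical_copies(self, rng):
        cfg = SimConfig(seed=4, n_chromosomes_ancestral=1,
                        genes_per_chromosome=3)
        g, t = simulate_ancestral_genome(cfg)
        g2, t2 = apply_wgd(g, t, 0.0, rng)
        for ga, gb, _, _ in t2.duplicate_pairs:
            assert g2.sequences[ga] == g2.sequences[gb]

    def test_two_rounds_give_four_copies_depth_two(self, rng):
        cfg = SimConfig(seed=4, n_chromosomes_ancestral=1,
                        genes_per_chromosome=2)
        g, t = simulate_ancestral_genome(cfg)
        g2, t2 = apply_wgd(g, t, 0.10, rng, label="3R")
        g3, t3 = apply_wgd(g2, t2, 0.05, rng, label="4R")
        assert g3.n_genes == 8
        roots = {}
        for gid in g3.sequences:
            roots.setdefault(t3.roots[gid], []).append(gid)
            # ancestry depth 2 back to the root
            parent, ev = t3.ancestry[gid]
            assert ev == "4R"
            gparent, ev2 = t3.ancestry[parent]
            assert ev2 == "3R"
        assert all(len(v) == 4 for v in roots.values())


class TestSpeciate:
    def test_orthologue_divergence_and_roots(self, rng):
        cfg = SimConfig(seed=6, n_chromosomes_ancestral=2,
                        genes_per_chromosome=4)
        g, t = simulate_ancestral_genome(cfg)
        (ga, ta), (gb, tb) = speciate(g, t, 0.10, rng, prefix="sp2")
        assert ga.n_genes == gb.n_genes == 8
        for gid in ga.sequences:
            bid = f"sp2|{gid}"
            sa, sb = ga.sequences[gid], gb.sequences[bid]
            diffs = sum(x != y for x, y in zip(sa, sb))
            assert diffs == round(0.10 * len(sa))
            assert tb.roots[bid] == ta.roots[gid]


class TestRearrangements:
    @pytest.fixture()
    def genome(self):
        cfg = SimConfig(seed=7, n_chromosomes_ancestral=3,
                        genes_per_chromosome=6)
        return simulate_ancestral_genome(cfg)

    def test_fission_partitions_gene_set(self, genome, rng):
        g, t = genome
        before = set(g.chromosomes["chr01"])
        g2, t2 = apply_rearrangement(g, t, Fission("chr01", 3), rng)
        assert len(g2.chromosomes) == 4
        assert (set(g2.chromosomes["chr01a"]) | set(g2.chromosomes["chr01b"])
                == before)
        assert not (set(g2.chromosomes["chr01a"])
                    & set(g2.chromosomes["chr01b"]))

    def test_fission_inside_gene_rejected(self, genome, rng):
        g, t = genome
        with pytest.raises(ValueError):
            apply_rearrangement(g, t, Fission("chr01", 0), rng)
        with pytest.raises(ValueError):
            apply_rearrangement(g, t, Fission("chr01", 6), rng)

    def test_fusion_concatenates(self, genome, rng):
        g, t = genome
        g2, t2 = apply_rearrangement(g, t, Fusion("chr01", "chr02"), rng)
        assert len(g2.chromosomes) == 2
        assert len(g2.chromosomes["chr01+chr02"]) == 12
        assert g2.n_genes == g.n_genes

    def test_translocation_conserves_genes(self, genome, rng):
        g, t = genome
        g2, t2 = apply_rearrangement(
            g, t, Translocation("chr01", 1, 3, "chr02", 2), rng)
        assert len(g2.chromosomes["chr01"]) == 3
        assert len(g2.chromosomes["chr02"]) == 9
        assert g2.n_genes == g.n_genes
        assert set(t2.chrom_ancestors["chr02"]) == {"chr01", "chr02"}


class TestScaffolds:
    @pytest.fixture()
    def genome(self):
        cfg = SimConfig(seed=8, n_chromosomes_ancestral=4,
                        genes_per_chromosome=8)
        return simulate_ancestral_genome(cfg)

    def test_no_chimera_scaffolds_are_single_origin(self, genome, rng):
        g, t = genome
        sc, anchors, t2 = fragment_into_scaffolds(g, t, 12, False, rng)
        gene_chrom = g.gene_chrom()
        for name, genes in sc.chromosomes.items():
            assert len({gene_chrom[x] for x in genes}) == 1
        assert not t2.chimeric_scaffolds

    def test_gene_set_conserved(self, genome, rng):
        g, t = genome
        sc, _, _ = fragment_into_scaffolds(g, t, 15, False, rng)
        assert (set(x for genes in sc.chromosomes.values() for x in genes)
                == set(g.sequences))

    def test_chimera_injection_flags_exactly_two(self, genome, rng):
        g, t = genome
        sc, anchors, t2 = fragment_into_scaffolds(g, t, 16, 2, rng)
        assert len(t2.chimeric_scaffolds) == 2
        gene_chrom = g.gene_chrom()
        for name in t2.chimeric_scaffolds:
            assert len({gene_chrom[x] for x in sc.chromosomes[name]}) == 2

    def test_too_few_scaffolds_rejected(self, genome, rng):
        g, t = genome
        with pytest.raises(ValueError):
            fragment_into_scaffolds(g, t, 3, False, rng)


class TestHalfSibFamily:
    def test_zero_distance_markers_never_recombine(self, rng):
        import pandas as pd
        tmap = pd.DataFrame({"marker": ["m1", "m2"], "lg": ["LG1", "LG1"],
                             "pos_cM": [0.0, 0.0]})
        fam = FamilyConfig(n_progeny_per_father=[500, 500], missing_rate=0.0,
                           mother_het=1.0, father_het=1.0)
        table = simulate_half_sib_family(tmap, fam, rng)
        from esoxsynt.linkage import TwoPointAnalysis
        an = TwoPointAnalysis(table)
        st = an.pair("m1", "m2", "mother")
        assert st.r == 0 and st.n == 1000

    def test_ten_cM_recombination_matches_inverse_haldane(self, rng):
        import pandas as pd
        tmap = pd.DataFrame({"marker": ["m1", "m2"], "lg": ["LG1", "LG1"],
                             "pos_cM": [0.0, 10.0]})
        fam = FamilyConfig(n_progeny_per_father=[5000, 5000],
                           missing_rate=0.0, mother_het=1.0, father_het=0.0)
        table = simulate_half_sib_family(tmap, fam, rng)
        from esoxsynt.linkage import TwoPointAnalysis
        an = TwoPointAnalysis(table)
        st = an.pair("m1", "m2", "mother")
        expected = haldane_r(10.0)
        assert expected == pytest.approx(0.0906, abs=1e-3)
        assert abs(st.r_hat - expected) < 0.01

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            haldane_r(-1.0)

    def test_zero_missing_rate_means_no_missing(self, rng):
        tmap = make_marker_map(2, 5, 5.0)
        fam = FamilyConfig(missing_rate=0.0)
        table = simulate_half_sib_family(tmap, fam, rng)
        assert (table.data[table.progeny] != "-").all().all()

    def test_missing_rate_injected_mcar(self, rng):
        tmap = make_marker_map(4, 10, 5.0)
        fam = FamilyConfig(missing_rate=0.10)
        table = simulate_half_sib_family(tmap, fam, rng)
        frac = table.missing_fraction().mean()
        assert 0.07 < frac < 0.13


class TestExpressionSim:
    def test_no_plantings_empty_truth(self, rng):
        cfg = ExpressionConfig(n_specialized_per_tissue=0)
        _, _, truth = simulate_expression(100, cfg, rng)
        assert truth.specialized == set()

    def test_planted_boost_exceeds_three_sd_rule(self, rng):
        cfg = ExpressionConfig(n_specialized_per_tissue=2, boost=100.0)
        counts, lengths, truth = simulate_expression(300, cfg, rng)
        from esoxsynt.expression import fpkm, specialized_calls
        flags, _, _ = specialized_calls(fpkm(counts, lengths))
        hit = sum(flags.at[t, tis] for t, tis in truth.specialized)
        assert hit / len(truth.specialized) >= 0.9

    def test_positive_library_totals(self, rng):
        cfg = ExpressionConfig(n_specialized_per_tissue=0)
        counts, _, _ = simulate_expression(50, cfg, rng)
        assert (counts.sum(axis=0) > 0).all()

    def test_too_many_plantings_rejected(self, rng):
        cfg = ExpressionConfig(n_specialized_per_tissue=10, n_tissues=13)
        with pytest.raises(ValueError):
            simulate_expression(50, cfg, rng)
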