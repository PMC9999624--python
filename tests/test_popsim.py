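import numpy as np
import pytest

from pseudohet import popsim
from pseudohet.dupconfirm import insertion_present
from pseudohet.io_formats import HET, HOM_ALT, HOM_REF

from conftest import eligible_genes, small_config


class TestPopulation:
    def test_single_founder_population_is_monomorphic(self):
        sim = popsim.simulate_population(small_config(1, n_founders=1,
                                                      founder_weights=None))
        assert sim.genotypes.n_snps == 0

    def test_zero_recombination_copies_one_founder(self):
        cfg = small_config(2, recomb_rate=0.0, n_accessions=20)
        sim = popsim.simulate_population(cfg)
        gm = sim.genotypes
        for a in range(gm.n_accessions):
            for chrom in cfg.chrom_names:
                sl = gm.chrom_slice(chrom)
                f = int(sim.founder_at(a, chrom, 1))
                expected = np.where(sim._founder_alleles[chrom][f],
                                    HOM_ALT, HOM_REF)
                assert np.array_equal(gm.calls[sl, a], expected)

    def test_no_heterozygosity_before_planting(self, small_sim):
        assert (small_sim.genotypes.calls == HET).sum() == 0

    def test_allele_frequencies_polymorphic(self, small_sim):
        calls = small_sim.genotypes.calls
        alt = (calls == HOM_ALT).mean(axis=1)
        assert np.all(alt > 0) and np.all(alt < 1)

    def test_deterministic_given_seed(self):
        a = popsim.simulate_population(small_config(5))
        b = popsim.simulate_population(small_config(5))
        assert a.genotypes == b.genotypes


class TestPlanting:
    def test_trans_injection_matches_per_site_oracle(self):
        """divergence=0: a carrier turns het exactly where its own allele
        differs from the origin founder's allele inside the source gene."""
        sim = popsim.simulate_population(small_config(9))
        before = sim.genotypes.copy()
        gene_id = eligible_genes(sim)[1]
        ev = popsim.plant_duplication(sim, gene_id, mode="trans",
                                      divergence=0.0, carrier_founder=0,
                                      origin_founder=1, add_tag_snp=False)
        gm = sim.genotypes
        gene = sim.gene(gene_id)
        sl = gm.chrom_slice(gene.chrom)
        F = sim._founder_alleles[gene.chrom]
        for j in range(sl.start, sl.stop):
            local = j - sl.start
            in_gene = gene.start <= gm.pos[j] <= gene.end
            origin_allele = HOM_ALT if F[1, local] else HOM_REF
            for a, acc in enumerate(gm.accessions):
                if acc in ev.carriers and in_gene \
                        and before.calls[j, a] != origin_allele:
                    assert gm.calls[j, a] == HET
                else:
                    assert gm.calls[j, a] == before.calls[j, a]

    def test_tandem_without_divergence_injects_nothing(self):
        sim = popsim.simulate_population(small_config(9))
        before = sim.genotypes.copy()
        gene_id = eligible_genes(sim)[1]
        popsim.plant_duplication(sim, gene_id, mode="tandem", divergence=0.0,
                                 carrier_founder=0, add_tag_snp=False)
        assert sim.genotypes == before

    def test_non_carriers_never_modified(self, planted_sim):
        sim, ev = planted_sim
        gm = sim.genotypes
        non_carriers = [i for i, a in enumerate(gm.accessions)
                        if a not in ev.carriers]
        assert (gm.calls[:, non_carriers] == HET).sum() == 0

    def test_injection_confined_to_source_interval(self, planted_sim):
        sim, ev = planted_sim
        gm = sim.genotypes
        injected = np.flatnonzero((sim.injected_by > 0).any(axis=1))
        for j in injected:
            assert gm.chrom[j] == ev.chrom
            assert ev.start <= gm.pos[j] <= ev.end

    def test_carriers_are_founder_defined(self, planted_sim):
        sim, ev = planted_sim
        expected = {a for i, a in enumerate(sim.genotypes.accessions)
                    if sim.founder_at(i, ev.insertion_chrom,
                                      ev.insertion_pos) == ev.carrier_founder}
        assert set(ev.carriers) == expected

    def test_tag_snp_in_perfect_ld_with_carrier_status(self, planted_sim):
        sim, ev = planted_sim
        gm = sim.genotypes
        j = gm.snp_index(ev.insertion_chrom, ev.insertion_pos)
        carrier = np.array([a in ev.carriers for a in gm.accessions])
        assert np.array_equal(gm.calls[j] == HOM_ALT, carrier)

    def test_empty_carrier_set_warns_and_leaves_matrix(self):
        sim = popsim.simulate_population(small_config(9, n_founders=2,
                                                      founder_weights=None))
        before = sim.genotypes.copy()
        gene_id = eligible_genes(sim)[0]
        with pytest.warns(UserWarning, match="no carriers"):
            popsim.plant_duplication(sim, gene_id, carrier_founder=7)
        assert sim.genotypes == before

    def test_divergence_injection_rate_matches_expectation(self):
        """New het sites per event ~ Binomial(SNP-free bases, divergence)."""
        d = 0.03
        total_sites = 0
        total_bases = 0
        for seed in range(50):
            sim = popsim.simulate_population(
                small_config(100 + seed, chrom_lengths=(50_000, 50_000),
                             n_genes_per_chrom=3))
            gene_id = eligible_genes(sim)[0]
            gene = sim.gene(gene_id)
            gm = sim.genotypes
            sl = gm.chrom_slice(gene.chrom)
            n_snps = int(((gm.pos[sl] >= gene.start)
                          & (gm.pos[sl] <= gene.end)).sum())
            before = gm.n_snps
            popsim.plant_duplication(sim, gene_id, mode="trans", divergence=d,
                                     carrier_founder=0, add_tag_snp=False)
            total_sites += sim.genotypes.n_snps - before
            total_bases += gene.length - n_snps
        expect = total_bases * d
        sd = np.sqrt(total_bases * d * (1 - d))
        assert abs(total_sites - expect) <= 3 * sd


class TestAssemblies:
    def test_non_carrier_genome_has_reference_length(self, planted_sim):
        sim, ev = planted_sim
        acc = next(a for a in sim.genotypes.accessions if a not in ev.carriers)
        genome = popsim.emit_assembly(sim, acc)
        for chrom, L in zip(sim.cfg.chrom_names, sim.cfg.chrom_lengths):
            assert len(genome[chrom]) == L

    def test_carrier_genome_gains_copy_length(self, planted_sim):
        sim, ev = planted_sim
        genome = popsim.emit_assembly(sim, ev.carriers[0])
        ins_chrom_len = dict(zip(sim.cfg.chrom_names, sim.cfg.chrom_lengths))
        assert (len(genome[ev.insertion_chrom])
                == ins_chrom_len[ev.insertion_chrom] + (ev.end - ev.start + 1))

    def test_zero_divergence_copies_are_identical_strings(self):
        sim = popsim.simulate_population(small_config(9))
        gene_id = eligible_genes(sim)[1]
        ev = popsim.plant_duplication(sim, gene_id, mode="trans",
                                      divergence=0.0, carrier_founder=0,
                                      origin_founder=0)
        # pick a carrier whose own haplotype at the source is founder 0:
        # its local gene sequence then equals the copy exactly
        gene = sim.gene(gene_id)
        carrier = next(
            a for i, a in enumerate(sim.genotypes.accessions)
            if a in ev.carriers
            and sim.founder_at(i, gene.chrom, gene.start)
            == sim.founder_at(i, gene.chrom, gene.end) == 0)
        genome = popsim.emit_assembly(sim, carrier)
        copy = popsim.copy_sequence(sim, ev, carrier)
        assert genome[ev.insertion_chrom].count(copy) >= 1
        assert genome[gene.chrom].count(copy) >= 1


class TestMethylation:
    def test_depth_below_one_rejected(self, planted_sim):
        sim, _ = planted_sim
        with pytest.raises(ValueError):
            popsim.emit_methylation(sim, depth=0)

    def test_single_copy_gene_targets_agree(self, small_sim):
        recs = popsim.emit_methylation(
            small_sim, depth=2000,
            accessions=small_sim.genotypes.accessions[:1],
            genes=[small_sim.annotation[0].gene_id])
        by_target = recs.groupby("mapping_target")[["methylated", "depth"]].sum()
        levels = by_target["methylated"] / by_target["depth"]
        assert abs(levels["reference"] - levels["own_genome"]) < 0.02

    def test_collapsed_pooling_averages_copy_levels(self, planted_sim):
        """Copies at levels 0 and 1 with equal depth collapse to ~0.5."""
        sim, ev = planted_sim
        truth = popsim.draw_methylation_truth(sim)
        truth.loc[(truth.gene_id == ev.source_gene)
                  & (truth["copy"] == "source"), "level"] = 0.0
        truth.loc[(truth.gene_id == ev.source_gene)
                  & (truth["copy"] == "dup"), "level"] = 1.0
        recs = popsim.emit_methylation(sim, depth=10_000, truth=truth,
                                       accessions=[ev.carriers[0]],
                                       genes=[ev.source_gene])
        ref = recs[recs.mapping_target == "reference"]
        level = ref["methylated"].sum() / ref["depth"].sum()
        assert abs(level - 0.5) < 0.02
        own = recs[(recs.mapping_target == "own_genome")
                   & (recs["copy"] == "dup")]
        assert abs(own["methylated"].sum() / own["depth"].sum() - 1.0) < 0.02


class TestReadPairsAndDepth:
    def test_carrier_spanning_pairs_reach_presence_threshold(self, planted_sim):
        sim, ev = planted_sim
        pairs = popsim.emit_read_pairs(sim, ev, n_pairs=10)
        junction = pairs.attrs["junction"]
        carrier = pairs[pairs.accession == ev.carriers[0]]
        call, n = insertion_present(carrier, junction)
        assert call == "present" and n >= 3

    def test_non_carrier_has_zero_spanning_pairs(self, planted_sim):
        sim, ev = planted_sim
        pairs = popsim.emit_read_pairs(sim, ev, n_pairs=10)
        junction = pairs.attrs["junction"]
        acc = next(a for a in sim.genotypes.accessions if a not in ev.carriers)
        call, n = insertion_present(pairs[pairs.accession == acc], junction)
        assert call == "absent" and n == 0

    def test_two_pairs_is_below_presence_threshold(self, planted_sim):
        sim, ev = planted_sim
        pairs = popsim.emit_read_pairs(sim, ev, n_pairs=2)
        carrier = pairs[pairs.accession == ev.carriers[0]]
        call, n = insertion_present(carrier, pairs.attrs["junction"])
        assert call == "absent" and n == 2

    def test_collapsed_depth_doubles_over_carried_duplication(self, planted_sim):
        sim, ev = planted_sim
        depth = popsim.emit_depth(sim, ev.carriers[0], mean_depth=200)
        gene = depth[(depth.chrom == ev.chrom) & (depth.end >= ev.start)
                     & (depth.start <= ev.end)]
        ratio = gene["depth"].mean() / depth["depth"].median()
        assert 1.8 < ratio < 2.2
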