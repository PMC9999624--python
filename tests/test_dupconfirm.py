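import numpy as np
import pytest
from Bio import Align

from pseudohet import dupconfirm, popsim
from pseudohet.dupconfirm import (align_search, build_genome_index,
                                  confirm_prediction, copy_number,
                                  flank_synteny, insertion_present,
                                  map_position, revcomp)

from conftest import eligible_genes, small_config

BASES = "ACGT"


def rand_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def sw_oracle(query, target):
    """Full Smith-Waterman via Biopython with the package's scoring."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(target, query)[0]
    t_start = int(aln.coordinates[0][0]) + 1
    t_end = int(aln.coordinates[0][-1])
    n_match = sum(
        1 for (ts, te), (qs, qe) in zip(
            zip(aln.coordinates[0][:-1], aln.coordinates[0][1:]),
            zip(aln.coordinates[1][:-1], aln.coordinates[1][1:]))
        if te > ts and qe > qs
        for k in range(te - ts)
        if target[ts + k] == query[qs + k])
    return aln.score, t_start, t_end, n_match


class TestAlignSearch:
    def test_verbatim_query_found_exactly(self):
        rng = np.random.default_rng(0)
        query = rand_seq(rng, 300)
        genome = {"c1": rand_seq(rng, 2000) + query + rand_seq(rng, 2000)}
        hits = align_search(query, genome)
        assert len(hits) == 1
        h = hits[0]
        assert (h.target_start, h.target_end) == (2001, 2300)
        assert h.percent_identity == 100.0 and h.query_coverage == 1.0
        assert h.strand == "+"

    def test_reverse_strand_hit_found(self):
        rng = np.random.default_rng(1)
        query = rand_seq(rng, 200)
        genome = {"c1": rand_seq(rng, 500) + revcomp(query) + rand_seq(rng, 500)}
        hits = align_search(query, genome)
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_heavily_substituted_copy_rejected(self):
        """35% substitution leaves < 70% identity: no acceptable match."""
        rng = np.random.default_rng(2)
        query = rand_seq(rng, 300)
        planted = mutate(rng, query, 0.35)
        genome = {"c1": rand_seq(rng, 1000) + planted + rand_seq(rng, 1000)}
        assert align_search(query, genome) == []

    def test_two_copies_found_at_truth_positions(self):
        rng = np.random.default_rng(3)
        query = rand_seq(rng, 400)
        diverged = mutate(rng, query, 0.1)
        genome = {"c1": rand_seq(rng, 1500) + query + rand_seq(rng, 3000)
                  + diverged + rand_seq(rng, 1500)}
        hits = align_search(query, genome)
        assert len(hits) == 2
        centers = sorted(h.center for h in hits)
        assert abs(centers[0] - 1700) <= 5 and abs(centers[1] - 5100) <= 5

    def test_adjacent_tandem_copies_not_merged(self):
        rng = np.random.default_rng(4)
        query = rand_seq(rng, 300)
        genome = {"c1": rand_seq(rng, 800) + query + "ACGT" * 25 + query
                  + rand_seq(rng, 800)}
        hits = align_search(query, genome)
        assert len(hits) == 2

    def test_split_hit_chained_across_small_insertion(self):
        """An unrelated 300 bp insertion splits the alignment; the two
        fragments chain back into one match with near-full coverage."""
        rng = np.random.default_rng(5)
        query = rand_seq(rng, 600)
        genome = {"c1": rand_seq(rng, 700) + query[:300]
                  + rand_seq(rng, 300) + query[300:] + rand_seq(rng, 700)}
        hits = align_search(query, genome)
        assert len(hits) == 1
        assert hits[0].n_segments == 2
        assert hits[0].query_coverage > 0.95

    def test_query_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            align_search("ACGT", {"c1": "ACGT" * 100})

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_smith_waterman_oracle(self, seed):
        """Best-hit interval within 1 column and identical match count
        against full quadratic Smith-Waterman (queries <= 300 bp)."""
        rng = np.random.default_rng(100 + seed)
        qlen = int(rng.integers(80, 301))
        target = rand_seq(rng, int(rng.integers(1000, 3001)))
        start = int(rng.integers(0, len(target) - qlen))
        query = mutate(rng, target[start:start + qlen],
                       rng.uniform(0.02, 0.15))
        hits = align_search(query, target and {"c1": target}, min_cov=0.5)
        score, t_start, t_end, n_match = sw_oracle(query, target)
        assert hits, "seeded hit must be found"
        h = hits[0]
        assert h.score == pytest.approx(score)
        assert abs(h.target_start - t_start) <= 1
        assert abs(h.target_end - t_end) <= 1
        assert abs(h._n_match - n_match) <= 1


@pytest.fixture(scope="module")
def confirm_sim():
    sim = popsim.simulate_population(
        small_config(19, chrom_lengths=(120_000, 120_000),
                     n_genes_per_chrom=6))
    gene = eligible_genes(sim)[1]
    ev = popsim.plant_duplication(sim, gene, mode="trans",
                                  divergence=0.05, carrier_founder=0,
                                  origin_founder=1)
    return sim, ev


class TestConfirmation:
    def test_match_near_mapped_peak_confirms(self, confirm_sim):
        sim, ev = confirm_sim
        ref = sim.reference_fasta()
        gene = sim.gene(ev.source_gene)
        gene_seq = ref[gene.chrom][gene.start - 1:gene.end]
        genome = popsim.emit_assembly(sim, ev.carriers[0])
        conf = confirm_prediction(
            gene_seq, ev.insertion_chrom, ev.insertion_pos + 5000, ref,
            genome, source_chrom=gene.chrom,
            source_pos=(gene.start + gene.end) // 2)
        assert conf.confirmed and conf.confirmed_nonsyntenic

    def test_match_beyond_radius_does_not_confirm(self, confirm_sim):
        sim, ev = confirm_sim
        ref = sim.reference_fasta()
        gene = sim.gene(ev.source_gene)
        gene_seq = ref[gene.chrom][gene.start - 1:gene.end]
        genome = popsim.emit_assembly(sim, ev.carriers[0])
        far = ev.insertion_pos + 40_000
        if far > sim.cfg.chrom_lengths[0]:
            far = ev.insertion_pos - 40_000
        conf = confirm_prediction(
            gene_seq, ev.insertion_chrom, far, ref, genome,
            source_chrom=gene.chrom, source_pos=(gene.start + gene.end) // 2)
        assert not conf.confirmed

    def test_non_carrier_genome_only_syntenic_match(self, confirm_sim):
        sim, ev = confirm_sim
        ref = sim.reference_fasta()
        gene = sim.gene(ev.source_gene)
        gene_seq = ref[gene.chrom][gene.start - 1:gene.end]
        acc = next(a for a in sim.genotypes.accessions
                   if a not in ev.carriers)
        genome = popsim.emit_assembly(sim, acc)
        conf = confirm_prediction(
            gene_seq, ev.insertion_chrom, ev.insertion_pos, ref, genome,
            source_chrom=gene.chrom, source_pos=(gene.start + gene.end) // 2)
        assert not conf.confirmed_nonsyntenic
        assert len(conf.matches) == 1  # the syntenic copy only

    def test_mapped_position_tracks_insertion_shift(self, confirm_sim):
        sim, ev = confirm_sim
        ref = sim.reference_fasta()
        genome = popsim.emit_assembly(sim, ev.carriers[0])
        probe = ev.insertion_pos + 20_000  # downstream of the insertion
        res = map_position(ref, ev.insertion_chrom, probe, genome)
        assert res is not None
        tid, mapped = res
        assert tid == ev.insertion_chrom
        copy_len = ev.end - ev.start + 1
        assert abs(mapped - (probe + copy_len)) < 500


class TestCopyNumber:
    def test_absent_gene_is_category_zero(self):
        rng = np.random.default_rng(6)
        est = copy_number("g", rand_seq(rng, 500), "acc",
                          {"c1": rand_seq(rng, 5000)})
        assert est.n_matches == 0 and est.category == "0"

    def test_single_copy_ratio_near_one(self, planted_sim):
        sim, ev = planted_sim
        acc = next(a for a in sim.genotypes.accessions
                   if a not in ev.carriers)
        ref = sim.reference_fasta()
        gene = sim.gene(ev.source_gene)
        gene_seq = ref[gene.chrom][gene.start - 1:gene.end]
        depth = popsim.emit_depth(sim, acc, mean_depth=100)
        est = copy_number(ev.source_gene, gene_seq, acc,
                          popsim.emit_assembly(sim, acc), depth,
                          (gene.chrom, gene.start, gene.end))
        assert est.category == "1"
        assert 0.8 < est.coverage_ratio < 1.2

    def test_carrier_ratio_near_two(self, planted_sim):
        sim, ev = planted_sim
        acc = ev.carriers[0]
        ref = sim.reference_fasta()
        gene = sim.gene(ev.source_gene)
        gene_seq = ref[gene.chrom][gene.start - 1:gene.end]
        depth = popsim.emit_depth(sim, acc, mean_depth=100)
        est = copy_number(ev.source_gene, gene_seq, acc,
                          popsim.emit_assembly(sim, acc), depth,
                          (gene.chrom, gene.start, gene.end))
        assert est.category == ">1" and est.n_matches == 2
        assert 1.8 < est.coverage_ratio < 2.2


class TestFlankSynteny:
    def test_unrearranged_region_collinear(self, small_sim):
        sim = small_sim
        ref = sim.reference_fasta()
        focal = sim.annotation[3].gene_id
        table = flank_synteny(focal, sim.annotation, ref, ref)
        assert (table["n_matches"] == 1).all()
        assert len(table) == 7  # focal + 3 flanks each side
        assert table["target_start"].is_monotonic_increasing

    def test_short_fragment_excluded_by_length_rule(self):
        """A planted fragment covering only 40% of the query fails the
        50%-of-input-length rule."""
        rng = np.random.default_rng(7)
        query = rand_seq(rng, 500)
        genome = {"c1": rand_seq(rng, 1000) + query[:200] + rand_seq(rng, 1000)}
        hits = align_search(query, genome, min_cov=0.5)
        assert hits == []

    def test_tandem_array_focal_multiplied_flanks_single(self):
        sim = popsim.simulate_population(
            small_config(23, chrom_lengths=(120_000,), n_genes_per_chrom=8))
        focal = eligible_genes(sim)[3]
        popsim.plant_duplication(sim, focal, mode="tandem", divergence=0.02,
                                 carrier_founder=0)
        carrier = sim.events[0].carriers[0]
        genome = popsim.emit_assembly(sim, carrier)
        table = flank_synteny(focal, sim.annotation,
                              sim.reference_fasta(), genome)
        assert table.loc[table.role == "focal", "n_matches"].iloc[0] > 1
        assert (table.loc[table.role == "flank", "n_matches"] == 1).all()


class TestInsertionPresence:
    def _pairs(self, n_span, junction=1000):
        import pandas as pd
        rows = []
        for _ in range(n_span):
            rows.append((800, 900, 1100, 1200))
        rows.append((500, 600, 700, 800))  # non-spanning filler
        return pd.DataFrame(rows, columns=["mate1_start", "mate1_end",
                                           "mate2_start", "mate2_end"])

    def test_three_spanning_pairs_present(self):
        call, n = insertion_present(self._pairs(3), 1000)
        assert call == "present" and n == 3

    def test_two_spanning_pairs_absent(self):
        call, n = insertion_present(self._pairs(2), 1000)
        assert call == "absent" and n == 2

    def test_mate_order_irrelevant(self):
        import pandas as pd
        pairs = pd.DataFrame([(1100, 1200, 800, 900)],
                             columns=["mate1_start", "mate1_end",
                                      "mate2_start", "mate2_end"])
        assert insertion_present(pairs, 1000)[1] == 1
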