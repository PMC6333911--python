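"""Genome layout, founder Fisher-Wright process, meiosis and genotype I/O."""

import numpy as np
import pytest
from scipy import stats

from breedsim import (ConfigError, FounderConfig, Haplotype, ParseError,
                      build_genome_map, export_phased_genomes,
                      import_phased_genomes, sample_gamete,
                      simulate_founder_population)
from breedsim.genome import ROLE_QTL, sample_gametes


class TestBuildGenomeMap:
    def test_explicit_qtl_designation_role_counts(self, rng):
        # 1039 of 9582 loci designated QTLs by explicit index list
        idx = rng.choice(9582, size=1039, replace=False)
        gmap = build_genome_map(21, 1.0, 9582, qtl_indices=idx, n_ibd=2)
        assert gmap.n_qtl == 1039
        assert gmap.marker_indices.size == 8543

    def test_single_locus_at_midpoint(self):
        gmap = build_genome_map(1, 1.0, 1, qtl_every_n=1)
        assert gmap.n_qtl == 1
        assert gmap.positions[0] == pytest.approx(0.5)

    def test_every_nth_rule_indices(self):
        gmap = build_genome_map(1, 1.0, 100, qtl_every_n=10)
        # QTLs at 1-based within-chromosome indices 10, 20, ..., 100
        assert np.array_equal(np.flatnonzero(gmap.roles == ROLE_QTL),
                              np.arange(9, 100, 10))

    def test_every_nth_restarts_per_chromosome(self):
        gmap = build_genome_map(2, 1.0, 10, qtl_every_n=3)
        per_chrom = [gmap.roles[gmap.chrom_slice(c)] for c in range(2)]
        for roles in per_chrom:
            assert np.flatnonzero(roles == ROLE_QTL).tolist() == [2]

    def test_ibd_loci_equidistant(self):
        gmap = build_genome_map(1, 2.0, 10, qtl_every_n=2, n_ibd=4)
        d = np.diff(gmap.ibd_positions)
        assert np.allclose(d, d[0])

    @pytest.mark.parametrize("kwargs", [
        dict(n_chrom=0, chrom_length=1.0, n_loci=10, qtl_every_n=1),
        dict(n_chrom=1, chrom_length=1.0, n_loci=0, qtl_every_n=1),
        dict(n_chrom=1, chrom_length=1.0, n_loci=10, qtl_every_n=0),
        dict(n_chrom=1, chrom_length=1.0, n_loci=10),          # no QTL mode
        dict(n_chrom=1, chrom_length=1.0, n_loci=10, qtl_every_n=2,
             qtl_indices=[1]),                                 # two modes
        dict(n_chrom=1, chrom_length=-1.0, n_loci=10, qtl_every_n=2),
    ])
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ConfigError):
            build_genome_map(**kwargs)


class TestFounder:
    def test_culling_count_is_exact_fraction(self, small_map, rng):
        # 100 offspring per generation at the default 5% culling
        cfg = FounderConfig(n_pat=50, n_mat=50, ng_founder=5, mutation_rate=1e-3)
        eff = np.ones(small_map.n_qtl)
        pool = simulate_founder_population(cfg, small_map, eff, rng)
        assert pool.cull_counts == [5] * 5

    def test_zero_mutation_rate_gives_monomorphic_wildtype(self, small_map, rng):
        cfg = FounderConfig(n_pat=5, n_mat=5, ng_founder=10, mutation_rate=0.0,
                            culling_fraction=0.0)
        with pytest.warns(UserWarning, match="monomorphic"):
            pool = simulate_founder_population(cfg, small_map,
                                               np.ones(small_map.n_qtl), rng)
        assert not pool.haplotypes.any()

    def test_selection_shifts_frequencies_of_beneficial_alleles(self, small_pool):
        # with 90% negative effects and TBV culling, the pool is polymorphic
        # but not an all-mutant sweep
        f = small_pool.allele_frequencies()
        assert 0 < f.mean() < 0.6
        assert ((f > 0) & (f < 1)).sum() > 10

    def test_neutral_drift_decay_of_heterozygosity(self, rng):
        # E[het_t] = het_0 (1 - 1/(2N))^t under pure drift
        gmap = build_genome_map(1, 40.0, 40, qtl_every_n=40)  # ~1 Morgan apart: ~unlinked
        n, t, reps = 10, 8, 60
        hets = []
        for r in range(reps):
            r_rng = np.random.default_rng(1000 + r)
            init = r_rng.integers(0, 2, size=(n, 2, 40)).astype(np.int8)
            cfg = FounderConfig(n_pat=n // 2, n_mat=n // 2, ng_founder=t,
                                mutation_rate=0.0, culling_fraction=0.0)
            pool = simulate_founder_population(cfg, gmap, np.zeros(1), r_rng,
                                               initial=init)
            p = pool.allele_frequencies()
            hets.append(np.mean(2 * p * (1 - p)))
        expected = 0.5 * (1 - 1 / (2 * n)) ** t
        assert np.mean(hets) == pytest.approx(expected, rel=0.12)

    def test_size_schedule_expansion(self, small_map, rng):
        cfg = FounderConfig(n_pat=5, n_mat=5, ng_founder=3, mutation_rate=1e-3,
                            size_schedule=[10, 20, 30])
        pool = simulate_founder_population(cfg, small_map,
                                           np.zeros(small_map.n_qtl), rng)
        assert pool.n_haplotypes == 60

    def test_too_few_parents_rejected(self, small_map, rng):
        with pytest.raises(ConfigError):
            FounderConfig(n_pat=0, n_mat=2)


class TestMeiosis:
    def test_homozygous_parent_gamete_identity(self, small_map, rng):
        h = rng.integers(0, 2, small_map.n_loci).astype(np.int8)
        ib = np.arange(small_map.n_ibd, dtype=np.int32)
        for _ in range(20):
            g = sample_gamete((Haplotype(h, ib), Haplotype(h.copy(), ib.copy())),
                              small_map, rng)
            assert np.array_equal(g.alleles, h)
            assert np.array_equal(g.ibd_alleles, ib)

    def test_gamete_alleles_come_from_parent(self, small_map, rng):
        alleles = rng.integers(0, 2, (50, 2, small_map.n_loci)).astype(np.int8)
        g, _ = sample_gametes(alleles, None, small_map, rng)
        match = (g == alleles[:, 0, :]) | (g == alleles[:, 1, :])
        assert match.all()

    def test_crossover_count_poisson(self):
        # parent heterozygous everywhere: strand switches count crossovers
        rng = np.random.default_rng(42)
        n, L = 20000, 400
        gmap = build_genome_map(1, 1.0, L, qtl_every_n=L)
        alleles = np.zeros((n, 2, L), dtype=np.int8)
        alleles[:, 1, :] = 1
        g, _ = sample_gametes(alleles, None, gmap, rng)
        switches = np.abs(np.diff(g.astype(int), axis=1)).sum(axis=1)
        assert switches.mean() == pytest.approx(1.0, abs=0.03)
        # chi-square goodness of fit against Poisson(1), tail pooled
        kmax = 5
        obs = np.bincount(np.minimum(switches, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), 1.0)
        probs = np.append(pmf, 1 - pmf.sum())
        chi2 = ((obs - n * probs) ** 2 / (n * probs)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=kmax)

    def test_single_heterozygous_locus_mendelian_transmission(self, rng):
        gmap = build_genome_map(1, 1.0, 1, qtl_every_n=1)
        n = 100_000
        alleles = np.zeros((n, 2, 1), dtype=np.int8)
        alleles[:, 1, 0] = 1
        g, _ = sample_gametes(alleles, None, gmap, rng)
        assert g.mean() == pytest.approx(0.5, abs=0.006)

    def test_ibd_labels_follow_crossovers(self, rng):
        gmap = build_genome_map(1, 1.0, 10, qtl_every_n=10, n_ibd=10)
        # IBD loci interleaved with selectable loci at identical layout:
        # a gamete's IBD label at a locus must match its strand choice
        alleles = np.zeros((500, 2, 10), dtype=np.int8)
        alleles[:, 1, :] = 1
        ibd = np.zeros((500, 2, 10), dtype=np.int32)
        ibd[:, 1, :] = 1
        g, gi = sample_gametes(alleles, ibd, gmap, rng)
        assert np.array_equal(g.astype(np.int32), gi)

    def test_mutation_toggles_alleles(self, rng):
        gmap = build_genome_map(1, 0.001, 200, qtl_every_n=200)
        alleles = np.zeros((500, 2, 200), dtype=np.int8)
        g, _ = sample_gametes(alleles, None, gmap, rng, mutation_rate=0.01)
        assert g.mean() == pytest.approx(0.01, abs=0.003)


class TestGenotypeIO:
    def test_round_trip(self, small_pool, tmp_path):
        m, g = tmp_path / "map.tsv", tmp_path / "geno.tsv"
        export_phased_genomes(small_pool, m, g)
        gmap2, pool2 = import_phased_genomes(m, g)
        assert np.array_equal(pool2.haplotypes, small_pool.haplotypes)
        assert np.allclose(gmap2.positions, small_pool.gmap.positions)
        assert np.array_equal(gmap2.roles, small_pool.gmap.roles)
        assert pool2.provenance == "imported"

    def test_two_individuals_make_four_haplotypes(self, tmp_path):
        m, g = tmp_path / "map.tsv", tmp_path / "geno.tsv"
        m.write_text("chromosome\tlocus_id\tposition_morgans\trole\n"
                     "1\tL0\t0.1\tQTL\n1\tL1\t0.2\tMARKER\n"
                     "1\tL2\t0.3\tMARKER\n1\tL3\t0.4\tMARKER\n")
        rows = [f"IND{i}\t{h}\t0\t1\t0\t1" for i in (1, 2) for h in (1, 2)]
        g.write_text("\n".join(rows) + "\n")
        _, pool = import_phased_genomes(m, g)
        assert pool.n_haplotypes == 4

    def test_bad_allele_code_is_parse_error(self, tmp_path):
        m, g = tmp_path / "map.tsv", tmp_path / "geno.tsv"
        m.write_text("chromosome\tlocus_id\tposition_morgans\trole\n"
                     "1\tL0\t0.1\tMARKER\n")
        g.write_text("IND1\t1\t2\nIND1\t2\t0\n")
        with pytest.raises(ParseError, match="allele codes"):
            import_phased_genomes(m, g)

    def test_unsorted_positions_rejected(self, tmp_path):
        m, g = tmp_path / "map.tsv", tmp_path / "geno.tsv"
        m.write_text("chromosome\tlocus_id\tposition_morgans\trole\n"
                     "1\tL0\t0.5\tMARKER\n1\tL1\t0.2\tMARKER\n")
        g.write_text("IND1\t1\t0\t0\nIND1\t2\t0\t0\n")
        with pytest.raises(ParseError, match="unsorted"):
            import_phased_genomes(m, g)
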