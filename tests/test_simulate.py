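"""The forward simulator: transmission genetics, phenotypes, pools, reads."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from afddmap import CrossConfig, GenomeSpec, build_pools, simulate_cross
from afddmap.simulate import (
    ConfigError,
    Population,
    PoolingError,
    _gamete_origins,
    assign_phenotypes,
    simulate_experiment,
    simulate_pool_reads,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        CrossConfig().validate()

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_offspring": 0}, "n_offspring"),
            ({"recomb_rate": -1.0}, "recomb_rate"),
            ({"depth_means": (-5.0, 30.0)}, "depth_means"),
            ({"penetrance": (1.2,)}, "penetrance"),
            ({"leak": 1.5}, "leak"),
            ({"dominant_locus": ("chrX", 100)}, "dominant_locus"),
            ({"suppressor_loci": (("chr1", 10**9),)}, "suppressor_loci"),
            ({"seq_error": 1.0}, "seq_error"),
        ],
    )
    def test_errors_name_offending_field(self, kwargs, field):
        if "suppressor_loci" in kwargs:
            kwargs = dict(kwargs, suppressor_genotypes=(("Rr", "Rr"),))
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            CrossConfig(**kwargs).validate()

    def test_locus1_must_be_het_in_both_parents(self):
        with pytest.raises(ConfigError, match="locus 1"):
            CrossConfig(suppressor_genotypes=(("rr", "Rr"), ("rr", "Rr"))).validate()

    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cross.yaml"
        small_config.to_yaml(path)
        assert CrossConfig.from_yaml(path) == small_config


def test_haldane_recombination_fraction():
    # two loci 1 Mb apart at 2 cM/Mb: r = (1 - exp(-0.04)) / 2
    rng = np.random.default_rng(99)
    origins = _gamete_origins(np.array([1, 1_000_001]), 2.0, 5000, rng)
    expected = (1 - np.exp(-0.04)) / 2
    observed = float(np.mean(origins[:, 0] != origins[:, 1]))
    se = np.sqrt(expected * (1 - expected) / 5000)
    assert abs(observed - expected) < 3 * se


def test_no_recombination_keeps_haplotypes_intact(small_config):
    from dataclasses import replace

    config = replace(small_config, recomb_rate=0.0)
    pop = simulate_cross(config, seed=5)
    for chrom in config.genome.lengths:
        org = pop.origins[chrom]
        # every gamete is a single parental haplotype end to end
        assert (org == org[:, :, :1]).all()


def test_allele_conservation_two_alleles_per_site(small_run):
    pop = small_run.population
    for chrom, arr in pop.alleles.items():
        assert arr.shape[1] == 2
        assert set(np.unique(arr)) <= {0, 1}


def test_dominant_locus_segregates_1_2_1():
    """Counts at the Co-like locus pass a 1:2:1 chi-square (alpha = 0.01)
    in at least 95 of 100 seeds."""
    config = CrossConfig(
        genome=GenomeSpec(chromosomes=(("chr1", 2_000_000),), snv_density=1e-5),
        dominant_locus=("chr1", 1_500_000),
        suppressor_loci=(("chr1", 500_000),),
        suppressor_genotypes=(("Rr", "Rr"),),
        n_offspring=275,
    )
    passed = 0
    for seed in range(100):
        pop = simulate_cross(config, seed=seed)
        counts = pop.individuals["co_genotype"].value_counts()
        obs = [counts.get(g, 0) for g in ("CoCo", "Coco", "coco")]
        n = sum(obs)
        _, p = sps.chisquare(obs, f_exp=[n / 4, n / 2, n / 4])
        passed += p > 0.01
    assert passed >= 95


def test_fully_linked_marker_equals_suppressor_genotype(small_config):
    """With zero recombination, a coupling-phase het/het marker on the
    suppressor chromosome mirrors the locus-1 genotype in every offspring."""
    from dataclasses import replace

    config = replace(small_config, recomb_rate=0.0)
    pop = simulate_cross(config, seed=11)
    chrom, pos = config.suppressor_loci[0]
    data = pop.chrom_data[chrom]
    j_locus = pop.locus_index(chrom, pos)
    marker_js = np.flatnonzero(data.is_marker & (data.derivative == "VRxVR"))
    assert len(marker_js) > 0
    arr = pop.alleles[chrom]
    for j in marker_js:
        assert (arr[:, :, j] == arr[:, :, j_locus]).all()


class TestPhenotypes:
    def test_deterministic_limit(self, small_config):
        from dataclasses import replace

        config = replace(small_config, penetrance=(1.0,), leak=0.0)
        pop = simulate_cross(config, seed=3)
        assign_phenotypes(pop, seed=3)
        ind = pop.individuals
        carrier = ind.co_genotype != "coco"
        std = ind.score_r0 >= 3
        assert (std[carrier] == ind.qualifying[carrier]).all()
        assert std[~carrier].all()  # coco individuals are always standard

    def test_penetrance_schedule_within_3_se(self):
        config = CrossConfig(
            genome=GenomeSpec(chromosomes=(("chr1", 2_000_000), ("chr2", 2_000_000)),
                              snv_density=1e-5),
            dominant_locus=("chr1", 1_500_000),
            suppressor_loci=(("chr1", 500_000), ("chr2", 1_000_000)),
            n_offspring=4000,
        )
        pop = simulate_cross(config, seed=21)
        assign_phenotypes(pop, seed=21)
        ind = pop.individuals
        qual = ind[(ind.co_genotype != "coco") & ind.qualifying]
        for t, pen in enumerate(config.penetrance):
            frac = (qual[f"score_r{t}"] >= 3).mean()
            se = np.sqrt(pen * (1 - pen) / len(qual))
            assert abs(frac - pen) < 3 * se

    def test_persistence_monotone_reversion(self, small_run):
        # with a non-increasing schedule nobody reverts standard -> columnar
        ind = small_run.population.individuals
        carrier = ind.co_genotype != "coco"
        std0 = ind.score_r0 >= 3
        std1 = ind.score_r1 >= 3
        assert not (std1[carrier] & ~std0[carrier]).any()


class TestPools:
    def test_pool_sizes_and_membership(self, small_run):
        config = small_run.config
        assert len(small_run.recessive_pool) == config.pool_sizes[0]
        assert len(small_run.dominant_pool) == config.pool_sizes[1]
        ind = small_run.population.individuals
        rec = ind.iloc[small_run.recessive_pool]
        dom = ind.iloc[small_run.dominant_pool]
        assert (rec.co_genotype != "coco").all() and (dom.co_genotype != "coco").all()
        assert (rec.score_r0 >= 3).all() and (dom.score_r0 <= 2).all()

    def test_insufficient_individuals_raises(self, small_config):
        from dataclasses import replace

        config = replace(small_config, pool_sizes=(500, 12))
        pop = simulate_cross(config, seed=1)
        assign_phenotypes(pop, seed=1)
        with pytest.raises(PoolingError, match="recessive pool needs 500"):
            build_pools(pop, seed=1)

    def test_same_seed_identical_pools(self, small_config):
        pop = simulate_cross(small_config, seed=9)
        assign_phenotypes(pop, seed=9)
        a = build_pools(pop, seed=123)
        b = build_pools(pop, seed=123)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()


class TestPoolReads:
    def test_error_rate_on_monomorphic_sites(self, small_config):
        """At sites where the pool carries no variant allele, the expected alt
        fraction is e/3 (substitution errors split over three bases)."""
        from dataclasses import replace

        config = replace(small_config, seq_error=0.006)
        pop = simulate_cross(config, seed=2)
        # force every allele to reference
        for chrom in pop.alleles:
            pop.alleles[chrom][:] = 0
        reads = simulate_pool_reads(pop, np.arange(20), depth_mean=100.0, seed=2)
        frac = reads.alt_count.sum() / reads.depth.sum()
        p = 0.006 / 3
        se = np.sqrt(p * (1 - p) / reads.depth.sum())
        assert abs(frac - p) < 3 * se

    def test_heterozygous_mean_af(self, small_config):
        pop = simulate_cross(small_config, seed=6)
        # one gamete variant, one reference everywhere: f = 0.5 at every site
        for chrom in pop.alleles:
            pop.alleles[chrom][:, 0, :] = 1
            pop.alleles[chrom][:, 1, :] = 0
        reads = simulate_pool_reads(pop, np.arange(10), depth_mean=100.0,
                                    seq_error=0.0, seed=6)
        mean_af = reads.alt_count.sum() / reads.depth.sum()
        se = np.sqrt(0.25 / reads.depth.sum())
        assert abs(mean_af - 0.5) < 3 * se


def test_experiment_determinism_byte_identical(small_config, tmp_path):
    from afddmap.io import write_pool_tsv

    a = simulate_experiment(small_config, seed=31)
    b = simulate_experiment(small_config, seed=31)
    pd.testing.assert_frame_equal(a.recessive_reads, b.recessive_reads)
    pd.testing.assert_frame_equal(a.dominant_reads, b.dominant_reads)
    pd.testing.assert_frame_equal(a.population.individuals, b.population.individuals)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_pool_tsv(a.recessive_reads, pa)
    write_pool_tsv(b.recessive_reads, pb)
    assert pa.read_bytes() == pb.read_bytes()
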