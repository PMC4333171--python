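"""Population simulator: Mendelian transmission, recombination, trait architecture."""

import numpy as np
import pytest

from gpimpute.gmap import GeneticMap, InvalidMapError
from gpimpute.precorrect import build_numerator_relationship
from gpimpute.simulate import (
    CovariatePlan,
    TraitArchitecture,
    simulate_phenotypes,
    simulate_population,
    simulate_study,
)

NO_COVARIATES = CovariatePlan(
    intercept=0.0, age_effect=0.0, gender_effect=0.0, month_effect_sd=0.0, density_effect=0.0
)


class TestGeneDropping:
    def test_mendelian_consistency_everywhere(self, small_map):
        pop = simulate_population(small_map, n_strains=4, n_families=6, litter_size=4, seed=5)
        parents = pop.pedigree.parent_indices()
        haps = pop.haplotypes
        for i, (s, d) in enumerate(parents):
            if s < 0:
                continue
            # gamete 0 comes from the sire, gamete 1 from the dam
            for gamete, parent in ((0, s), (1, d)):
                child = haps[i, :, gamete]
                match = (child == haps[parent, :, 0]) | (child == haps[parent, :, 1])
                assert match.all()

    def test_f1_heterozygous_where_strains_differ(self, small_map):
        pop = simulate_population(
            small_map, n_strains=2, n_families=1, litter_size=2, n_generations=1, seed=0
        )
        strains = pop.haplotypes[:2, :, 0]
        differs = strains[0] != strains[1]
        offspring = pop.study_genotypes().codes
        assert (offspring[:, differs] == 1).all()

    def test_zero_distance_loci_never_recombine(self):
        # chromosome with two tightly linked blocks: 0 cM inside a block
        gmap = GeneticMap(
            chromosome=[1, 1, 1],
            position_cM=[0.0, 1e-9, 50.0],
            locus_id=["a", "b", "c"],
        )
        pop = simulate_population(gmap, n_strains=4, n_families=20, litter_size=10, seed=2)
        parents = pop.pedigree.parent_indices()
        haps = pop.haplotypes
        for i, (s, d) in enumerate(parents):
            if s < 0:
                continue
            for gamete, parent in ((0, s), (1, d)):
                pair = tuple(haps[i, :2, gamete])
                parental = {tuple(haps[parent, :2, 0]), tuple(haps[parent, :2, 1])}
                assert pair in parental

    def test_recombination_fraction_matches_haldane(self):
        # two loci 50 cM apart: expected r = 0.5 (1 - e^{-1}) ~ 0.3161
        gmap = GeneticMap(chromosome=[1, 1], position_cM=[0.0, 50.0], locus_id=["a", "b"])
        rng = np.random.default_rng(7)
        from gpimpute.simulate import _meiosis

        # heterozygous-at-both parent so every recombination is observable
        parent = np.array([[0, 1], [0, 1]], dtype=np.int8)  # hap0 = (0,0), hap1 = (1,1)
        n = 10_000
        rec = 0
        for _ in range(n):
            gam = _meiosis(parent, gmap, rng)
            rec += gam[0] != gam[1]
        expected = 0.5 * (1.0 - np.exp(-1.0))
        assert abs(rec / n - expected) < 0.02

    def test_configuration_errors(self, small_map):
        with pytest.raises(ValueError):
            simulate_population(small_map, n_strains=1)
        with pytest.raises(InvalidMapError):
            GeneticMap(chromosome=[1, 2, 2], position_cM=[0.0, 0.0, 1.0])

    def test_inbreeding_grows_with_generations(self, small_map):
        f_by_depth = []
        for gens in (1, 3, 6):
            pop = simulate_population(
                small_map, n_strains=4, n_families=10, litter_size=4,
                n_generations=gens, n_intermediate=12, seed=3,
            )
            A = build_numerator_relationship(pop.pedigree)
            last = pop.pedigree.table["generation"].max()
            rows = np.flatnonzero((pop.pedigree.table["generation"] == last).to_numpy())
            f_by_depth.append(np.diag(A)[rows].mean() - 1.0)
        assert f_by_depth[0] == 0.0  # F1 of distinct founders is non-inbred
        assert f_by_depth[0] < f_by_depth[1] < f_by_depth[2]

    def test_ld_decays_with_map_distance(self, qc_study):
        g = qc_study["genotypes"]
        codes = g.codes.astype(float)
        chrom = g.loci["chromosome"].to_numpy()
        pos = g.loci["position_cM"].to_numpy()
        bins = [(0, 3), (3, 9), (9, 27), (27, 90)]
        means = []
        for lo, hi in bins:
            r2 = []
            for c in np.unique(chrom):
                idx = np.flatnonzero(chrom == c)
                for a in range(len(idx)):
                    for b in range(a + 1, len(idx)):
                        d = pos[idx[b]] - pos[idx[a]]
                        if lo <= d < hi:
                            r = np.corrcoef(codes[:, idx[a]], codes[:, idx[b]])[0, 1]
                            r2.append(r * r)
            means.append(np.mean(r2))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestTraitSimulation:
    def test_pure_noise_architecture_has_no_heritability(self, qc_study):
        arch = TraitArchitecture(
            n_qtl=10, additive_variance=0.0, cage_variance=0.0, residual_variance=1.0
        )
        s = simulate_phenotypes(
            qc_study["genotypes"], qc_study["study"].pedigree, arch,
            covariate_plan=NO_COVARIATES, seed=1,
        )
        y = s.phenotypes["trait"].to_numpy()
        assert np.allclose(s.true_breeding_values, 0.0)
        assert abs(y.std() - 1.0) < 0.1

    def test_noiseless_additive_trait_equals_breeding_value(self, qc_study):
        arch = TraitArchitecture(
            n_qtl=20, additive_variance=1.0, cage_variance=0.0, residual_variance=0.0
        )
        s = simulate_phenotypes(
            qc_study["genotypes"], qc_study["study"].pedigree, arch,
            covariate_plan=NO_COVARIATES, seed=2,
        )
        y = s.phenotypes["trait"].to_numpy()
        assert abs(np.corrcoef(y, s.true_breeding_values)[0, 1] - 1.0) < 1e-12

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            TraitArchitecture(additive_variance=-1.0)

    def test_realized_heritability_matches_target(self):
        """Monte-Carlo: h2 = 0.5 at n = 2,000 recovered within tolerance."""
        arch = TraitArchitecture(
            n_qtl=30, additive_variance=1.0, cage_variance=0.0, residual_variance=1.0
        )
        slopes, h2s = [], []
        for seed in range(20):
            s = simulate_study(
                architecture=arch, seed=seed, n_families=200, litter_size=10,
                covariate_plan=NO_COVARIATES,
            )
            y = s.phenotypes["trait"].to_numpy()
            bv = s.true_breeding_values
            slopes.append(np.polyfit(bv, y, 1)[0])
            h2s.append(bv.var() / y.var())
        assert abs(np.mean(slopes) - 1.0) < 0.1
        assert abs(np.mean(h2s) - 0.5) < 0.07
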