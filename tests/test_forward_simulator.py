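import numpy as np
import pytest
from scipy.stats import chisquare

from admixmate.forward_simulator import (
    FEMALE,
    MALE,
    ChromosomeMap,
    GeneticMap,
    Haplotype,
    Individual,
    Population,
    ScenarioConfig,
    Tract,
    apply_pulse,
    found_population,
    largest_remainder_counts,
    make_founder,
    meiosis,
    read_hapmap,
    run_scenario,
    step_generation,
    write_hapmap,
)
from admixmate.mating_model import MatingParams, build_kernel
from admixmate.synthetic_data import toy_genetic_map


class TestGeneticMap:
    def test_lengths_and_x(self, tiny_map):
        assert len(tiny_map) == 3
        assert tiny_map.x_index == 2
        assert tiny_map.autosome_indices == [0, 1]
        assert tiny_map.lengths_cm == pytest.approx([100.0, 80.0, 60.0])

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            ChromosomeMap(name="chr1", length_cm=0.0)

    def test_hapmap_round_trip(self, tiny_map, tmp_path):
        path = tmp_path / "map.tsv"
        write_hapmap(tiny_map, path)
        back = read_hapmap(path)
        assert len(back) == len(tiny_map)
        for a, b in zip(tiny_map, back):
            assert a.name == b.name
            assert a.length_cm == pytest.approx(b.length_cm)
            assert a.is_x == b.is_x

    def test_hapmap_interpolation(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "chrom\tpos\trate\tmap\n"
            "chr1\t0\t1\t0\n"
            "chr1\t1000000\t1\t1\n"
            "chr1\t3000000\t0\t2\n"
        )
        gmap = read_hapmap(path)
        assert gmap[0].length_cm == pytest.approx(2.0)
        assert gmap[0].phys_to_genetic(2000000) == pytest.approx(1.5)


class TestHaplotype:
    def test_tract_views(self):
        h = Haplotype([10.0, 50.0, 100.0], [1, 3, 1])
        tracts = h.tracts()
        assert tracts[0] == Tract(0.0, 10.0, 1)
        assert [t.length_cm for t in tracts] == [10.0, 40.0, 50.0]
        assert h.ancestry_lengths() == pytest.approx([60.0, 0.0, 40.0])

    def test_validation_catches_non_maximal(self):
        h = Haplotype([10.0, 100.0], [2, 2])
        with pytest.raises(ValueError):
            h.validate(100.0)

    def test_validation_catches_bad_tiling(self):
        h = Haplotype([10.0, 90.0], [1, 2])
        with pytest.raises(ValueError):
            h.validate(100.0)


class TestLargestRemainder:
    def test_exact_total(self):
        counts = largest_remainder_counts(np.array([0.5, 0.3, 0.2]), 7)
        assert counts.sum() == 7

    def test_proportionality(self):
        counts = largest_remainder_counts(np.array([0.5, 0.3, 0.2]), 1000)
        assert list(counts) == [500, 300, 200]


class TestFounding:
    def test_single_ancestry(self, tiny_map, rng):
        config = ScenarioConfig(
            genetic_map=tiny_map, founding_proportions=(1.0, 0.0, 0.0),
            population_size=20, generations=3,
        )
        params = MatingParams.from_sb12((0, 0, 0), 0, 0)
        pop = found_population(config, params, rng)
        assert pop.mean_proportions() == pytest.approx([1.0, 0.0, 0.0])

    def test_exact_sex_ratio(self, tiny_map, rng):
        config = ScenarioConfig(
            genetic_map=tiny_map, founding_proportions=(0.3, 0.5, 0.2),
            population_size=100, generations=3,
        )
        pop = found_population(config, MatingParams.from_sb12((0, 0, 0), 0, 0), rng)
        assert len(pop.females) == 50 and len(pop.males) == 50

    def test_two_pulse_first_wave_composition(self, tiny_map, rng):
        # (1-GFR_s) c_s renormalised: GFR=(0,1,0) removes ancestry 2 entirely
        config = ScenarioConfig(
            genetic_map=tiny_map, founding_proportions=(0.5, 0.3, 0.2),
            population_size=140, generations=12, migration_model="two_pulses",
        )
        params = MatingParams.from_sb12((0, 0, 0), 0, 0, gfr=(0.0, 1.0, 0.0))
        pop = found_population(config, params, rng)
        expected = np.array([0.5, 0.0, 0.2]) / 0.7
        assert pop.mean_proportions() == pytest.approx(expected, abs=0.01)

    def test_founder_haplotypes_single_tract(self, tiny_map):
        f = make_founder(2, FEMALE, tiny_map)
        for haps in f.haplotypes:
            for h in haps:
                assert h.n_tracts == 1
        m = make_founder(2, MALE, tiny_map)
        assert len(m.haplotypes[tiny_map.x_index]) == 1

    def test_warning_on_lost_ancestry(self, tiny_map, rng):
        config = ScenarioConfig(
            genetic_map=tiny_map, founding_proportions=(0.999, 0.001, 0.0),
            population_size=10, generations=3,
        )
        with pytest.warns(UserWarning):
            found_population(config, MatingParams.from_sb12((0, 0, 0), 0, 0), rng)


class TestAncestryProportions:
    def test_founder(self, tiny_map):
        assert make_founder(3, FEMALE, tiny_map).proportions == pytest.approx(
            [0.0, 0.0, 1.0]
        )

    def test_f1_autosomes(self, single_autosome_map):
        h1 = Haplotype([100.0], [1])
        h3 = Haplotype([100.0], [3])
        child = Individual(FEMALE, [[h1, h3]], single_autosome_map)
        assert child.proportions == pytest.approx([0.5, 0.0, 0.5])

    def test_invariant_under_resegmentation(self, single_autosome_map):
        a = Individual(FEMALE, [[Haplotype([100.0], [1]), Haplotype([100.0], [3])]],
                       single_autosome_map)
        # same genome with one tract split at 40 cM (non-maximal, but the
        # length accounting must not care)
        b = Individual(
            FEMALE,
            [[Haplotype([40.0, 100.0], [1, 1]), Haplotype([100.0], [3])]],
            single_autosome_map,
        )
        assert a.proportions == pytest.approx(b.proportions)


class TestMeiosis:
    def test_identical_homologs(self, single_autosome_map, rng):
        parent = make_founder(1, FEMALE, single_autosome_map)
        gamete = meiosis(parent, single_autosome_map, rng)
        assert gamete[0] == parent.haplotypes[0][0]

    def test_crossover_count_poisson_mean(self, single_autosome_map):
        # heterozygous homologs make every crossover visible as a switch
        rng = np.random.default_rng(42)
        parent = Individual(
            FEMALE,
            [[Haplotype([100.0], [1]), Haplotype([100.0], [3])]],
            single_autosome_map,
        )
        switches = [
            meiosis(parent, single_autosome_map, rng)[0].n_tracts - 1
            for _ in range(10_000)
        ]
        mean = np.mean(switches)
        se = np.std(switches) / np.sqrt(len(switches))
        assert abs(mean - 1.0) < 3 * se

    def test_single_crossover_partition(self, single_autosome_map):
        rng = np.random.default_rng(3)
        parent = Individual(
            FEMALE,
            [[Haplotype([100.0], [1]), Haplotype([100.0], [3])]],
            single_autosome_map,
        )
        for _ in range(200):
            g = meiosis(parent, single_autosome_map, rng)[0]
            if g.n_tracts == 2:
                lengths = g.tract_lengths()
                assert lengths.sum() == pytest.approx(100.0)
                assert set(g.ancestries) == {1, 3}

    def test_male_x_transmitted_intact(self, tiny_map, rng):
        father = make_founder(2, MALE, tiny_map)
        gamete = meiosis(father, tiny_map, rng, [tiny_map.x_index])
        assert gamete[0] == father.haplotypes[tiny_map.x_index][0]


class TestStepGeneration:
    def test_tract_tiling_preserved(self, tiny_scenario, moderate_params, rng):
        kernel = build_kernel(moderate_params)
        pop = found_population(tiny_scenario, moderate_params, rng)
        for _ in range(3):
            pop = step_generation(pop, kernel, tiny_scenario, rng)
            for ind in pop:
                ind.validate(tiny_scenario.genetic_map)

    def test_single_ancestry_conserved(self, tiny_map, rng, random_mating_params):
        config = ScenarioConfig(
            genetic_map=tiny_map, founding_proportions=(0.0, 1.0, 0.0),
            population_size=40, generations=2,
        )
        kernel = build_kernel(random_mating_params)
        pop = found_population(config, random_mating_params, rng)
        pop = step_generation(pop, kernel, config, rng)
        assert pop.mean_proportions() == pytest.approx([0.0, 1.0, 0.0])

    def test_exact_sex_ratio_every_generation(self, tiny_scenario, moderate_params, rng):
        kernel = build_kernel(moderate_params)
        pop = found_population(tiny_scenario, moderate_params, rng)
        for _ in range(4):
            pop = step_generation(pop, kernel, tiny_scenario, rng)
            assert len(pop.females) == tiny_scenario.population_size // 2

    def test_mate_choice_uniform_under_flat_kernel(self, rng):
        # chi-square on father identity under AM=0, SB=0
        gmap = toy_genetic_map([50.0], include_x=False)
        config = ScenarioConfig(
            genetic_map=gmap, founding_proportions=(0.4, 0.3, 0.3),
            population_size=20, generations=2,
        )
        params = MatingParams.from_sb12((0, 0, 0), 0, 0)
        kernel = build_kernel(params)
        pop = found_population(config, params, rng)
        males = pop.males
        counts = dict.fromkeys(range(len(males)), 0)
        from admixmate.forward_simulator import _draw_couples

        _, fathers = _draw_couples(kernel, pop.females, males, 10_000, rng)
        for f in fathers:
            counts[int(f)] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.001

    def test_x_gene_pool_two_thirds_maternal(self, rng):
        # all-female ancestry 1, all-male ancestry 3 founders: offspring X
        # pool is 2/3 ancestry 1 in expectation
        gmap = toy_genetic_map([80.0], include_x=True, x_length_cm=60.0)
        founders = [make_founder(1, FEMALE, gmap) for _ in range(30)] + [
            make_founder(3, MALE, gmap) for _ in range(30)
        ]
        pop = Population(founders, gmap)
        config = ScenarioConfig(
            genetic_map=gmap, founding_proportions=(0.5, 0.0, 0.5),
            population_size=60, generations=2,
        )
        params = MatingParams.from_sb12((0, 0, 0), 0, 0)
        kernel = build_kernel(params)
        x = gmap.x_index
        frac = []
        for _ in range(50):
            off = step_generation(pop, kernel, config, rng)
            anc1 = total = 0.0
            for ind in off:
                for h in ind.haplotypes[x]:
                    lens = h.ancestry_lengths()
                    anc1 += lens[0]
                    total += lens.sum()
            frac.append(anc1 / total)
        assert np.mean(frac) == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_x_exceeds_autosome_when_founding_sex_skewed(self, rng):
        # female founders all ancestry 1: X should carry more ancestry 1
        # than autosomes after some generations
        gmap = toy_genetic_map([80.0], include_x=True, x_length_cm=60.0)
        founders = [make_founder(1, FEMALE, gmap) for _ in range(30)] + [
            make_founder(3, MALE, gmap) for _ in range(30)
        ]
        pop = Population(founders, gmap)
        config = ScenarioConfig(
            genetic_map=gmap, founding_proportions=(0.5, 0.0, 0.5),
            population_size=60, generations=6,
        )
        params = MatingParams.from_sb12((0, 0, 0), 0, 0)
        kernel = build_kernel(params)
        x_fracs, a_fracs = [], []
        for rep in range(20):
            p = pop
            for _ in range(6):
                p = step_generation(p, kernel, config, rng)
            x1 = a1 = xt = at = 0.0
            for ind in p:
                for ci in range(len(gmap)):
                    for h in ind.haplotypes[ci]:
                        lens = h.ancestry_lengths()
                        if ci == gmap.x_index:
                            x1 += lens[0]
                            xt += lens.sum()
                        else:
                            a1 += lens[0]
                            at += lens.sum()
            x_fracs.append(x1 / xt)
            a_fracs.append(a1 / at)
        assert np.mean(x_fracs) > np.mean(a_fracs)


class TestApplyPulse:
    def _config(self, tiny_map, n=100):
        return ScenarioConfig(
            genetic_map=tiny_map, founding_proportions=(0.5, 0.3, 0.2),
            population_size=n, generations=12, migration_model="two_pulses",
        )

    def test_zero_gfr_is_plain_step(self, tiny_map, rng):
        config = self._config(tiny_map)
        params = MatingParams.from_sb12((0, 0, 0), 0, 0, gfr=(0.0, 0.0, 0.0))
        kernel = build_kernel(params)
        pop = found_population(config, params, rng)
        new = apply_pulse(pop, config, params, kernel, rng)
        assert len(new) == config.population_size
        assert len(new.females) == config.population_size // 2

    def test_migrant_count_from_rho(self, tiny_map, rng):
        # rho = sum GFR_s c_s = 0.3 -> 30 unadmixed migrants of ancestry 2
        config = self._config(tiny_map, n=100)
        params = MatingParams.from_sb12((0, 0, 0), 0, 0, gfr=(0.0, 1.0, 0.0))
        kernel = build_kernel(params)
        pop = found_population(config, params, rng)
        pop = step_generation(pop, kernel, config, rng)
        new = apply_pulse(pop, config, params, kernel, rng)
        unadmixed_nat = sum(
            1 for ind in new if ind.proportions[1] == 1.0
        )
        assert unadmixed_nat == 30
        assert len(new) == 100

    def test_post_pulse_composition_near_c(self, tiny_map):
        rng = np.random.default_rng(11)
        config = self._config(tiny_map, n=200)
        params = MatingParams.from_sb12((0, 0, 0), 0, 0, gfr=(0.3, 0.5, 0.2))
        kernel = build_kernel(params)
        means = []
        for _ in range(20):
            pop = found_population(config, params, rng)
            pop = step_generation(pop, kernel, config, rng)
            new = apply_pulse(pop, config, params, kernel, rng)
            means.append(new.mean_proportions())
        assert np.mean(means, axis=0) == pytest.approx(
            config.founding_proportions, abs=0.02
        )

    def test_rho_one_rejected(self, tiny_map, rng):
        config = self._config(tiny_map)
        found_params = MatingParams.from_sb12((0, 0, 0), 0, 0, gfr=(0.1, 0.1, 0.1))
        kernel = build_kernel(found_params)
        pop = found_population(config, found_params, rng)
        all_migrant = MatingParams.from_sb12((0, 0, 0), 0, 0, gfr=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="rho"):
            apply_pulse(pop, config, all_migrant, kernel, rng)


class TestRunScenario:
    def test_seed_reproducibility(self, tiny_scenario, moderate_params):
        r1 = run_scenario(tiny_scenario, moderate_params, np.random.default_rng(9))
        r2 = run_scenario(tiny_scenario, moderate_params, np.random.default_rng(9))
        assert np.array_equal(
            r1.mean_proportions_by_generation, r2.mean_proportions_by_generation
        )
        for a, b in zip(r1.population, r2.population):
            assert a.sex == b.sex
            for ha, hb in zip(a.haplotypes, b.haplotypes):
                assert all(x == y for x, y in zip(ha, hb))

    def test_history_shape(self, tiny_scenario, moderate_params, rng):
        r = run_scenario(tiny_scenario, moderate_params, rng)
        assert r.mean_proportions_by_generation.shape == (
            tiny_scenario.generations + 1,
            3,
        )

    def test_recombination_only_fragments(self, tiny_map, rng, random_mating_params):
        config = ScenarioConfig(
            genetic_map=tiny_map, founding_proportions=(0.5, 0.2, 0.3),
            population_size=40, generations=1,
        )
        r = run_scenario(config, random_mating_params, rng)
        founder_tracts = 2 * len(tiny_map) - 1  # male minimum
        assert all(ind.n_tracts() >= founder_tracts for ind in r.population)

    def test_ancestry_martingale_over_replicates(self, random_mating_params):
        # mean final proportions across replicates stay at founding values
        gmap = toy_genetic_map([100.0, 80.0], include_x=True, x_length_cm=60.0)
        config = ScenarioConfig(
            genetic_map=gmap, founding_proportions=(0.3, 0.5, 0.2),
            population_size=50, generations=8,
        )
        rng = np.random.default_rng(123)
        finals = np.stack(
            [
                run_scenario(config, random_mating_params, rng)
                .population.mean_proportions()
                for _ in range(60)
            ]
        )
        se = finals.std(axis=0) / np.sqrt(len(finals))
        assert np.all(
            np.abs(finals.mean(axis=0) - config.founding_proportions) < 3.5 * se + 1e-3
        )

    def test_variance_increases_with_am(self):
        # stronger assortment slows homogenisation of that ancestry
        gmap = toy_genetic_map([100.0], include_x=False)
        rng = np.random.default_rng(21)
        spreads = []
        for a in (0.0, 0.5, 1.0):
            params = MatingParams.from_sb12((a, a, a), 0, 0)
            config = ScenarioConfig(
                genetic_map=gmap, founding_proportions=(0.4, 0.3, 0.3),
                population_size=100, generations=10,
            )
            var = []
            for _ in range(25):
                r = run_scenario(config, params, rng)
                var.append(r.population.proportions_matrix()[:, 0].var())
            spreads.append(np.mean(var))
        assert spreads[0] < spreads[1] < spreads[2]


class TestScenarioConfigValidation:
    def test_odd_population_rejected(self, tiny_map):
        with pytest.raises(ValueError):
            ScenarioConfig(
                genetic_map=tiny_map, founding_proportions=(1, 0, 0),
                population_size=11, generations=3,
            )

    def test_pulse_generation_bounds(self, tiny_map):
        with pytest.raises(ValueError):
            ScenarioConfig(
                genetic_map=tiny_map, founding_proportions=(1, 0, 0),
                population_size=10, generations=3,
                migration_model="two_pulses", pulse_generation=3,
            )

    def test_full_scale_config_constructible(self):
        from admixmate.synthetic_data import default_human_map

        gmap = default_human_map()
        assert len(gmap) == 23 and gmap.x_index == 22
        config = ScenarioConfig(
            genetic_map=gmap, founding_proportions=(0.032, 0.754, 0.214),
            population_size=1000, generations=19,
            migration_model="two_pulses", pulse_generation=10,
        )
        assert config.population_size == 1000
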