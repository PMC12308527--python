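import math

import numpy as np
import pytest

from odload.mutation_model import (
    DFEConfig,
    FitnessScheme,
    MutationClass,
    MutationRecord,
    ODModel,
    Trait,
)
from odload.population_engine import (
    ExtinctionError,
    Individual,
    Population,
    RecombinationMap,
    individual_fitness,
    make_gamete,
    mutate_gamete,
    next_generation,
)

NO_MUT = DFEConfig(U=0, U_let=0, U_o=0, U_n=0)


def binom_3se(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


class TestMakeGamete:
    def test_homozygous_sites_always_transmit(self, rng):
        ind = Individual((1, 2, 3), (2, 3, 4))
        for _ in range(20):
            g = make_gamete(ind, RecombinationMap(), rng)
            assert 2 in g and 3 in g

    def test_heterozygous_site_transmits_half_the_time(self, rng):
        ind = Individual((7,), ())
        n = 10_000
        carriers = sum(7 in make_gamete(ind, RecombinationMap(), rng) for _ in range(n))
        assert abs(carriers / n - 0.5) < binom_3se(0.5, n)

    def test_mapped_recombinant_fraction_follows_haldane(self, rng):
        """Two heterozygous sites 0.5 Morgan apart in cis recombine at
        r = (1 - exp(-2*0.5))/2 ~ 0.316."""
        reg = {
            1: MutationRecord(1, MutationClass.NEUTRAL, position=0.25),
            2: MutationRecord(2, MutationClass.NEUTRAL, position=0.75),
        }
        ind = Individual((1, 2), ())
        rmap = RecombinationMap("mapped", 20.0)
        n = 20_000
        rec = 0
        for _ in range(n):
            g = make_gamete(ind, rmap, rng, registry=reg)
            rec += (1 in g) != (2 in g)
        r_exp = (1 - math.exp(-1.0)) / 2
        assert abs(rec / n - r_exp) < binom_3se(r_exp, n)

    def test_batch_mapped_gametes_match_haldane(self, rng):
        pop = Population(50, FitnessScheme(), NO_MUT, RecombinationMap("mapped", 20.0))
        even = list(range(0, 100, 2))
        a = pop.seed_mutation({"mclass": MutationClass.NEUTRAL, "position": 5.0}, even, rng)
        b = pop.seed_mutation({"mclass": MutationClass.NEUTRAL, "position": 5.5}, even, rng)
        M = 8000
        parents = rng.integers(0, 50, M)
        _, masks = pop._crossover_masks(M, rng)
        g = pop._apply_masks(pop.neu, parents, masks)
        bits = np.unpackbits(g, axis=1)
        sa = pop.neu.slot_of_id(a)
        sb = pop.neu.slot_of_id(b)
        rec = (bits[:, sa] != bits[:, sb]).mean()
        r_exp = (1 - math.exp(-1.0)) / 2
        assert abs(rec - r_exp) < binom_3se(r_exp, M)


class TestMutateGamete:
    def test_zero_rates_leave_gamete_unchanged(self, rng):
        g, new = mutate_gamete((1, 5), NO_MUT, t=3, rng=rng)
        assert g == (1, 5) and new == []

    def test_poisson_rate_of_new_deleterious(self, rng):
        dfe = DFEConfig(U=0.2, U_let=0, U_o=0, U_n=0)
        n = 30_000
        total = 0
        for _ in range(n):
            _, new = mutate_gamete((), dfe, t=0, rng=rng)
            total += len(new)
        se = math.sqrt(0.2 / n)  # Poisson variance equals the rate
        assert abs(total / n - 0.2) < 3 * se

    def test_population_influx_rate_of_overdominant_mutations(self, rng):
        """With U_o = 1e-4 and n = 1000, 2n U_o = 0.2 new OD loci arise per
        generation on average."""
        dfe = DFEConfig(U=0, U_let=0, U_o=1e-4, s_o=0.04, U_n=0)
        pop = Population(
            1000, FitnessScheme(od_model=ODModel.CLASSICAL_SYMMETRIC), dfe
        )
        gens = 3000
        for _ in range(gens):
            pop.step(0.0, rng)
        arisen = pop._next_id
        rate = arisen / gens
        se = math.sqrt(0.2 / gens)
        assert abs(rate - 0.2) < 3 * se

    def test_new_records_carry_birth_generation_and_fresh_ids(self, rng):
        dfe = DFEConfig(U=2.0, U_let=0.5, U_o=0.1, s_o=0.02, U_n=1.0)
        g, new = mutate_gamete((0,), dfe, t=7, rng=rng, id_start=100)
        assert all(m.birth_gen == 7 for m in new)
        ids = [m.id for m in new]
        assert len(set(ids)) == len(ids) and all(i >= 100 for i in ids)
        assert set(g) == {0} | set(ids)


class TestIndividualFitness:
    def test_mutation_free_individual_has_fitness_one(self):
        pop = Population(4, FitnessScheme(), NO_MUT)
        assert individual_fitness(Individual((), ()), FitnessScheme(), pop) == 1.0

    def test_product_of_factors(self, rng):
        scheme = FitnessScheme(od_model=ODModel.CLASSICAL_SYMMETRIC)
        pop = Population(4, scheme, NO_MUT)
        od = pop.seed_mutation(
            {"mclass": MutationClass.OVERDOMINANT, "s_hom_wild": 0.04, "s_hom_mut": 0.04},
            [0],
            rng,
        )
        dl = pop.seed_mutation(
            {"mclass": MutationClass.DELETERIOUS, "s": 0.1, "h": 0.2}, [2], rng
        )
        ind = Individual((od,), (dl,))
        assert individual_fitness(ind, scheme, pop) == pytest.approx(0.98)
        # a non-carrier still pays the homozygote penalty of the OD locus
        assert individual_fitness(Individual((), ()), scheme, pop) == pytest.approx(
            0.96 * 1.0
        )

    def test_many_od_loci_crush_the_wild_homozygote(self, rng):
        scheme = FitnessScheme(od_model=ODModel.CLASSICAL_SYMMETRIC)
        pop = Population(4, scheme, NO_MUT)
        for _ in range(153):
            pop.seed_mutation(
                {
                    "mclass": MutationClass.OVERDOMINANT,
                    "s_hom_wild": 0.04,
                    "s_hom_mut": 0.04,
                },
                [1],
                rng,
            )
        w = individual_fitness(Individual((), ()), scheme, pop)
        assert w == pytest.approx(0.96**153, rel=1e-9)
        assert w == pytest.approx(1.95e-3, rel=0.02)

    def test_unresolved_id_raises(self):
        pop = Population(4, FitnessScheme(), NO_MUT)
        with pytest.raises(KeyError):
            individual_fitness(Individual((99,), ()), FitnessScheme(), pop)

    def test_batch_engine_agrees_with_record_level_fitness(self, rng):
        """The bit-packed fitness evaluation equals the sparse per-record
        product for every individual."""
        from tests.conftest import seeded_population

        scheme = FitnessScheme(od_model=ODModel.CLASSICAL_SYMMETRIC)
        loci = [
            ({"mclass": MutationClass.DELETERIOUS, "s": 0.3, "h": 0.1}, 0.3),
            ({"mclass": MutationClass.DELETERIOUS, "s": 0.05, "h": 0.4}, 0.5),
            ({"mclass": MutationClass.LETHAL, "s": 1.0, "h": 0.02}, 0.1),
            (
                {
                    "mclass": MutationClass.OVERDOMINANT,
                    "s_hom_wild": 0.04,
                    "s_hom_mut": 0.04,
                },
                0.5,
            ),
        ]
        pop = seeded_population(30, scheme, sel_loci=loci, seed=5)
        batch = pop.fitness_values()
        for i in range(30):
            ind = pop.individual(i)
            # the batch path uses float32 lookup tables for log factors
            assert individual_fitness(ind, scheme, pop) == pytest.approx(
                batch[i], rel=1e-5
            )


class TestNextGeneration:
    def test_offspring_count_and_copy_conservation(self, rng):
        dfe = DFEConfig(U=0.5, U_let=0.05, U_o=0, U_n=0.5)
        pop = Population(40, FitnessScheme(), dfe)
        for _ in range(25):
            next_generation(pop, S=0.3, rng=rng)
            assert pop.sel.H.shape[0] == 80
            assert pop.copy_count_check()

    def test_neutral_frequency_martingale(self, rng):
        """Without selection the mean final frequency stays at the initial
        frequency across replicates."""
        finals = []
        q0 = 0.3
        for rep in range(400):
            r = np.random.default_rng(rep)
            pop = Population(20, FitnessScheme(), NO_MUT)
            rows = r.choice(40, size=12, replace=False)  # q0 = 0.3
            mid = pop.seed_mutation(
                {"mclass": MutationClass.DELETERIOUS, "s": 1e-9, "h": 0.5}, rows, r
            )
            for _ in range(10):
                pop.step(0.0, r)
            try:
                sl = pop.sel.slot_of_id(mid)
                finals.append(pop.sel.count[sl] / 40)
            except KeyError:
                fixed = any(e[1] == mid and e[2] == "fixed" for e in pop.fixed_log)
                finals.append(1.0 if fixed else 0.0)
        finals = np.asarray(finals)
        se = finals.std(ddof=1) / math.sqrt(finals.size)
        assert abs(finals.mean() - q0) < 3 * se

    def test_neutral_heterozygosity_decay(self, rng):
        """E[H_t] = H_0 (1 - 1/(2n))^t for neutral drift at S = 0."""
        n, t_end, reps = 50, 30, 120
        hets = []
        for rep in range(reps):
            r = np.random.default_rng(1000 + rep)
            pop = Population(n, FitnessScheme(), NO_MUT)
            mids = []
            for _ in range(20):
                rows = r.choice(2 * n, size=n, replace=False)  # q = 0.5
                mids.append(
                    pop.seed_mutation(
                        {"mclass": MutationClass.DELETERIOUS, "s": 1e-9, "h": 0.5},
                        rows,
                        r,
                    )
                )
            for _ in range(t_end):
                pop.step(0.0, r)
            h = 0.0
            for mid in mids:
                try:
                    sl = pop.sel.slot_of_id(mid)
                    q = pop.sel.count[sl] / (2 * n)
                except KeyError:
                    q = 0.0
                h += 2 * q * (1 - q)
            hets.append(h / 20)
        hets = np.asarray(hets)
        expected = 0.5 * (1 - 1 / (2 * n)) ** t_end
        se = hets.std(ddof=1) / math.sqrt(reps)
        assert abs(hets.mean() - expected) < 3 * se

    def test_full_selfing_halves_heterozygosity_per_generation(self, rng):
        """Under S = 1 a heterozygous locus becomes homozygous with
        probability 1/2 per generation."""
        n, reps = 30, 2000
        still_het = 0
        for rep in range(reps):
            r = np.random.default_rng(rep)
            pop = Population(n, FitnessScheme(), NO_MUT)
            rows = np.arange(0, 2 * n, 2)  # every individual heterozygous
            mid = pop.seed_mutation(
                {"mclass": MutationClass.DELETERIOUS, "s": 1e-9, "h": 0.5}, rows, r
            )
            pop.step(1.0, r)
            x, _ = pop.genotype_matrix("sel")
            if x.size:
                still_het += (x[:, 0] == 1).sum() / n
        frac = still_het / reps
        assert abs(frac - 0.5) < binom_3se(0.5, reps * n)

    def test_viability_selection_rejects_lethal_homozygotes(self, rng):
        dfe = NO_MUT
        for rep in range(50):
            r = np.random.default_rng(rep)
            pop = Population(2, FitnessScheme(), dfe)
            pop.seed_mutation(
                {"mclass": MutationClass.LETHAL, "s": 1.0, "h": 0.0}, [0], r
            )
            pop.step(0.0, r)
            x, _ = pop.genotype_matrix("sel")
            if x.size:
                assert (x < 2).all()

    def test_selfing_rate_validation(self, rng):
        pop = Population(10, FitnessScheme(), NO_MUT)
        with pytest.raises(ValueError):
            pop.step(1.5, rng)

    def test_engine_fixation_probability_matches_markov_chain(self):
        """Empirical single-locus fixation frequencies agree with the exact
        genotype-count chain on a tiny population."""
        from odload.analytic_oracles import single_locus_chain

        N, reps = 10, 4000
        w = (1.0, 0.97, 0.8)  # partially recessive deleterious allele
        chain = single_locus_chain(N, w, S=0.0)
        p_chain = chain.fixation_probability((N - 1, 1, 0))
        fixed = 0
        for rep in range(reps):
            r = np.random.default_rng(rep)
            pop = Population(N, FitnessScheme(), NO_MUT)
            mid = pop.seed_mutation(
                {"mclass": MutationClass.DELETERIOUS, "s": 0.2, "h": 0.15}, [0], r
            )
            for _ in range(400):
                pop.step(0.0, r)
                if not pop.sel.active.any():
                    break
            fixed += any(e[1] == mid and e[2] == "fixed" for e in pop.fixed_log)
        p_hat = fixed / reps
        assert abs(p_hat - p_chain) < binom_3se(max(p_chain, 1e-3), reps)

    def test_strong_symmetric_overdominance_preserves_polymorphism(self, rng):
        """With s_o = 0.2 and n = 1000, balancing selection holds the allele
        near 0.5 for the whole test horizon."""
        scheme = FitnessScheme(od_model=ODModel.CLASSICAL_SYMMETRIC)
        pop = Population(1000, scheme, NO_MUT)
        rows = rng.choice(2000, size=1000, replace=False)
        mid = pop.seed_mutation(
            {"mclass": MutationClass.OVERDOMINANT, "s_hom_wild": 0.2, "s_hom_mut": 0.2},
            rows,
            rng,
        )
        for _ in range(300):
            pop.step(0.0, rng)
        sl = pop.sel.slot_of_id(mid)  # raises KeyError if lost
        q = pop.sel.count[sl] / 2000
        assert 0.35 < q < 0.65

    def test_fecundity_sterile_parents_never_reproduce(self, rng):
        scheme = FitnessScheme(trait=Trait.FECUNDITY)
        pop = Population(6, scheme, NO_MUT)
        # one individual homozygous sterile, the rest mutation-free
        pop.seed_mutation({"mclass": MutationClass.LETHAL, "s": 1.0, "h": 0.0}, [0, 1], rng)
        pop.refresh_fitness_cache()
        pop.step(0.0, rng)
        x, _ = pop.genotype_matrix("sel")
        assert x.size == 0 or (x == 0).all()

    def test_fecundity_outcrossing_with_single_fertile_parent_is_extinction(self, rng):
        scheme = FitnessScheme(trait=Trait.FECUNDITY)
        pop = Population(2, scheme, NO_MUT)
        pop.seed_mutation({"mclass": MutationClass.LETHAL, "s": 1.0, "h": 0.0}, [0, 1], rng)
        pop.refresh_fitness_cache()
        with pytest.raises(ExtinctionError):
            pop.step(0.0, rng)

    def test_fixed_deleterious_folded_into_w_fix(self, rng):
        pop = Population(10, FitnessScheme(), NO_MUT)
        pop.seed_mutation(
            {"mclass": MutationClass.DELETERIOUS, "s": 0.1, "h": 0.5},
            list(range(1, 20)),
            rng,
        )
        for _ in range(200):
            pop.step(0.0, rng)
            if not pop.sel.active.any():
                break
        if pop.fixed_log and pop.fixed_log[-1][2] == "fixed":
            assert pop.w_fix == pytest.approx(0.9)
            assert pop.mean_fitness() == pytest.approx(0.9)


class TestKernelFallbacks:
    def test_numpy_fallbacks_match_accelerated_kernels(self, rng):
        """The pure-numpy kernel fallbacks compute exactly what the
        compiled word-wise paths compute (given zero-weight empty bytes)."""
        from odload import _kernels

        M, nb = 40, 16
        H = rng.integers(0, 256, size=(30, nb), dtype=np.uint8)
        H[:, 5] = 0  # a fully empty byte column
        parents = rng.integers(0, 15, size=M)
        masks = rng.integers(0, 256, size=(M, nb), dtype=np.uint8)
        g_fast = _kernels.gamete_batch(H, parents, masks)
        g_ref = _kernels._gamete_batch_numpy(H, parents, masks)
        assert np.array_equal(g_fast, g_ref)

        assert np.array_equal(
            _kernels.popcount_columns(H), _kernels._popcount_columns_numpy(H)
        )

        # lookup tables built from per-locus weights have lut[:, 0] == 0,
        # which the zero-skip in the compiled path relies on
        w = rng.normal(size=nb * 8).astype(np.float64)
        from odload.population_engine import _BITS

        lut = np.ascontiguousarray((_BITS @ w.reshape(nb, 8).astype(np.float32).T).T)
        g1 = rng.integers(0, 256, size=(M, nb), dtype=np.uint8)
        g2 = rng.integers(0, 256, size=(M, nb), dtype=np.uint8)
        s_fast = _kernels.score_pairs(g1, g2, lut, lut)
        s_ref = _kernels._score_pairs_numpy(g1, g2, lut, lut)
        assert np.allclose(s_fast, s_ref, atol=1e-4)
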