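import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def seeded_population(
    n,
    scheme=None,
    *,
    sel_loci=(),
    neutral_loci=0,
    neutral_q=0.5,
    seed=0,
    dfe=None,
):
    """Build a population with explicit segregating loci (no mutation influx).

    ``sel_loci`` is a sequence of (record_kwargs, q) pairs; carriers are
    assigned by Bernoulli(q) per haplotype, redrawn until segregating.
    """
    from odload.mutation_model import DFEConfig, FitnessScheme, MutationClass
    from odload.population_engine import Population

    scheme = scheme or FitnessScheme()
    dfe = dfe or DFEConfig(U=0, U_let=0, U_o=0, U_n=0)
    pop = Population(n, scheme, dfe)
    gen = np.random.default_rng(seed)
    for args, q in sel_loci:
        rows = _segregating_rows(gen, 2 * n, q)
        pop.seed_mutation(args, rows, gen)
    for _ in range(neutral_loci):
        rows = _segregating_rows(gen, 2 * n, neutral_q)
        pop.seed_mutation({"mclass": MutationClass.NEUTRAL}, rows, gen)
    pop.refresh_fitness_cache()
    return pop


def _segregating_rows(gen, n_hap, q):
    while True:
        rows = np.nonzero(gen.random(n_hap) < q)[0]
        if 0 < rows.size < n_hap:
            return rows
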