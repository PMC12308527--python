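# Methods

`odload` is a forward-time, individual-based Wright–Fisher simulator built to
study how the inbreeding load *B* carried by a finite population — and the
inbreeding depression it causes — behaves when the load comes from partially
recessive deleterious mutations (the dominance model), from heterozygote
advantage (overdominance), or from both at once. This note documents the
model, the numerical design, the parameter defaults and what they were
calibrated against, and the limits of what the simulations show.

## Population model

A population is `n` diploid individuals with non-overlapping generations.
Each generation:

1. **Parent choice.** With probability `S` an offspring is produced by
   self-fertilization of a single parent; otherwise two distinct parents are
   drawn. Under the *viability* trait parents are drawn uniformly; under the
   *fecundity* trait they are drawn with probability proportional to their
   fitness.
2. **Meiosis.** Each parent contributes one gamete. Under free recombination
   every heterozygous site transmits independently with probability 1/2.
   Under the mapped mode a single chromosome of `total_length` Morgans
   receives Poisson(`total_length`) crossovers at uniform positions with no
   interference.
3. **Mutation.** New mutations arrive per gamete at Poisson rates per
   haploid genome: deleterious (`U`), lethal/sterile (`U_let`),
   overdominant (`U_o`) and neutral markers (`U_n`). Sites are
   infinite-sites and non-recurrent: every mutation is a new locus with a
   permanent integer id.
4. **Selection.** Fitness is multiplicative over loci with the single-locus
   factors

   | model | AA | Aa | aa |
   |---|---|---|---|
   | dominance | 1 | 1 − *sh* | 1 − *s* |
   | classical overdominance | 1 − *s₀* | 1 | 1 − *s₀* |
   | classical asymmetric | 1 − *s*₍A₀₎ | 1 | 1 − *s*₍a₀₎ |
   | alternative overdominance | 1 | 1 + *s₀* | 1 |

   Viability is a survival probability and is capped at one per individual.
   Under viability selection, candidate offspring are accepted by rejection
   sampling with probability proportional to viability until `n` survivors
   exist; only relative viabilities determine survivor composition at fixed
   census size, which is why rejection against the candidate-batch maximum
   is exact (up to an O(1/batch) edge effect from the batch maximum itself
   being random; batches are thousands of candidates). Under fecundity
   selection all offspring survive and selection acts through parent
   sampling. A generation in which no viable offspring can be formed (or
   fewer than two fertile parents exist when outcrossing is required) is an
   extinction event: the replicate stops and is recorded as failed.

   New mutations enter the offspring *after* the survival lottery of their
   birth generation; they first experience selection as parents/zygotes one
   generation later. At the mutation rates used this one-generation
   deferral is negligible against the multi-thousand-generation balance.

**Classical-overdominance bookkeeping.** Once an overdominant mutation
exists, the locus penalizes every homozygote — including individuals
carrying zero copies, whose factor is 1 − *s₀*. When such a locus loses
polymorphism (either allele fixes), the surviving homozygote's factor
becomes a permanent fitness deficit: it is pruned from genotypes, counted in
`n_o_fixed` and folded into the fixed-fitness accumulator, exactly as the
maximum-attainable-fitness accounting requires
(`W_max = W_fix (1 − s₀)^n_o_fixed` in the symmetric case; the
surviving-allele factor is used in the asymmetric case). Fixed deleterious
mutations are likewise pruned into `W_fix`. At **line foundation** the
accounting restarts: loci monomorphic among the founders (including
overdominant loci fixed in the base population, which would otherwise drag
every fitness toward zero) leave the model, and `W_fix`, `n_o_fixed` reset.
Within a long base-population burn-in the reported mean fitness therefore
only has an absolute meaning for the dominance-only model; for classical
overdominance it is meaningful relative to the accumulated fixed-OD
background, which is the same convention the line-foundation reset encodes.

## Load statistics

* **Inbreeding load** `B = Σ 2 d p q` over segregating selective loci, in
  lethal equivalents, partitioned into deleterious (*s* < 0.9),
  lethal/sterile (*s* ≥ 0.9) and overdominant parts. The dominance
  deviation is `d = s(1/2 − h)` for deleterious alleles (the printed sign
  convention is chosen so partially recessive alleles hide positive load),
  `d = s₀` for a classical symmetric overdominant locus,
  `d = (s_hom_wild + s_hom_mut)/2` asymmetric, and `d = s₀/(1+s₀)` under
  the alternative scaling. A symmetric overdominant locus at q = 1/2
  contributes exactly `s₀/2`.
* **Expressed load** `L = (W_max − W)/W_max` with `W_max` the best genotype
  constructible from present alleles (see above; for the alternative
  viability model `W_max = min(1, W_fix (1+s₀)^{n_o})`).
* **Inbreeding depression.** A selfing assay produces one selfed progeny
  per individual and one outbred progeny for each of `n_pairs` random
  distinct parent pairs. Progeny fitness is the deterministic genotypic
  fitness (meiosis is random; no survival lottery), so `W_o` and `W_s`
  estimate expectations with reduced noise. `δ = ln(W_o/W_s)` and the rate
  estimate `δ* = δ/(F̂_s − F̂_o)` uses the marker-based inbreeding
  coefficient (the per-locus genotype quadratic standardized by minor-allele
  frequency, averaged over segregating neutral loci). Reference
  minor-allele frequencies come from the assayed (parent) population;
  monomorphic loci are excluded, and δ* is reported undefined when
  F̂_s ≤ F̂_o.

## Mutational parameters and calibration

Rates are per haploid genome per generation. `U = 0.2` for deleterious
mutations, with lethals treated as a separate class at `U_let` (so `U`
excludes lethals). Overdominant levels used in the experiments:
`U_o = 5×10⁻⁵` with `s₀ = 0.02` or `0.04`, `U_o = 10⁻⁴` with `s₀ = 0.04`,
and `U_o = 10⁻⁵` with `s₀ = 0.2`; an asymmetric variant uses
`s_A₀ = 0.04, s_a₀ = 0.02`.

The distribution of deleterious effects is not uniquely determined by the
study design, so the package ships a calibrated default:

* `s ~ Gamma(shape 0.3, mean 0.2)` clipped to (0, 1] (the clipped upper
  tail yields a small supply of nearly recessive semi-lethals);
* `h | s ~ Uniform(0, exp(−6 s))` — mutations of tiny effect are additive
  on average, severe ones nearly recessive;
* lethals at `U_let = 0.018` with `s = 1`, `h = 0.058`.

These four numbers (shape, mean-decay pairing, lethal rate, lethal
dominance) were calibrated so that an `n = 1000` random-mating population
at mutation–selection–drift balance, sampled by 50-individual founder
groups, reproduces the reference base-population state: total
`B ≈ 2.3–2.4` split roughly 60/40 between deleterious and lethal classes,
≈1500 segregating deleterious mutations at mean frequency ≈0.09, ≈70
segregating lethals at mean frequency ≈0.01, and mean viability ≈0.69.
They are calibration values, not externally measured rates; the
configuration accepts any other DFE.

## Analytic references

Closed forms used as oracles and expected-value overlays: equilibrium
inbreeding `F = S/(2−S)` and selfed-progeny inbreeding `F_s = 1/(2−S)`;
purging-free prediction `W_i = W_o e^{−B F_i}`; expected depression of
selfed progeny `δ = B/(2−S)`; expected overdominant load
`B_o = n_o s₀/2`; the stability condition `F < s_A/s_a` for asymmetric
overdominant polymorphism under inbreeding. Two brute-force references
validate the engine: an exact Markov chain on genotype counts
(n_AA, n_Aa, n_aa) for one locus — genotype counts, not allele counts,
because selfing breaks Hardy–Weinberg — whose transition law enumerates the
engine's own offspring-sampling scheme; and the deterministic
infinite-population genotype-frequency recursion under partial selfing
(iterated to 10⁻¹² convergence).

## Implementation and numerics

Haplotypes are bit-packed (one bit per haplotype × locus slot). A gamete is
three bitwise operations on 64-bit words; the log-fitness of a zygote is
`const + Σ lutx[g₁⊕g₂ byte] + Σ luta[g₁∧g₂ byte]`, using per-byte lookup
tables of partial log-factor sums (fitness factors are stored as float32
log factors, accurate to ~10⁻⁷ per locus; zero-viability genotypes use a
log factor of −800, which underflows to exactly 0). Lookup tables are
cached and only byte rows whose loci changed are rebuilt. Slots of lost and
fixed mutations are recycled, and the matrix is compacted every 500
generations so per-generation cost tracks the number of segregating loci.
The inner loops have numba-compiled paths that skip zero words (the matrix
is sparse in set bits at equilibrium frequencies) and pure-numpy fallbacks
with identical semantics.

Randomness: every replicate draws from
`numpy.random.default_rng([base_seed, replicate_index])`; a run is fully
determined by its configuration and base seed, and snapshots can embed the
generator state so a restored run continues bit-identically.

## Experiment designs and problem sizes

* **Selfing sweep.** Bases of `n = 1000` evolve 10,000 generations at each
  selfing rate S ∈ {0, 0.25, 0.5, 0.75, 1}; 50-individual samples are
  assayed for B, n_o, B_o, δ and δ*. The full design uses 200 replicates;
  the packaged tests exercise reduced versions.
* **Bottleneck lines.** Lines of `n = 50` founded from an S = 0 base evolve
  250 generations of random mating with every-generation load summaries,
  aggregated at 50-generation intervals in the standard table layout.
* **Scaled-down acceptance runs** (`scripts/acceptance.py`): the burn-in
  length is kept at 10,000 generations for overdominant scenarios — the
  supply of balanced polymorphisms accumulates roughly linearly in time
  (establishment-limited at ≈ 2 s₀ · 2nU_o per generation), so shortening
  the burn-in would shrink n_o proportionally — while the dominance-only
  burn-in uses 5,000 generations (its balance is reached within a few
  thousand). Replicates are reduced from 200 to 3 burn-ins per scenario and
  10–12 lines per line experiment. Replicate means at these sizes carry
  sampling errors of a few percent, which is the tolerance regime the
  checks use.

## What the generator does and does not emulate

The synthetic populations realize the exact processes under study: drift,
partial selfing, purging, balancing selection, and mutation influx under an
idealized genome (free recombination or one 20-Morgan chromosome, no
epistasis, no environmental fitness variation, constant rates). Passing
tests show the load-accounting machinery and the population-genetic
dynamics are correct under these assumptions; they say nothing about how
well the calibrated DFE describes any real species, about linked selection
on realistic genetic maps beyond the single-chromosome mode, or about
pseudo-overdominance from linked recessives, which this model deliberately
excludes.

## Known limitations

* The classical-overdominance base population accumulates fixed-OD fitness
  deficits whose absolute size is an artefact of the infinite-sites
  bookkeeping; all line-level results are founded with the reset described
  above, matching the reference convention.
* Viability rejection against the batch maximum has an O(1/batch)
  inclusion bias (batches are ≥ a thousand candidates).
* The exact single-locus chain is limited to N ≤ 40 (state space grows
  quadratically).
* Under full selfing with the fecundity trait, a population consisting
  entirely of sterile homozygotes is reported as extinct rather than
  continuing with zero reproduction.
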