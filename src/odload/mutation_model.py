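"""Mutation classes, fitness schemes and the distribution of fitness effects.

A mutation belongs to one of four classes: partially recessive *deleterious*
mutations, recessive (or nearly so) *lethal/sterile* mutations, *overdominant*
mutations with heterozygote advantage, and *neutral* marker mutations used
only for inbreeding-coefficient estimation. Single-locus genotype fitnesses
follow the standard parameterizations

====================  =========  =====  =========
model                 AA         Aa     aa
====================  =========  =====  =========
dominance             1          1-sh   1-s
classical OD          1-s_o      1      1-s_o
classical asym. OD    1-s_Ao     1      1-s_ao
alternative OD        1          1+s_o  1
====================  =========  =====  =========

where ``a`` denotes the mutant allele. Fitness is multiplicative across loci.

The dominance deviation ``d`` (heterozygote minus mid-homozygote value) feeds
the inbreeding load B = sum(2 d p q) over segregating loci. For deleterious
alleles d = s(1/2 - h), so that fully recessive alleles (h=0) hide d = s/2 per
copy; for a symmetric overdominant locus d = s_o (classical) or
d = s_o/(1+s_o) (alternative scaling).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MutationClass",
    "ODModel",
    "Trait",
    "MutationRecord",
    "FitnessScheme",
    "DFEConfig",
    "sample_deleterious_effect",
    "sample_deleterious_effects",
    "genotype_fitness_factor",
    "dominance_deviation",
    "LETHAL_S_THRESHOLD",
]

#: reporting threshold: mutations with s >= 0.9 are tallied as lethal/sterile
LETHAL_S_THRESHOLD = 0.9


class MutationClass(enum.IntEnum):
    """Functional class of a mutation."""

    DELETERIOUS = 0
    LETHAL = 1  # lethal or sterile, depending on the fitness trait
    OVERDOMINANT = 2
    NEUTRAL = 3


class ODModel(str, enum.Enum):
    """Which overdominance parameterization applies to overdominant loci."""

    NONE = "none"
    CLASSICAL_SYMMETRIC = "classical_symmetric"
    CLASSICAL_ASYMMETRIC = "classical_asymmetric"
    ALTERNATIVE = "alternative"


class Trait(str, enum.Enum):
    """Fitness trait: survival probability or offspring number."""

    VIABILITY = "viability"
    FECUNDITY = "fecundity"


class ConfigurationError(ValueError):
    """Raised when mutation/DFE parameters are invalid."""


@dataclass(frozen=True)
class MutationRecord:
    """One mutation under the infinite-sites model.

    Parameters
    ----------
    id : int
        Unique forever within a run (sites are non-recurrent).
    mclass : MutationClass
        Functional class.
    s, h : float
        Selection and dominance coefficients (deleterious/lethal classes).
    s_hom_wild, s_hom_mut : float
        Homozygote disadvantages of an overdominant locus. Symmetric case
        ``s_hom_wild == s_hom_mut == s_o``; under the alternative model the
        common value is reinterpreted as the heterozygote advantage ``s_o``.
    position : float
        Map position in Morgans (ignored under free recombination).
    birth_gen : int
        Generation in which the mutation arose.
    """

    id: int
    mclass: MutationClass
    s: float = 0.0
    h: float = 0.0
    s_hom_wild: float = 0.0
    s_hom_mut: float = 0.0
    position: float = 0.0
    birth_gen: int = 0

    def __post_init__(self) -> None:
        if self.mclass in (MutationClass.DELETERIOUS, MutationClass.LETHAL):
            if not (0.0 < self.s <= 1.0):
                raise ConfigurationError(f"selective s must be in (0,1], got {self.s}")
            if not (0.0 <= self.h <= 1.0):
                raise ConfigurationError(f"h must be in [0,1], got {self.h}")
        elif self.mclass is MutationClass.OVERDOMINANT:
            if self.s_hom_wild <= 0.0 or self.s_hom_mut <= 0.0:
                raise ConfigurationError("overdominant homozygote disadvantages must be > 0")

    @property
    def is_lethal_class(self) -> bool:
        """Reporting classification: s >= 0.9 counts as lethal/sterile."""
        return (
            self.mclass in (MutationClass.DELETERIOUS, MutationClass.LETHAL)
            and self.s >= LETHAL_S_THRESHOLD
        )


@dataclass(frozen=True)
class FitnessScheme:
    """Which overdominance model applies, and for which fitness trait.

    ``cap_at_one`` is forced for viability (a survival probability cannot
    exceed one) and forbidden for fecundity.
    """

    od_model: ODModel = ODModel.NONE
    trait: Trait = Trait.VIABILITY
    cap_at_one: bool | None = None

    def __post_init__(self) -> None:
        expected = self.trait is Trait.VIABILITY
        if self.cap_at_one is None:
            object.__setattr__(self, "cap_at_one", expected)
        elif self.cap_at_one is not expected:
            raise ConfigurationError(
                "cap_at_one must hold exactly when trait is viability "
                f"(trait={self.trait.value}, cap_at_one={self.cap_at_one})"
            )


@dataclass(frozen=True)
class DFEConfig:
    """Mutation rates and effect distributions, per haploid genome.

    Rates
    -----
    U : deleterious rate (excludes lethals, which arise at ``U_let``).
    U_let : lethal/sterile rate; these carry ``s = lethal_s`` and ``h = h_let``.
    U_o : overdominant rate, effect ``s_o`` (or ``s_Ao``/``s_ao`` asymmetric).
    U_n : neutral marker rate.

    Deleterious effects
    -------------------
    ``s`` is gamma distributed (``s_shape``, mean ``s_mean``), clipped to
    (0, 1]; ``h`` given ``s`` is Uniform(0, exp(-h_decay * s)), so mutations of
    tiny effect are additive on average while severe ones are nearly
    recessive. ``s_dist="fixed"`` / ``h_rule="fixed"`` give point masses
    (useful for controlled experiments).

    The default shape/mean/decay values and the lethal rate are calibrated so
    that an n=1000 random-mating population at mutation-selection-drift
    balance carries B ~= 2.34 lethal equivalents split between ~1500
    deleterious (mean q ~= 0.09) and ~70 lethal (mean q ~= 0.01) segregating
    mutations, with mean viability ~= 0.69; they are calibration values, not
    externally measured rates.
    """

    U: float = 0.2
    U_let: float = 0.018  # calibrated (see class docstring)
    U_o: float = 0.0
    U_n: float = 1.0
    s_dist: str = "gamma"
    s_mean: float = 0.2  # calibrated
    s_shape: float = 0.3  # calibrated
    h_rule: str = "uniform_exp"
    h_decay: float = 6.0  # calibrated
    h_fixed: float = 0.25
    lethal_s: float = 1.0
    h_let: float = 0.058  # calibrated
    s_o: float = 0.0
    s_Ao: float | None = None
    s_ao: float | None = None

    def __post_init__(self) -> None:
        for name in ("U", "U_let", "U_o", "U_n"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"mutation rate {name} must be >= 0")
        if self.s_dist not in ("gamma", "fixed"):
            raise ConfigurationError(f"unknown s_dist {self.s_dist!r}")
        if self.h_rule not in ("uniform_exp", "fixed"):
            raise ConfigurationError(f"unknown h_rule {self.h_rule!r}")
        if self.s_dist == "gamma" and (self.s_mean <= 0 or self.s_shape <= 0):
            raise ConfigurationError("gamma DFE needs s_mean > 0 and s_shape > 0")
        if self.s_dist == "fixed" and not (0.0 < self.s_mean <= 1.0):
            raise ConfigurationError("fixed s must be in (0,1]")
        if not (0.0 < self.lethal_s <= 1.0):
            raise ConfigurationError("lethal_s must be in (0,1]")
        if not (0.0 <= self.h_let <= 1.0):
            raise ConfigurationError("h_let must be in [0,1]")
        if self.h_rule == "fixed" and not (0.0 <= self.h_fixed <= 1.0):
            raise ConfigurationError("fixed h must be in [0,1]")
        if self.U_o > 0 and self.s_o <= 0 and self.s_Ao is None:
            raise ConfigurationError("U_o > 0 requires s_o (or s_Ao/s_ao)")
        if (self.s_Ao is None) != (self.s_ao is None):
            raise ConfigurationError("asymmetric OD needs both s_Ao and s_ao")

    @property
    def od_hom_disadvantages(self) -> tuple[float, float]:
        """(s_hom_wild, s_hom_mut) applied to new overdominant mutations."""
        if self.s_Ao is not None:
            return (float(self.s_Ao), float(self.s_ao))
        return (float(self.s_o), float(self.s_o))


def sample_deleterious_effects(
    rng: np.random.Generator, dfe: DFEConfig, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of ``size`` deleterious (s, h) pairs from the DFE."""
    if dfe.s_dist == "gamma":
        s = rng.gamma(dfe.s_shape, dfe.s_mean / dfe.s_shape, size=size)
        # clip into (0, 1]: the rare upper-tail mass becomes lethal-class
        np.clip(s, 1e-8, 1.0, out=s)
    else:
        s = np.full(size, dfe.s_mean)
    if dfe.h_rule == "uniform_exp":
        h = rng.uniform(0.0, 1.0, size=size) * np.exp(-dfe.h_decay * s)
    else:
        h = np.full(size, dfe.h_fixed)
    return s, h


def sample_deleterious_effect(rng: np.random.Generator, dfe: DFEConfig) -> tuple[float, float]:
    """Draw one deleterious (s, h) pair.

    Lethal/sterile mutations are not drawn here; they arise separately at rate
    ``U_let`` with ``s = lethal_s`` and ``h = h_let``.
    """
    s, h = sample_deleterious_effects(rng, dfe, 1)
    return float(s[0]), float(h[0])


def genotype_fitness_factor(m: MutationRecord, copies: int, scheme: FitnessScheme) -> float:
    """Multiplicative fitness factor of one locus given mutant-copy number.

    Under the classical overdominance models the wild-type homozygote
    (``copies == 0``) has fitness ``1 - s_hom_wild``: once an overdominant
    mutation has arisen, the locus penalizes every homozygote in the
    population.
    """
    if copies not in (0, 1, 2):
        raise ValueError(f"copies must be 0, 1 or 2, got {copies}")
    if m.mclass is MutationClass.NEUTRAL:
        return 1.0
    if m.mclass in (MutationClass.DELETERIOUS, MutationClass.LETHAL):
        return (1.0, 1.0 - m.s * m.h, 1.0 - m.s)[copies]
    # overdominant
    if scheme.od_model is ODModel.ALTERNATIVE:
        return (1.0, 1.0 + m.s_hom_wild, 1.0)[copies]
    if scheme.od_model in (ODModel.CLASSICAL_SYMMETRIC, ODModel.CLASSICAL_ASYMMETRIC):
        return (1.0 - m.s_hom_wild, 1.0, 1.0 - m.s_hom_mut)[copies]
    raise ConfigurationError("overdominant mutation under a scheme with od_model='none'")


def dominance_deviation(m: MutationRecord, scheme: FitnessScheme) -> float:
    """Dominance deviation d entering B = sum(2 d p q).

    Deleterious/lethal: d = s(1/2 - h), positive for partially recessive
    alleles. Classical symmetric overdominance: d = s_o; classical asymmetric:
    d = (s_hom_wild + s_hom_mut)/2; alternative: d = s_o / (1 + s_o) (the
    same locus rescaled so the heterozygote has fitness one).
    """
    if m.mclass is MutationClass.NEUTRAL:
        raise ValueError("dominance deviation undefined for neutral mutations")
    if m.mclass in (MutationClass.DELETERIOUS, MutationClass.LETHAL):
        return m.s * (0.5 - m.h)
    if scheme.od_model is ODModel.ALTERNATIVE:
        return m.s_hom_wild / (1.0 + m.s_hom_wild)
    if scheme.od_model in (ODModel.CLASSICAL_SYMMETRIC, ODModel.CLASSICAL_ASYMMETRIC):
        return 0.5 * (m.s_hom_wild + m.s_hom_mut)
    raise ConfigurationError("overdominant mutation under a scheme with od_model='none'")
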