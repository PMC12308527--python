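"""Inbreeding load, expressed load and inbreeding-depression statistics.

The inbreeding load is B = sum over segregating selective loci of 2 d p q,
in lethal equivalents, with d the dominance deviation of the locus; it is
partitioned into a deleterious part (s < 0.9), a lethal/sterile part
(s >= 0.9) and an overdominant part. The expressed load is
L = (W_max - W) / W_max, where W_max is the fitness of the best genotype
constructible from the alleles present (accounting for deleterious mutations
fixed in the line and overdominant loci that lost polymorphism). Marker-based
inbreeding coefficients use the single-locus genotype estimator of Yang and
colleagues, averaged over segregating neutral loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from odload.mutation_model import (
    LETHAL_S_THRESHOLD,
    FitnessScheme,
    MutationClass,
    ODModel,
)
from odload.population_engine import Population

__all__ = [
    "LoadSummary",
    "SelfingAssayResult",
    "inbreeding_load",
    "max_fitness",
    "expressed_load",
    "yang_inbreeding",
    "depression_stats",
    "summarize",
    "SUMMARY_COLUMNS",
]

#: column order of the per-generation summary table
SUMMARY_COLUMNS = (
    "t",
    "n_del",
    "q_del",
    "B_del",
    "n_let",
    "q_let",
    "B_let",
    "n_o",
    "q_o",
    "B_o",
    "dW_pct",
)


@dataclass(frozen=True)
class LoadSummary:
    """One per-generation row of the load-accounting table."""

    t: int
    W: float
    W_max: float
    L: float
    B: float
    B_del: float
    B_let: float
    B_o: float
    n_del: int
    n_let: int
    n_o: int
    q_del: float
    q_let: float
    q_o: float
    n_o_fixed: int
    dW_pct: float


@dataclass(frozen=True)
class SelfingAssayResult:
    """Outbred/selfed progeny fitness and derived depression statistics.

    ``delta = ln(W_o / W_s)``; the rate-of-depression estimate
    ``delta_star = delta / (F_s - F_o)`` approximates the inbreeding load B
    and is undefined (NaN, ``delta_star_defined=False``) when the marker-based
    inbreeding of selfed progeny does not exceed that of outbred progeny.
    """

    W_o: float
    W_s: float
    delta: float
    delta_star: float
    F_hat_s: float
    F_hat_o: float
    delta_star_defined: bool = True


def _per_locus_d(blk, slots: np.ndarray, scheme: FitnessScheme) -> np.ndarray:
    """Vectorized dominance deviations for active selective slots."""
    d = np.zeros(slots.size)
    mc = blk.mclass[slots]
    sel = (mc == MutationClass.DELETERIOUS) | (mc == MutationClass.LETHAL)
    d[sel] = blk.s[slots[sel]] * (0.5 - blk.h[slots[sel]])
    od = mc == MutationClass.OVERDOMINANT
    if np.any(od):
        if scheme.od_model is ODModel.ALTERNATIVE:
            so = blk.shw[slots[od]]
            d[od] = so / (1.0 + so)
        else:
            d[od] = 0.5 * (blk.shw[slots[od]] + blk.shm[slots[od]])
    return d


def _class_partition(blk, slots: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(deleterious, lethal, overdominant) boolean masks by reporting class."""
    mc = blk.mclass[slots]
    selective = (mc == MutationClass.DELETERIOUS) | (mc == MutationClass.LETHAL)
    lethal = selective & (blk.s[slots] >= LETHAL_S_THRESHOLD)
    deleterious = selective & ~lethal
    od = mc == MutationClass.OVERDOMINANT
    return deleterious, lethal, od


def inbreeding_load(
    pop: Population, scheme: FitnessScheme | None = None
) -> tuple[float, float, float, float]:
    """(B, B_del, B_let, B_o): B = sum 2 d p q over segregating selective loci.

    Partitioned into deleterious (s < 0.9), lethal/sterile (s >= 0.9) and
    overdominant contributions; fixed loci contribute nothing.
    """
    scheme = scheme or pop.scheme
    blk = pop.sel
    slots = np.nonzero(blk.active)[0]
    if slots.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    q = blk.count[slots] / (2.0 * pop.n)
    d = _per_locus_d(blk, slots, scheme)
    contrib = 2.0 * d * q * (1.0 - q)
    m_del, m_let, m_od = _class_partition(blk, slots)
    b_del = float(contrib[m_del].sum())
    b_let = float(contrib[m_let].sum())
    b_o = float(contrib[m_od].sum())
    return b_del + b_let + b_o, b_del, b_let, b_o


def max_fitness(pop: Population, scheme: FitnessScheme | None = None) -> float:
    """Fitness of the best genotype constructible from present alleles.

    Classical models: ``W_fix`` times the surviving-homozygote factor of each
    overdominant locus that lost polymorphism (``(1-s_o)^n_o_fixed`` in the
    symmetric case). Alternative model: ``W_fix (1+s_o)^n_o`` over segregating
    overdominant loci, capped at one for viability. Dominance-only: ``W_fix``.
    """
    scheme = scheme or pop.scheme
    if scheme.od_model is ODModel.ALTERNATIVE:
        blk = pop.sel
        slots = np.nonzero(blk.active & (blk.mclass == MutationClass.OVERDOMINANT))[0]
        wmax = pop.w_fix * float(np.prod(1.0 + blk.shw[slots])) if slots.size else pop.w_fix
        if scheme.cap_at_one:
            wmax = min(wmax, 1.0)
        return wmax
    return pop.w_fix * pop.od_fix_factor


def expressed_load(W: float, W_max: float) -> float:
    """L = (W_max - W) / W_max."""
    if W_max <= 0:
        raise ValueError(f"W_max must be > 0, got {W_max}")
    return (W_max - W) / W_max


def yang_inbreeding(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Marker-based inbreeding coefficient F-hat per individual.

    Parameters
    ----------
    x : (n_individuals, L) minor-allele copy counts in {0, 1, 2}.
    p : (L,) minor-allele frequencies of the reference sample, all in (0, 1).

    Returns
    -------
    (n_individuals,) array: mean over loci of
    ``(x^2 - (1+2p) x + 2 p^2) / (2 p (1-p))``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("at least one polymorphic locus is required")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic loci must be filtered out before estimating F")
    num = x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p
    return (num / (2.0 * p * (1.0 - p))).mean(axis=1)


def depression_stats(
    W_o: float, W_s: float, F_hat_s: float, F_hat_o: float
) -> SelfingAssayResult:
    """Inbreeding depression of selfed progeny and its rate.

    delta = ln(W_o/W_s); delta* = delta / (F_s - F_o) estimates the
    inbreeding load B.
    """
    if W_o <= 0 or W_s <= 0:
        raise ValueError("mean progeny fitness must be positive to take logs")
    delta = math.log(W_o / W_s)
    dF = F_hat_s - F_hat_o
    if dF > 0:
        return SelfingAssayResult(W_o, W_s, delta, delta / dF, F_hat_s, F_hat_o, True)
    return SelfingAssayResult(W_o, W_s, delta, float("nan"), F_hat_s, F_hat_o, False)


def summarize(pop: Population, scheme: FitnessScheme | None = None, W0: float | None = None) -> LoadSummary:
    """One row of the trajectory table for the population's current state."""
    scheme = scheme or pop.scheme
    blk = pop.sel
    slots = np.nonzero(blk.active)[0]
    q = blk.count[slots] / (2.0 * pop.n) if slots.size else np.empty(0)
    m_del, m_let, m_od = (
        _class_partition(blk, slots) if slots.size else (np.empty(0, bool),) * 3
    )
    B, B_del, B_let, B_o = inbreeding_load(pop, scheme)
    W = pop.mean_fitness()
    Wmax = max_fitness(pop, scheme)
    L = expressed_load(W, Wmax) if Wmax > 0 else float("nan")
    if W0 is None:
        dw = 0.0
    else:
        dw = 100.0 * (W0 - W) / W0
    mean_q = lambda m: float(q[m].mean()) if np.any(m) else float("nan")
    return LoadSummary(
        t=pop.t,
        W=W,
        W_max=Wmax,
        L=L,
        B=B,
        B_del=B_del,
        B_let=B_let,
        B_o=B_o,
        n_del=int(m_del.sum()),
        n_let=int(m_let.sum()),
        n_o=int(m_od.sum()),
        q_del=mean_q(m_del),
        q_let=mean_q(m_let),
        q_o=mean_q(m_od),
        n_o_fixed=pop.n_o_fixed,
        dW_pct=dw,
    )
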