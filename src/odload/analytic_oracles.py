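"""Closed-form and exact brute-force references for the simulator.

These are the quantities the simulation results are checked against: the
equilibrium inbreeding coefficient under partial selfing, the predicted
fitness of inbred individuals ``W_i = W_o exp(-B F_i)``, the expected
overdominant load ``B_o = n_o s_o / 2``, the stability condition for
asymmetric overdominant polymorphisms under inbreeding, an exact single-locus
Markov chain over genotype counts (used to validate the reproduction engine
on tiny populations), and the deterministic infinite-population
genotype-frequency recursion under partial selfing and selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelfingEquilibrium",
    "equilibrium_F",
    "expected_selfed_depression",
    "predicted_inbred_fitness",
    "expected_Bo",
    "asym_polymorphism_stable",
    "SingleLocusChain",
    "single_locus_chain",
    "deterministic_selfing_recursion",
]

# offspring genotype distribution from selfing one parent, rows AA, Aa, aa
_SELF_TABLE = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.25, 0.5, 0.25],
        [0.0, 0.0, 1.0],
    ]
)
# probability that a gamete from each genotype carries the mutant allele a
_GAMETE_A = np.array([0.0, 0.5, 1.0])


def equilibrium_F(S: float) -> float:
    """Equilibrium inbreeding coefficient F = S / (2 - S) under selfing rate S."""
    if not (0.0 <= S <= 1.0):
        raise ValueError(f"selfing rate must be in [0,1], got {S}")
    return S / (2.0 - S)


@dataclass(frozen=True)
class SelfingEquilibrium:
    """Equilibrium inbreeding under a constant selfing rate.

    F = S/(2-S) is the population's inbreeding coefficient and
    F_s = (1+F)/2 = 1/(2-S) the inbreeding of selfed progeny.
    """

    S: float
    F: float
    F_s: float

    @classmethod
    def from_selfing_rate(cls, S: float) -> "SelfingEquilibrium":
        F = equilibrium_F(S)
        return cls(S=S, F=F, F_s=0.5 * (1.0 + F))


def expected_selfed_depression(B: float, S: float) -> float:
    """Expected inbreeding depression of selfed progeny: delta = B / (2 - S)."""
    if B < 0:
        raise ValueError("inbreeding load B must be >= 0")
    if not (0.0 <= S <= 1.0):
        raise ValueError(f"selfing rate must be in [0,1], got {S}")
    return B / (2.0 - S)


def predicted_inbred_fitness(W_o: float, B: float, F_i: float) -> float:
    """Purging-free prediction W_i = W_o exp(-B F_i)."""
    if W_o <= 0:
        raise ValueError("outbred fitness must be positive")
    if not (0.0 <= F_i <= 1.0):
        raise ValueError(f"inbreeding coefficient must be in [0,1], got {F_i}")
    return W_o * math.exp(-B * F_i)


def expected_Bo(n_o: float, s_o: float) -> float:
    """Expected overdominant load of n_o symmetric loci: B_o = n_o s_o / 2."""
    if n_o < 0:
        raise ValueError("number of overdominant loci must be >= 0")
    return n_o * s_o / 2.0


def asym_polymorphism_stable(F: float, s_A: float, s_a: float) -> bool:
    """Stability of an asymmetric overdominant polymorphism under inbreeding.

    With homozygote disadvantages s_A < s_a, the polymorphism is stable iff
    the inbreeding coefficient satisfies F < s_A / s_a.
    """
    if not (0.0 < s_A < s_a):
        raise ValueError("requires 0 < s_A < s_a")
    return F < s_A / s_a


@dataclass
class SingleLocusChain:
    """Exact Markov chain over genotype counts (n_AA, n_Aa, n_aa) for one locus.

    Genotype counts (not allele counts) are the state, which is exact under
    selfing. Transitions enumerate the engine's offspring-sampling scheme:
    with probability S a uniformly drawn (viability trait) or fitness-weighted
    (fecundity trait) parent is selfed, otherwise two distinct parents are
    drawn; viability selection reweights the offspring-genotype mixture by
    genotype fitness. The next state is multinomial in the resulting
    offspring distribution.
    """

    N: int
    states: list[tuple[int, int, int]]
    index: dict[tuple[int, int, int], int]
    P: np.ndarray
    absorbing: np.ndarray  # per-state: 0 transient, 1 a lost, 2 a fixed, 3 extinct

    def fixation_probability(self, state: tuple[int, int, int]) -> float:
        """Probability that the mutant allele a reaches fixation (all aa)."""
        return float(self._absorption_probs()[self.index[state], 1])

    def loss_probability(self, state: tuple[int, int, int]) -> float:
        return float(self._absorption_probs()[self.index[state], 0])

    def mean_absorption_time(self, state: tuple[int, int, int]) -> float:
        """Expected generations until the polymorphism is lost either way."""
        trans = np.nonzero(self.absorbing == 0)[0]
        if self.index[state] not in set(trans):
            return 0.0
        Q = self.P[np.ix_(trans, trans)]
        t = np.linalg.solve(np.eye(trans.size) - Q, np.ones(trans.size))
        return float(t[list(trans).index(self.index[state])])

    def _absorption_probs(self) -> np.ndarray:
        trans = np.nonzero(self.absorbing == 0)[0]
        out = np.zeros((len(self.states), 3))
        for code in (1, 2, 3):
            out[self.absorbing == code, code - 1] = 1.0
        if trans.size:
            Q = self.P[np.ix_(trans, trans)]
            R = np.zeros((trans.size, 3))
            for col, code in enumerate((1, 2, 3)):
                targets = np.nonzero(self.absorbing == code)[0]
                if targets.size:
                    R[:, col] = self.P[np.ix_(trans, targets)].sum(axis=1)
            sol = np.linalg.solve(np.eye(trans.size) - Q, R)
            out[trans] = sol
        return out


def _offspring_distribution(
    counts: tuple[int, int, int],
    w: np.ndarray,
    S: float,
    trait: str,
) -> np.ndarray | None:
    """Post-selection offspring genotype distribution, or None if extinct."""
    N = sum(counts)
    n = np.array(counts, dtype=float)
    if trait == "viability":
        parent1 = n / N
        # ordered distinct pair (g1, g2): uniform draws without replacement
        pair = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if n[i] == 0 or (n[j] - (i == j)) <= 0:
                    continue
                pair[i, j] = (n[i] / N) * ((n[j] - (i == j)) / (N - 1))
        psi = _mix_offspring(parent1, pair, S)
        if psi is None:
            return None
        psi = psi * w
        total = psi.sum()
        if total <= 0:
            return None
        return psi / total
    # fecundity: parents drawn proportionally to fitness, offspring all survive
    weight = n * w
    W_tot = weight.sum()
    if W_tot <= 0:
        return None
    parent1 = weight / W_tot
    pair = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            if n[i] == 0 or (n[j] - (i == j)) <= 0:
                continue
            denom = W_tot - w[i]
            if denom <= 0:
                continue
            pair[i, j] = (n[i] * w[i] / W_tot) * ((n[j] - (i == j)) * w[j] / denom)
    psi = _mix_offspring(parent1, pair, S)
    if psi is None:
        return None
    total = psi.sum()
    if total <= 0:
        return None
    return psi / total


def _mix_offspring(parent1: np.ndarray, pair: np.ndarray, S: float) -> np.ndarray | None:
    psi_self = parent1 @ _SELF_TABLE
    pa = _GAMETE_A  # per-genotype gamete mutant-allele probability
    psi_out = np.zeros(3)
    for i in range(3):
        for j in range(3):
            if pair[i, j] == 0:
                continue
            qa1, qa2 = pa[i], pa[j]
            psi_out[0] += pair[i, j] * (1 - qa1) * (1 - qa2)
            psi_out[1] += pair[i, j] * ((1 - qa1) * qa2 + qa1 * (1 - qa2))
            psi_out[2] += pair[i, j] * qa1 * qa2
    out_total = pair.sum()
    if out_total > 0:
        return S * psi_self + (1.0 - S) * psi_out / out_total
    if S == 1.0:
        return psi_self
    return None  # outcrossing required but no valid parent pair exists


def single_locus_chain(
    N: int,
    fitnesses: tuple[float, float, float],
    S: float = 0.0,
    trait: str = "viability",
) -> SingleLocusChain:
    """Build the exact genotype-count Markov chain for one locus.

    Parameters
    ----------
    N : population size (kept small; the state space has ~N^2/2 states).
    fitnesses : (w_AA, w_Aa, w_aa) genotype fitnesses.
    S : selfing rate.
    trait : "viability" or "fecundity".
    """
    if N > 40:
        raise ValueError(
            "state space grows as N^2; use N <= 40 (larger sizes belong to simulation)"
        )
    if trait not in ("viability", "fecundity"):
        raise ValueError(f"trait must be 'viability' or 'fecundity', got {trait!r}")
    w = np.asarray(fitnesses, dtype=float)
    states = [
        (a, b, N - a - b) for a in range(N + 1) for b in range(N + 1 - a)
    ]
    index = {s: i for i, s in enumerate(states)}
    P = np.zeros((len(states), len(states)))
    absorbing = np.zeros(len(states), dtype=np.int8)
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, N + 1)))])
    for i, st in enumerate(states):
        if st[1] == 0 and st[2] == 0:
            absorbing[i] = 1  # mutant allele lost
            P[i, i] = 1.0
            continue
        if st[0] == 0 and st[1] == 0:
            absorbing[i] = 2  # mutant allele fixed
            P[i, i] = 1.0
            continue
        psi = _offspring_distribution(st, w, S, trait)
        if psi is None:
            absorbing[i] = 3  # extinction: no viable/fertile offspring
            P[i, i] = 1.0
            continue
        logpsi = np.where(psi > 0, np.log(np.maximum(psi, 1e-300)), -np.inf)
        for j, st2 in enumerate(states):
            if any(c > 0 and psi[k] == 0 for k, c in enumerate(st2)):
                continue
            logp = log_fact[N] - sum(log_fact[c] for c in st2)
            logp += sum(c * logpsi[k] for k, c in enumerate(st2) if c > 0)
            P[i, j] = math.exp(logp)
    return SingleLocusChain(N=N, states=states, index=index, P=P, absorbing=absorbing)


def deterministic_selfing_recursion(
    fitnesses: tuple[float, float, float],
    S: float,
    q0: float = 0.5,
    F0: float | None = None,
    tol: float = 1e-12,
    max_iter: int = 2_000_000,
) -> tuple[float, float, float]:
    """Infinite-population genotype frequencies under selfing and selection.

    Starts from inbreeding coefficient ``F0`` (default: the equilibrium
    F = S/(2-S)) at mutant frequency ``q0`` and iterates
    selection -> (selfed + outcrossed) reproduction until genotype
    frequencies change by less than ``tol``.

    Returns (x_AA, x_Aa, x_aa).
    """
    if not (0.0 <= S <= 1.0):
        raise ValueError(f"selfing rate must be in [0,1], got {S}")
    if not (0.0 <= q0 <= 1.0):
        raise ValueError(f"initial frequency must be in [0,1], got {q0}")
    w = np.asarray(fitnesses, dtype=float)
    F = equilibrium_F(S) if F0 is None else F0
    p = 1.0 - q0
    x = np.array(
        [
            p * p * (1 - F) + p * F,
            2 * p * q0 * (1 - F),
            q0 * q0 * (1 - F) + q0 * F,
        ]
    )
    for _ in range(max_iter):
        xw = x * w
        mean_w = xw.sum()
        if mean_w <= 0:
            raise RuntimeError("mean fitness reached zero in the recursion")
        xs = xw / mean_w
        qa = xs[2] + 0.5 * xs[1]
        outcross = np.array([(1 - qa) ** 2, 2 * qa * (1 - qa), qa * qa])
        x_new = S * (xs @ _SELF_TABLE) + (1 - S) * outcross
        if np.max(np.abs(x_new - x)) < tol:
            return tuple(float(v) for v in x_new)
        x = x_new
    raise RuntimeError(f"recursion did not converge within {max_iter} iterations")
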