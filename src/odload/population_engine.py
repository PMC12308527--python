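"""Forward-time Wright-Fisher reproduction with partial selfing.

The population is a fixed number ``n`` of diploid individuals. Every
generation, offspring are produced by drawing parents (a single selfed parent
with probability ``S``, otherwise two distinct parents), forming one gamete
per parent by free recombination or by crossing-over on a genetic map, and
adding new mutations at Poisson rates per haploid genome. Selection acts on
viability (candidate offspring are accepted by rejection sampling in
proportion to their viability, holding census size constant) or on fecundity
(parents are drawn in proportion to their fitness and all offspring survive).

Implementation notes
--------------------
Haplotypes are stored bit-packed: one bit per (haplotype, locus slot), so a
gamete is three bitwise operations on byte arrays, and the log-fitness of a
zygote is evaluated with per-byte lookup tables (multiplicative fitness
across loci is a sum of per-locus log factors, which is linear in the allele
bits of the two gametes plus an interaction term on their AND). Loci occupy
"slots"; slots of lost or fixed mutations are recycled. Fixed selective
mutations are pruned from genotypes and folded into the fixed-fitness
accumulators, as required by the W_max accounting.

The public, record-level operations (:func:`make_gamete`,
:func:`mutate_gamete`, :func:`individual_fitness`) work on sparse
mutation-id collections and are the readable specification of what the
batched bit-level path computes; tests check the two against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from odload import _kernels
from odload.mutation_model import (
    DFEConfig,
    FitnessScheme,
    MutationClass,
    MutationRecord,
    ODModel,
    Trait,
    genotype_fitness_factor,
    sample_deleterious_effects,
)

__all__ = [
    "LOG_ZERO",
    "ExtinctionError",
    "Haplotype",
    "Individual",
    "RecombinationMap",
    "Population",
    "make_gamete",
    "mutate_gamete",
    "individual_fitness",
    "next_generation",
]

#: log-fitness assigned to zero-viability genotypes; exp(LOG_ZERO) == 0.0
LOG_ZERO = -800.0

_BITS = np.unpackbits(np.arange(256, dtype=np.uint8)[:, None], axis=1).astype(np.float32)


def _random_bytes(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Uniform random bytes drawn as 64-bit words (much faster than uint8)."""
    words = (cols + 7) // 8
    raw = rng.integers(0, 2**64, size=(rows, words), dtype=np.uint64, endpoint=False)
    return raw.view(np.uint8)[:, :cols]
_BIT_OF_SLOT = (0x80 >> np.arange(8)).astype(np.uint8)


class ExtinctionError(RuntimeError):
    """All candidate offspring are inviable (or no fertile parents remain)."""

    def __init__(self, generation: int, message: str | None = None):
        self.generation = generation
        super().__init__(message or f"population extinct at generation {generation}")


@dataclass(frozen=True)
class RecombinationMap:
    """Free recombination, or a single chromosome of ``total_length`` Morgans."""

    mode: str = "free"
    total_length: float = 20.0

    def __post_init__(self) -> None:
        if self.mode not in ("free", "mapped"):
            raise ValueError(f"recombination mode must be 'free' or 'mapped', got {self.mode!r}")
        if self.mode == "mapped" and self.total_length <= 0:
            raise ValueError("mapped genome length must be > 0 Morgans")


Haplotype = tuple  # ordered tuple of mutation ids


@dataclass
class Individual:
    """Two haplotypes (sparse mutation-id tuples) and cached fitness."""

    hap1: Haplotype
    hap2: Haplotype
    fitness: float = 1.0

    def copies(self, mut_id: int) -> int:
        return (mut_id in set(self.hap1)) + (mut_id in set(self.hap2))


class _LocusBlock:
    """Bit-packed genotype columns plus per-slot mutation metadata."""

    _FLOAT_FIELDS = ("s", "h", "shw", "shm", "pos", "lf0", "lf1", "lf2")

    def __init__(self, n_hap: int, capacity_bits: int = 256):
        # whole 64-bit words so the matrix can be walked word-wise
        capacity_bits = max(64, int(np.ceil(capacity_bits / 64)) * 64)
        self.n_hap = n_hap
        self.H = np.zeros((n_hap, capacity_bits // 8), dtype=np.uint8)
        cap = capacity_bits
        self.ids = np.full(cap, -1, dtype=np.int64)
        self.mclass = np.full(cap, -1, dtype=np.int8)
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.zeros(cap, dtype=np.float64))
        self.birth = np.zeros(cap, dtype=np.int64)
        self.active = np.zeros(cap, dtype=bool)
        self.count = np.zeros(cap, dtype=np.int64)
        self._free: list[int] = list(range(cap - 1, -1, -1))
        #: byte columns whose fitness weights changed; None = rebuild all
        self.dirty_bytes: set[int] | None = None

    @property
    def capacity(self) -> int:
        return self.ids.size

    @property
    def nbytes_row(self) -> int:
        return self.H.shape[1]

    def _grow(self, min_extra: int) -> None:
        extra = max(min_extra, self.capacity // 2, 64)
        extra = int(np.ceil(extra / 64)) * 64
        old = self.capacity
        self.H = np.hstack([self.H, np.zeros((self.n_hap, extra // 8), dtype=np.uint8)])
        self.ids = np.concatenate([self.ids, np.full(extra, -1, dtype=np.int64)])
        self.mclass = np.concatenate([self.mclass, np.full(extra, -1, dtype=np.int8)])
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.concatenate([getattr(self, name), np.zeros(extra)]))
        self.birth = np.concatenate([self.birth, np.zeros(extra, dtype=np.int64)])
        self.active = np.concatenate([self.active, np.zeros(extra, dtype=bool)])
        self.count = np.concatenate([self.count, np.zeros(extra, dtype=np.int64)])
        self._free.extend(range(old + extra - 1, old - 1, -1))
        self.dirty_bytes = None  # lookup tables must be re-sized

    def allocate(self, k: int) -> np.ndarray:
        if len(self._free) < k:
            self._grow(k - len(self._free))
        slots = np.array([self._free.pop() for _ in range(k)], dtype=np.int64)
        return slots

    def release(self, slots: np.ndarray) -> None:
        if self.dirty_bytes is not None:
            self.dirty_bytes.update(int(sl) >> 3 for sl in slots)
        self.active[slots] = False
        self.ids[slots] = -1
        self.mclass[slots] = -1
        for name in self._FLOAT_FIELDS:
            getattr(self, name)[slots] = 0.0
        self.count[slots] = 0
        self._free.extend(int(s) for s in slots)

    def set_bits(self, rows: np.ndarray, slots: np.ndarray) -> None:
        np.bitwise_or.at(self.H, (rows, slots >> 3), _BIT_OF_SLOT[slots & 7])

    def clear_columns(self, slots: np.ndarray) -> None:
        if slots.size == 0:
            return
        mask = np.zeros(self.nbytes_row, dtype=np.uint8)
        np.bitwise_or.at(mask, slots >> 3, _BIT_OF_SLOT[slots & 7])
        self.H &= ~mask[None, :]

    def popcount(self) -> np.ndarray:
        """Copy count per slot (column sums of the bit matrix)."""
        return _kernels.popcount_columns(self.H)

    def unpack_rows(self, rows: np.ndarray | slice) -> np.ndarray:
        return np.unpackbits(self.H[rows], axis=1)

    def slot_of_id(self, mut_id: int) -> int:
        hits = np.nonzero(self.active & (self.ids == mut_id))[0]
        if hits.size == 0:
            raise KeyError(f"mutation id {mut_id} is not segregating in this block")
        return int(hits[0])


def _log_factors(
    mclass: np.ndarray,
    s: np.ndarray,
    h: np.ndarray,
    shw: np.ndarray,
    shm: np.ndarray,
    scheme: FitnessScheme,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-slot log genotype factors (copies 0, 1, 2) under ``scheme``."""
    lf0 = np.zeros_like(s)
    lf1 = np.zeros_like(s)
    lf2 = np.zeros_like(s)
    selc = (mclass == MutationClass.DELETERIOUS) | (mclass == MutationClass.LETHAL)
    with np.errstate(divide="ignore"):
        lf1[selc] = np.log1p(-s[selc] * h[selc])
        lf2[selc] = np.log1p(-s[selc])
    lf1[selc & (s * h >= 1.0)] = LOG_ZERO
    lf2[selc & (s >= 1.0)] = LOG_ZERO
    od = mclass == MutationClass.OVERDOMINANT
    if np.any(od):
        if scheme.od_model is ODModel.ALTERNATIVE:
            lf1[od] = np.log1p(shw[od])
        elif scheme.od_model in (ODModel.CLASSICAL_SYMMETRIC, ODModel.CLASSICAL_ASYMMETRIC):
            lf0[od] = np.log1p(-shw[od])
            lf2[od] = np.log1p(-shm[od])
        else:
            raise ValueError("overdominant mutations require an overdominance model")
    return lf0, lf1, lf2


class Population:
    """A Wright-Fisher population with a sparse infinite-sites mutation registry.

    Parameters
    ----------
    n : number of diploid individuals.
    scheme : fitness scheme applied to every selective locus.
    dfe : mutation rates and effect distributions.
    rmap : recombination map.

    Attributes
    ----------
    t : generation index (0 at construction).
    w_fix : product of homozygote fitness factors of deleterious mutations
        fixed since this population (or line) was founded.
    od_fix_factor : product of surviving-homozygote factors of classical
        overdominant loci that lost polymorphism since foundation.
    n_o_fixed : number of overdominant loci fixed for either allele.
    """

    SNAPSHOT_VERSION = 1

    def __init__(
        self,
        n: int,
        scheme: FitnessScheme,
        dfe: DFEConfig,
        rmap: RecombinationMap | None = None,
        neutral_sweep_interval: int = 10,
    ):
        if n < 1:
            raise ValueError("population size must be >= 1")
        self.n = int(n)
        self.scheme = scheme
        self.dfe = dfe
        self.rmap = rmap or RecombinationMap()
        self.t = 0
        self.sel = _LocusBlock(2 * n, 512)
        self.neu = _LocusBlock(2 * n, 64)
        self.w_fix = 1.0
        self.od_fix_factor = 1.0
        self.n_o_fixed = 0
        self.n_lost = 0
        self.fixed_log: list[tuple[int, int, str]] = []  # (generation, id, event)
        self._next_id = 0
        self._logw_seg = np.zeros(n)
        self._lut_cache: tuple[np.ndarray, np.ndarray] | None = None
        self._acc_rate = 0.5
        self.compact_interval = 500
        self._neutral_sweep_interval = max(1, int(neutral_sweep_interval))

    # ------------------------------------------------------------------ ids
    def _take_ids(self, k: int) -> np.ndarray:
        out = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        return out

    # ------------------------------------------------------- fitness tables
    @property
    def w_fix_total(self) -> float:
        return self.w_fix * self.od_fix_factor

    def _batch_logw(
        self, g1: np.ndarray, g2: np.ndarray, luts: tuple[float, np.ndarray, np.ndarray]
    ) -> np.ndarray:
        const, lut_x, lut_a = luts
        return const + _kernels.score_pairs(g1, g2, lut_x, lut_a)

    def _make_luts(self) -> tuple[float, np.ndarray, np.ndarray]:
        """Byte lookup tables: logW = const + lutx[bits(g1 XOR g2)] + luta[bits(g1 AND g2)].

        With allele bits b1, b2 the per-locus log factor is
        lf0 + (lf1-lf0)(b1 XOR b2) + (lf2-lf0)(b1 AND b2). Tables are cached
        and only the byte rows whose loci changed are rebuilt.
        """
        blk = self.sel
        nb = blk.nbytes_row
        cache = self._lut_cache
        if cache is None or blk.dirty_bytes is None or cache[0].shape[0] != nb:
            wx8 = (blk.lf1 - blk.lf0).reshape(nb, 8).astype(np.float32)
            wa8 = (blk.lf2 - blk.lf0).reshape(nb, 8).astype(np.float32)
            lutx = np.ascontiguousarray((_BITS @ wx8.T).T)
            luta = np.ascontiguousarray((_BITS @ wa8.T).T)
            self._lut_cache = (lutx, luta)
            blk.dirty_bytes = set()
        elif blk.dirty_bytes:
            rows = np.fromiter(blk.dirty_bytes, dtype=np.int64)
            lutx, luta = cache
            sl = (rows[:, None] * 8 + np.arange(8)[None, :]).ravel()
            wx8 = (blk.lf1[sl] - blk.lf0[sl]).reshape(-1, 8).astype(np.float32)
            wa8 = (blk.lf2[sl] - blk.lf0[sl]).reshape(-1, 8).astype(np.float32)
            lutx[rows] = (_BITS @ wx8.T).T
            luta[rows] = (_BITS @ wa8.T).T
            blk.dirty_bytes = set()
        lutx, luta = self._lut_cache
        return float(blk.lf0.sum()), lutx, luta

    def evaluate_cohort_logw(self) -> np.ndarray:
        """Log fitness over segregating selective loci, per individual."""
        luts = self._make_luts()
        return self._batch_logw(self.sel.H[0::2], self.sel.H[1::2], luts)

    def refresh_fitness_cache(self) -> None:
        self._logw_seg = self.evaluate_cohort_logw()

    def fitness_values(self) -> np.ndarray:
        """Absolute fitness per individual (viability capped at one)."""
        w = self.w_fix_total * np.exp(self._logw_seg)
        if self.scheme.cap_at_one:
            np.minimum(w, 1.0, out=w)
        return w

    def mean_fitness(self) -> float:
        return float(self.fitness_values().mean())

    # ------------------------------------------------------------- gametes
    def _gamete_batch_free(
        self, block: _LocusBlock, parents: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        mask = _random_bytes(rng, parents.size, block.nbytes_row)
        return _kernels.gamete_batch(block.H, parents, mask)

    def _crossover_masks(
        self, M: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-gamete transmission masks for both blocks under the genetic map.

        Crossover counts are Poisson(total_length), breakpoints uniform with
        no interference; the transmitted haplotype alternates at breakpoints.
        """
        L = self.rmap.total_length
        ks = rng.poisson(L, size=M)
        starts = rng.integers(0, 2, size=M)
        mask_sel = np.empty((M, self.sel.nbytes_row), dtype=np.uint8)
        mask_neu = np.empty((M, self.neu.nbytes_row), dtype=np.uint8)
        pos_sel = self.sel.pos
        pos_neu = self.neu.pos
        for i in range(M):
            br = np.sort(rng.uniform(0.0, L, size=ks[i]))
            phase_sel = ((starts[i] + np.searchsorted(br, pos_sel)) & 1).astype(np.uint8)
            phase_neu = ((starts[i] + np.searchsorted(br, pos_neu)) & 1).astype(np.uint8)
            mask_sel[i] = np.packbits(phase_sel)
            mask_neu[i] = np.packbits(phase_neu)
        return mask_sel, mask_neu

    @staticmethod
    def _apply_masks(block: _LocusBlock, parents: np.ndarray, masks: np.ndarray) -> np.ndarray:
        return _kernels.gamete_batch(block.H, parents, masks)

    # -------------------------------------------------------- reproduction
    def _draw_pairs(
        self, M: int, S: float, rng: np.random.Generator, prob: np.ndarray | None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Parent indices per candidate: selfed with probability S, else two
        distinct parents; uniform draws, or weighted when ``prob`` is given."""
        n = self.n
        selfed = rng.random(M) < S if S > 0 else np.zeros(M, dtype=bool)
        if prob is None:
            p1 = rng.integers(0, n, size=M)
            p2 = p1.copy()
            out = np.nonzero(~selfed)[0]
            if out.size:
                if n < 2:
                    raise ExtinctionError(self.t, "outcrossing requires n >= 2")
                p2[out] = (p1[out] + 1 + rng.integers(0, n - 1, size=out.size)) % n
        else:
            p1 = rng.choice(n, size=M, p=prob)
            p2 = p1.copy()
            todo = np.nonzero(~selfed)[0]
            fertile = int((prob > 0).sum())
            if todo.size and fertile < 2:
                raise ExtinctionError(self.t, "fewer than two fertile parents for outcrossing")
            tries = 0
            while todo.size:
                p2[todo] = rng.choice(n, size=todo.size, p=prob)
                todo = todo[p2[todo] == p1[todo]]
                tries += 1
                if tries > 10_000:  # pragma: no cover - defensive
                    raise ExtinctionError(self.t, "could not draw distinct parents")
        return p1, p2

    def _reproduce_viability(self, S: float, rng: np.random.Generator):
        n = self.n
        luts = self._make_luts()
        mapped = self.rmap.mode == "mapped"
        need = n
        parts: list[tuple] = []
        empty_rounds = 0
        while need > 0:
            M = int(need / max(self._acc_rate, 0.02) * 1.15) + 16
            M = min(M, 50 * n + 1000)
            p1, p2 = self._draw_pairs(M, S, rng, None)
            if mapped:
                m1_sel, m1_neu = self._crossover_masks(M, rng)
                m2_sel, m2_neu = self._crossover_masks(M, rng)
                g1 = self._apply_masks(self.sel, p1, m1_sel)
                g2 = self._apply_masks(self.sel, p2, m2_sel)
                g1n = self._apply_masks(self.neu, p1, m1_neu)
                g2n = self._apply_masks(self.neu, p2, m2_neu)
            else:
                g1 = self._gamete_batch_free(self.sel, p1, rng)
                g2 = self._gamete_batch_free(self.sel, p2, rng)
                g1n = g2n = None
            logw = self._batch_logw(g1, g2, luts)
            w = self.w_fix_total * np.exp(logw)
            if self.scheme.cap_at_one:
                np.minimum(w, 1.0, out=w)
            c = float(w.max())
            if c <= 0.0:
                empty_rounds += 1
                if empty_rounds >= 3:
                    raise ExtinctionError(self.t, "all candidate offspring inviable")
                continue
            acc = np.nonzero(rng.random(M) * c < w)[0]
            taken = acc[:need]
            self._acc_rate = 0.8 * self._acc_rate + 0.2 * max(acc.size / M, 0.01)
            if taken.size:
                parts.append(
                    (
                        g1[taken],
                        g2[taken],
                        logw[taken],
                        p1[taken],
                        p2[taken],
                        g1n[taken] if mapped else None,
                        g2n[taken] if mapped else None,
                    )
                )
                need -= taken.size
        g1 = np.vstack([p[0] for p in parts])
        g2 = np.vstack([p[1] for p in parts])
        logw = np.concatenate([p[2] for p in parts])
        if mapped:
            g1n = np.vstack([p[5] for p in parts])
            g2n = np.vstack([p[6] for p in parts])
        else:
            par1 = np.concatenate([p[3] for p in parts])
            par2 = np.concatenate([p[4] for p in parts])
            # neutral loci are unlinked to selected loci under free
            # recombination, so their gametes can be drawn after acceptance
            g1n = self._gamete_batch_free(self.neu, par1, rng)
            g2n = self._gamete_batch_free(self.neu, par2, rng)
        return g1, g2, g1n, g2n, logw

    def _reproduce_fecundity(self, S: float, rng: np.random.Generator):
        n = self.n
        w = self.w_fix_total * np.exp(self._logw_seg)
        total = w.sum()
        if not np.isfinite(total) or total <= 0.0:
            raise ExtinctionError(self.t, "no fertile parents (total fecundity zero)")
        prob = w / total
        p1, p2 = self._draw_pairs(n, S, rng, prob)
        if self.rmap.mode == "mapped":
            m1_sel, m1_neu = self._crossover_masks(n, rng)
            m2_sel, m2_neu = self._crossover_masks(n, rng)
            g1 = self._apply_masks(self.sel, p1, m1_sel)
            g2 = self._apply_masks(self.sel, p2, m2_sel)
            g1n = self._apply_masks(self.neu, p1, m1_neu)
            g2n = self._apply_masks(self.neu, p2, m2_neu)
        else:
            g1 = self._gamete_batch_free(self.sel, p1, rng)
            g2 = self._gamete_batch_free(self.sel, p2, rng)
            g1n = self._gamete_batch_free(self.neu, p1, rng)
            g2n = self._gamete_batch_free(self.neu, p2, rng)
        luts = self._make_luts()
        logw = self._batch_logw(g1, g2, luts)
        return g1, g2, g1n, g2n, logw

    # ---------------------------------------------------------- mutation
    def _inject(
        self,
        block: _LocusBlock,
        rows: np.ndarray,
        mclass: int,
        s: np.ndarray,
        h: np.ndarray,
        shw: np.ndarray,
        shm: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        k = rows.size
        if k == 0:
            return np.empty(0, dtype=np.int64)
        slots = block.allocate(k)
        block.ids[slots] = self._take_ids(k)
        block.mclass[slots] = mclass
        block.s[slots] = s
        block.h[slots] = h
        block.shw[slots] = shw
        block.shm[slots] = shm
        pos_span = self.rmap.total_length if self.rmap.mode == "mapped" else 1.0
        block.pos[slots] = rng.uniform(0.0, pos_span, size=k)
        block.birth[slots] = self.t
        block.active[slots] = True
        block.count[slots] = 1
        lf0, lf1, lf2 = _log_factors(
            np.full(k, mclass, dtype=np.int8), np.asarray(s, float), np.asarray(h, float),
            np.asarray(shw, float), np.asarray(shm, float), self.scheme,
        )
        block.lf0[slots] = lf0
        block.lf1[slots] = lf1
        block.lf2[slots] = lf2
        if block.dirty_bytes is not None:
            block.dirty_bytes.update(int(sl) >> 3 for sl in slots)
        block.set_bits(rows, slots)
        return slots

    def _mutation_influx(self, rng: np.random.Generator) -> None:
        dfe = self.dfe
        two_n = 2 * self.n
        # deleterious
        k = rng.poisson(two_n * dfe.U)
        if k:
            rows = rng.integers(0, two_n, size=k)
            s, h = sample_deleterious_effects(rng, dfe, k)
            slots = self._inject(
                self.sel, rows, int(MutationClass.DELETERIOUS), s, h,
                np.zeros(k), np.zeros(k), rng,
            )
            np.add.at(self._logw_seg, rows // 2, self.sel.lf1[slots] - self.sel.lf0[slots])
        # lethal / sterile
        k = rng.poisson(two_n * dfe.U_let)
        if k:
            rows = rng.integers(0, two_n, size=k)
            s = np.full(k, dfe.lethal_s)
            h = np.full(k, dfe.h_let)
            slots = self._inject(
                self.sel, rows, int(MutationClass.LETHAL), s, h, np.zeros(k), np.zeros(k), rng
            )
            np.add.at(self._logw_seg, rows // 2, self.sel.lf1[slots] - self.sel.lf0[slots])
        # overdominant
        k = rng.poisson(two_n * dfe.U_o)
        if k:
            rows = rng.integers(0, two_n, size=k)
            shw_v, shm_v = dfe.od_hom_disadvantages
            slots = self._inject(
                self.sel, rows, int(MutationClass.OVERDOMINANT),
                np.zeros(k), np.zeros(k), np.full(k, shw_v), np.full(k, shm_v), rng,
            )
            # a new OD locus multiplies every non-carrier by its lf0 factor
            self._logw_seg += self.sel.lf0[slots].sum()
            np.add.at(self._logw_seg, rows // 2, self.sel.lf1[slots] - self.sel.lf0[slots])
        # neutral markers
        k = rng.poisson(two_n * dfe.U_n)
        if k:
            rows = rng.integers(0, two_n, size=k)
            self._inject(self.neu, rows, int(MutationClass.NEUTRAL), np.zeros(k),
                         np.zeros(k), np.zeros(k), np.zeros(k), rng)

    # -------------------------------------------------- fixation and loss
    def _process_sel_turnover(self) -> None:
        blk = self.sel
        counts = blk.popcount()
        counts[~blk.active] = 0
        blk.count = counts
        two_n = 2 * self.n
        act = blk.active
        lost = np.nonzero(act & (counts == 0))[0]
        fixed = np.nonzero(act & (counts == two_n))[0]
        shift = 0.0
        if lost.size:
            od_lost = lost[blk.mclass[lost] == MutationClass.OVERDOMINANT]
            for sl in od_lost:
                self.od_fix_factor *= 1.0 - blk.shw[sl]
                self.n_o_fixed += 1
                self.fixed_log.append((self.t, int(blk.ids[sl]), "od_lost"))
            # removing a lost locus changes the constant term by -lf0, which
            # is non-zero only for classical OD (folded into od_fix_factor)
            shift -= blk.lf0[lost].sum()
            self.n_lost += int(lost.size) - int(od_lost.size)
            blk.release(lost)
        if fixed.size:
            blk.clear_columns(fixed)
            for sl in fixed:
                mc = blk.mclass[sl]
                if mc == MutationClass.OVERDOMINANT:
                    if self.scheme.od_model in (
                        ODModel.CLASSICAL_SYMMETRIC,
                        ODModel.CLASSICAL_ASYMMETRIC,
                    ):
                        self.od_fix_factor *= 1.0 - blk.shm[sl]
                    self.n_o_fixed += 1
                    self.fixed_log.append((self.t, int(blk.ids[sl]), "od_fixed"))
                else:
                    self.w_fix *= 1.0 - blk.s[sl]
                    self.fixed_log.append((self.t, int(blk.ids[sl]), "fixed"))
            shift -= blk.lf2[fixed].sum()
            blk.release(fixed)
        if shift != 0.0:
            self._logw_seg += shift

    def _sweep_neutral(self) -> None:
        blk = self.neu
        counts = blk.popcount()
        counts[~blk.active] = 0
        blk.count = counts
        act = blk.active
        lost = np.nonzero(act & (counts == 0))[0]
        fixed = np.nonzero(act & (counts == 2 * self.n))[0]
        if fixed.size:
            blk.clear_columns(fixed)
            blk.release(fixed)
        if lost.size:
            blk.release(lost)

    def _compact_block(self, name: str) -> None:
        """Renumber active loci to the front and shrink the bit matrix.

        Slot recycling leaves holes after the initial approach to balance;
        compaction keeps every per-generation pass proportional to the number
        of segregating loci. Purely an internal relabeling: ids, counts and
        all accounting are preserved.
        """
        blk = getattr(self, name)
        act = np.nonzero(blk.active)[0]
        k = act.size
        need = max(64, int(np.ceil((k * 1.25 + 256) / 64.0)) * 64)
        if need >= blk.capacity:
            return
        bits = np.unpackbits(blk.H, axis=1)
        newbits = np.zeros((blk.n_hap, need), dtype=np.uint8)
        newbits[:, :k] = bits[:, act]
        fresh = _LocusBlock(blk.n_hap, need)
        fresh.H = np.packbits(newbits, axis=1)
        fresh.ids[:k] = blk.ids[act]
        fresh.mclass[:k] = blk.mclass[act]
        for f in _LocusBlock._FLOAT_FIELDS:
            getattr(fresh, f)[:k] = getattr(blk, f)[act]
        fresh.birth[:k] = blk.birth[act]
        fresh.active[:k] = True
        fresh.count[:k] = blk.count[act]
        fresh._free = list(range(fresh.capacity - 1, k - 1, -1))
        fresh.dirty_bytes = None
        setattr(self, name, fresh)
        if name == "sel":
            self._lut_cache = None

    # ------------------------------------------------------------ stepping
    def step(self, S: float, rng: np.random.Generator) -> "Population":
        """Advance one generation in place (see :func:`next_generation`)."""
        if not (0.0 <= S <= 1.0):
            raise ValueError(f"selfing rate must be in [0,1], got {S}")
        if self.n < 2 and S < 1.0:
            raise ValueError("n must be >= 2 unless S == 1")
        if self.scheme.trait is Trait.VIABILITY:
            g1, g2, g1n, g2n, logw = self._reproduce_viability(S, rng)
        else:
            g1, g2, g1n, g2n, logw = self._reproduce_fecundity(S, rng)
        self.sel.H[0::2] = g1
        self.sel.H[1::2] = g2
        self.neu.H[0::2] = g1n
        self.neu.H[1::2] = g2n
        self._logw_seg = logw
        self.t += 1
        self._mutation_influx(rng)
        self._process_sel_turnover()
        if self.t % self._neutral_sweep_interval == 0:
            self._sweep_neutral()
        if self.compact_interval and self.t % self.compact_interval == 0:
            self._compact_block("sel")
            self._compact_block("neu")
        return self

    # ----------------------------------------------------------- sampling
    def sample_founders(self, k: int, rng: np.random.Generator) -> "Population":
        """Found a line from ``k`` individuals sampled without replacement.

        Loci monomorphic among the founders stop being accounted: classical
        overdominant loci fixed in the base would otherwise depress every
        fitness permanently, and the within-line load accounting (W_max,
        n_o_fixed, w_fix) starts fresh at foundation.
        """
        if k > self.n:
            raise ValueError(f"cannot sample {k} individuals from n={self.n}")
        chosen = np.sort(rng.choice(self.n, size=k, replace=False))
        rows = np.empty(2 * k, dtype=np.int64)
        rows[0::2] = 2 * chosen
        rows[1::2] = 2 * chosen + 1
        line = Population(k, self.scheme, self.dfe, self.rmap, self._neutral_sweep_interval)
        line._next_id = self._next_id
        for src, dst in ((self.sel, "sel"), (self.neu, "neu")):
            blk = _LocusBlock(2 * k, src.capacity)
            blk.H = src.H[rows].copy()
            blk.ids = src.ids.copy()
            blk.mclass = src.mclass.copy()
            for name in _LocusBlock._FLOAT_FIELDS:
                setattr(blk, name, getattr(src, name).copy())
            blk.birth = src.birth.copy()
            blk.active = src.active.copy()
            blk._free = list(src._free)
            counts = blk.popcount()
            counts[~blk.active] = 0
            blk.count = counts
            mono = np.nonzero(blk.active & ((counts == 0) | (counts == 2 * k)))[0]
            if mono.size:
                blk.clear_columns(mono[counts[mono] == 2 * k])
                blk.release(mono)
            setattr(line, dst, blk)
        line.refresh_fitness_cache()
        return line

    # -------------------------------------------------------- introspection
    def segregating(self, block: str = "sel") -> np.ndarray:
        blk = self.sel if block == "sel" else self.neu
        return np.nonzero(blk.active)[0]

    def mutant_frequencies(self, block: str = "sel") -> tuple[np.ndarray, np.ndarray]:
        """(slots, q) for active loci of a block."""
        blk = self.sel if block == "sel" else self.neu
        slots = np.nonzero(blk.active)[0]
        return slots, blk.count[slots] / (2.0 * self.n)

    def genotype_matrix(self, block: str = "neu") -> tuple[np.ndarray, np.ndarray]:
        """(mutant-copy counts per individual x active locus, frequencies)."""
        blk = self.neu if block == "neu" else self.sel
        slots = np.nonzero(blk.active)[0]
        bits = np.unpackbits(blk.H, axis=1)[:, slots]
        x = bits[0::2].astype(np.int16) + bits[1::2].astype(np.int16)
        q = blk.count[slots] / (2.0 * self.n)
        return x, q

    def haplotype(self, individual: int, which: int) -> Haplotype:
        row = 2 * individual + which
        ids = []
        for blk in (self.sel, self.neu):
            bits = np.unpackbits(blk.H[row])
            slots = np.nonzero(bits[: blk.capacity] & blk.active)[0]
            ids.extend(int(i) for i in blk.ids[slots])
        return tuple(sorted(ids))

    def individual(self, i: int) -> Individual:
        w = float(self.fitness_values()[i])
        return Individual(self.haplotype(i, 0), self.haplotype(i, 1), w)

    def record_of(self, mut_id: int) -> MutationRecord:
        for blk in (self.sel, self.neu):
            try:
                sl = blk.slot_of_id(mut_id)
            except KeyError:
                continue
            return MutationRecord(
                id=int(blk.ids[sl]),
                mclass=MutationClass(int(blk.mclass[sl])),
                s=float(blk.s[sl]),
                h=float(blk.h[sl]),
                s_hom_wild=float(blk.shw[sl]),
                s_hom_mut=float(blk.shm[sl]),
                position=float(blk.pos[sl]),
                birth_gen=int(blk.birth[sl]),
            )
        raise KeyError(f"mutation id {mut_id} not segregating")

    def active_records(self) -> list[MutationRecord]:
        out = []
        for blk in (self.sel, self.neu):
            for sl in np.nonzero(blk.active)[0]:
                out.append(
                    MutationRecord(
                        id=int(blk.ids[sl]),
                        mclass=MutationClass(int(blk.mclass[sl])),
                        s=float(blk.s[sl]),
                        h=float(blk.h[sl]),
                        s_hom_wild=float(blk.shw[sl]),
                        s_hom_mut=float(blk.shm[sl]),
                        position=float(blk.pos[sl]),
                        birth_gen=int(blk.birth[sl]),
                    )
                )
        return out

    def copy_count_check(self) -> bool:
        """Registry copy counts equal the column sums of the bit matrix."""
        counts = self.sel.popcount()
        counts[~self.sel.active] = 0
        return bool(np.array_equal(counts, self.sel.count))

    # --------------------------------------------- seeding for experiments
    def seed_mutation(
        self,
        record_args: dict,
        carrier_rows: Sequence[int],
        rng: np.random.Generator,
    ) -> int:
        """Place one mutation into explicit haplotype rows (test/assay setup)."""
        mclass = MutationClass(record_args.get("mclass", MutationClass.DELETERIOUS))
        block = self.neu if mclass is MutationClass.NEUTRAL else self.sel
        rows = np.asarray(sorted(set(int(r) for r in carrier_rows)), dtype=np.int64)
        if rows.size == 0 or rows.size >= 2 * self.n:
            raise ValueError("seeded mutation must be segregating (0 < copies < 2n)")
        slot = int(block.allocate(1)[0])
        block.ids[slot] = self._take_ids(1)[0]
        block.mclass[slot] = int(mclass)
        block.s[slot] = float(record_args.get("s", 0.0))
        block.h[slot] = float(record_args.get("h", 0.0))
        block.shw[slot] = float(record_args.get("s_hom_wild", 0.0))
        block.shm[slot] = float(record_args.get("s_hom_mut", 0.0))
        block.pos[slot] = float(record_args.get("position", rng.uniform()))
        block.birth[slot] = self.t
        block.active[slot] = True
        block.count[slot] = rows.size
        lf0, lf1, lf2 = _log_factors(
            np.array([int(mclass)], dtype=np.int8),
            np.array([block.s[slot]]), np.array([block.h[slot]]),
            np.array([block.shw[slot]]), np.array([block.shm[slot]]),
            self.scheme,
        )
        block.lf0[slot], block.lf1[slot], block.lf2[slot] = lf0[0], lf1[0], lf2[0]
        if block.dirty_bytes is not None:
            block.dirty_bytes.add(slot >> 3)
        block.set_bits(rows, np.full(rows.size, slot, dtype=np.int64))
        self.refresh_fitness_cache()
        return int(block.ids[slot])


# ------------------------------------------- record-level operations
def make_gamete(
    ind: Individual,
    rmap: RecombinationMap,
    rng: np.random.Generator,
    registry: "Population | dict | None" = None,
) -> Haplotype:
    """One gamete from an individual, as a sparse mutation-id tuple.

    Free mode: each heterozygous site transmits independently with
    probability 1/2 (homozygous sites always transmit). Mapped mode:
    Poisson(total_length) crossovers at uniform positions, alternating
    between the parental haplotypes; requires a ``registry`` resolving
    mutation positions.
    """
    s1, s2 = set(ind.hap1), set(ind.hap2)
    hom = s1 & s2
    het1 = sorted(s1 - s2)
    het2 = sorted(s2 - s1)
    if rmap.mode == "free":
        take = set(hom)
        for mid in het1:
            if rng.random() < 0.5:
                take.add(mid)
        for mid in het2:
            if rng.random() < 0.5:
                take.add(mid)
        return tuple(sorted(take))
    if registry is None:
        raise ValueError("mapped recombination requires a registry for positions")

    def pos_of(mid: int) -> float:
        if isinstance(registry, Population):
            return registry.record_of(mid).position
        return registry[mid].position

    br = np.sort(rng.uniform(0.0, rmap.total_length, size=rng.poisson(rmap.total_length)))
    start = int(rng.integers(0, 2))
    take = set(hom)
    for mid in het1:
        if (start + np.searchsorted(br, pos_of(mid))) % 2 == 0:
            take.add(mid)
    for mid in het2:
        if (start + np.searchsorted(br, pos_of(mid))) % 2 == 1:
            take.add(mid)
    return tuple(sorted(take))


def mutate_gamete(
    hap: Haplotype,
    dfe: DFEConfig,
    t: int,
    rng: np.random.Generator,
    id_start: int = 0,
    rmap: RecombinationMap | None = None,
) -> tuple[Haplotype, list[MutationRecord]]:
    """Add Poisson-distributed new mutations of every class to a gamete.

    Returns the augmented haplotype and the new :class:`MutationRecord` list
    (fresh sites, ids from ``id_start``, ``birth_gen = t``) for registration.
    """
    rmap = rmap or RecombinationMap()
    span = rmap.total_length if rmap.mode == "mapped" else 1.0
    new: list[MutationRecord] = []
    nid = id_start
    k = rng.poisson(dfe.U)
    for _ in range(k):
        s, h = sample_deleterious_effects(rng, dfe, 1)
        new.append(
            MutationRecord(nid, MutationClass.DELETERIOUS, float(s[0]), float(h[0]),
                           position=float(rng.uniform(0, span)), birth_gen=t)
        )
        nid += 1
    for _ in range(rng.poisson(dfe.U_let)):
        new.append(
            MutationRecord(nid, MutationClass.LETHAL, dfe.lethal_s, dfe.h_let,
                           position=float(rng.uniform(0, span)), birth_gen=t)
        )
        nid += 1
    shw, shm = dfe.od_hom_disadvantages
    for _ in range(rng.poisson(dfe.U_o)):
        new.append(
            MutationRecord(nid, MutationClass.OVERDOMINANT, s_hom_wild=shw, s_hom_mut=shm,
                           position=float(rng.uniform(0, span)), birth_gen=t)
        )
        nid += 1
    for _ in range(rng.poisson(dfe.U_n)):
        new.append(
            MutationRecord(nid, MutationClass.NEUTRAL,
                           position=float(rng.uniform(0, span)), birth_gen=t)
        )
        nid += 1
    return tuple(sorted(list(hap) + [m.id for m in new])), new


def individual_fitness(
    ind: Individual,
    scheme: FitnessScheme,
    registry: "Population | dict",
) -> float:
    """Multiplicative fitness over all segregating selective loci.

    Under classical overdominance a segregating locus contributes
    ``1 - s_hom_wild`` even to individuals carrying zero copies, so the
    product runs over every active selective locus of the registry, not just
    the mutations the individual carries. Viability is capped at one.
    """
    if isinstance(registry, Population):
        records = {
            m.id: m for m in registry.active_records() if m.mclass is not MutationClass.NEUTRAL
        }
    else:
        records = {
            mid: m for mid, m in registry.items() if m.mclass is not MutationClass.NEUTRAL
        }
    carried = list(ind.hap1) + list(ind.hap2)
    for mid in carried:
        if mid not in records and not _is_known_neutral(mid, registry):
            raise KeyError(f"mutation id {mid} not resolved by the registry")
    copies: dict[int, int] = {}
    for mid in carried:
        if mid in records:
            copies[mid] = copies.get(mid, 0) + 1
    w = 1.0
    for mid, m in records.items():
        w *= genotype_fitness_factor(m, copies.get(mid, 0), scheme)
    if scheme.cap_at_one:
        w = min(w, 1.0)
    return w


def _is_known_neutral(mid: int, registry) -> bool:
    if isinstance(registry, Population):
        try:
            return registry.record_of(mid).mclass is MutationClass.NEUTRAL
        except KeyError:
            return False
    m = registry.get(mid)
    return m is not None and m.mclass is MutationClass.NEUTRAL


def next_generation(
    pop: Population,
    S: float,
    scheme: FitnessScheme | None = None,
    rmap: RecombinationMap | None = None,
    dfe: DFEConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """Advance the population one Wright-Fisher generation (in place).

    ``scheme``/``rmap``/``dfe`` default to the population's own; passing
    different ones temporarily overrides them for this step.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    saved = (pop.scheme, pop.rmap, pop.dfe)
    try:
        if scheme is not None:
            pop.scheme = scheme
        if rmap is not None:
            pop.rmap = rmap
        if dfe is not None:
            pop.dfe = dfe
        return pop.step(S, rng)
    finally:
        pop.scheme, pop.rmap, pop.dfe = saved
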