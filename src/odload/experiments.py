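"""Experiment drivers: equilibrium burn-ins, selfing sweeps, bottleneck lines.

Two designs are orchestrated here. In the *selfing sweep*, a base population
of ``n_base`` individuals evolves for ``burnin_gens`` generations at each
selfing rate S; a sample of ``sample_size`` individuals is then assayed for
inbreeding load (B), the number of segregating overdominant loci, and the
inbreeding depression of selfed relative to outbred progeny (delta, delta*).
In the *bottleneck design*, panmictic lines of ``sample_size`` individuals
are founded from an S = 0 base and maintained with random mating for
``line_gens`` generations, tracking W, W_max, L and B every generation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from odload.load_metrics import (
    SUMMARY_COLUMNS,
    LoadSummary,
    SelfingAssayResult,
    depression_stats,
    inbreeding_load,
    summarize,
    yang_inbreeding,
)
from odload.mutation_model import DFEConfig, FitnessScheme, ODModel, Trait
from odload.population_engine import (
    ExtinctionError,
    Population,
    RecombinationMap,
)

logger = logging.getLogger("odload")

__all__ = [
    "RunConfig",
    "replicate_rng",
    "run_burnin",
    "found_sample",
    "selfing_assay",
    "selfing_sweep",
    "run_bottleneck_lines",
    "replicate_orchestrator",
    "BottleneckResult",
]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one experiment.

    Defaults follow the main study design: base populations of n = 1000
    maintained 10,000 generations, 50-individual samples/lines kept 250
    generations, 200 replicates.
    """

    n_base: int = 1000
    S: float = 0.0
    burnin_gens: int = 10_000
    sample_size: int = 50
    line_gens: int = 250
    n_replicates: int = 200
    report_interval: int = 50
    burnin_log_interval: int = 500
    assay_pairs: int = 50
    base_seed: int = 1234
    share_base: bool = False
    neutral_sweep_interval: int = 10
    scheme: FitnessScheme = field(default_factory=FitnessScheme)
    dfe: DFEConfig = field(default_factory=DFEConfig)
    rmap: RecombinationMap = field(default_factory=RecombinationMap)

    def __post_init__(self) -> None:
        if self.n_base < 1:
            raise ValueError("n_base must be >= 1")
        if not (0.0 <= self.S <= 1.0):
            raise ValueError(f"selfing rate S must be in [0,1], got {self.S}")
        for name in (
            "burnin_gens",
            "sample_size",
            "line_gens",
            "n_replicates",
            "report_interval",
            "burnin_log_interval",
            "assay_pairs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sample_size > self.n_base:
            raise ValueError("sample_size cannot exceed n_base")

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        """Named configurations: ``paper`` (full scale) or ``desk`` (quick)."""
        if name == "paper":
            base = cls()
        elif name == "desk":
            base = cls(
                n_base=200,
                burnin_gens=500,
                sample_size=20,
                line_gens=100,
                n_replicates=5,
                burnin_log_interval=100,
                dfe=DFEConfig(U_n=0.2),
            )
        else:
            raise ValueError(f"unknown preset {name!r} (expected 'paper' or 'desk')")
        return replace(base, **overrides) if overrides else base


def replicate_rng(base_seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator (SeedSequence on [seed, r])."""
    return np.random.default_rng([int(base_seed), int(replicate)])


def run_burnin(
    cfg: RunConfig,
    replicate: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[Population, list[LoadSummary]]:
    """Evolve a base population to mutation-selection-drift balance.

    Returns the final population and periodic load summaries. Extinction
    raises :class:`ExtinctionError`, which the orchestrator records as a
    failed replicate.
    """
    rng = rng or replicate_rng(cfg.base_seed, replicate)
    pop = Population(
        cfg.n_base, cfg.scheme, cfg.dfe, cfg.rmap, cfg.neutral_sweep_interval
    )
    history: list[LoadSummary] = []
    for _ in range(cfg.burnin_gens):
        pop.step(cfg.S, rng)
        if pop.t % cfg.burnin_log_interval == 0:
            row = summarize(pop)
            history.append(row)
            logger.debug(
                "burnin t=%d W=%.4f B=%.3f n_del=%d n_let=%d n_o=%d",
                row.t, row.W, row.B, row.n_del, row.n_let, row.n_o,
            )
    if not history or history[-1].t != pop.t:
        history.append(summarize(pop))
    return pop, history


def found_sample(
    base: Population,
    k: int,
    scheme: FitnessScheme | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """Found a line from ``k`` individuals sampled without replacement.

    Overdominant loci fixed in the base are excluded from the line's load
    accounting (under the classical models they would depress every fitness
    permanently; under the alternative model their homozygote fitness is one,
    so exclusion is a no-op), and the fixed-mutation log restarts at
    foundation.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if scheme is not None and scheme != base.scheme:
        raise ValueError("sampling cannot change the fitness scheme of the base")
    return base.sample_founders(k, rng)


def _progeny_batch(
    pop: Population,
    p1: np.ndarray,
    p2: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(fitness, neutral-genotype matrix) of one deterministic progeny per pair.

    Gametes are sampled (meiosis is random) but no survival lottery is
    applied: the fitness recorded is the genotypic fitness of the progeny.
    """
    if pop.rmap.mode == "mapped":
        m1s, m1n = pop._crossover_masks(p1.size, rng)
        m2s, m2n = pop._crossover_masks(p2.size, rng)
        g1 = pop._apply_masks(pop.sel, p1, m1s)
        g2 = pop._apply_masks(pop.sel, p2, m2s)
        g1n = pop._apply_masks(pop.neu, p1, m1n)
        g2n = pop._apply_masks(pop.neu, p2, m2n)
    else:
        g1 = pop._gamete_batch_free(pop.sel, p1, rng)
        g2 = pop._gamete_batch_free(pop.sel, p2, rng)
        g1n = pop._gamete_batch_free(pop.neu, p1, rng)
        g2n = pop._gamete_batch_free(pop.neu, p2, rng)
    luts = pop._make_luts()
    logw = pop._batch_logw(g1, g2, luts)
    w = pop.w_fix_total * np.exp(logw)
    if pop.scheme.cap_at_one:
        np.minimum(w, 1.0, out=w)
    slots = np.nonzero(pop.neu.active)[0]
    if slots.size:
        b1 = np.unpackbits(g1n, axis=1)[:, slots]
        b2 = np.unpackbits(g2n, axis=1)[:, slots]
        x = b1.astype(np.int16) + b2.astype(np.int16)
    else:
        x = np.zeros((p1.size, 0), dtype=np.int16)
    return w, x


def selfing_assay(
    pop: Population,
    scheme: FitnessScheme | None = None,
    n_pairs: int = 50,
    rng: np.random.Generator | None = None,
) -> SelfingAssayResult:
    """Estimate delta and delta* from outbred and selfed progeny.

    Outbred progeny come from ``n_pairs`` random pairs of distinct parents
    (one progeny each); every individual also contributes one selfed progeny.
    Mean progeny fitness is the deterministic genotypic fitness; the
    inbreeding coefficients of both progeny groups are estimated with the
    marker-based estimator using the parent population's neutral allele
    frequencies as reference.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if scheme is not None and scheme != pop.scheme:
        raise ValueError("assay cannot change the fitness scheme of the population")
    n = pop.n
    if n < 2:
        raise ValueError("assay requires at least two individuals")
    p1 = rng.integers(0, n, size=n_pairs)
    p2 = (p1 + 1 + rng.integers(0, n - 1, size=n_pairs)) % n
    w_out, x_out = _progeny_batch(pop, p1, p2, rng)
    selfp = np.arange(n)
    w_self, x_self = _progeny_batch(pop, selfp, selfp, rng)
    W_o = float(w_out.mean())
    W_s = float(w_self.mean())
    # reference minor-allele frequencies from the parent population
    slots = np.nonzero(pop.neu.active)[0]
    counts = np.unpackbits(pop.neu.H, axis=1)[:, slots].sum(axis=0) if slots.size else np.empty(0)
    q = counts / (2.0 * n) if slots.size else np.empty(0)
    poly = (q > 0) & (q < 1)
    if poly.sum() == 0:
        if W_o <= 0 or W_s <= 0:
            raise ValueError("mean progeny fitness must be positive")
        delta = math.log(W_o / W_s)
        return SelfingAssayResult(W_o, W_s, delta, float("nan"),
                                  float("nan"), float("nan"), False)
    q = q[poly]
    minor_is_mut = q <= 0.5
    p_ref = np.where(minor_is_mut, q, 1.0 - q)
    xo = x_out[:, poly]
    xs = x_self[:, poly]
    xo = np.where(minor_is_mut, xo, 2 - xo)
    xs = np.where(minor_is_mut, xs, 2 - xs)
    F_o = float(yang_inbreeding(xo, p_ref).mean())
    F_s = float(yang_inbreeding(xs, p_ref).mean())
    return depression_stats(W_o, W_s, F_s, F_o)


def selfing_sweep(
    cfg: RunConfig,
    S_values: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> pd.DataFrame:
    """Burn-in + assay across selfing rates; one aggregated row per S.

    Columns report replicate means (with standard errors) of the total
    inbreeding load B of the sample, the deleterious+lethal and overdominant
    partitions, the number of segregating overdominant loci, delta and
    delta*, plus the expected-value references E[B_o] = n_o s_o / 2 and
    E[delta] = (B/2)(1+F) with F = S/(2-S).
    """
    rows = []
    for si, S in enumerate(S_values):
        cfg_s = replace(cfg, S=float(S))

        def one_replicate(r: int, rng: np.random.Generator) -> dict:
            base, _ = run_burnin(cfg_s, rng=rng)
            sample = found_sample(base, cfg_s.sample_size, rng=rng)
            B, B_del, B_let, B_o = inbreeding_load(sample)
            n_o = int(
                (
                    sample.sel.active
                    & (sample.sel.mclass == 2)  # MutationClass.OVERDOMINANT
                ).sum()
            )
            assay = selfing_assay(sample, n_pairs=cfg_s.assay_pairs, rng=rng)
            b_dl = B_del + B_let
            return {
                "B": B,
                "B_del_let": b_dl,
                "B_o": B_o,
                "ratio_Bo_Bdl": B_o / b_dl if b_dl > 0 else float("nan"),
                "n_o": n_o,
                "delta": assay.delta,
                "delta_star": assay.delta_star,
                "F_hat_s": assay.F_hat_s,
                "F_hat_o": assay.F_hat_o,
            }

        agg, _ = replicate_orchestrator(
            replace(cfg_s, base_seed=cfg.base_seed + si), one_replicate
        )
        F = S / (2.0 - S)
        s_o = cfg.dfe.od_hom_disadvantages[0]
        row = {"S": S, "F": F}
        for col in agg.index:
            row[col] = agg.loc[col, "mean"]
            row[f"{col}_se"] = agg.loc[col, "se"]
        row["E_Bo"] = row["n_o"] * s_o / 2.0
        row["E_delta"] = row["B"] / (2.0 - S)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BottleneckResult:
    """Aggregated output of the bottleneck-line design."""

    trajectory: pd.DataFrame  # per-generation means of W, W_max, L, B, ...
    table: pd.DataFrame  # report-interval rows in the summary-table layout
    per_line: list[list[LoadSummary]]
    n_lines: int
    failures: list[tuple[int, int]]  # (line index, extinction generation)


def run_bottleneck_lines(
    cfg: RunConfig,
    bases: Sequence[Population] | None = None,
    n_lines: int | None = None,
) -> BottleneckResult:
    """Found panmictic lines of ``sample_size`` individuals and track load.

    ``bases`` supplies pre-equilibrated S = 0 base populations (cycled over
    lines); if omitted, an independent burn-in is run per line (or a single
    shared base when ``cfg.share_base``). Lines evolve ``line_gens``
    generations of random mating; every generation is summarized and line
    means are aggregated per generation and at report intervals.
    """
    n_lines = n_lines or cfg.n_replicates
    shared: list[Population] = []
    per_line: list[list[LoadSummary]] = []
    failures: list[tuple[int, int]] = []
    for li in range(n_lines):
        rng = replicate_rng(cfg.base_seed, li)
        if bases is not None:
            base = bases[li % len(bases)]
        elif cfg.share_base:
            if not shared:
                shared.append(run_burnin(replace(cfg, S=0.0), rng=replicate_rng(cfg.base_seed, 10_000_000))[0])
            base = shared[0]
        else:
            base, _ = run_burnin(replace(cfg, S=0.0), rng=rng)
        line = found_sample(base, cfg.sample_size, rng=rng)
        W0 = line.mean_fitness()
        rows = [summarize(line, W0=W0)]
        try:
            for _ in range(cfg.line_gens):
                line.step(0.0, rng)
                rows.append(summarize(line, W0=W0))
        except ExtinctionError as exc:
            failures.append((li, exc.generation))
        per_line.append(rows)
    # aggregate by generation over lines still alive at that generation
    frames = []
    for li, rows in enumerate(per_line):
        df = pd.DataFrame([r.__dict__ for r in rows])
        df["line"] = li
        frames.append(df)
    allrows = pd.concat(frames, ignore_index=True)
    numeric = [c for c in allrows.columns if c != "line"]
    grouped = allrows[numeric].groupby("t")
    trajectory = grouped.mean()
    trajectory["n_lines"] = grouped.size()
    report_ts = [t for t in range(0, cfg.line_gens + 1, cfg.report_interval)]
    table = trajectory.loc[[t for t in report_ts if t in trajectory.index],
                           list(SUMMARY_COLUMNS[1:])].reset_index()
    table = table[list(SUMMARY_COLUMNS)]
    return BottleneckResult(
        trajectory=trajectory,
        table=table,
        per_line=per_line,
        n_lines=n_lines,
        failures=failures,
    )


def replicate_orchestrator(
    cfg: RunConfig,
    experiment: Callable[[int, np.random.Generator], dict],
    out_dir: str | None = None,
    label: str = "experiment",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run ``experiment`` over ``cfg.n_replicates`` seeded replicates.

    ``experiment(replicate_index, rng)`` returns a flat dict of scalars.
    Returns (aggregated, per_replicate): the aggregate has one row per
    statistic with columns mean, se, n. Failed replicates (extinction) are
    recorded and excluded; the replicate count actually aggregated is
    reported per statistic. When ``out_dir`` is given, TSV outputs and a JSON
    run manifest are written there.
    """
    records: list[dict] = []
    failures: list[int] = []
    for r in range(cfg.n_replicates):
        rng = replicate_rng(cfg.base_seed, r)
        try:
            out = experiment(r, rng)
        except ExtinctionError:
            failures.append(r)
            continue
        out = dict(out)
        out["replicate"] = r
        records.append(out)
    per_rep = pd.DataFrame(records)
    stats = [c for c in per_rep.columns if c != "replicate"]
    agg_rows = {}
    for c in stats:
        vals = per_rep[c].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        n = int(ok.sum())
        mean = float(vals[ok].mean()) if n else float("nan")
        se = float(vals[ok].std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        agg_rows[c] = {"mean": mean, "se": se, "n": n}
    agg = pd.DataFrame(agg_rows).T
    if failures:
        agg.attrs["failed_replicates"] = failures
    if out_dir is not None:
        from odload import io_cli

        io_cli.write_orchestrator_outputs(cfg, label, agg, per_rep, failures, out_dir)
    return agg, per_rep
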