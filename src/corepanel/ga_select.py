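"""Genetic-algorithm search for a core SNP panel.

The optimisation problem: from M candidate SNPs choose a panel of C loci
maximising the fraction of samples whose genotype profile over the panel is
unique in the population (raw fitness F = U/N, where U is the number of
uniquely identified samples).  A GA individual *is* a panel — an ordered set
of C distinct locus indices — and the population of P panels evolves by
fitness-proportional roulette selection, single-point tail-swap crossover with
duplicate repair, multi-site mutation, and an elitist merge of parents and
offspring truncated back to size P.

Profiles are ordered tuples of the per-locus integer genotype codes
(45/97/98/104); two samples are distinguished as soon as any panel locus
differs.  Missing calls are ordinary profile symbols by default; with
``missing_wildcard`` a missing call matches anything, so a sample counts as
identified only if no other sample is *compatible* with it.

Raw fitness feeds selection directly by default.  Optional rank-based
transforms (linear with selection pressure ``sp`` in [1, 2], or nonlinear with
a free base > 0) can replace raw fitness before the roulette draw; both assign
the largest value to the best-ranked member and sum to the population size.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import ConfigError, InputError
from .vcf_io import EncodedMatrix, Locus

__all__ = [
    "GAConfig",
    "GAPopulation",
    "GAResult",
    "init_population",
    "assemble_profiles",
    "fitness",
    "rank_fitness_linear",
    "rank_fitness_nonlinear",
    "selection_probabilities",
    "roulette_pick",
    "crossover",
    "mutate",
    "merge_and_truncate",
    "run_ga",
    "brute_force_best_panel",
    "chromosome_spread_tiebreak",
]

Panel = np.ndarray  # C distinct locus indices, order significant

RANKINGS = ("none", "linear", "nonlinear")
_MISSING_CODE = 45


@dataclass(frozen=True)
class GAConfig:
    """Search parameters; defaults target a 100-SNP fingerprint panel."""

    panel_size: int = 100
    population_size: int = 100
    max_iterations: int = 500
    crossover_probability: float = 0.8
    mutation_probability: float = 0.1
    mutation_fraction: float = 0.3
    ranking: str = "none"
    sp: float = 1.5
    nonlinear_base: float = 2.0
    rng_seed: int = 0
    early_stop_patience: int = 50  # stop after this many generations at 1.0
    missing_wildcard: bool = False

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ConfigError("panel_size must be >= 1")
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if self.max_iterations < 0:
            raise ConfigError("max_iterations must be >= 0")
        for name in ("crossover_probability", "mutation_probability", "mutation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.ranking not in RANKINGS:
            raise ConfigError(f"ranking must be one of {RANKINGS}")
        if not 1.0 <= self.sp <= 2.0:
            raise ConfigError("sp must be in [1.0, 2.0]")
        if self.nonlinear_base <= 0:
            raise ConfigError("nonlinear_base must be > 0")


@dataclass
class GAPopulation:
    members: list[Panel]
    fitnesses: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GAResult:
    """Final ranked population plus the per-generation search trace."""

    panels: list[Panel]  # sorted by fitness descending
    fitnesses: np.ndarray
    best_fitness: list[float]
    mean_fitness: list[float]
    best_panels: list[Panel]
    chosen_panel: Panel
    generations: int
    config: GAConfig

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
            }
        )


def _check_panel(panel: Panel, m_loci: int) -> np.ndarray:
    p = np.asarray(panel, dtype=np.intp)
    if p.ndim != 1 or len(np.unique(p)) != p.size:
        raise InputError("panel must be a 1-D array of distinct locus indices")
    if p.size and (p.min() < 0 or p.max() >= m_loci):
        raise InputError("panel index out of range")
    return p


def init_population(
    m_loci: int, panel_size: int, population_size: int, rng: np.random.Generator
) -> GAPopulation:
    """P uniform random C-subsets (without replacement) of the locus indices."""
    if panel_size > m_loci:
        raise ConfigError(f"panel_size {panel_size} exceeds {m_loci} loci")
    members = [
        rng.choice(m_loci, size=panel_size, replace=False).astype(np.intp)
        for _ in range(population_size)
    ]
    return GAPopulation(members=members, fitnesses=np.full(population_size, np.nan))


def assemble_profiles(enc: EncodedMatrix, panel: Panel) -> list[tuple[int, ...]]:
    """Per-sample profile: the ordered tuple of codes at the panel's loci."""
    p = _check_panel(panel, enc.m_loci)
    sub = enc.codes[:, p]
    return [tuple(int(v) for v in row) for row in sub]


def fitness(enc: EncodedMatrix, panel: Panel, missing_wildcard: bool = False) -> float:
    """Fraction of samples whose panel profile occurs exactly once (F = U/N)."""
    p = np.asarray(panel, dtype=np.intp)
    sub = np.ascontiguousarray(enc.codes[:, p])
    n = sub.shape[0]
    if not missing_wildcard:
        counts = Counter(row.tobytes() for row in sub)
        unique = sum(1 for row in sub if counts[row.tobytes()] == 1)
    else:
        miss = sub == _MISSING_CODE
        eq = sub[:, None, :] == sub[None, :, :]
        compat = (eq | miss[:, None, :] | miss[None, :, :]).all(axis=2)
        unique = int((compat.sum(axis=1) == 1).sum())
    return unique / n


def rank_fitness_linear(n_ind: int, sp: float) -> np.ndarray:
    """Linear ranking values for pos = 1..Nind (ascending raw fitness).

    FitnV(pos) = 2 - sp + 2 (sp - 1)(pos - 1)/(Nind - 1); the best member
    (pos = Nind) gets sp, the worst gets 2 - sp, and the values sum to Nind.
    """
    if not 1.0 <= sp <= 2.0:
        raise ConfigError("sp must be in [1.0, 2.0]")
    if n_ind < 2:
        raise ConfigError("n_ind must be >= 2")
    pos = np.arange(1, n_ind + 1, dtype=float)
    return 2.0 - sp + 2.0 * (sp - 1.0) * (pos - 1.0) / (n_ind - 1.0)


def rank_fitness_nonlinear(n_ind: int, base: float) -> np.ndarray:
    """Nonlinear ranking: Nind * base^(pos-1) / sum_i base^(i-1); sums to Nind."""
    if base <= 0:
        raise ConfigError("base must be > 0")
    powers = np.power(float(base), np.arange(n_ind, dtype=float))
    return n_ind * powers / powers.sum()


def selection_probabilities(fitness_values: Sequence[float]) -> np.ndarray:
    """O(i) = F(i) / sum F; uniform when all fitnesses are zero."""
    f = np.asarray(fitness_values, dtype=float)
    if (f < 0).any():
        raise InputError("fitness values must be non-negative")
    total = f.sum()
    if total == 0.0:
        return np.full(f.size, 1.0 / f.size)
    return f / total


def roulette_pick(probabilities: np.ndarray, rng: np.random.Generator) -> int:
    """Draw R ~ U(0,1); return the member whose cumulative interval holds R."""
    cum = np.cumsum(probabilities)
    r = rng.random()
    return int(min(np.searchsorted(cum, r, side="left"), len(cum) - 1))


def _repair_duplicates(child: np.ndarray, m_loci: int) -> np.ndarray:
    """Replace repeated loci (left to right) by absent loci in ascending order."""
    seen: set[int] = set()
    dup_positions = []
    for k, v in enumerate(child):
        if int(v) in seen:
            dup_positions.append(k)
        else:
            seen.add(int(v))
    if not dup_positions:
        return child
    absent = sorted(set(range(m_loci)) - seen)
    for k, new in zip(dup_positions, absent):
        child[k] = new
    return child


def crossover(
    a: Panel,
    b: Panel,
    crossover_probability: float,
    rng: np.random.Generator,
    m_loci: int,
) -> tuple[Panel, Panel]:
    """Single-point tail swap at B1 ~ U{1..C-1}, with duplicate repair.

    With probability ``crossover_probability`` the tails (positions after B1)
    of the two parents are exchanged; a locus then appearing twice in a child
    is replaced by the smallest locus absent from that child, in ascending
    order.  Otherwise (or when C = 1) the children are copies of the parents.
    """
    a = _check_panel(a, m_loci)
    b = _check_panel(b, m_loci)
    c = a.size
    if c < 2 or rng.random() >= crossover_probability:
        return a.copy(), b.copy()
    b1 = int(rng.integers(1, c))  # crossover bit in [1, C-1]
    child1 = np.concatenate([a[:b1], b[b1:]])
    child2 = np.concatenate([b[:b1], a[b1:]])
    return (
        _repair_duplicates(child1, m_loci),
        _repair_duplicates(child2, m_loci),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mutate(
    panel: Panel,
    mutation_probability: float,
    mutation_fraction: float,
    rng: np.random.Generator,
    m_loci: int,
) -> Panel:
    """With the given probability, re-draw round(fraction*C) panel positions.

    The selected positions are emptied first; replacements are drawn without
    replacement from the ascending list of loci absent from the remainder of
    the panel (so an emptied locus may re-enter).
    """
    p = _check_panel(panel, m_loci)
    if rng.random() >= mutation_probability:
        return p.copy()
    c = p.size
    n_mut = min(_round_half_away(mutation_fraction * c), c)
    if n_mut == 0:
        return p.copy()
    positions = rng.choice(c, size=n_mut, replace=False)
    kept = np.delete(p, positions)
    absent = np.setdiff1d(np.arange(m_loci), kept)  # ascending by construction
    n_eff = min(n_mut, absent.size)
    picks = absent[rng.choice(absent.size, size=n_eff, replace=False)]
    out = p.copy()
    out[positions[:n_eff]] = picks
    return out


def _panel_key(panel: Panel) -> tuple[int, ...]:
    return tuple(sorted(int(v) for v in panel))


def merge_and_truncate(
    parents: GAPopulation,
    offspring: GAPopulation,
    population_size: int,
    *,
    enc: EncodedMatrix | None = None,
    rng: np.random.Generator | None = None,
    missing_wildcard: bool = False,
) -> GAPopulation:
    """Elitist merge: dedupe identical locus sets, keep top P by fitness.

    If deduplication leaves fewer than P members, fresh random panels are
    drawn to refill (requires ``enc`` and ``rng``).
    """
    members = list(parents.members) + list(offspring.members)
    fits = np.concatenate([parents.fitnesses, offspring.fitnesses])
    seen: set[tuple[int, ...]] = set()
    uniq_members: list[Panel] = []
    uniq_fits: list[float] = []
    for m, f in zip(members, fits):
        key = _panel_key(m)
        if key in seen:
            continue
        seen.add(key)
        uniq_members.append(m)
        uniq_fits.append(float(f))
    order = np.argsort(-np.asarray(uniq_fits), kind="stable")[:population_size]
    out_members = [uniq_members[i] for i in order]
    out_fits = [uniq_fits[i] for i in order]
    attempts = 0
    while len(out_members) < population_size:
        if enc is None or rng is None:
            raise InputError(
                "refill after deduplication needs enc and rng to draw new panels"
            )
        c = len(out_members[0]) if out_members else population_size
        cand = rng.choice(enc.m_loci, size=c, replace=False).astype(np.intp)
        attempts += 1
        # tiny universes can run out of distinct C-subsets; then allow repeats
        if _panel_key(cand) in seen and attempts < 100:
            continue
        seen.add(_panel_key(cand))
        out_members.append(cand)
        out_fits.append(fitness(enc, cand, missing_wildcard))
    return GAPopulation(members=out_members, fitnesses=np.asarray(out_fits))


def _transformed_selection_values(fits: np.ndarray, cfg: GAConfig) -> np.ndarray:
    if cfg.ranking == "none":
        return fits
    order = np.argsort(fits, kind="stable")  # ascending: pos=Nind is the best
    if cfg.ranking == "linear":
        ranked = rank_fitness_linear(fits.size, cfg.sp)
    else:
        ranked = rank_fitness_nonlinear(fits.size, cfg.nonlinear_base)
    out = np.empty_like(ranked)
    out[order] = ranked
    return out


def run_ga(
    enc: EncodedMatrix, cfg: GAConfig, loci: list[Locus] | None = None
) -> GAResult:
    """Full GA loop; deterministic under ``cfg.rng_seed``.

    Each generation: selection values (raw or rank-transformed) -> roulette
    parent draws -> crossover -> mutation -> elitist merge back to size P.
    The best-fitness trace is non-decreasing.  The run ends at
    ``max_iterations``, or earlier once the best fitness has sat at 1.0 for
    ``early_stop_patience`` consecutive generations.  ``loci`` metadata, when
    given, lets the final tie-break prefer the panel spread most evenly across
    chromosomes.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    if loci is None:
        loci = enc.loci
    pop = init_population(enc.m_loci, cfg.panel_size, cfg.population_size, rng)
    pop.fitnesses = np.array(
        [fitness(enc, m, cfg.missing_wildcard) for m in pop.members]
    )
    best_trace: list[float] = []
    mean_trace: list[float] = []
    best_panels: list[Panel] = []

    def record() -> None:
        i = int(np.argmax(pop.fitnesses))
        best_trace.append(float(pop.fitnesses[i]))
        mean_trace.append(float(pop.fitnesses.mean()))
        best_panels.append(pop.members[i].copy())

    record()
    at_optimum = 0
    generations = 0
    for _ in range(cfg.max_iterations):
        sel = _transformed_selection_values(pop.fitnesses, cfg)
        probs = selection_probabilities(sel)
        children: list[Panel] = []
        while len(children) < cfg.population_size:
            i = roulette_pick(probs, rng)
            j = roulette_pick(probs, rng)
            c1, c2 = crossover(
                pop.members[i], pop.members[j], cfg.crossover_probability, rng, enc.m_loci
            )
            children.append(
                mutate(c1, cfg.mutation_probability, cfg.mutation_fraction, rng, enc.m_loci)
            )
            if len(children) < cfg.population_size:
                children.append(
                    mutate(c2, cfg.mutation_probability, cfg.mutation_fraction, rng, enc.m_loci)
                )
        off = GAPopulation(
            members=children,
            fitnesses=np.array(
                [fitness(enc, m, cfg.missing_wildcard) for m in children]
            ),
        )
        pop = merge_and_truncate(
            pop,
            off,
            cfg.population_size,
            enc=enc,
            rng=rng,
            missing_wildcard=cfg.missing_wildcard,
        )
        generations += 1
        record()
        if best_trace[-1] >= 1.0:
            at_optimum += 1
            if at_optimum >= cfg.early_stop_patience:
                break
        else:
            at_optimum = 0

    order = np.argsort(-pop.fitnesses, kind="stable")
    panels = [pop.members[i] for i in order]
    fits = pop.fitnesses[order]
    top = [p for p, f in zip(panels, fits) if f == fits[0]]
    chosen = chromosome_spread_tiebreak(top, loci)
    return GAResult(
        panels=panels,
        fitnesses=fits,
        best_fitness=best_trace,
        mean_fitness=mean_trace,
        best_panels=best_panels,
        chosen_panel=chosen,
        generations=generations,
        config=cfg,
    )


def brute_force_best_panel(
    enc: EncodedMatrix,
    panel_size: int,
    missing_wildcard: bool = False,
    guard: int = 10**6,
) -> tuple[Panel, float]:
    """Exhaustive search over all C-subsets (test oracle, guarded by size).

    Returns the lexicographically smallest subset attaining the maximum
    fitness.
    """
    n_comb = math.comb(enc.m_loci, panel_size)
    if n_comb > guard:
        raise InputError(f"{n_comb} combinations exceed the guard of {guard}")
    best: tuple[int, ...] | None = None
    best_fit = -1.0
    for combo in combinations(range(enc.m_loci), panel_size):
        f = fitness(enc, np.array(combo, dtype=np.intp), missing_wildcard)
        if f > best_fit:
            best, best_fit = combo, f
    assert best is not None
    return np.array(best, dtype=np.intp), best_fit


def chromosome_spread_tiebreak(candidates: list[Panel], loci: list[Locus]) -> Panel:
    """Among equally fit panels, pick the most evenly spread across chromosomes.

    Minimises the maximum per-chromosome locus count; remaining ties go to the
    lexicographically smallest sorted index tuple.
    """
    if not candidates:
        raise InputError("empty candidate list")

    def key(panel: Panel):
        counts = Counter(loci[int(i)].chrom for i in panel)
        return (max(counts.values()), _panel_key(panel))

    return min(candidates, key=key)
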