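"""Synthetic genotyped populations with known subgroup structure.

A Balding–Nichols-style model: each locus draws an ancestral REF frequency
uniform in [0.05, 0.95]; each of K subgroups perturbs it by a divergence
parameter F (subgroup frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)); genotypes
are Binomial(2, q) ALT-allele dosages.  A configurable fraction of loci are
exact copies of their left neighbour (perfect adjacent LD, to exercise the LD
filter) and calls are masked missing at a configurable rate.  Everything is
deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .vcf_io import MISSING, GenotypeMatrix, Locus

__all__ = ["SimConfig", "simulate_population", "inject_missing", "subgroup_labels"]


@dataclass(frozen=True)
class SimConfig:
    """Defaults emulate a mid-sized crop diversity panel (200 x 1000)."""

    n_samples: int = 200
    n_loci: int = 1000
    n_chromosomes: int = 12
    n_subgroups: int = 5
    divergence: float = 0.15  # Balding-Nichols F
    missing_rate: float = 0.01
    duplicate_fraction: float = 0.10  # loci copied from their left neighbour
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_loci < 0:
            raise ConfigError("n_samples >= 1 and n_loci >= 0 required")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if not 1 <= self.n_subgroups <= self.n_samples:
            raise ConfigError("n_subgroups must be in [1, n_samples]")
        for name in ("divergence", "missing_rate", "duplicate_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")


def subgroup_labels(n_samples: int, n_subgroups: int) -> np.ndarray:
    """Deterministic round-robin subgroup assignment used by the simulator."""
    return np.arange(n_samples) % n_subgroups


def _locus_map(n_loci: int, n_chromosomes: int) -> list[Locus]:
    base = n_loci // n_chromosomes
    extra = n_loci % n_chromosomes
    loci: list[Locus] = []
    for c in range(n_chromosomes):
        size = base + (1 if c < extra else 0)
        chrom = f"chr{c + 1:02d}"
        for k in range(size):
            pos = (k + 1) * 1000
            loci.append(Locus(chrom, pos, f"{chrom}_{pos}"))
    return loci


def _duplicate_targets(loci: list[Locus], n_dup: int, rng: np.random.Generator):
    """Pick n_dup loci to copy from their left neighbour.

    Targets are isolated (no target adjacent to another, and never the first
    locus of a chromosome) so each contributes exactly one perfect-LD adjacent
    pair.
    """
    candidates = [
        j for j in range(1, len(loci)) if loci[j].chrom == loci[j - 1].chrom
    ]
    rng.shuffle(candidates)
    chosen: list[int] = []
    used: set[int] = set()
    for j in candidates:
        if {j - 1, j, j + 1} & used:
            continue
        chosen.append(j)
        used.update({j - 1, j, j + 1})
        if len(chosen) == n_dup:
            break
    if len(chosen) < n_dup:
        raise ConfigError(
            f"cannot place {n_dup} isolated duplicate loci among {len(loci)}"
        )
    return sorted(chosen)


def simulate_population(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a structured population; see the module docstring for the model."""
    rng = np.random.default_rng(cfg.rng_seed)
    n, m, k = cfg.n_samples, cfg.n_loci, cfg.n_subgroups
    loci = _locus_map(m, cfg.n_chromosomes)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = cfg.divergence
    if f > 0 and k > 1:
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_sub = rng.beta(a, b, size=(k, m))
    else:
        p_sub = np.broadcast_to(p_anc, (k, m)).copy()
    groups = subgroup_labels(n, k)
    alt_dosage = rng.binomial(2, 1.0 - p_sub[groups, :]).astype(np.int8)

    n_dup = round(cfg.duplicate_fraction * m)
    if n_dup:
        for j in _duplicate_targets(loci, n_dup, rng):
            alt_dosage[:, j] = alt_dosage[:, j - 1]

    samples = [f"S{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(samples=samples, loci=loci, calls=alt_dosage)
    if cfg.missing_rate > 0:
        gm = inject_missing(gm, cfg.missing_rate, rng)
    return gm


def inject_missing(
    gm: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> GenotypeMatrix:
    """Independently mask each call missing with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("rate must be in [0, 1]")
    calls = gm.calls.copy()
    mask = rng.random(calls.shape) < rate
    calls[mask] = MISSING
    return GenotypeMatrix(samples=list(gm.samples), loci=list(gm.loci), calls=calls)
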