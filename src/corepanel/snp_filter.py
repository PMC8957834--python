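"""Locus filters that reduce a raw SNP matrix to the GA candidate set.

Three stages are applied in a fixed order:

1. missingness — drop loci whose missing-call fraction is strictly greater
   than ``max_missing_fraction`` (default 0.01);
2. homozygote count — drop loci with fewer than ``min_homozygote_count``
   (default 2) samples of *either* homozygous genotype, removing
   near-monomorphic sites;
3. adjacent-pair LD — squared Pearson correlation of ALT dosages between
   neighbouring loci on the same chromosome; ``prune`` mode (default) keeps
   one representative of each run of highly correlated neighbours, while
   ``literal_retain`` keeps exactly the loci participating in a high-r2
   adjacent pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .vcf_io import ALT_HOM, MISSING, REF_HOM, GenotypeMatrix

__all__ = [
    "FilterConfig",
    "StageReport",
    "FilterReport",
    "filter_by_missing",
    "filter_by_homozygote_count",
    "adjacent_r2",
    "ld_filter",
    "apply_filters",
]

LD_MODES = ("prune", "literal_retain")


@dataclass(frozen=True)
class FilterConfig:
    max_missing_fraction: float = 0.01
    min_homozygote_count: int = 2
    r2_threshold: float = 0.95
    ld_mode: str = "prune"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ConfigError("max_missing_fraction must be in [0, 1]")
        if self.min_homozygote_count < 0:
            raise ConfigError("min_homozygote_count must be >= 0")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ConfigError("r2_threshold must be in [0, 1]")
        if self.ld_mode not in LD_MODES:
            raise ConfigError(f"ld_mode must be one of {LD_MODES}")


@dataclass
class StageReport:
    stage: str
    n_input: int
    n_removed: int
    n_surviving: int
    removed: dict[str, str] = field(default_factory=dict)  # locus id -> reason

    def __post_init__(self) -> None:
        assert self.n_input == self.n_removed + self.n_surviving


@dataclass
class FilterReport:
    stages: list[StageReport] = field(default_factory=list)

    @property
    def n_surviving(self) -> int:
        return self.stages[-1].n_surviving if self.stages else 0

    def extend(self, other: "FilterReport") -> "FilterReport":
        self.stages.extend(other.stages)
        return self

    def summary(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "input": s.n_input,
                    "removed": s.n_removed,
                    "surviving": s.n_surviving,
                }
                for s in self.stages
            ]
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def removed_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": lid, "stage": s.stage, "reason": why}
            for s in self.stages
            for lid, why in s.removed.items()
        ]
        return pd.DataFrame(rows, columns=["locus", "stage", "reason"])


def _apply_mask(
    gm: GenotypeMatrix, keep: np.ndarray, stage: str, reason_fn
) -> tuple[GenotypeMatrix, FilterReport]:
    removed = {gm.loci[j].id: reason_fn(j) for j in np.nonzero(~keep)[0]}
    out = gm.subset_loci(np.nonzero(keep)[0])
    report = FilterReport(
        [StageReport(stage, gm.m_loci, int((~keep).sum()), int(keep.sum()), removed)]
    )
    return out, report


def filter_by_missing(
    gm: GenotypeMatrix, max_missing_fraction: float = 0.01
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep a locus iff missing fraction <= threshold (strict-greater removal)."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ConfigError("max_missing_fraction must be in [0, 1]")
    frac = (gm.calls == MISSING).mean(axis=0)
    keep = frac <= max_missing_fraction
    return _apply_mask(
        gm,
        keep,
        "missing",
        lambda j: f"missing_fraction={frac[j]:.4g}>{max_missing_fraction:g}",
    )


def filter_by_homozygote_count(
    gm: GenotypeMatrix, min_homozygote_count: int = 2
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep a locus iff both homozygote classes have >= the minimum count."""
    if min_homozygote_count < 0:
        raise ConfigError("min_homozygote_count must be >= 0")
    n_ref = (gm.calls == REF_HOM).sum(axis=0)
    n_alt = (gm.calls == ALT_HOM).sum(axis=0)
    keep = (n_ref >= min_homozygote_count) & (n_alt >= min_homozygote_count)
    return _apply_mask(
        gm,
        keep,
        "homozygote",
        lambda j: f"hom_counts=({n_ref[j]},{n_alt[j]})<{min_homozygote_count}",
    )


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson r of dosages over pairwise-complete samples.

    Pairs with fewer than 2 complete observations, or zero variance at either
    locus, get r2 = 0 by convention.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float((xc @ yc) ** 2 / (sx * sy))


def _chrom_blocks(gm: GenotypeMatrix) -> list[list[int]]:
    blocks: list[list[int]] = []
    prev = None
    for j, loc in enumerate(gm.loci):
        if loc.chrom != prev:
            blocks.append([])
            prev = loc.chrom
        blocks[-1].append(j)
    return blocks


def adjacent_r2(gm: GenotypeMatrix) -> list[tuple[int, int, float]]:
    """r2 for each within-chromosome adjacent locus pair, in locus order."""
    pairs = []
    for block in _chrom_blocks(gm):
        for a, b in zip(block, block[1:]):
            pairs.append((a, b, _pair_r2(gm.calls[:, a], gm.calls[:, b])))
    return pairs


def ld_filter(
    gm: GenotypeMatrix, r2_threshold: float = 0.95, ld_mode: str = "prune"
) -> tuple[GenotypeMatrix, FilterReport]:
    """Thin loci by adjacent-pair LD.

    ``prune``: sweep each chromosome left to right keeping a running survivor;
    the next locus is dropped when its r2 with the last survivor exceeds the
    threshold, so removals cascade through runs of correlated loci.
    ``literal_retain``: keep exactly the loci that belong to at least one
    original adjacent pair with r2 above the threshold.
    """
    if ld_mode not in LD_MODES:
        raise ConfigError(f"ld_mode must be one of {LD_MODES}")
    keep = np.zeros(gm.m_loci, dtype=bool)
    if ld_mode == "prune":
        for block in _chrom_blocks(gm):
            last = block[0]
            keep[last] = True
            for j in block[1:]:
                if _pair_r2(gm.calls[:, last], gm.calls[:, j]) > r2_threshold:
                    continue
                keep[j] = True
                last = j
        reason = f"adjacent_r2>{r2_threshold:g}"
    else:
        for a, b, r2 in adjacent_r2(gm):
            if r2 > r2_threshold:
                keep[a] = keep[b] = True
        reason = f"no_adjacent_pair_r2>{r2_threshold:g}"
    return _apply_mask(gm, keep, "ld", lambda j: reason)


def apply_filters(
    gm: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run missing -> homozygote -> LD in order; report all three stages."""
    cfg = config or FilterConfig()
    gm1, rep = filter_by_missing(gm, cfg.max_missing_fraction)
    gm2, r2 = filter_by_homozygote_count(gm1, cfg.min_homozygote_count)
    gm3, r3 = ld_filter(gm2, cfg.r2_threshold, cfg.ld_mode)
    return gm3, rep.extend(r2).extend(r3)
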