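"""Fingerprint codes and panel-validation statistics.

Turns a chosen panel into per-sample fingerprint strings over ``{0, 1, 2, -}``
(0/0 -> '1', 1/1 -> '2', 0/1 -> '0', missing -> '-') and computes the
statistics used to judge a panel: discrimination fraction, pairwise
differing-locus counts, genotype-mismatch distances, the Mantel-style
correlation between panel and full-matrix distances, allele frequencies and
per-SNP polymorphism information content (PIC), and per-chromosome locus
counts.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .vcf_io import ALT_HOM, HET, MISSING, REF_HOM, GenotypeMatrix, Locus

__all__ = [
    "FingerprintTable",
    "PanelEvalReport",
    "binary_fingerprint",
    "pairwise_differing_loci",
    "mismatch_distance_matrix",
    "panel_fit_correlation",
    "allele_frequencies",
    "pic",
    "per_chromosome_counts",
    "evaluate_panel",
]

_BINARY = {int(REF_HOM): "1", int(ALT_HOM): "2", int(HET): "0", int(MISSING): "-"}


@dataclass
class FingerprintTable:
    """One code string of length C per sample, alphabet {0, 1, 2, -}."""

    samples: list[str]
    codes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.samples, "code": self.codes})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def n_distinct(self) -> int:
        return len(set(self.codes))


@dataclass
class PanelEvalReport:
    discrimination_fraction: float
    differing_locus_matrix: np.ndarray
    per_snp_pic: np.ndarray
    mean_pic: float
    per_chromosome_counts: dict[str, int]
    panel_fit_correlation: float | None

    def to_dict(self) -> dict:
        return {
            "discrimination_fraction": self.discrimination_fraction,
            "mean_pic": self.mean_pic,
            "per_snp_pic": [None if np.isnan(v) else float(v) for v in self.per_snp_pic],
            "per_chromosome_counts": self.per_chromosome_counts,
            "panel_fit_correlation": self.panel_fit_correlation,
            "min_differing_loci": int(self._offdiag().min())
            if self.differing_locus_matrix.shape[0] > 1
            else None,
            "max_differing_loci": int(self._offdiag().max())
            if self.differing_locus_matrix.shape[0] > 1
            else None,
        }

    def _offdiag(self) -> np.ndarray:
        m = self.differing_locus_matrix
        return m[np.triu_indices(m.shape[0], k=1)]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _panel_array(panel, m_loci: int) -> np.ndarray:
    p = np.asarray(panel, dtype=np.intp)
    if p.size and (p.min() < 0 or p.max() >= m_loci):
        raise InputError("panel index out of range")
    return p


def binary_fingerprint(gm: GenotypeMatrix, panel) -> FingerprintTable:
    """Fingerprint code per sample, concatenated in panel locus order."""
    p = _panel_array(panel, gm.m_loci)
    sub = gm.calls[:, p]
    codes = ["".join(_BINARY[int(v)] for v in row) for row in sub]
    return FingerprintTable(samples=list(gm.samples), codes=codes)


def pairwise_differing_loci(gm: GenotypeMatrix, panel) -> np.ndarray:
    """Counts of panel loci where both samples are called and differ."""
    p = _panel_array(panel, gm.m_loci)
    sub = gm.calls[:, p]
    valid = sub != MISSING
    both = valid[:, None, :] & valid[None, :, :]
    diff = sub[:, None, :] != sub[None, :, :]
    return (both & diff).sum(axis=2)


def mismatch_distance_matrix(gm: GenotypeMatrix, loci) -> np.ndarray:
    """Genotype-mismatch distance: differing / shared non-missing loci.

    Symmetric with zero diagonal, entries in [0, 1].  Pairs sharing no called
    locus get distance 1 with a warning.
    """
    p = _panel_array(loci, gm.m_loci)
    if p.size == 0:
        raise InputError("at least one locus is required")
    sub = gm.calls[:, p]
    valid = sub != MISSING
    both = valid[:, None, :] & valid[None, :, :]
    diff = (sub[:, None, :] != sub[None, :, :]) & both
    shared = both.sum(axis=2)
    if (shared == 0).any():
        warnings.warn(
            "sample pair(s) share no non-missing locus; distance set to 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(shared > 0, diff.sum(axis=2) / np.maximum(shared, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def panel_fit_correlation(full_dm: np.ndarray, panel_dm: np.ndarray) -> float:
    """Mantel-style Pearson correlation of the strict upper triangles."""
    full_dm = np.asarray(full_dm, dtype=float)
    panel_dm = np.asarray(panel_dm, dtype=float)
    if full_dm.shape != panel_dm.shape or full_dm.shape[0] != full_dm.shape[1]:
        raise InputError("distance matrices must be square and same-shaped")
    iu = np.triu_indices(full_dm.shape[0], k=1)
    x, y = full_dm[iu], panel_dm[iu]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for constant distance triangles")
    return float(stats.pearsonr(x, y).statistic)


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus REF allele frequency p = (2*ref_hom + het) / (2*called).

    All-missing loci get NaN with a warning.
    """
    n_ref = (gm.calls == REF_HOM).sum(axis=0)
    n_het = (gm.calls == HET).sum(axis=0)
    n_called = (gm.calls != MISSING).sum(axis=0)
    if (n_called == 0).any():
        warnings.warn("all-missing locus/loci: allele frequency undefined (NaN)",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2.0 * n_ref + n_het) / (2.0 * n_called)
    return np.where(n_called > 0, p, np.nan)


def pic(p):
    """Biallelic polymorphism information content: 1 - (p^2+q^2) - 2 p^2 q^2.

    Maximum 0.375 at p = 0.5; symmetric in p and q = 1 - p.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p[~np.isnan(p)] < 0) | (p[~np.isnan(p)] > 1)):
        raise InputError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(out) if out.ndim == 0 else out


def per_chromosome_counts(panel, loci: list[Locus]) -> dict[str, int]:
    """Panel loci per chromosome; counts sum to the panel size."""
    p = _panel_array(panel, len(loci))
    return dict(Counter(loci[int(i)].chrom for i in p))


def _discrimination_fraction(gm: GenotypeMatrix, panel) -> float:
    sub = np.ascontiguousarray(gm.calls[:, np.asarray(panel, dtype=np.intp)])
    counts = Counter(row.tobytes() for row in sub)
    return sum(1 for row in sub if counts[row.tobytes()] == 1) / sub.shape[0]


def evaluate_panel(
    gm: GenotypeMatrix, panel, full_gm: GenotypeMatrix | None = None
) -> PanelEvalReport:
    """Full validation report for a panel on the population ``gm``.

    ``full_gm`` (typically the filtered candidate matrix) enables the
    panel-vs-full distance correlation; it must carry the same samples.
    """
    p = _panel_array(panel, gm.m_loci)
    panel_gm = gm.subset_loci(p)
    freqs = allele_frequencies(panel_gm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pics = pic(freqs)
    corr = None
    if full_gm is not None:
        if full_gm.samples != gm.samples:
            raise InputError("full matrix must carry the same samples")
        full_dm = mismatch_distance_matrix(full_gm, np.arange(full_gm.m_loci))
        panel_dm = mismatch_distance_matrix(gm, p)
        corr = panel_fit_correlation(full_dm, panel_dm)
    return PanelEvalReport(
        discrimination_fraction=_discrimination_fraction(gm, p),
        differing_locus_matrix=pairwise_differing_loci(gm, p),
        per_snp_pic=pics,
        mean_pic=float(np.nanmean(pics)) if pics.size else float("nan"),
        per_chromosome_counts=per_chromosome_counts(p, gm.loci),
        panel_fit_correlation=corr,
    )
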