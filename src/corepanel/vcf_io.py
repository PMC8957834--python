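"""Genotype containers, integer genotype encodings, and VCF/TSV input-output.

Diploid biallelic calls are held as a samples x loci ``int8`` matrix over four
states: homozygous reference (0/0), heterozygous (0/1), homozygous alternate
(1/1) and missing (./.).  Two text encodings of the same alphabet are
supported, both used downstream:

* the integer codes ``{45, 97, 98, 104}`` consumed by the genetic-algorithm
  search (the ASCII codes of ``-``, ``a``, ``b``, ``h``);
* the single-letter TSV alphabet ``A`` (1/1), ``B`` (0/0), ``h`` (0/1),
  ``-`` (missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import InputError, VcfFormatError

__all__ = [
    "REF_HOM",
    "HET",
    "ALT_HOM",
    "MISSING",
    "Locus",
    "GenotypeMatrix",
    "EncodedMatrix",
    "encode_genotypes",
    "decode_genotypes",
    "read_vcf",
    "write_vcf",
    "write_panel_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
]

logger = logging.getLogger(__name__)

# Call states double as ALT-allele dosage for the three observed genotypes;
# MISSING is negative so masking is a single comparison.
REF_HOM = np.int8(0)
HET = np.int8(1)
ALT_HOM = np.int8(2)
MISSING = np.int8(-1)

CALL_STATES = (REF_HOM, HET, ALT_HOM, MISSING)

# state -> GA integer code; indexed by (call + 1)
_ENCODE_LUT = np.array([45, 97, 104, 98], dtype=np.uint8)  # MISSING, REF, HET, ALT
_DECODE = {45: MISSING, 97: REF_HOM, 104: HET, 98: ALT_HOM}

# state <-> TSV symbol
_TSV_SYMBOL = {REF_HOM: "B", HET: "h", ALT_HOM: "A", MISSING: "-"}
_TSV_STATE = {v: k for k, v in _TSV_SYMBOL.items()}

_GT_STRING = {REF_HOM: "0/0", HET: "0/1", ALT_HOM: "1/1", MISSING: "./."}


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP site: 1-based VCF coordinates plus alleles."""

    chrom: str
    pos: int
    id: str
    ref: str = "A"
    alt: str = "G"


@dataclass
class GenotypeMatrix:
    """Samples x loci genotype calls with locus metadata.

    ``calls[i, j]`` is the state of sample ``i`` at locus ``j``; sample IDs are
    unique and loci are kept sorted by (chromosome, position) by the readers.
    """

    samples: list[str]
    loci: list[Locus]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise InputError("calls must be a 2-D samples x loci array")
        n, m = self.calls.shape
        if n != len(self.samples):
            raise InputError(f"{len(self.samples)} sample IDs but {n} call rows")
        if m != len(self.loci):
            raise InputError(f"{len(self.loci)} loci but {m} call columns")
        if n < 1:
            raise InputError("at least one sample is required")
        if len(set(self.samples)) != len(self.samples):
            raise InputError("sample IDs must be unique")
        bad = ~np.isin(self.calls, [REF_HOM, HET, ALT_HOM, MISSING])
        if bad.any():
            raise InputError(f"invalid call value(s): {np.unique(self.calls[bad])}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def m_loci(self) -> int:
        return self.calls.shape[1]

    def subset_loci(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """Restrict to the given locus columns (order as given)."""
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )

    def dosage(self) -> np.ndarray:
        """ALT-allele dosage as float with NaN at missing calls."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class EncodedMatrix:
    """The genotype matrix mapped to the GA integer codes {45, 97, 98, 104}."""

    samples: list[str]
    loci: list[Locus]
    codes: np.ndarray = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def m_loci(self) -> int:
        return self.codes.shape[1]


def encode_genotypes(gm: GenotypeMatrix) -> EncodedMatrix:
    """Map calls elementwise: ./. -> 45, 0/0 -> 97, 1/1 -> 98, 0/1 -> 104."""
    codes = _ENCODE_LUT[gm.calls.astype(np.intp) + 1]
    return EncodedMatrix(samples=list(gm.samples), loci=list(gm.loci), codes=codes)


def decode_genotypes(enc: EncodedMatrix) -> GenotypeMatrix:
    """Inverse of :func:`encode_genotypes`; round-trip is the identity."""
    lut = np.full(256, 127, dtype=np.int8)
    for code, state in _DECODE.items():
        lut[code] = state
    calls = lut[enc.codes.astype(np.intp)]
    if (calls == 127).any():
        bad = np.unique(enc.codes[calls == 127])
        raise InputError(f"invalid encoded value(s): {bad}")
    return GenotypeMatrix(samples=list(enc.samples), loci=list(enc.loci), calls=calls)


def _sort_loci(loci: list[Locus], cols: np.ndarray, chrom_rank: dict[str, int]):
    order = sorted(
        range(len(loci)),
        key=lambda i: (chrom_rank.get(loci[i].chrom, len(chrom_rank)), loci[i].pos),
    )
    return [loci[i] for i in order], cols[:, order]


def read_vcf(path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; multi-allelic, indel and symbolic
    records are skipped with a logged count.  Phased separators are treated as
    unphased, and half-calls (e.g. ``./1``) as missing.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    vcf = VCF(str(path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfFormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no sample columns")
    if len(set(samples)) != len(samples):
        raise InputError(f"{path}: duplicate sample IDs")

    bases = {"A", "C", "G", "T"}
    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        if (
            len(alts) != 1
            or len(var.REF) != 1
            or var.REF.upper() not in bases
            or len(alts[0]) != 1
            or alts[0].upper() not in bases
        ):
            n_skipped += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            alleles = g[:-1]  # last element is the phased flag
            if len(alleles) != 2 or alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING
            else:
                col[i] = np.int8(alleles[0] + alleles[1])  # dosage == state
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        loci.append(Locus(var.CHROM, var.POS, vid, var.REF, alts[0]))
        columns.append(col)
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic/non-SNP record(s)", path, n_skipped)

    calls = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), np.int8)
    )
    # chromosome order follows the VCF header contigs, else first appearance
    header_chroms = list(vcf.seqnames)
    seen: dict[str, int] = {c: i for i, c in enumerate(header_chroms)}
    for loc in loci:
        seen.setdefault(loc.chrom, len(seen))
    loci, calls = _sort_loci(loci, calls, seen)
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT-only records."""
    path = Path(path)
    chrom_max: dict[str, int] = {}
    for loc in gm.loci:
        chrom_max[loc.chrom] = max(chrom_max.get(loc.chrom, 0), loc.pos)
    lines = ["##fileformat=VCFv4.2", "##source=corepanel"]
    lines += [
        f"##contig=<ID={c},length={chrom_max[c] + 1}>" for c in chrom_max
    ]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
    )
    for j, loc in enumerate(gm.loci):
        gts = "\t".join(_GT_STRING[int(c)] for c in gm.calls[:, j])
        lines.append(
            f"{loc.chrom}\t{loc.pos}\t{loc.id}\t{loc.ref}\t{loc.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write VCF to {path}: {exc}") from exc


def write_panel_vcf(gm: GenotypeMatrix, panel: Iterable[int], path) -> None:
    """Write only the panel's loci (position-sorted), all samples, to a VCF."""
    idx = sorted(set(int(i) for i in panel))
    for i in idx:
        if not 0 <= i < gm.m_loci:
            raise InputError(f"panel index {i} out of range for {gm.m_loci} loci")
    write_vcf(gm.subset_loci(idx), path)


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    """Write the A/B/h/- matrix TSV: samples as rows, locus IDs as columns."""
    sym = np.empty(gm.calls.shape, dtype="U1")
    for state, s in _TSV_SYMBOL.items():
        sym[gm.calls == state] = s
    frame = pd.DataFrame(sym, index=gm.samples, columns=[l.id for l in gm.loci])
    frame.to_csv(path, sep="\t", index_label="sample")


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read the alternate A/B/h/- genotype-matrix TSV.

    Locus IDs of the form ``chrom:pos`` or ``chrom_pos`` recover coordinates;
    otherwise loci land on a single pseudo-chromosome in column order.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    samples = [str(s) for s in frame.index]
    if len(set(samples)) != len(samples):
        raise InputError(f"{path}: duplicate sample IDs")
    calls = np.empty(frame.shape, dtype=np.int8)
    values = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            v = str(values[i, j])
            if v not in _TSV_STATE:
                raise VcfFormatError(f"{path}: unknown genotype symbol {v!r}")
            calls[i, j] = _TSV_STATE[v]
    loci = []
    for j, cid in enumerate(str(c) for c in frame.columns):
        chrom, pos = "1", j + 1
        for sep in (":", "_"):
            head, _, tail = cid.rpartition(sep)
            if head and tail.isdigit():
                chrom, pos = head, int(tail)
                break
        loci.append(Locus(chrom, pos, cid))
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)
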