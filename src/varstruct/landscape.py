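"""Genome-wide variant summaries: SNP spectrum, indel lengths, density tracks.

The six-type SNP spectrum collapses strands onto the pyrimidine-context
reference (a G→A call is the same event as C→T on the other strand, so both
count as C:G>T:A).  Density tracks count features in non-overlapping tiling
windows per chromosome; association between two tracks is summarized by
Spearman's rho, Pearson's r and an ordinary least-squares fit.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenomicVariant",
    "WindowDensity",
    "AssociationResult",
    "SPECTRUM_BINS",
    "snp_spectrum",
    "indel_lengths",
    "windowed_density",
    "density_association",
]

log = logging.getLogger(__name__)

SPECTRUM_BINS = (
    "C:G>T:A", "T:A>C:G", "C:G>A:T", "C:G>G:C", "T:A>A:T", "T:A>G:C",
)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class GenomicVariant:
    """One genomic variant in 1-based coordinates; kind derived from alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"


@dataclass(frozen=True)
class WindowDensity:
    """Feature counts in one tiling window (1-based, closed interval)."""

    chrom: str
    start: int
    end: int
    counts: Mapping[str, int]


@dataclass(frozen=True)
class AssociationResult:
    spearman_rho: float
    pearson_r: float
    slope: float
    intercept: float
    r_squared: float


def snp_spectrum(variants: Sequence[GenomicVariant]) -> dict[str, int]:
    """Counts over the six strand-collapsed substitution types.

    Non-SNP records are filtered out (their count is returned under
    ``"non_snp_filtered"``); records with ambiguity-code bases are rejected
    with a warning (``"rejected"``).  SNP totals are conserved across bins.
    """
    counts: Counter[str] = Counter({b: 0 for b in SPECTRUM_BINS})
    counts["non_snp_filtered"] = 0
    counts["rejected"] = 0
    for v in variants:
        if v.kind != "SNP":
            counts["non_snp_filtered"] += 1
            continue
        ref, alt = v.ref, v.alt
        if ref not in _COMP or alt not in _COMP:
            log.warning("ambiguity code at %s:%d (%s>%s); rejected",
                        v.chrom, v.pos, ref, alt)
            counts["rejected"] += 1
            continue
        if ref in "AG":  # collapse onto the pyrimidine-context label
            ref, alt = _COMP[ref], _COMP[alt]
        counts[f"{ref}:{_COMP[ref]}>{alt}:{_COMP[alt]}"] += 1
    return dict(counts)


def indel_lengths(variants: Sequence[GenomicVariant]) -> dict[int, int]:
    """Histogram of signed indel lengths (positive = insertion)."""
    hist: Counter[int] = Counter()
    for v in variants:
        if v.kind == "SNP":
            continue
        net = len(v.alt) - len(v.ref)
        if net == 0:
            raise ValueError(f"zero-length indel at {v.chrom}:{v.pos}")
        hist[net] += 1
    return dict(sorted(hist.items()))


def windowed_density(
    features: Mapping[str, Mapping[str, Sequence[int]]],
    window_size: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[WindowDensity]:
    """Count features of each class in tiling windows along each chromosome.

    ``features`` maps feature class → chromosome → 1-based positions.  The
    chromosome length defaults to the largest observed position; the last
    window is truncated at the chromosome end.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    chroms = sorted({c for per in features.values() for c in per})
    if chrom_lengths:
        chroms = sorted(set(chroms) | set(chrom_lengths))
    out: list[WindowDensity] = []
    for chrom in chroms:
        length = 0
        if chrom_lengths and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        for per in features.values():
            if per.get(chrom):
                length = max(length, max(per[chrom]))
        n_win = max(1, -(-length // window_size))
        binned: dict[str, np.ndarray] = {}
        for cls, per in features.items():
            pos = np.asarray(per.get(chrom, []), dtype=int)
            if pos.size and (pos.min() < 1 or pos.max() > length):
                raise ValueError(f"feature position off chromosome {chrom}")
            binned[cls] = np.bincount((pos - 1) // window_size, minlength=n_win)
        for i in range(n_win):
            out.append(
                WindowDensity(
                    chrom=chrom,
                    start=i * window_size + 1,
                    end=min((i + 1) * window_size, length),
                    counts={cls: int(b[i]) for cls, b in binned.items()},
                )
            )
    return out


def density_association(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Spearman rho (mid-ranks), Pearson r, and OLS slope/intercept/R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rho = stats.spearmanr(x, y).statistic
    fit = stats.linregress(x, y)
    return AssociationResult(
        spearman_rho=float(rho),
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
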