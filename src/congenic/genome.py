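"""Genomic data model: intervals, genes, SNPs, donor regions, IBD blocks, binning.

Coordinates are 0-based, half-open throughout (BED convention). Strand is
stored on gene annotations but plays no role in any containment test; the
rules implemented here (donor-region membership, IBD membership, binning)
are purely positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

IBD_WINDOW = 10_000  # bp tiles anchored at coordinate 0
IBD_MIN_UNINFORMATIVE = 10  # uninformative SNPs per qualifying window

#: Category labels accepted by :func:`bin_gene_counts`, outermost first.
#: Each category must be a subset of the one before it.
BIN_CATEGORIES = ("all", "on_array", "expressed", "de")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus. ``start``/``end`` are the unstranded interval; ``tss``/``tes``
    are the same endpoints oriented by strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class SNPRecord:
    """A SNP position; ``informative`` means the two compared strains carry
    different alleles (an informative SNP is incompatible with IBD)."""

    chrom: str
    pos: int
    informative: bool

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"SNP position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class IBDBlock:
    interval: GenomicInterval
    n_uninformative: int


@dataclass(frozen=True)
class DonorRegion:
    """The introgressed donor interval of one congenic strain."""

    strain_id: str
    interval: GenomicInterval


def call_ibd_blocks(
    snps: Sequence[SNPRecord],
    chrom_length: int,
    window: int = IBD_WINDOW,
    min_uninformative: int = IBD_MIN_UNINFORMATIVE,
) -> list[IBDBlock]:
    """Call IBD blocks on one chromosome from a sorted SNP list.

    The chromosome is tiled into fixed non-overlapping ``window``-bp windows
    anchored at coordinate 0. A window qualifies iff it contains at least
    ``min_uninformative`` uninformative SNPs and *no* informative SNP; runs of
    adjacent qualifying windows are merged into single blocks.
    """
    if chrom_length <= 0:
        raise ValidationError("chrom_length must be positive")
    if not snps:
        return []
    chroms = {s.chrom for s in snps}
    if len(chroms) > 1:
        raise ValidationError(f"SNPs span multiple chromosomes: {sorted(chroms)}")
    pos = np.array([s.pos for s in snps])
    if np.any(np.diff(pos) < 0):
        raise ValidationError("SNPs must be sorted by position")
    informative = np.array([s.informative for s in snps], dtype=bool)

    n_windows = int(np.ceil(chrom_length / window))
    widx = np.minimum(pos // window, n_windows - 1)
    n_uninf = np.bincount(widx[~informative], minlength=n_windows)
    n_inf = np.bincount(widx[informative], minlength=n_windows)
    qualifies = (n_uninf >= min_uninformative) & (n_inf == 0)

    chrom = snps[0].chrom
    blocks: list[IBDBlock] = []
    i = 0
    while i < n_windows:
        if qualifies[i]:
            j = i
            while j + 1 < n_windows and qualifies[j + 1]:
                j += 1
            start = i * window
            end = min((j + 1) * window, chrom_length)
            blocks.append(
                IBDBlock(
                    GenomicInterval(chrom, start, end),
                    int(n_uninf[i : j + 1].sum()),
                )
            )
            i = j + 1
        else:
            i += 1
    return blocks


def gene_in_ibd(gene: GeneAnnotation, blocks: Sequence[IBDBlock]) -> bool:
    """True iff one single block contains both gene endpoints (TSS and TES)."""
    for b in blocks:
        if b.interval.chrom != gene.chrom:
            continue
        if b.interval.contains(gene.tss) and b.interval.contains(gene.tes):
            return True
    return False


def gene_in_region(gene: GeneAnnotation, region: GenomicInterval) -> bool:
    """True iff the gene interval is fully contained in ``region`` (containment,
    not overlap, mirroring the IBD membership rule)."""
    return region.contains_interval(gene.interval)


def bin_gene_counts(
    genes: Sequence[GeneAnnotation],
    categories: Mapping[str, Iterable[str]],
    region: GenomicInterval,
    width: int = 2_000_000,
) -> pd.DataFrame:
    """Count genes per fixed-width bin, per nested category.

    Bins tile ``region`` from its start; the last bin may be short. A gene is
    assigned to the bin containing its start coordinate. ``categories`` maps
    category name (a subset of :data:`BIN_CATEGORIES`) to an iterable of gene
    ids; categories must be nested (de ⊆ expressed ⊆ on_array ⊆ all). The
    "all" category defaults to every gene handed in.
    """
    if width <= 0:
        raise ValidationError("bin width must be positive")
    unknown = set(categories) - set(BIN_CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown categories: {sorted(unknown)}")
    sets = {name: set(ids) for name, ids in categories.items()}
    sets.setdefault("all", {g.gene_id for g in genes})
    present = [c for c in BIN_CATEGORIES if c in sets]
    for outer, inner in zip(present, present[1:]):
        if not sets[inner] <= sets[outer]:
            extra = sorted(sets[inner] - sets[outer])[:5]
            raise ValidationError(
                f"category '{inner}' is not nested in '{outer}': e.g. {extra}"
            )

    n_bins = int(np.ceil(region.length / width))
    edges = [
        (region.start + i * width, min(region.start + (i + 1) * width, region.end))
        for i in range(n_bins)
    ]
    counts = np.zeros((n_bins, len(present)), dtype=int)
    for g in genes:
        if g.chrom != region.chrom or not region.contains(g.start):
            continue
        b = (g.start - region.start) // width
        for j, cat in enumerate(present):
            if g.gene_id in sets[cat]:
                counts[b, j] += 1
    out = pd.DataFrame(counts, columns=present)
    out.insert(0, "bin_start", [e[0] for e in edges])
    out.insert(1, "bin_end", [e[1] for e in edges])
    return out


@dataclass(frozen=True)
class GeneticMap:
    """A monotone genetic↔physical map for one chromosome."""

    cM: np.ndarray = field()
    bp: np.ndarray = field()

    def __post_init__(self) -> None:
        cM = np.asarray(self.cM, dtype=float)
        bp = np.asarray(self.bp, dtype=float)
        object.__setattr__(self, "cM", cM)
        object.__setattr__(self, "bp", bp)
        if cM.size < 2 or cM.size != bp.size:
            raise ValidationError("map needs >= 2 paired points")
        if np.any(np.diff(cM) <= 0) or np.any(np.diff(bp) <= 0):
            raise ValidationError("map must be strictly increasing in cM and bp")


def genetic_to_physical(query_cM, gmap: GeneticMap):
    """Piecewise-linear interpolation of genetic position onto physical bp.

    Queries beyond the map ends clamp to the terminal points. Accepts a
    scalar or array of cM positions.
    """
    res = np.interp(np.asarray(query_cM, dtype=float), gmap.cM, gmap.bp)
    return float(res) if np.isscalar(query_cM) or np.ndim(query_cM) == 0 else res
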