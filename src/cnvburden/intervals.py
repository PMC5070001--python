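"""Genomic interval primitives and overlap arithmetic.

All coordinates are 0-based, half-open: an interval [start, end) on a named
chromosome covers ``end - start`` bases.  Readers for 1-based inclusive
formats (GFF3 and the hg19 convention of most array CNV reports) convert at
the I/O boundary, so everything in memory uses one unambiguous convention.

CNVs are strandless; strand fields in annotation inputs are ignored.

The two overlap statistics that drive the whole pipeline live here:

* :func:`reciprocal_overlap` — the symmetric min-fraction overlap used to
  decide whether two CNV calls describe "the same" variant (two calls match
  at reciprocal overlap >= 0.5 throughout the analysis);
* :func:`covered_fraction` — the fraction of a CNV lying inside a union of
  regions, used for the copy-number-stability filter (>= 75 % stable) and
  for known-locus annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneModel",
    "GeneIndex",
    "overlap_length",
    "reciprocal_overlap",
    "covered_fraction",
    "genes_hit",
    "merge_intervals",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by ``a`` and ``b`` (0 if disjoint or trans)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); symmetric, in [0, 1]."""
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) spans into a disjoint union."""
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


class IntervalSet:
    """A collection of intervals indexed per chromosome for overlap queries.

    Query results are defined to be identical to a brute-force scan of all
    members; the interval tree is purely an acceleration structure.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def __iter__(self) -> Iterator[GenomicInterval]:
        for tree in self._trees.values():
            for node in sorted(tree):
                yield node.data

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals sharing >= 1 bp with ``query``, sorted."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(query.start, query.end)]
        hits.sort()
        return hits

    def coverage_length(self, query: GenomicInterval) -> int:
        """Bases of ``query`` covered by the union of members (no double count)."""
        hits = self.overlapping(query)
        if not hits:
            return 0
        clipped = [
            (max(h.start, query.start), min(h.end, query.end)) for h in hits
        ]
        return sum(e - s for s, e in merge_intervals(clipped))


def covered_fraction(a: GenomicInterval, regions: IntervalSet) -> float:
    """Fraction of ``a``'s bases covered by the union of ``regions``."""
    if len(regions) == 0:
        return 0.0
    return regions.coverage_length(a) / a.length


@dataclass(frozen=True)
class GeneModel:
    """A gene with its coding exons.

    ``interval`` is the gene body span; ``exons`` are the coding exons used
    when intersection is restricted to protein-coding sequence.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(
                    f"exon of {self.gene_id} on {ex.chrom} but gene on "
                    f"{self.interval.chrom}"
                )


class GeneIndex:
    """Indexed gene models supporting body-level and exon-level hit queries."""

    def __init__(self, genes: Iterable[GeneModel]) -> None:
        self.genes: dict[str, GeneModel] = {}
        self._body_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            iv = g.interval
            self._body_trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, g.gene_id
            )
            for ex in g.exons:
                self._exon_trees.setdefault(ex.chrom, IntervalTree()).addi(
                    ex.start, ex.end, g.gene_id
                )

    def __len__(self) -> int:
        return len(self.genes)

    def genes_hit(
        self, a: GenomicInterval, coding_exons_only: bool = False
    ) -> set[str]:
        trees = self._exon_trees if coding_exons_only else self._body_trees
        tree = trees.get(a.chrom)
        if tree is None:
            return set()
        return {node.data for node in tree.overlap(a.start, a.end)}


def genes_hit(
    a: GenomicInterval,
    genes: GeneIndex | Iterable[GeneModel],
    coding_exons_only: bool = False,
) -> set[str]:
    """Identifiers of genes intersected by ``a``.

    With ``coding_exons_only`` a gene counts only if >= 1 bp of >= 1 coding
    exon intersects ``a``; otherwise any gene-body overlap counts.
    """
    if not isinstance(genes, GeneIndex):
        genes = GeneIndex(genes)
    return genes.genes_hit(a, coding_exons_only=coding_exons_only)
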