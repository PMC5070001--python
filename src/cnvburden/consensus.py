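"""Consensus ("stringent") CNV calling from multiple per-sample algorithms.

Array CNV callers disagree on both presence and breakpoints, so the pipeline
keeps only variants supported by at least two independent algorithms.  Two
calls from the same sample support the same variant when they have the same
type (DEL/DUP), come from *different* algorithms, and match at reciprocal
overlap >= 0.5; support is transitive (connected components of the match
relation).  A component becomes one stringent CNV iff it contains calls from
at least two distinct algorithms.

Boundary policy: the emitted interval is the intersection of the component's
member intervals when non-empty (conservative — avoids inflating the gene
content of borderline calls), otherwise the member with the most probes.
A ``boundary="union"`` mode is available for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .intervals import GenomicInterval, reciprocal_overlap

__all__ = ["CnvCall", "StringentCnv", "build_stringent_set", "summarize_consensus"]

CnvType = Literal["DEL", "DUP"]
_VALID_TYPES = ("DEL", "DUP")


@dataclass(frozen=True, order=True)
class CnvCall:
    """One CNV interval reported in one sample by one algorithm."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    n_probes: int
    algorithm: str
    platform: str

    def __post_init__(self) -> None:
        if self.cnv_type not in _VALID_TYPES:
            raise ValueError(f"cnv_type must be DEL or DUP, got {self.cnv_type!r}")
        if self.n_probes < 1:
            raise ValueError(f"n_probes must be >= 1, got {self.n_probes}")


@dataclass(frozen=True, order=True)
class StringentCnv:
    """A consensus CNV supported by >= 2 algorithms in one sample."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    n_probes: int
    supporting_algorithms: frozenset[str]
    platform: str

    def __post_init__(self) -> None:
        if len(self.supporting_algorithms) < 2:
            raise ValueError("a stringent CNV needs >= 2 supporting algorithms")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_stringent_set(
    calls: Iterable[CnvCall],
    ro_threshold: float = 0.5,
    boundary: Literal["intersection", "union"] = "intersection",
) -> list[StringentCnv]:
    """Merge one sample's per-algorithm calls into the stringent set.

    Parameters
    ----------
    calls
        All calls for a single sample (any algorithm mix); mixed sample ids
        raise ``ValueError``.
    ro_threshold
        Reciprocal-overlap threshold for two calls to support the same
        variant (default 0.5).
    boundary
        How to derive the consensus interval from a component:
        ``"intersection"`` (default, conservative) or ``"union"``.

    Returns
    -------
    Sorted list of :class:`StringentCnv`.  Output is independent of input
    order: calls are canonically sorted before component construction.
    """
    # Canonical sort makes union-find roots, and therefore output, order-stable.
    calls = sorted(calls)
    if not calls:
        return []
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(
            f"build_stringent_set expects one sample, got {sorted(sample_ids)}"
        )
    platforms = {c.platform for c in calls}
    if len(platforms) > 1:
        raise ValueError(
            f"build_stringent_set expects one platform, got {sorted(platforms)}"
        )

    uf = _UnionFind(len(calls))
    # Same type + different algorithm + RO >= threshold => mutual support.
    for i in range(len(calls)):
        a = calls[i]
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if a.cnv_type != b.cnv_type or a.algorithm == b.algorithm:
                continue
            if reciprocal_overlap(a.interval, b.interval) >= ro_threshold:
                uf.union(i, j)

    components: dict[int, list[CnvCall]] = {}
    for i, call in enumerate(calls):
        components.setdefault(uf.find(i), []).append(call)

    out: list[StringentCnv] = []
    for members in components.values():
        algos = {m.algorithm for m in members}
        if len(algos) < 2:
            continue
        out.append(_emit(members, algos, boundary))
    out.sort()
    return out


def _emit(
    members: Sequence[CnvCall], algorithms: set[str], boundary: str
) -> StringentCnv:
    chroms = {m.interval.chrom for m in members}
    if len(chroms) != 1:  # impossible via the RO relation; guard anyway
        raise AssertionError("consensus component spans chromosomes")
    chrom = chroms.pop()
    if boundary == "union":
        start = min(m.interval.start for m in members)
        end = max(m.interval.end for m in members)
    else:
        start = max(m.interval.start for m in members)
        end = min(m.interval.end for m in members)
        if end <= start:
            # Chained components can have an empty global intersection; fall
            # back to the best-supported single call (most probes, then sort).
            best = max(members, key=lambda m: (m.n_probes, m))
            start, end = best.interval.start, best.interval.end
    return StringentCnv(
        sample_id=members[0].sample_id,
        interval=GenomicInterval(chrom, start, end),
        cnv_type=members[0].cnv_type,
        n_probes=max(m.n_probes for m in members),
        supporting_algorithms=frozenset(algorithms),
        platform=members[0].platform,
    )


def summarize_consensus(
    calls: Sequence[CnvCall], stringent: Sequence[StringentCnv]
) -> dict:
    """Per-sample accounting of calls in vs consensus variants out.

    Every stringent variant corresponds to >= 2 input calls, so
    ``calls_in >= 2 * consensus_out`` whenever ``consensus_out > 0``.
    """
    per_algorithm: dict[str, int] = {}
    for c in calls:
        per_algorithm[c.algorithm] = per_algorithm.get(c.algorithm, 0) + 1
    return {
        "calls_in": len(calls),
        "consensus_out": len(stringent),
        "per_algorithm_in": dict(sorted(per_algorithm.items())),
        "min_supporting_calls": 2 * len(stringent),
    }
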