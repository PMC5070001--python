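"""De novo / inherited classification of proband CNVs in parent-child trios.

A proband CNV is matched against each parent's *stringent* (pre-rarity)
call set: a parent carries the variant iff that parent has a same-type call
at reciprocal overlap >= the threshold.  Matching against stringent rather
than rare-filtered parental calls prevents a parent's frequency-filtered
common variant from masquerading as absent and faking a de novo event.

Status vocabulary: ``de_novo`` (neither parent), ``maternal``, ``paternal``,
``biparental`` (both).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .consensus import StringentCnv
from .intervals import reciprocal_overlap

__all__ = ["Trio", "InheritanceCall", "classify_inheritance", "de_novo_rate"]

STATUSES = ("de_novo", "maternal", "paternal", "biparental")


@dataclass(frozen=True)
class Trio:
    proband_id: str
    mother_id: str
    father_id: str

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise ValueError(f"trio members must be distinct: {self}")


@dataclass(frozen=True)
class InheritanceCall:
    cnv: StringentCnv
    status: str
    matched_parent_calls: tuple[StringentCnv, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "de_novo") != (len(self.matched_parent_calls) == 0):
            raise ValueError("de_novo iff no matched parental calls")


def _parent_matches(
    cnv: StringentCnv,
    parent_calls: Sequence[StringentCnv],
    ro_threshold: float,
) -> list[StringentCnv]:
    return [
        p
        for p in sorted(parent_calls)
        if p.cnv_type == cnv.cnv_type
        and reciprocal_overlap(cnv.interval, p.interval) >= ro_threshold
    ]


def classify_inheritance(
    cnv: StringentCnv,
    mother_calls: Sequence[StringentCnv] | None,
    father_calls: Sequence[StringentCnv] | None,
    ro_threshold: float = 0.5,
) -> InheritanceCall:
    """Classify one proband CNV against both parents' stringent calls.

    ``None`` for either parent's call set means the trio is incomplete and
    raises — an empty list (parent genotyped, no CNVs called) is valid.
    """
    if mother_calls is None or father_calls is None:
        raise ValueError(
            f"incomplete trio for proband CNV {cnv.interval}: both parents' "
            "call sets are required"
        )
    mat = _parent_matches(cnv, mother_calls, ro_threshold)
    pat = _parent_matches(cnv, father_calls, ro_threshold)
    if mat and pat:
        status = "biparental"
    elif mat:
        status = "maternal"
    elif pat:
        status = "paternal"
    else:
        status = "de_novo"
    return InheritanceCall(cnv=cnv, status=status, matched_parent_calls=tuple(mat + pat))


def de_novo_rate(
    trios: Sequence[Trio],
    inheritance_calls: Mapping[str, Sequence[InheritanceCall]],
) -> tuple[float, int, int]:
    """Fraction of probands carrying >= 1 de novo CNV.

    The numerator counts probands, not events: a proband with two de novo
    CNVs counts once.  Returns ``(rate, n_probands_with_de_novo, n_trios)``;
    report the rate as a percentage to one decimal.
    """
    if not trios:
        raise ValueError("de_novo_rate requires >= 1 trio")
    carriers = 0
    for trio in trios:
        calls = inheritance_calls.get(trio.proband_id, ())
        if any(c.status == "de_novo" for c in calls):
            carriers += 1
    return carriers / len(trios), carriers, len(trios)
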