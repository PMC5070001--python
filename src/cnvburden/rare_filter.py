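"""Rarity and quality filtering of stringent CNVs.

The filter cascade reduces the stringent call set to rare, high-confidence
CNVs in four steps, applied in this order:

1. **frequency** — pooled frequency <= 0.5 % in a stratum of cases plus
   controls matched on ancestry, platform and sex, counting distinct
   subjects that carry a same-type CNV at reciprocal overlap >= 0.5
   (the carrier itself included, so a private variant has frequency 1/n);
2. **stability** — >= 75 % of the CNV's length lies within regions annotated
   copy-number stable in the supplied genome map;
3. **size** — length >= 15 kb;
4. **probes** — supported by >= 10 array probes.

The retained set is order-stable (each criterion is evaluated per CNV
independently); only the audit trail's "first failed filter" labels depend
on the order, which follows the cascade above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .consensus import StringentCnv
from .intervals import GenomicInterval, IntervalSet, covered_fraction, overlap_length, reciprocal_overlap

__all__ = [
    "FilterParams",
    "FrequencyPool",
    "build_pools",
    "cnv_frequency",
    "apply_filters",
    "annotate_known_loci",
]

STRATUM_FIELDS = ("ancestry", "platform", "sex")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the rare-CNV filter cascade (defaults per the analysis)."""

    max_frequency: float = 0.005
    ro_threshold: float = 0.5
    min_stable_fraction: float = 0.75
    min_length_bp: int = 15_000
    min_probes: int = 10

    def __post_init__(self) -> None:
        for name in ("max_frequency", "ro_threshold", "min_stable_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


class FrequencyPool:
    """Stringent CNVs from all subjects of one (ancestry, platform, sex) stratum.

    ``n_subjects`` counts every subject assigned to the stratum, including
    those contributing zero CNVs — the frequency denominator is subjects,
    not calls.
    """

    def __init__(
        self,
        stratum: tuple[str, str, str],
        members: Iterable[StringentCnv],
        subject_ids: Iterable[str],
    ) -> None:
        self.stratum = stratum
        self.members = sorted(members)
        self.subject_ids = frozenset(subject_ids)
        self.n_subjects = len(self.subject_ids)
        if self.n_subjects < 1:
            raise ValueError(f"pool {stratum} has no subjects")
        for m in self.members:
            if m.sample_id not in self.subject_ids:
                raise ValueError(
                    f"CNV of sample {m.sample_id} not in pool stratum {stratum}"
                )
        # (chrom, type) -> IntervalTree of member CNVs, for frequency queries.
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for m in self.members:
            key = (m.interval.chrom, m.cnv_type)
            self._trees.setdefault(key, IntervalTree()).addi(
                m.interval.start, m.interval.end, m
            )

    def carriers(self, cnv: StringentCnv, ro_threshold: float) -> set[str]:
        """Distinct pool subjects owning >= 1 same-type match of ``cnv``."""
        tree = self._trees.get((cnv.interval.chrom, cnv.cnv_type))
        if tree is None:
            return set()
        out: set[str] = set()
        for node in tree.overlap(cnv.interval.start, cnv.interval.end):
            other: StringentCnv = node.data
            if reciprocal_overlap(cnv.interval, other.interval) >= ro_threshold:
                out.add(other.sample_id)
        return out


def build_pools(
    stringent: Mapping[str, Sequence[StringentCnv]],
    manifest: pd.DataFrame,
) -> dict[tuple[str, str, str], FrequencyPool]:
    """One pool per (ancestry, platform, sex) stratum over cases and controls.

    Parameters
    ----------
    stringent
        sample_id -> that sample's stringent CNVs.  Samples absent from the
        mapping contribute zero CNVs but still count in their stratum's
        denominator.
    manifest
        Must contain sample_id, status, ancestry, platform, sex.  Only rows
        with status in {case, control} enter pools (trio parents do not).
    """
    required = {"sample_id", "status", *STRATUM_FIELDS}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    rows = manifest[manifest["status"].isin(["case", "control"])]
    for _, row in rows.iterrows():
        for f in STRATUM_FIELDS:
            v = row[f]
            if pd.isna(v) or v == "":
                raise ValueError(f"sample {row['sample_id']} missing {f}")
    strata: dict[tuple[str, str, str], list[str]] = {}
    for _, row in rows.iterrows():
        key = tuple(str(row[f]) for f in STRATUM_FIELDS)
        strata.setdefault(key, []).append(str(row["sample_id"]))
    pools = {}
    for key, samples in sorted(strata.items()):
        members = [m for s in samples for m in stringent.get(s, ())]
        pools[key] = FrequencyPool(key, members, samples)
    return pools


def pool_for_sample(
    pools: Mapping[tuple[str, str, str], FrequencyPool], sample_id: str
) -> FrequencyPool:
    for pool in pools.values():
        if sample_id in pool.subject_ids:
            return pool
    raise KeyError(f"sample {sample_id} not assigned to any pool")


def cnv_frequency(
    cnv: StringentCnv, pool: FrequencyPool, ro_threshold: float = 0.5
) -> float:
    """Pooled subject frequency of ``cnv`` (always >= 1/n: self counts)."""
    if cnv.sample_id not in pool.subject_ids:
        raise ValueError(
            f"CNV sample {cnv.sample_id} not in pool stratum {pool.stratum}"
        )
    carriers = pool.carriers(cnv, ro_threshold)
    carriers.add(cnv.sample_id)
    return len(carriers) / pool.n_subjects


def apply_filters(
    stringent: Mapping[str, Sequence[StringentCnv]],
    pools: Mapping[tuple[str, str, str], FrequencyPool],
    stable_map: IntervalSet,
    params: FilterParams = FilterParams(),
) -> tuple[dict[str, list[StringentCnv]], pd.DataFrame]:
    """Run the frequency -> stability -> size -> probes cascade.

    Returns
    -------
    (rare, audit)
        ``rare`` maps sample_id to its retained CNVs; ``audit`` has one row
        per input CNV with the measured statistics and the first failed
        filter (empty string when retained).
    """
    if stable_map is None:
        raise ValueError("a copy-number-stability map is required")
    sample_pool = {
        s: pool for pool in pools.values() for s in pool.subject_ids
    }
    rare: dict[str, list[StringentCnv]] = {}
    records = []
    for sample_id in sorted(stringent):
        pool = sample_pool.get(sample_id)
        if pool is None:
            raise KeyError(f"sample {sample_id} not assigned to any pool")
        for cnv in sorted(stringent[sample_id]):
            freq = cnv_frequency(cnv, pool, params.ro_threshold)
            stable = covered_fraction(cnv.interval, stable_map)
            failed = ""
            if freq > params.max_frequency:
                failed = "frequency"
            elif stable < params.min_stable_fraction:
                failed = "stability"
            elif cnv.interval.length < params.min_length_bp:
                failed = "size"
            elif cnv.n_probes < params.min_probes:
                failed = "probes"
            if not failed:
                rare.setdefault(sample_id, []).append(cnv)
            records.append(
                {
                    "sample_id": sample_id,
                    "chrom": cnv.interval.chrom,
                    "start": cnv.interval.start,
                    "end": cnv.interval.end,
                    "cnv_type": cnv.cnv_type,
                    "length_bp": cnv.interval.length,
                    "n_probes": cnv.n_probes,
                    "frequency": freq,
                    "stable_fraction": stable,
                    "retained": not failed,
                    "failed_filter": failed,
                }
            )
    audit = pd.DataFrame.from_records(
        records,
        columns=[
            "sample_id", "chrom", "start", "end", "cnv_type", "length_bp",
            "n_probes", "frequency", "stable_fraction", "retained",
            "failed_filter",
        ],
    )
    return rare, audit


def annotate_known_loci(
    rare_cnvs: Mapping[str, Sequence[StringentCnv]],
    loci: Sequence[tuple[str, GenomicInterval]],
) -> pd.DataFrame:
    """Overlap of each rare CNV with curated genomic-disorder loci.

    Any overlap (>= 1 bp) is reported, together with the fraction of the
    locus covered by the CNV and the fraction of the CNV covered by the
    locus; downstream exclusion re-runs consume these fractions rather than
    a hard-coded rule.
    """
    trees: dict[str, IntervalTree] = {}
    for label, iv in loci:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (label, iv))
    records = []
    for sample_id in sorted(rare_cnvs):
        for cnv in sorted(rare_cnvs[sample_id]):
            tree = trees.get(cnv.interval.chrom)
            if tree is None:
                continue
            for node in sorted(tree.overlap(cnv.interval.start, cnv.interval.end)):
                label, locus = node.data
                ov = overlap_length(cnv.interval, locus)
                records.append(
                    {
                        "sample_id": sample_id,
                        "chrom": cnv.interval.chrom,
                        "start": cnv.interval.start,
                        "end": cnv.interval.end,
                        "cnv_type": cnv.cnv_type,
                        "locus": label,
                        "locus_fraction_covered": ov / locus.length,
                        "cnv_fraction_covered": ov / cnv.interval.length,
                    }
                )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "sample_id", "chrom", "start", "end", "cnv_type", "locus",
            "locus_fraction_covered", "cnv_fraction_covered",
        ],
    )
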