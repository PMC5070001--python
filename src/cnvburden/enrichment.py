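"""Gene-set burden enrichment with BH FDR and a known-loci-excluded re-run.

For each gene set the per-subject statistic is the number of *distinct* set
genes with >= 1 coding exon impacted by the subject's rare CNVs of a given
class (DEL, DUP, or both).  The test is a binomial logistic regression
deviance test: case status is modelled on the set count, corrected for the
subject's total CNV gene count (global burden — a penalty for large CNVs
that would otherwise drive every set) and for genotyping platform as a
categorical covariate.  Descriptive odds ratios compare subjects with
exactly one and with two-or-more set genes hit against subjects with none,
from a categorical variant of the same model.

The whole analysis runs twice: once on all rare CNVs and once after
excluding CNVs falling in curated neurodevelopmental/genomic-disorder loci,
to show whether a signal is driven by already-recognized regions.  BH
q-values are computed within each (CNV class, loci-exclusion) family across
gene sets; sets that are untestable (set count constant in the cohort) are
excluded from the family size m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import StringentCnv
from .intervals import GeneIndex
from .logistic import deviance_test

__all__ = [
    "GeneSet",
    "subject_set_count",
    "enrichment_test",
    "bh_fdr",
    "run_enrichment_suite",
    "FDR_TIERS",
]

# Named significance tiers: the primary threshold and the relaxed one.
FDR_TIERS = {"strict": 0.15, "relaxed": 0.275}

CNV_CLASSES = ("both", "DEL", "DUP")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")

    @property
    def size(self) -> int:
        return len(self.genes)


def subject_set_count(
    cnvs: Sequence[StringentCnv],
    gene_set: GeneSet,
    genes: GeneIndex,
    cnv_class: str = "both",
) -> int:
    """Distinct set genes with >= 1 coding exon hit by the subject's CNVs.

    ``cnv_class`` restricts to DEL or DUP events; ``"both"`` uses all.
    Multiple CNVs hitting the same gene count it once.
    """
    hit: set[str] = set()
    for cnv in cnvs:
        if cnv_class != "both" and cnv.cnv_type != cnv_class:
            continue
        hit |= genes.genes_hit(cnv.interval, coding_exons_only=True)
    return len(hit & gene_set.genes)


@dataclass
class EnrichmentResult:
    """Per gene-set test output for one (CNV class, loci-exclusion) arm."""

    set_name: str
    set_size: int
    cnv_class: str
    loci_excluded: bool
    p_value: float
    odds_ratio: float  # per unit set-count
    or_one_hit: float  # count == 1 vs count == 0, descriptive
    or_two_plus: float  # count >= 2 vs count == 0, descriptive
    q_value: float = np.nan
    testable: bool = True
    note: str = ""


def enrichment_test(
    set_counts: Sequence[int],
    total_gene_counts: Sequence[int],
    platforms: Sequence[str],
    case_status: Sequence[int],
) -> dict:
    """Deviance test of one gene set's per-subject count.

    Full model: case ~ set_count + total_gene_count + platform (categorical);
    the reduced model drops set_count; p from a 1-df chi-square on the
    deviance difference.  Returns a dict with the nominal p, the per-unit
    odds ratio, the descriptive ORs for one and two-plus set genes hit, and
    a testable flag with diagnostic note.
    """
    counts = np.asarray(set_counts, dtype=float)
    y = np.asarray(case_status, dtype=int)
    X = pd.DataFrame({"set_count": counts,
                      "total_gene_count": np.asarray(total_gene_counts, float)})
    plat = pd.Series(list(platforms), dtype="object")
    if plat.nunique() > 1:
        dummies = pd.get_dummies(plat, prefix="platform", drop_first=True, dtype=float)
        X = pd.concat([X, dummies.set_axis(X.index)], axis=1)
    if counts.max() == counts.min():
        return {
            "p_value": np.nan, "odds_ratio": np.nan,
            "or_one_hit": np.nan, "or_two_plus": np.nan,
            "testable": False, "note": "set never hit (constant count)",
        }
    res = deviance_test(y, X, "set_count")
    out = {
        "p_value": res.p_value,
        "odds_ratio": res.odds_ratio,
        "testable": res.ok,
        "note": res.note,
    }
    # Descriptive ORs from the categorical variant of the model.
    one = (counts == 1).astype(float)
    two = (counts >= 2).astype(float)
    Xc = X.drop(columns=["set_count"])
    or1 = or2 = np.nan
    cat_cols = []
    if one.max() > 0:
        Xc = Xc.assign(hit_one=one)
        cat_cols.append("hit_one")
    if two.max() > 0:
        Xc = Xc.assign(hit_two_plus=two)
        cat_cols.append("hit_two_plus")
    if cat_cols:
        cres = deviance_test(y, Xc, cat_cols)
        if cres.ok:
            or1 = float(np.exp(cres.coef["hit_one"])) if "hit_one" in cres.coef else np.nan
            or2 = (
                float(np.exp(cres.coef["hit_two_plus"]))
                if "hit_two_plus" in cres.coef else np.nan
            )
    out["or_one_hit"] = or1
    out["or_two_plus"] = or2
    return out


def bh_fdr(nominal_ps: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    q_i = min over ranks j >= rank(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(nominal_ps, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_enrichment_suite(
    rare_cnvs: Mapping[str, Sequence[StringentCnv]],
    gene_sets: Sequence[GeneSet],
    genes: GeneIndex,
    manifest: pd.DataFrame,
    loci_annotations: pd.DataFrame | None = None,
    cnv_classes: Sequence[str] = CNV_CLASSES,
    exclusion_cnv_fraction: float = 0.5,
) -> pd.DataFrame:
    """Full gene-set enrichment table.

    One row per gene set x CNV class x {with loci, loci excluded}; q-values
    computed within each (class, exclusion) family.  The loci-excluded arm
    drops every CNV whose fraction covered by a curated locus is >= the
    ``exclusion_cnv_fraction`` threshold (annotations come from
    :func:`cnvburden.rare_filter.annotate_known_loci`).  Per-set failures
    (never hit, separation) are flagged in-row; the suite never aborts.
    """
    cohort = manifest[manifest["status"].isin(["case", "control"])]
    samples = [str(s) for s in cohort["sample_id"]]
    y = (cohort["status"] == "case").astype(int).to_numpy()
    platforms = [str(p) for p in cohort["platform"]]

    excluded_keys: set[tuple] = set()
    if loci_annotations is not None and len(loci_annotations):
        mask = loci_annotations["cnv_fraction_covered"] >= exclusion_cnv_fraction
        excluded_keys = {
            (r.sample_id, r.chrom, r.start, r.end, r.cnv_type)
            for r in loci_annotations[mask].itertuples()
        }

    def cnvs_for(sample: str, exclude_loci: bool) -> list[StringentCnv]:
        out = []
        for cnv in rare_cnvs.get(sample, ()):
            key = (cnv.sample_id, cnv.interval.chrom, cnv.interval.start,
                   cnv.interval.end, cnv.cnv_type)
            if exclude_loci and key in excluded_keys:
                continue
            out.append(cnv)
        return out

    rows = []
    for exclude in (False, True):
        per_sample = {s: cnvs_for(s, exclude) for s in samples}
        for cnv_class in cnv_classes:
            # Global burden covariate: total CNV gene count per subject,
            # coding-exon based, for the same CNV class.
            totals = []
            for s in samples:
                hit: set[str] = set()
                for cnv in per_sample[s]:
                    if cnv_class != "both" and cnv.cnv_type != cnv_class:
                        continue
                    hit |= genes.genes_hit(cnv.interval, coding_exons_only=True)
                totals.append(len(hit))
            for gs in gene_sets:
                counts = [
                    subject_set_count(per_sample[s], gs, genes, cnv_class)
                    for s in samples
                ]
                res = enrichment_test(counts, totals, platforms, y)
                rows.append(
                    {
                        "set": gs.name,
                        "set_size": gs.size,
                        "cnv_class": cnv_class,
                        "loci_excluded": exclude,
                        "n_carriers": int(np.count_nonzero(counts)),
                        "p_value": res["p_value"],
                        "odds_ratio": res["odds_ratio"],
                        "or_one_hit": res["or_one_hit"],
                        "or_two_plus": res["or_two_plus"],
                        "testable": res["testable"],
                        "note": res["note"],
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["set", "set_size", "cnv_class", "loci_excluded", "n_carriers",
                 "p_value", "odds_ratio", "or_one_hit", "or_two_plus",
                 "testable", "note"],
    )
    if len(table) == 0:
        table["q_value"] = pd.Series(dtype=float)
        return table
    table["q_value"] = np.nan
    for (_, _), idx in table.groupby(["cnv_class", "loci_excluded"]).groups.items():
        sub = table.loc[idx]
        testable = sub[sub["testable"]].index
        if len(testable):
            table.loc[testable, "q_value"] = bh_fdr(
                table.loc[testable, "p_value"].to_numpy()
            )
    return table
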