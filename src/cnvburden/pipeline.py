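"""End-to-end orchestration of the rare-CNV case-control analysis.

Stage order follows the analysis design: consensus calling per sample,
frequency/stability/size/probe filtering against matched pools, trio
inheritance classification, global and size-stratified burden tests, and
gene-set enrichment with the known-loci-excluded re-run.  Every stage logs
records in / out / filtered so count conservation can be audited, and all
output tables carry the config hash and seed in their header.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as cio
from .burden import burden_table, burden_test, stratified_burden_table, summarize_subject
from .consensus import StringentCnv, build_stringent_set
from .enrichment import FDR_TIERS, run_enrichment_suite
from .intervals import GeneIndex, GeneModel, GenomicInterval, IntervalSet
from .rare_filter import FilterParams, annotate_known_loci, apply_filters, build_pools
from .trio import Trio, classify_inheritance, de_novo_rate

logger = logging.getLogger("cnvburden")

__all__ = ["RunConfig", "PipelineResult", "analyze_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """File locations and analysis parameters for a pipeline run."""

    calls: str
    manifest: str
    genes: str
    gene_sets: str
    stable_map: str
    out_dir: str
    trios: str | None = None
    known_loci: str | None = None
    one_based: bool = False
    seed: int | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    fdr_tiers: Mapping[str, float] = field(default_factory=lambda: dict(FDR_TIERS))
    cnv_classes: Sequence[str] = ("both", "DEL", "DUP")
    exclusion_cnv_fraction: float = 0.5
    boundary: str = "intersection"
    burden_coding_exons_only: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fp = raw.pop("filter_params", None)
        cfg = cls(**raw)
        if fp:
            cfg.filter_params = FilterParams(**fp)
        return cfg

    def validate(self) -> None:
        for name in ("calls", "manifest", "genes", "gene_sets", "stable_map",
                     "trios", "known_loci"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for tier, thr in self.fdr_tiers.items():
            if not (0 < thr < 1):
                raise ValueError(f"FDR tier {tier} threshold out of (0,1): {thr}")

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["filter_params"] = dataclasses.asdict(self.filter_params)
        return cio.config_hash({k: str(v) for k, v in d.items()})


@dataclass
class PipelineResult:
    stringent: dict[str, list[StringentCnv]]
    rare: dict[str, list[StringentCnv]]
    audit: pd.DataFrame
    loci_annotations: pd.DataFrame
    inheritance: pd.DataFrame
    de_novo: tuple[float, int, int] | None
    burden_subjects: pd.DataFrame
    burden_global: object
    burden_strata: pd.DataFrame
    enrichment: pd.DataFrame
    stage_counts: dict[str, dict[str, int]]


def analyze_cohort(
    calls: pd.DataFrame,
    manifest: pd.DataFrame,
    genes: Sequence[GeneModel],
    gene_sets,
    stable_map: IntervalSet,
    trios: pd.DataFrame | None = None,
    known_loci: Sequence[tuple[str, GenomicInterval]] = (),
    params: FilterParams = FilterParams(),
    cnv_classes: Sequence[str] = ("both", "DEL", "DUP"),
    exclusion_cnv_fraction: float = 0.5,
    boundary: str = "intersection",
    burden_coding_exons_only: bool = False,
) -> PipelineResult:
    """Run every analysis stage on an in-memory cohort."""
    cio.validate_cohort(calls, manifest, trios)
    gene_index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    stage_counts: dict[str, dict[str, int]] = {}

    # 1. consensus, per sample
    per_sample_calls = cio.calls_to_objects(calls)
    stringent = {
        s: build_stringent_set(cs, ro_threshold=params.ro_threshold, boundary=boundary)
        for s, cs in sorted(per_sample_calls.items())
    }
    stringent = {s: v for s, v in stringent.items() if v}
    n_in = int(len(calls))
    n_out = sum(len(v) for v in stringent.values())
    stage_counts["consensus"] = {"records_in": n_in, "records_out": n_out,
                                 "records_filtered": n_in - n_out}
    logger.info("consensus: %d calls -> %d stringent CNVs", n_in, n_out)

    # 2. rarity filtering on the case/control cohort
    cohort_ids = set(
        manifest.loc[manifest["status"].isin(["case", "control"]), "sample_id"].astype(str)
    )
    cohort_stringent = {s: v for s, v in stringent.items() if s in cohort_ids}
    pools = build_pools(cohort_stringent, manifest)
    rare, audit = apply_filters(cohort_stringent, pools, stable_map, params)
    n_in = sum(len(v) for v in cohort_stringent.values())
    n_out = sum(len(v) for v in rare.values())
    stage_counts["rare_filter"] = {"records_in": n_in, "records_out": n_out,
                                   "records_filtered": n_in - n_out}
    logger.info("rare filter: %d stringent -> %d rare CNVs", n_in, n_out)

    loci_annotations = annotate_known_loci(rare, list(known_loci))

    # 3. trio inheritance on proband rare CNVs vs parental stringent calls
    inheritance_rows = []
    dn = None
    if trios is not None and len(trios):
        trio_objs = [
            Trio(str(r.proband_id), str(r.mother_id), str(r.father_id))
            for r in trios.itertuples()
        ]
        inh_by_proband: dict[str, list] = {}
        for t in trio_objs:
            mother_calls = stringent.get(t.mother_id, [])
            father_calls = stringent.get(t.father_id, [])
            for cnv in rare.get(t.proband_id, []):
                ic = classify_inheritance(
                    cnv, mother_calls, father_calls, params.ro_threshold
                )
                inh_by_proband.setdefault(t.proband_id, []).append(ic)
                inheritance_rows.append(
                    {
                        "proband_id": t.proband_id,
                        "chrom": cnv.interval.chrom,
                        "start": cnv.interval.start,
                        "end": cnv.interval.end,
                        "type": cnv.cnv_type,
                        "cnv_source": {
                            "de_novo": "de novo", "maternal": "mat",
                            "paternal": "pat", "biparental": "biparental",
                        }[ic.status],
                    }
                )
        dn = de_novo_rate(trio_objs, inh_by_proband)
        logger.info("de novo: %d/%d probands (%.1f%%)", dn[1], dn[2], 100 * dn[0])
    inheritance = pd.DataFrame(
        inheritance_rows,
        columns=["proband_id", "chrom", "start", "end", "type", "cnv_source"],
    )

    # 4. burden
    cohort = manifest[manifest["status"].isin(["case", "control"])]
    burdens = [
        summarize_subject(
            str(r.sample_id), r.status == "case", rare.get(str(r.sample_id), []),
            gene_index, coding_exons_only=burden_coding_exons_only,
        )
        for r in cohort.itertuples()
    ]
    burden_subjects = burden_table(burdens)
    burden_global = burden_test(burden_subjects)
    burden_strata = stratified_burden_table(burden_subjects)

    # 5. gene-set enrichment (+ known-loci-excluded re-run)
    enrichment = run_enrichment_suite(
        rare, list(gene_sets), gene_index, manifest,
        loci_annotations=loci_annotations,
        cnv_classes=cnv_classes,
        exclusion_cnv_fraction=exclusion_cnv_fraction,
    )

    return PipelineResult(
        stringent=stringent,
        rare=rare,
        audit=audit,
        loci_annotations=loci_annotations,
        inheritance=inheritance,
        de_novo=dn,
        burden_subjects=burden_subjects,
        burden_global=burden_global,
        burden_strata=burden_strata,
        enrichment=enrichment,
        stage_counts=stage_counts,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based pipeline run: read, validate, analyze, write all tables."""
    config.validate()
    calls = cio.read_calls(config.calls, one_based=config.one_based)
    manifest = cio.read_manifest(config.manifest)
    trios = cio.read_trios(config.trios) if config.trios else None
    genes = cio.read_gff3_genes(config.genes)
    gene_sets = cio.read_gmt(config.gene_sets)
    stable_map = cio.read_bed_intervals(config.stable_map)
    known_loci = cio.read_bed(config.known_loci) if config.known_loci else []

    result = analyze_cohort(
        calls, manifest, genes, gene_sets, stable_map,
        trios=trios, known_loci=known_loci, params=config.filter_params,
        cnv_classes=config.cnv_classes,
        exclusion_cnv_fraction=config.exclusion_cnv_fraction,
        boundary=config.boundary,
        burden_coding_exons_only=config.burden_coding_exons_only,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    cio.write_stringent(result.stringent, out / "stringent.tsv", meta)
    cio.write_stringent(result.rare, out / "rare.tsv", meta)
    cio.write_table(result.audit, out / "filter_audit.tsv", meta)
    cio.write_table(result.loci_annotations, out / "known_loci_overlap.tsv", meta)
    cio.write_table(result.inheritance, out / "inheritance.tsv", meta)
    cio.write_table(result.burden_subjects, out / "burden_subjects.tsv", meta)
    cio.write_table(result.burden_strata, out / "burden_strata.tsv", meta)
    cio.write_table(result.enrichment, out / "enrichment.tsv", meta)
    counts = pd.DataFrame(
        [{"stage": k, **v} for k, v in result.stage_counts.items()]
    )
    cio.write_table(counts, out / "stage_counts.tsv", meta)
    return result
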