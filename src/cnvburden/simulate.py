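"""Synthetic CNV cohorts with the statistical structure the analysis assumes.

The generator emulates a case-control microarray CNV study: a genome of
non-overlapping genes with coding exons, a copy-number-stability map,
curated known loci, per-algorithm call tables with breakpoint jitter and
dropout, polymorphic loci segregating above the rarity threshold, trios
with Mendelian transmission and de novo events, and a planted case
enrichment in one gene set.  Defaults mirror the cohort structure the
pipeline was designed for: 259 cases / 1773 controls of one ancestry,
174 trios, ~2.8 rare CNVs per subject, a 2.3 % per-proband de novo
probability, and an 840-gene target set with planted odds 1.75.

Every planted fact is recorded in a truth ledger so each pipeline stage can
be scored (``truth_compare``).  A fixed seed reproduces the full output
bit-for-bit.

``simulate_count_table`` is the simulator's count-level statistical kernel:
it draws per-subject gene-set counts, global gene counts, platform and case
status directly from the same distributional assumptions, without building
a genome, so calibration and power studies over hundreds of replicates stay
cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .consensus import CnvCall, StringentCnv
from .intervals import GeneIndex, GeneModel, GenomicInterval, IntervalSet, reciprocal_overlap
from .enrichment import GeneSet

__all__ = [
    "SimulationConfig",
    "Genome",
    "SimulatedCohort",
    "simulate_genome",
    "simulate_cohort",
    "simulate_count_table",
    "simulate_burden_table",
    "truth_compare",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the emulated study design."""

    n_cases: int = 259
    n_controls: int = 1773
    n_trios: int = 174  # trio probands are the first n_trios cases
    platforms: tuple[str, ...] = ("cytoscan_hd", "omni25")
    platform_mix: tuple[float, ...] = (0.7, 0.3)
    probe_spacing_bp: Mapping[str, int] = field(
        default_factory=lambda: {"cytoscan_hd": 1100, "omni25": 1200}
    )
    ancestry: str = "EUR"
    mean_cnvs_per_subject: float = 2.8
    size_range_bp: tuple[int, int] = (15_000, 3_000_000)  # log-uniform
    del_fraction: float = 0.5
    # Genome layout.
    n_chromosomes: int = 3
    genome_size_bp: int = 300_000_000
    n_genes: int = 3000
    gene_length_bp: int = 10_000
    exons_per_gene: int = 8
    stable_fraction: float = 0.85
    n_known_loci: int = 5
    known_locus_genes: int = 10
    # Gene sets; the target set carries the planted enrichment.
    gene_set_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "fmrp_targets": 840,
            "nervous_system_dev": 600,
            "synaptic": 400,
            "ion_channels": 250,
            "chromatin": 500,
            "metabolic": 700,
        }
    )
    target_set: str = "fmrp_targets"
    enrichment_odds: float = 1.75  # omega; 1.0 = null
    # Polymorphic (common) loci.
    n_polymorphic_loci: int = 8
    polymorphic_freq_range: tuple[float, float] = (0.01, 0.04)
    polymorphic_size_range_bp: tuple[int, int] = (50_000, 200_000)
    # Trio structure.
    transmission_prob: float = 0.5
    de_novo_prob: float = 0.023
    # Call emission.
    algorithms: tuple[str, ...] = ("algA", "algB", "algC")
    jitter_bp: int = 500
    dropout: float = 0.1
    # Background events are resampled until unique (no same-type match at
    # RO >= 0.5 anywhere in the cohort), so planted rarity labels are exact.
    enforce_unique_background: bool = True

    def __post_init__(self) -> None:
        probs = [
            self.del_fraction, self.transmission_prob, self.de_novo_prob,
            self.dropout, self.stable_fraction, *self.platform_mix,
            *self.polymorphic_freq_range,
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.platform_mix) - 1) > 1e-9:
            raise ValueError("platform_mix must sum to 1")
        if self.n_trios > self.n_cases:
            raise ValueError("n_trios cannot exceed n_cases")
        if self.enrichment_odds < 1:
            raise ValueError("enrichment_odds must be >= 1")
        if self.target_set not in self.gene_set_sizes:
            raise ValueError(f"target_set {self.target_set!r} not among gene sets")
        if max(self.gene_set_sizes.values()) > self.n_genes:
            raise ValueError("a gene set is larger than the gene catalog")


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    gene_index: GeneIndex
    gene_sets: list[GeneSet]
    target_set: str
    stable_map: IntervalSet
    known_loci: list[tuple[str, GenomicInterval]]

    @property
    def target_genes(self) -> frozenset[str]:
        for gs in self.gene_sets:
            if gs.name == self.target_set:
                return gs.genes
        raise KeyError(self.target_set)


@dataclass
class SimulatedCohort:
    calls: pd.DataFrame          # per-algorithm CnvCall rows
    manifest: pd.DataFrame       # sample_id, status, sex, ancestry, platform, family_id, role
    trios: pd.DataFrame          # proband_id, mother_id, father_id
    truth: pd.DataFrame          # one row per planted CNV
    polymorphic_loci: pd.DataFrame
    seed: int | None = None


def simulate_genome(config: SimulationConfig, rng: np.random.Generator) -> Genome:
    """Gene models, stability map and known loci for a synthetic genome."""
    chrom_sizes = {
        f"chr{i + 1}": config.genome_size_bp // config.n_chromosomes
        for i in range(config.n_chromosomes)
    }
    chroms = list(chrom_sizes)
    genes: list[GeneModel] = []
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    gid = 0
    for chrom, n_on_chrom in zip(chroms, per_chrom):
        if n_on_chrom == 0:
            continue
        slot = chrom_sizes[chrom] // n_on_chrom
        if slot < config.gene_length_bp:
            raise ValueError(
                f"infeasible packing: {n_on_chrom} genes of "
                f"{config.gene_length_bp} bp on a {chrom_sizes[chrom]} bp chromosome"
            )
        for i in range(n_on_chrom):
            start = i * slot + int(rng.integers(0, slot - config.gene_length_bp + 1))
            genes.append(_make_gene(f"gene_{gid:05d}", chrom, start, config))
            gid += 1

    gene_ids = [g.gene_id for g in genes]
    gene_sets = []
    for name, size in config.gene_set_sizes.items():
        members = rng.choice(gene_ids, size=size, replace=False)
        gene_sets.append(GeneSet(name=name, genes=frozenset(members.tolist())))

    stable_map = _simulate_stable_map(config, chrom_sizes, rng)
    known_loci = _simulate_known_loci(config, genes, rng)
    return Genome(
        chrom_sizes=chrom_sizes,
        genes=genes,
        gene_index=GeneIndex(genes),
        gene_sets=gene_sets,
        target_set=config.target_set,
        stable_map=stable_map,
        known_loci=known_loci,
    )


def _make_gene(gene_id: str, chrom: str, start: int, config: SimulationConfig) -> GeneModel:
    length = config.gene_length_bp
    n_ex = config.exons_per_gene
    pitch = length // n_ex
    ex_len = max(1, pitch // 2)
    exons = tuple(
        GenomicInterval(chrom, start + k * pitch, start + k * pitch + ex_len)
        for k in range(n_ex)
    )
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, start + length),
        exons=exons,
    )


def _simulate_stable_map(
    config: SimulationConfig, chrom_sizes: dict[str, int], rng: np.random.Generator
) -> IntervalSet:
    # Tile each chromosome; a random subset of tiles is "variable", the rest
    # (merged) form the copy-number-stable map.
    tile = 200_000
    out = IntervalSet()
    for chrom, size in chrom_sizes.items():
        n_tiles = size // tile
        n_unstable = int(round((1 - config.stable_fraction) * n_tiles))
        unstable = set(
            rng.choice(n_tiles, size=n_unstable, replace=False).tolist()
        ) if n_unstable else set()
        run_start = None
        for t in range(n_tiles + 1):
            stable_tile = t < n_tiles and t not in unstable
            if stable_tile and run_start is None:
                run_start = t * tile
            elif not stable_tile and run_start is not None:
                out.add(GenomicInterval(chrom, run_start, t * tile))
                run_start = None
        if size % tile and n_tiles * tile < size:
            out.add(GenomicInterval(chrom, n_tiles * tile, size))
    return out


def _simulate_known_loci(
    config: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator
) -> list[tuple[str, GenomicInterval]]:
    loci = []
    if config.n_known_loci == 0 or not genes:
        return loci
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for i in range(config.n_known_loci):
        chrom = list(by_chrom)[int(rng.integers(0, len(by_chrom)))]
        row = by_chrom[chrom]
        span = min(config.known_locus_genes, len(row))
        j = int(rng.integers(0, len(row) - span + 1))
        start = max(0, row[j].interval.start - 5_000)
        end = row[j + span - 1].interval.end + 5_000
        loci.append((f"locus_{i + 1:02d}", GenomicInterval(chrom, start, end)))
    return loci


class _UniquenessPool:
    """Tracks drawn background CNVs so new draws can be kept mutually unique."""

    def __init__(self) -> None:
        self._trees: dict[tuple[str, str], IntervalTree] = {}

    def matches(self, iv: GenomicInterval, cnv_type: str) -> bool:
        tree = self._trees.get((iv.chrom, cnv_type))
        if tree is None:
            return False
        return any(
            reciprocal_overlap(iv, GenomicInterval(iv.chrom, n.begin, n.end)) >= 0.5
            for n in tree.overlap(iv.start, iv.end)
        )

    def add(self, iv: GenomicInterval, cnv_type: str) -> None:
        self._trees.setdefault((iv.chrom, cnv_type), IntervalTree()).addi(
            iv.start, iv.end
        )


def _draw_background_cnv(
    rng: np.random.Generator,
    genome: Genome,
    config: SimulationConfig,
    enriched: bool,
    pool: _UniquenessPool | None,
) -> tuple[GenomicInterval, str]:
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    lo, hi = config.size_range_bp
    target = genome.target_genes if enriched and config.enrichment_odds > 1 else None
    for _ in range(1000):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        length = min(length, genome.chrom_sizes[chrom] - 1)
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - length))
        iv = GenomicInterval(chrom, start, start + length)
        cnv_type = "DEL" if rng.random() < config.del_fraction else "DUP"
        if pool is not None and pool.matches(iv, cnv_type):
            continue
        if target is not None:
            hits_target = bool(
                genome.gene_index.genes_hit(iv, coding_exons_only=True) & target
            )
            # Accept hits outright, non-hits with probability 1/omega: the
            # odds of a case CNV hitting the target set are multiplied by omega.
            if not hits_target and rng.random() >= 1 / config.enrichment_odds:
                continue
        if pool is not None:
            pool.add(iv, cnv_type)
        return iv, cnv_type
    raise RuntimeError("could not place a unique background CNV in 1000 tries")


def simulate_cohort(
    config: SimulationConfig,
    genome: Genome,
    rng: np.random.Generator,
    seed: int | None = None,
) -> SimulatedCohort:
    """Per-algorithm call tables, manifest, trios and the truth ledger."""
    pool = _UniquenessPool() if config.enforce_unique_background else None

    # Polymorphic loci: fixed coordinates, population frequency above the
    # rarity threshold, placed independently of the background process.
    loci_rows = []
    for i in range(config.n_polymorphic_loci):
        chroms = list(genome.chrom_sizes)
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(*config.polymorphic_size_range_bp))
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - length))
        loci_rows.append(
            {
                "locus": f"poly_{i + 1:02d}",
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "type": "DEL" if rng.random() < config.del_fraction else "DUP",
                "frequency": float(rng.uniform(*config.polymorphic_freq_range)),
            }
        )
    poly = pd.DataFrame(
        loci_rows, columns=["locus", "chrom", "start", "end", "type", "frequency"]
    )
    if pool is not None:
        # Background draws must not collide with polymorphic loci either,
        # otherwise a "unique" event inherits the locus's pooled frequency.
        for row in poly.itertuples():
            pool.add(GenomicInterval(row.chrom, row.start, row.end), row.type)

    manifest_rows: list[dict] = []
    trio_rows: list[dict] = []
    truth_rows: list[dict] = []
    call_rows: list[dict] = []
    target = genome.target_genes

    def platform_for(rng: np.random.Generator) -> str:
        return config.platforms[int(rng.choice(len(config.platforms),
                                               p=list(config.platform_mix)))]

    def record_truth(sample: str, iv: GenomicInterval, cnv_type: str,
                     origin: str, locus: str, freq: float, emitted: int) -> None:
        truth_rows.append(
            {
                "sample_id": sample,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "type": cnv_type,
                "origin": origin,
                "locus": locus,
                "planted_frequency": freq,
                "is_common": freq > 0.005,
                "hits_target": bool(
                    genome.gene_index.genes_hit(iv, coding_exons_only=True) & target
                ),
                "n_algorithms_emitted": emitted,
            }
        )

    def emit(sample: str, platform: str, iv: GenomicInterval, cnv_type: str) -> int:
        kept = [a for a in config.algorithms if rng.random() >= config.dropout]
        if not kept:
            kept = [config.algorithms[int(rng.integers(0, len(config.algorithms)))]]
        spacing = config.probe_spacing_bp[platform]
        chrom_size = genome.chrom_sizes[iv.chrom]
        for algo in kept:
            j = config.jitter_bp
            s = iv.start + (int(rng.integers(-j, j + 1)) if j else 0)
            e = iv.end + (int(rng.integers(-j, j + 1)) if j else 0)
            s = max(0, min(s, chrom_size - 2))
            e = max(s + 1, min(e, chrom_size))
            call_rows.append(
                {
                    "sample_id": sample,
                    "chrom": iv.chrom,
                    "start": s,
                    "end": e,
                    "type": cnv_type,
                    "n_probes": max(1, (e - s) // spacing),
                    "algorithm": algo,
                    "platform": platform,
                }
            )
        return len(kept)

    def draw_subject_cnvs(enriched: bool) -> list[tuple[GenomicInterval, str, str, str, float]]:
        """Background + polymorphic true CNVs: (iv, type, origin, locus, freq)."""
        out = []
        k = int(rng.poisson(config.mean_cnvs_per_subject))
        for _ in range(k):
            iv, cnv_type = _draw_background_cnv(rng, genome, config, enriched, pool)
            out.append((iv, cnv_type, "background", "", np.nan))
        for row in poly.itertuples():
            if rng.random() < row.frequency:
                iv = GenomicInterval(row.chrom, row.start, row.end)
                out.append((iv, row.type, "polymorphic", row.locus, row.frequency))
        return out

    def add_subject(sample: str, status: str, platform: str, family: str = "",
                    role: str = "", sex: str | None = None) -> None:
        manifest_rows.append(
            {
                "sample_id": sample,
                "status": status,
                "sex": sex or ("M" if rng.random() < 0.5 else "F"),
                "ancestry": config.ancestry,
                "platform": platform,
                "family_id": family,
                "role": role,
            }
        )

    # --- trio families -----------------------------------------------------
    for t in range(config.n_trios):
        fam = f"fam_{t + 1:04d}"
        proband = f"case_t{t + 1:04d}"
        mother, father = f"mother_{t + 1:04d}", f"father_{t + 1:04d}"
        platform = platform_for(rng)
        add_subject(proband, "case", platform, fam, "proband")
        add_subject(mother, "parent", platform, fam, "mother", sex="F")
        add_subject(father, "parent", platform, fam, "father", sex="M")
        trio_rows.append(
            {"proband_id": proband, "mother_id": mother, "father_id": father}
        )
        proband_cnvs: list[tuple[GenomicInterval, str, str, str, float]] = []
        for parent, parent_origin in ((mother, "maternal"), (father, "paternal")):
            for iv, cnv_type, origin, locus, freq in draw_subject_cnvs(enriched=False):
                emitted = emit(parent, platform, iv, cnv_type)
                record_truth(parent, iv, cnv_type, origin, locus, freq, emitted)
                if rng.random() < config.transmission_prob:
                    proband_cnvs.append((iv, cnv_type, parent_origin, locus, freq))
        # Identical polymorphic CNV transmitted from both parents collapses
        # to one biparental event in the proband.
        collapsed: dict[tuple, tuple] = {}
        for iv, cnv_type, origin, locus, freq in proband_cnvs:
            key = (iv.chrom, iv.start, iv.end, cnv_type)
            if key in collapsed:
                prev = collapsed[key]
                collapsed[key] = (iv, cnv_type, "biparental", locus, freq)
            else:
                collapsed[key] = (iv, cnv_type, origin, locus, freq)
        proband_cnvs = list(collapsed.values())
        if rng.random() < config.de_novo_prob:
            iv, cnv_type = _draw_background_cnv(rng, genome, config, True, pool)
            proband_cnvs.append((iv, cnv_type, "de_novo", "", np.nan))
        for iv, cnv_type, origin, locus, freq in proband_cnvs:
            emitted = emit(proband, platform, iv, cnv_type)
            record_truth(proband, iv, cnv_type, origin, locus, freq, emitted)

    # --- unrelated cases and controls --------------------------------------
    for i in range(config.n_trios, config.n_cases):
        sample = f"case_u{i + 1:04d}"
        platform = platform_for(rng)
        add_subject(sample, "case", platform)
        for iv, cnv_type, origin, locus, freq in draw_subject_cnvs(enriched=True):
            emitted = emit(sample, platform, iv, cnv_type)
            record_truth(sample, iv, cnv_type, origin, locus, freq, emitted)
    for i in range(config.n_controls):
        sample = f"control_{i + 1:04d}"
        platform = platform_for(rng)
        add_subject(sample, "control", platform)
        for iv, cnv_type, origin, locus, freq in draw_subject_cnvs(enriched=False):
            emitted = emit(sample, platform, iv, cnv_type)
            record_truth(sample, iv, cnv_type, origin, locus, freq, emitted)

    calls = pd.DataFrame(
        call_rows,
        columns=["sample_id", "chrom", "start", "end", "type", "n_probes",
                 "algorithm", "platform"],
    )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["sample_id", "status", "sex", "ancestry", "platform",
                 "family_id", "role"],
    )
    trios = pd.DataFrame(
        trio_rows, columns=["proband_id", "mother_id", "father_id"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "start", "end", "type", "origin", "locus",
                 "planted_frequency", "is_common", "hits_target",
                 "n_algorithms_emitted"],
    )
    return SimulatedCohort(
        calls=calls, manifest=manifest, trios=trios, truth=truth,
        polymorphic_loci=poly, seed=seed,
    )


# ---------------------------------------------------------------------------
# Count-level kernel for calibration / power studies.
# ---------------------------------------------------------------------------

def simulate_count_table(
    rng: np.random.Generator,
    n_cases: int = 250,
    n_controls: int = 1750,
    set_fractions: Mapping[str, float] | None = None,
    target_set: str = "fmrp_targets",
    omega: float = 1.75,
    mean_total: float = 4.0,
    platform_mix: tuple[float, float] = (0.7, 0.3),
    beta_total: float = 0.05,
    beta_platform: float = 0.1,
) -> pd.DataFrame:
    """Per-subject gene-set counts and case status from the kernel model.

    Each subject's total CNV gene count T is Poisson(``mean_total``); the
    count for a set covering fraction f of the gene catalog is
    Binomial(T, f).  Case status follows the logistic model

        logit P(case) = b0 + log(omega) * target_count
                        + beta_total * (T - mean_total) + beta_platform * platform

    and subjects are accumulated until both case and control quotas are
    filled (retrospective sampling, which preserves the odds ratios).  With
    ``omega=1`` the target coefficient is zero and the enrichment test's p
    is uniform under the null.
    """
    if set_fractions is None:
        # Default gene-set sizes over a 3000-gene catalog.
        set_fractions = {
            "fmrp_targets": 840 / 3000,
            "nervous_system_dev": 600 / 3000,
            "synaptic": 400 / 3000,
            "ion_channels": 250 / 3000,
            "chromatin": 500 / 3000,
            "metabolic": 700 / 3000,
        }
    if target_set not in set_fractions:
        raise ValueError(f"target_set {target_set!r} not in set_fractions")
    prevalence = n_cases / (n_cases + n_controls)
    b0 = math.log(prevalence / (1 - prevalence)) - math.log(omega) * mean_total * set_fractions[target_set]
    names = list(set_fractions)
    got_cases: list[np.ndarray] = []
    got_controls: list[np.ndarray] = []
    need_cases, need_controls = n_cases, n_controls
    for _ in range(200):
        if need_cases <= 0 and need_controls <= 0:
            break
        batch = max(2000, 4 * (need_cases + need_controls))
        T = rng.poisson(mean_total, size=batch)
        counts = np.column_stack(
            [rng.binomial(T, set_fractions[n]) for n in names]
        )
        platform = (rng.random(batch) >= platform_mix[0]).astype(int)
        eta = (
            b0
            + math.log(omega) * counts[:, names.index(target_set)]
            + beta_total * (T - mean_total)
            + beta_platform * platform
        )
        case = rng.random(batch) < 1 / (1 + np.exp(-eta))
        block = np.column_stack([case.astype(int), platform, T, counts])
        cases_block = block[case]
        controls_block = block[~case]
        if need_cases > 0:
            got_cases.append(cases_block[:need_cases])
            need_cases -= len(cases_block[:need_cases])
        if need_controls > 0:
            got_controls.append(controls_block[:need_controls])
            need_controls -= len(controls_block[:need_controls])
    if need_cases > 0 or need_controls > 0:
        raise RuntimeError("could not fill case/control quotas")
    data = np.vstack(got_cases + got_controls)
    df = pd.DataFrame(
        data,
        columns=["is_case", "platform_idx", "total_gene_count", *names],
    )
    df["platform"] = np.where(df.pop("platform_idx") == 0, "cytoscan_hd", "omni25")
    return df


def simulate_burden_table(
    rng: np.random.Generator,
    n_cases: int = 250,
    n_controls: int = 250,
    mean_cnvs: float = 2.8,
    mean_genes_per_cnv: float = 1.5,
    size_range_bp: tuple[int, int] = (15_000, 3_000_000),
    gene_or: float = 1.0,
) -> pd.DataFrame:
    """Per-subject burden summaries from the kernel model.

    Each subject gets ``n_cnvs`` ~ Poisson(``mean_cnvs``), a total length
    summing that many log-uniform CNV sizes, and a gene count ~
    Poisson(``mean_genes_per_cnv`` * n_cnvs).  With ``gene_or == 1`` case
    labels are assigned independently of the data (the exchangeable null);
    otherwise case status follows logit P(case) = b0 + log(gene_or) *
    gene_count with quota sampling, so the planted per-gene odds ratio is
    exactly ``gene_or``.
    """

    def draw(batch: int) -> pd.DataFrame:
        k = rng.poisson(mean_cnvs, size=batch)
        lo, hi = size_range_bp
        lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), size=int(k.sum())))
        offsets = np.concatenate([[0], np.cumsum(k)[:-1]])
        total = np.zeros(batch)
        nz = k > 0
        if k.sum():
            sums = np.add.reduceat(lengths, offsets[nz]) if nz.any() else []
            total[nz] = sums
        genes = rng.poisson(mean_genes_per_cnv * k)
        return pd.DataFrame(
            {"n_cnvs": k, "total_length_bp": total.astype(int), "gene_count": genes}
        )

    n = n_cases + n_controls
    if gene_or == 1.0:
        df = draw(n)
        df["is_case"] = np.arange(n) < n_cases
        return df[["is_case", "n_cnvs", "total_length_bp", "gene_count"]]
    prevalence = n_cases / n
    b0 = math.log(prevalence / (1 - prevalence)) - math.log(gene_or) * mean_cnvs * mean_genes_per_cnv
    cases, controls = [], []
    need_cases, need_controls = n_cases, n_controls
    for _ in range(200):
        if need_cases <= 0 and need_controls <= 0:
            break
        df = draw(max(2000, 4 * (need_cases + need_controls)))
        eta = b0 + math.log(gene_or) * df["gene_count"].to_numpy()
        is_case = rng.random(len(df)) < 1 / (1 + np.exp(-eta))
        take_c = df[is_case].iloc[:max(need_cases, 0)]
        take_n = df[~is_case].iloc[:max(need_controls, 0)]
        cases.append(take_c)
        controls.append(take_n)
        need_cases -= len(take_c)
        need_controls -= len(take_n)
    if need_cases > 0 or need_controls > 0:
        raise RuntimeError("could not fill case/control quotas")
    out = pd.concat(
        [c.assign(is_case=True) for c in cases]
        + [c.assign(is_case=False) for c in controls],
        ignore_index=True,
    )
    return out[["is_case", "n_cnvs", "total_length_bp", "gene_count"]]


# ---------------------------------------------------------------------------
# Scoring pipeline output against the truth ledger.
# ---------------------------------------------------------------------------

def _match_truth(
    cnv: StringentCnv, truth_trees: dict[tuple[str, str, str], IntervalTree]
) -> int | None:
    """Index of the best-RO truth CNV of the same sample/type, or None."""
    tree = truth_trees.get((cnv.sample_id, cnv.interval.chrom, cnv.cnv_type))
    if tree is None:
        return None
    best, best_ro = None, 0.5
    for node in tree.overlap(cnv.interval.start, cnv.interval.end):
        ro = reciprocal_overlap(
            cnv.interval, GenomicInterval(cnv.interval.chrom, node.begin, node.end)
        )
        if ro >= best_ro:
            best, best_ro = node.data, ro
    return best


def truth_compare(
    cohort: SimulatedCohort,
    stringent: Mapping[str, Sequence[StringentCnv]],
    audit: pd.DataFrame | None = None,
    inheritance: Mapping[str, Sequence] | None = None,
    seed: int | None = None,
) -> dict:
    """Per-stage recall/precision of pipeline output against the truth ledger.

    ``seed`` (when given) must equal the cohort's recorded seed — comparing
    a ledger against a run from different randomness is a usage error.
    """
    if seed is not None and cohort.seed is not None and seed != cohort.seed:
        raise ValueError(
            f"truth ledger was generated under seed {cohort.seed}, got {seed}"
        )
    truth = cohort.truth.reset_index(drop=True)
    trees: dict[tuple[str, str, str], IntervalTree] = {}
    for idx, row in truth.iterrows():
        trees.setdefault(
            (row.sample_id, row.chrom, row.type), IntervalTree()
        ).addi(int(row.start), int(row.end), idx)

    report: dict[str, dict] = {}

    # Consensus: truth CNVs emitted by >= 2 algorithms should be recovered.
    eligible = truth[truth["n_algorithms_emitted"] >= 2]
    matched_truth: set[int] = set()
    n_stringent = 0
    n_stringent_matched = 0
    for sample, cnvs in stringent.items():
        for cnv in cnvs:
            n_stringent += 1
            m = _match_truth(cnv, trees)
            if m is not None:
                n_stringent_matched += 1
                matched_truth.add(m)
    recovered = len(matched_truth & set(eligible.index))
    report["consensus"] = {
        "recall": recovered / len(eligible) if len(eligible) else 1.0,
        "precision": n_stringent_matched / n_stringent if n_stringent else 1.0,
        "n_eligible_truth": int(len(eligible)),
        "n_stringent": n_stringent,
    }

    # Frequency filter: removal decisions vs planted commonness, on stringent
    # CNVs that map to a truth event.
    if audit is not None and len(audit):
        tp = fp = fn = tn = 0
        for row in audit.itertuples():
            cnv_iv = GenomicInterval(row.chrom, row.start, row.end)
            key = (row.sample_id, row.chrom, row.cnv_type)
            tree = trees.get(key)
            m = None
            if tree is not None:
                best_ro = 0.5
                for node in tree.overlap(row.start, row.end):
                    ro = reciprocal_overlap(
                        cnv_iv, GenomicInterval(row.chrom, node.begin, node.end)
                    )
                    if ro >= best_ro:
                        m, best_ro = node.data, ro
            if m is None:
                continue
            common = bool(truth.loc[m, "is_common"])
            removed = row.failed_filter == "frequency"
            tp += common and removed
            fp += (not common) and removed
            fn += common and (not removed)
            tn += (not common) and (not removed)
        report["frequency_filter"] = {
            "recall": tp / (tp + fn) if (tp + fn) else 1.0,
            "precision": tp / (tp + fp) if (tp + fp) else 1.0,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        }

    # De novo calls vs planted origins.
    if inheritance is not None:
        planted = truth[truth["origin"] == "de_novo"]
        called_de_novo: set[int] = set()
        false_de_novo = 0
        n_calls = 0
        for sample, calls in inheritance.items():
            for ic in calls:
                n_calls += 1
                if ic.status != "de_novo":
                    continue
                m = _match_truth(ic.cnv, trees)
                if m is not None and truth.loc[m, "origin"] == "de_novo":
                    called_de_novo.add(m)
                else:
                    false_de_novo += 1
        n_called = len(called_de_novo) + false_de_novo
        report["de_novo"] = {
            "recall": len(called_de_novo) / len(planted) if len(planted) else 1.0,
            "precision": len(called_de_novo) / n_called if n_called else 1.0,
            "n_planted": int(len(planted)),
            "n_called": n_called,
            "n_classified": n_calls,
        }
    return report
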