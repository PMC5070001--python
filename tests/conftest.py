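"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own data structures and
algorithms: overlap quantities are counted per base over explicit position
sets, and likelihood-ratio p-values come from a direct maximum-likelihood
fit with scipy.optimize.  They exist to cross-check the fast implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from cnvburden import GenomicInterval, GeneModel, SimulationConfig
from cnvburden.consensus import CnvCall, StringentCnv


# ---------------------------------------------------------------------------
# per-base oracles (small coordinates only)
# ---------------------------------------------------------------------------

def bp_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def bp_reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = bp_overlap(a, b)
    return min(ov / a.length, ov / b.length) if ov else 0.0


def bp_covered_fraction(a: GenomicInterval, regions) -> float:
    covered: set[int] = set()
    for r in regions:
        if r.chrom == a.chrom:
            covered |= set(range(r.start, r.end))
    return len(covered & set(range(a.start, a.end))) / a.length


def brute_force_genes_hit(a, genes, coding_exons_only=False):
    hit = set()
    for g in genes:
        targets = g.exons if coding_exons_only else (g.interval,)
        if any(bp_overlap(a, t) > 0 for t in targets):
            hit.add(g.gene_id)
    return hit


# ---------------------------------------------------------------------------
# maximum-likelihood logistic oracle
# ---------------------------------------------------------------------------

def _fit_nll(y: np.ndarray, X: np.ndarray) -> float:
    """Minimized negative log-likelihood of a logistic regression."""

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return X.T @ (p - y)

    res = optimize.minimize(
        nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    return float(res.fun)


def ml_lr_pvalue(y, X_full: pd.DataFrame, drop: list[str]) -> float:
    """Likelihood-ratio p for dropping columns, by direct ML optimization."""
    y = np.asarray(y, float)
    Xf = np.column_stack([np.ones(len(y)), np.asarray(X_full, float)])
    keep = [i for i, c in enumerate(X_full.columns) if c not in drop]
    Xr = np.column_stack([np.ones(len(y)), np.asarray(X_full.iloc[:, keep], float)])
    lr = 2.0 * (_fit_nll(y, Xr) - _fit_nll(y, Xf))
    return float(stats.chi2.sf(max(lr, 0.0), len(drop)))


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------

def make_call(sample="s1", chrom="chr1", start=0, end=100_000, cnv_type="DEL",
              n_probes=20, algorithm="algA", platform="p1") -> CnvCall:
    return CnvCall(sample, GenomicInterval(chrom, start, end), cnv_type,
                   n_probes, algorithm, platform)


def make_stringent(sample="s1", chrom="chr1", start=0, end=100_000,
                   cnv_type="DEL", n_probes=20,
                   algorithms=("algA", "algB"), platform="p1") -> StringentCnv:
    return StringentCnv(sample, GenomicInterval(chrom, start, end), cnv_type,
                        n_probes, frozenset(algorithms), platform)


def small_sim_config(**overrides) -> SimulationConfig:
    """A desk-scale cohort: one platform so frequency strata stay >= 200."""
    defaults = dict(
        n_cases=80,
        n_controls=480,
        n_trios=20,
        platform_mix=(1.0, 0.0),
        n_genes=600,
        genome_size_bp=120_000_000,
        gene_set_sizes={"fmrp_targets": 168, "other": 120},
        n_polymorphic_loci=4,
        n_known_loci=3,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_gene_fixture():
    """Two adjacent genes with well-separated exons on chr1."""
    g1 = GeneModel(
        "gA",
        GenomicInterval("chr1", 1_000, 11_000),
        exons=(GenomicInterval("chr1", 1_000, 1_500),
               GenomicInterval("chr1", 10_500, 11_000)),
    )
    g2 = GeneModel(
        "gB",
        GenomicInterval("chr1", 12_000, 22_000),
        exons=(GenomicInterval("chr1", 12_000, 12_500),
               GenomicInterval("chr1", 21_500, 22_000)),
    )
    return [g1, g2]
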