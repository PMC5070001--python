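"""Frequency pooling and the rare-CNV filter cascade."""

import numpy as np
import pandas as pd
import pytest

from cnvburden import (
    FilterParams,
    GenomicInterval,
    IntervalSet,
    annotate_known_loci,
    apply_filters,
    build_pools,
    cnv_frequency,
)
from cnvburden.rare_filter import FrequencyPool, pool_for_sample

from conftest import make_stringent


def manifest_of(samples, ancestry="EUR", platform="p1", sexes=None, status="control"):
    rows = []
    for i, s in enumerate(samples):
        rows.append(
            {
                "sample_id": s,
                "status": status,
                "sex": sexes[i] if sexes else "M",
                "ancestry": ancestry,
                "platform": platform,
                "family_id": "",
                "role": "",
            }
        )
    return pd.DataFrame(rows)


class TestBuildPools:
    def test_single_stratum_contains_everyone(self):
        mf = manifest_of([f"s{i}" for i in range(10)])
        pools = build_pools({}, mf)
        assert len(pools) == 1
        assert next(iter(pools.values())).n_subjects == 10

    def test_stratum_enumeration(self):
        # 2 ancestries x 2 sexes on one platform -> 4 pools.
        rows = []
        for anc in ("EUR", "AFR"):
            for sex in ("M", "F"):
                for i in range(3):
                    rows.append({
                        "sample_id": f"{anc}_{sex}_{i}", "status": "control",
                        "sex": sex, "ancestry": anc, "platform": "p1",
                        "family_id": "", "role": "",
                    })
        pools = build_pools({}, pd.DataFrame(rows))
        assert len(pools) == 4
        assert all(p.n_subjects == 3 for p in pools.values())

    def test_missing_sex_names_the_sample(self):
        mf = manifest_of(["ok", "broken"])
        mf.loc[1, "sex"] = ""
        with pytest.raises(ValueError, match="broken"):
            build_pools({}, mf)

    def test_parents_not_pooled(self):
        mf = manifest_of(["c1", "mom"])
        mf.loc[1, "status"] = "parent"
        pools = build_pools({}, mf)
        assert next(iter(pools.values())).subject_ids == {"c1"}


class TestCnvFrequency:
    def _pool(self, members, n=1000):
        samples = [f"s{i}" for i in range(n)]
        return FrequencyPool(("EUR", "p1", "M"), members, samples)

    def test_private_cnv_in_pool_of_1000(self):
        cnv = make_stringent(sample="s0")
        pool = self._pool([cnv])
        assert cnv_frequency(cnv, pool) == pytest.approx(0.001)

    def test_six_carriers_fail_half_percent_cut(self):
        carriers = [make_stringent(sample=f"s{i}") for i in range(6)]
        pool = self._pool(carriers)
        f = cnv_frequency(carriers[0], pool)
        assert f == pytest.approx(0.006)
        assert f > FilterParams().max_frequency

    def test_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(42)
        members = []
        for i in range(60):
            s = int(rng.integers(0, 40)) * 25_000
            members.append(
                make_stringent(
                    sample=f"s{int(rng.integers(0, 30))}",
                    start=s, end=s + int(rng.integers(1, 5)) * 25_000,
                    cnv_type="DEL" if rng.random() < 0.5 else "DUP",
                )
            )
        pool = FrequencyPool(("EUR", "p1", "M"), members,
                             [f"s{i}" for i in range(30)])
        from cnvburden import reciprocal_overlap
        for cnv in members[:20]:
            expected = {
                m.sample_id for m in members
                if m.cnv_type == cnv.cnv_type
                and reciprocal_overlap(m.interval, cnv.interval) >= 0.5
            } | {cnv.sample_id}
            assert cnv_frequency(cnv, pool) == pytest.approx(len(expected) / 30)

    def test_subject_counted_once_despite_two_matching_calls(self):
        a = make_stringent(sample="s0", start=0, end=100_000)
        b = make_stringent(sample="s0", start=5_000, end=105_000)
        pool = self._pool([a, b], n=100)
        assert cnv_frequency(a, pool) == pytest.approx(1 / 100)

    def test_cnv_outside_pool_rejected(self):
        pool = self._pool([], n=10)
        with pytest.raises(ValueError):
            cnv_frequency(make_stringent(sample="stranger"), pool)


class TestApplyFilters:
    def _setup(self, cnvs_by_sample, n_subjects=1000, stable=None):
        samples = sorted(
            set(cnvs_by_sample) | {f"pad{i}" for i in range(n_subjects - len(cnvs_by_sample))}
        )
        mf = manifest_of(samples)
        pools = build_pools(cnvs_by_sample, mf)
        stable = stable if stable is not None else IntervalSet(
            [GenomicInterval("chr1", 0, 10_000_000)]
        )
        return pools, stable

    def test_small_cnv_removed_at_size_step(self):
        cnv = make_stringent(sample="s1", start=0, end=14_000, n_probes=50)
        cnvs = {"s1": [cnv]}
        pools, stable = self._setup(cnvs)
        rare, audit = apply_filters(cnvs, pools, stable)
        assert rare == {}
        assert audit.iloc[0]["failed_filter"] == "size"

    def test_unstable_cnv_removed_at_stability_step(self):
        # 100 kb CNV with 70 kb in stable regions: 0.70 < 0.75.
        cnv = make_stringent(sample="s1", start=0, end=100_000, n_probes=90)
        stable = IntervalSet([GenomicInterval("chr1", 0, 70_000)])
        cnvs = {"s1": [cnv]}
        pools, _ = self._setup(cnvs)
        rare, audit = apply_filters(cnvs, pools, stable)
        assert rare == {}
        assert audit.iloc[0]["failed_filter"] == "stability"
        assert audit.iloc[0]["stable_fraction"] == pytest.approx(0.70)

    def test_low_probe_cnv_removed_at_probe_step(self):
        cnv = make_stringent(sample="s1", n_probes=9)
        cnvs = {"s1": [cnv]}
        pools, stable = self._setup(cnvs)
        rare, audit = apply_filters(cnvs, pools, stable)
        assert audit.iloc[0]["failed_filter"] == "probes"

    def test_polymorphic_locus_removed_at_frequency_step(self):
        # 2 % of a 1000-subject pool carries the same interval.
        carriers = {f"s{i}": [make_stringent(sample=f"s{i}", n_probes=50)]
                    for i in range(20)}
        pools, stable = self._setup(carriers)
        rare, audit = apply_filters(carriers, pools, stable)
        assert rare == {}
        assert (audit["failed_filter"] == "frequency").all()
        assert audit["frequency"].iloc[0] == pytest.approx(0.02)

    def test_clean_cnv_retained(self):
        cnv = make_stringent(sample="s1", n_probes=50)
        cnvs = {"s1": [cnv]}
        pools, stable = self._setup(cnvs)
        rare, audit = apply_filters(cnvs, pools, stable)
        assert rare == {"s1": [cnv]}
        assert bool(audit.iloc[0]["retained"])

    def test_retained_set_is_order_free(self):
        """Retention = conjunction of the four criteria, independent of the
        audit order: verify each retained/removed decision against the four
        criteria computed separately."""
        rng = np.random.default_rng(8)
        cnvs = {}
        for i in range(40):
            s = int(rng.integers(0, 50)) * 20_000
            cnvs.setdefault(f"s{i % 25}", []).append(
                make_stringent(
                    sample=f"s{i % 25}", start=s,
                    end=s + int(rng.integers(1, 8)) * 10_000,
                    n_probes=int(rng.integers(1, 60)),
                )
            )
        pools, _ = self._setup(cnvs, n_subjects=500)
        stable = IntervalSet([GenomicInterval("chr1", 0, 500_000)])
        params = FilterParams()
        rare, audit = apply_filters(cnvs, pools, stable, params)
        from cnvburden import covered_fraction
        for row in audit.itertuples():
            sample_pool = pool_for_sample(pools, row.sample_id)
            cnv = next(
                c for c in cnvs[row.sample_id]
                if (c.interval.start, c.interval.end, c.cnv_type)
                == (row.start, row.end, row.cnv_type)
            )
            passes = (
                cnv_frequency(cnv, sample_pool, params.ro_threshold) <= params.max_frequency
                and covered_fraction(cnv.interval, stable) >= params.min_stable_fraction
                and cnv.interval.length >= params.min_length_bp
                and cnv.n_probes >= params.min_probes
            )
            assert passes == bool(row.retained)

    def test_raising_max_frequency_is_monotone(self):
        carriers = {f"s{i}": [make_stringent(sample=f"s{i}", n_probes=50)]
                    for i in range(4)}
        pools, stable = self._setup(carriers)
        low, _ = apply_filters(carriers, pools, stable, FilterParams(max_frequency=0.002))
        high, _ = apply_filters(carriers, pools, stable, FilterParams(max_frequency=0.01))
        low_set = {(s, c.interval) for s, v in low.items() for c in v}
        high_set = {(s, c.interval) for s, v in high.items() for c in v}
        assert low_set <= high_set

    def test_missing_stable_map_is_an_error(self):
        cnvs = {"s1": [make_stringent(sample="s1")]}
        pools, _ = self._setup(cnvs)
        with pytest.raises(ValueError, match="stability map"):
            apply_filters(cnvs, pools, None)


class TestAnnotateKnownLoci:
    def test_identical_cnv_and_locus(self):
        cnv = make_stringent(sample="s1", start=0, end=100_000)
        ann = annotate_known_loci(
            {"s1": [cnv]}, [("locus_A", GenomicInterval("chr1", 0, 100_000))]
        )
        assert len(ann) == 1
        assert ann.iloc[0]["locus_fraction_covered"] == 1.0
        assert ann.iloc[0]["cnv_fraction_covered"] == 1.0

    def test_cnv_inside_half_of_locus(self):
        cnv = make_stringent(sample="s1", start=0, end=50_000)
        ann = annotate_known_loci(
            {"s1": [cnv]}, [("locus_A", GenomicInterval("chr1", 0, 100_000))]
        )
        assert ann.iloc[0]["locus_fraction_covered"] == pytest.approx(0.5)
        assert ann.iloc[0]["cnv_fraction_covered"] == pytest.approx(1.0)

    def test_chromosome_without_loci_gets_no_annotation(self):
        cnv = make_stringent(sample="s1", chrom="chr9")
        ann = annotate_known_loci(
            {"s1": [cnv]}, [("locus_A", GenomicInterval("chr1", 0, 100_000))]
        )
        assert len(ann) == 0
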