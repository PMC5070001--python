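"""Gene-set enrichment: counts, deviance test, BH FDR and the suite."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from cnvburden import (
    GeneIndex,
    GeneSet,
    bh_fdr,
    enrichment_test,
    run_enrichment_suite,
    simulate_count_table,
    subject_set_count,
)

from conftest import make_stringent, ml_lr_pvalue


class TestSubjectSetCount:
    def test_no_cnvs(self, two_gene_fixture):
        gs = GeneSet("s", frozenset({"gA"}))
        assert subject_set_count([], gs, GeneIndex(two_gene_fixture)) == 0

    def test_class_restriction(self, two_gene_fixture):
        index = GeneIndex(two_gene_fixture)
        gs = GeneSet("s", frozenset({"gA", "gB"}))
        del_cnv = make_stringent(sample="s1", start=0, end=25_000, cnv_type="DEL")
        assert subject_set_count([del_cnv], gs, index, cnv_class="DEL") == 2
        assert subject_set_count([del_cnv], gs, index, cnv_class="DUP") == 0

    def test_distinct_genes_counted_once(self, two_gene_fixture):
        index = GeneIndex(two_gene_fixture)
        gs = GeneSet("s", frozenset({"gA"}))
        cnvs = [
            make_stringent(sample="s1", start=0, end=2_000),
            make_stringent(sample="s1", start=10_000, end=11_500),
        ]
        assert subject_set_count(cnvs, gs, index) == 1

    def test_intronic_cnv_does_not_count(self, two_gene_fixture):
        index = GeneIndex(two_gene_fixture)
        gs = GeneSet("s", frozenset({"gA"}))
        intronic = make_stringent(sample="s1", start=2_000, end=10_000)
        assert subject_set_count([intronic], gs, index) == 0


class TestEnrichmentTest:
    def test_deviance_p_matches_ml_oracle(self, rng):
        df = simulate_count_table(rng, n_cases=150, n_controls=450, omega=2.0)
        res = enrichment_test(
            df["fmrp_targets"], df["total_gene_count"], df["platform"], df["is_case"]
        )
        X = pd.DataFrame(
            {
                "set_count": df["fmrp_targets"].astype(float),
                "total_gene_count": df["total_gene_count"].astype(float),
                "platform_omni25": (df["platform"] == "omni25").astype(float),
            }
        )
        oracle_p = ml_lr_pvalue(df["is_case"].astype(int), X, ["set_count"])
        assert res["p_value"] == pytest.approx(oracle_p, abs=1e-6)

    def test_never_hit_set_is_untestable(self):
        res = enrichment_test([0, 0, 0, 0], [1, 2, 3, 4],
                              ["p1"] * 4, [1, 1, 0, 0])
        assert not res["testable"]
        assert np.isnan(res["p_value"])

    def test_parameter_recovery_of_planted_odds(self):
        """Median fitted OR over 200 replicates within 15% of the planted
        omega at 250 cases / 1750 controls."""
        rng = np.random.default_rng(7)
        omega = 1.75
        fractions = {"target": 0.28, "other": 0.2}
        ors = []
        for _ in range(200):
            df = simulate_count_table(
                rng, n_cases=250, n_controls=1750, omega=omega,
                set_fractions=fractions, target_set="target",
            )
            res = enrichment_test(
                df["target"], df["total_gene_count"], df["platform"], df["is_case"]
            )
            ors.append(res["odds_ratio"])
        median = float(np.median(ors))
        assert abs(median - omega) / omega < 0.15


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.001, 0.02, 0.04])
        assert np.allclose(q, [0.003, 0.03, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(1e-6, 1, size=50)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_sm)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_monotone_in_p_rank(self, rng):
        p = np.sort(rng.uniform(1e-4, 1, size=20))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1).all()


def _manifest(n_cases, n_controls, platform="p1"):
    rows = []
    for i in range(n_cases):
        rows.append({"sample_id": f"ca{i}", "status": "case", "sex": "M",
                     "ancestry": "EUR", "platform": platform,
                     "family_id": "", "role": ""})
    for i in range(n_controls):
        rows.append({"sample_id": f"co{i}", "status": "control", "sex": "M",
                     "ancestry": "EUR", "platform": platform,
                     "family_id": "", "role": ""})
    return pd.DataFrame(rows)


def _three_genes():
    """gA and gB are candidate set genes; gC is background (not in any set),
    so the total-gene-count covariate is not collinear with set counts."""
    from cnvburden import GeneModel, GenomicInterval

    def gene(gid, start):
        return GeneModel(
            gid,
            GenomicInterval("chr1", start, start + 10_000),
            exons=(GenomicInterval("chr1", start, start + 500),
                   GenomicInterval("chr1", start + 9_500, start + 10_000)),
        )

    return [gene("gA", 1_000), gene("gB", 50_000), gene("gC", 100_000)]


def _hit(sample, gene_start, cnv_type="DEL"):
    return make_stringent(sample=sample, start=gene_start, end=gene_start + 20_000,
                          cnv_type=cnv_type)


class TestEnrichmentSuite:
    def test_empty_gene_set_collection(self, two_gene_fixture):
        table = run_enrichment_suite(
            {}, [], GeneIndex(two_gene_fixture), _manifest(3, 3)
        )
        assert len(table) == 0

    def test_exclusion_logic_isolates_known_locus_signal(self):
        """All case-biased hits lie inside a curated locus: signal present
        with loci included, gone (untestable) once the locus is excluded."""
        genes = _three_genes()
        index = GeneIndex(genes)
        gs = GeneSet("target", frozenset({"gA"}))
        manifest = _manifest(40, 40)
        rare: dict = {}
        for i in range(25):  # case-biased gA deletions, all inside locus_A
            rare[f"ca{i}"] = [_hit(f"ca{i}", 1_000)]
        for i in range(4):  # a few control carriers avoid separation
            rare[f"co{i}"] = [_hit(f"co{i}", 1_000)]
        for i in range(15):  # background gC hits in both groups
            rare.setdefault(f"ca{25 + i % 10}", []).append(_hit(f"ca{25 + i % 10}", 100_000))
            rare.setdefault(f"co{10 + i}", []).append(_hit(f"co{10 + i}", 100_000))
        ann_rows = [
            {"sample_id": s, "chrom": "chr1", "start": 1_000, "end": 21_000,
             "cnv_type": "DEL", "locus": "locus_A",
             "locus_fraction_covered": 1.0, "cnv_fraction_covered": 1.0}
            for s in list(rare)
            for c in rare[s] if c.interval.start == 1_000
        ]
        table = run_enrichment_suite(
            rare, [gs], index, manifest,
            loci_annotations=pd.DataFrame(ann_rows),
            cnv_classes=("both",),
        )
        with_loci = table[(~table["loci_excluded"])].iloc[0]
        without = table[table["loci_excluded"]].iloc[0]
        assert with_loci["testable"] and with_loci["p_value"] < 0.05
        assert not without["testable"]  # no set hits left without the locus

    def test_duplication_only_effect_lands_in_dup_family(self):
        genes = _three_genes()
        index = GeneIndex(genes)
        gs = GeneSet("target", frozenset({"gA", "gB"}))
        manifest = _manifest(40, 40)
        rare: dict = {}
        for i in range(25):  # planted case-biased DUPs on a set gene
            rare[f"ca{i}"] = [_hit(f"ca{i}", 1_000, "DUP")]
        for i in range(4):
            rare[f"co{i}"] = [_hit(f"co{i}", 1_000, "DUP")]
        for i in range(12):  # balanced DELs on the other set gene
            rare.setdefault(f"ca{25 + i % 10}", []).append(_hit(f"ca{25 + i % 10}", 50_000))
            rare.setdefault(f"co{10 + i}", []).append(_hit(f"co{10 + i}", 50_000))
        for i in range(16):  # background gC hits of both types, both groups
            t = "DUP" if i % 2 else "DEL"
            rare.setdefault(f"ca{i % 20}", []).append(_hit(f"ca{i % 20}", 100_000, t))
            rare.setdefault(f"co{20 + i}", []).append(_hit(f"co{20 + i}", 100_000, t))
        table = run_enrichment_suite(
            rare, [gs], index, manifest, cnv_classes=("DEL", "DUP")
        ).set_index(["cnv_class", "loci_excluded"])
        dup = table.loc[("DUP", False)]
        del_ = table.loc[("DEL", False)]
        assert dup["testable"] and dup["p_value"] < 0.05
        assert (not bool(del_["testable"])) or del_["p_value"] > 0.05

    def test_q_within_family_and_monotone(self, two_gene_fixture, rng):
        index = GeneIndex(two_gene_fixture)
        sets = [GeneSet("a", frozenset({"gA"})), GeneSet("b", frozenset({"gB"})),
                GeneSet("ab", frozenset({"gA", "gB"}))]
        manifest = _manifest(25, 25)
        rare = {}
        for i in range(25):
            if rng.random() < 0.6:
                s = int(rng.choice([0, 12_000]))
                rare[f"ca{i}"] = [make_stringent(sample=f"ca{i}", start=s, end=s + 10_000)]
            if rng.random() < 0.5:
                s = int(rng.choice([0, 12_000]))
                rare[f"co{i}"] = [make_stringent(sample=f"co{i}", start=s, end=s + 10_000)]
        table = run_enrichment_suite(rare, sets, index, manifest, cnv_classes=("both",))
        for _, fam in table.groupby(["cnv_class", "loci_excluded"]):
            fam = fam[fam["testable"]].sort_values("p_value")
            if len(fam) > 1:
                assert (fam["q_value"].diff().dropna() >= -1e-12).all()
            assert (fam["q_value"] >= fam["p_value"] - 1e-12).all()
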