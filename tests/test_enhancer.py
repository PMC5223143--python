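"""Proximity enrichment, persistence classification and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from enhrev import (
    Contrast,
    GeneModel,
    GenomicInterval,
    RegionSet,
    classify_persistence,
    differential_acetylation,
    persistence_diagnostics,
    proximity_enrichment,
)
from enhrev.enhancer_activity import PERSISTENCE_CLASSES
from conftest import nb_counts, two_group_matrix


def make_genes(tss_list, chrom="chr1"):
    return [
        GeneModel(f"g{i}", chrom, "+", ((t, t + 1000),))
        for i, t in enumerate(tss_list)
    ]


class TestDifferentialAcetylation:
    def test_identical_replicates_show_no_signal(self):
        block = np.array([[30, 40, 50], [100, 90, 80], [10, 20, 15]])
        cm = two_group_matrix(np.hstack([block, block]))
        res = differential_acetylation(cm, Contrast("Chow", "HFD"))
        assert (res["p"] > 0.5).all()

    def test_planted_gain_recovered_with_controlled_fdr(self):
        # full four-group design as in real use: dispersion is estimated on
        # all groups, the contrast tests Chow vs HFD; averaged over seeds so
        # the check targets the expected sensitivity/FDP, not one draw
        import pandas as pd
        from enhrev import CountMatrix

        n = 5000
        sens_list, fdp_list = [], []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            mu = np.full((n, 12), 200.0)  # moderately covered regions
            planted = rng.choice(n, 100, replace=False)
            mu[np.ix_(planted, [3, 4, 5])] *= 2.0  # gain in HFD samples only
            meta = pd.DataFrame(
                {
                    "group": np.repeat(["Chow", "HFD", "ChowChow", "HFDChow"], 3),
                    "replicate": [1, 2, 3] * 4,
                },
                index=[f"s{i}" for i in range(12)],
            )
            counts = pd.DataFrame(
                nb_counts(rng, mu, 0.05, (n, 12)),
                columns=meta.index,
                index=[f"f{i}" for i in range(n)],
            )
            cm = CountMatrix(counts, meta)
            res = differential_acetylation(cm, Contrast("Chow", "HFD"))
            called = res.index[res["fdr"] < 0.1]
            sens_list.append(len(set(called) & set(res.index[planted])) / 100)
            fdp_list.append(
                len(set(called) - set(res.index[planted])) / max(len(called), 1)
            )
        assert np.mean(sens_list) >= 0.6
        assert np.mean(fdp_list) <= 0.15


class TestProximityEnrichment:
    def test_empty_region_set_reports_missing_ratio(self):
        genes = make_genes(range(0, 10_000_000, 20_000))
        enr = proximity_enrichment(
            RegionSet([], name="none"), genes, ["g0", "g1"], n_random=50
        )
        assert enr.observed == 0
        assert np.isnan(enr.ratio)

    def test_deterministic_and_region_order_invariant(self):
        rng = np.random.default_rng(0)
        genes = make_genes(range(0, 10_000_000, 20_000))
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 500, ".", f"r{i}")
            for i, s in enumerate(rng.choice(9_000_000, 200, replace=False))
        ]
        test_set = [g.gene_id for g in genes[:30]]
        a = proximity_enrichment(RegionSet(regions), genes, test_set, seed=7)
        b = proximity_enrichment(RegionSet(regions[::-1]), genes, test_set, seed=7)
        assert a.observed == b.observed
        assert a.null_values == b.null_values
        assert a.p == b.p

    def test_too_few_background_genes_rejected(self):
        genes = make_genes(range(0, 200_000, 20_000))
        with pytest.raises(ValueError, match="background"):
            proximity_enrichment(RegionSet([]), genes, ["g0"], n_random=200)

    def test_planted_coupling_enriched_random_set_not(self):
        rng = np.random.default_rng(11)
        genes = make_genes(range(0, 30_000_000, 100_000))  # 300 genes, sparse
        test_ids = [f"g{i}" for i in rng.choice(300, 30, replace=False)]
        by_id = {g.gene_id: g for g in genes}
        regions = []
        for i in range(90):  # all induced regions within 100 kb of test genes
            g = by_id[test_ids[i % 30]]
            s = int(g.tss + rng.integers(-90_000, 90_000))
            regions.append(GenomicInterval("chr1", max(s, 0), max(s, 0) + 500, ".", f"r{i}"))
        rs = RegionSet(regions)
        enr = proximity_enrichment(rs, genes, test_ids, n_random=100, seed=2)
        assert enr.ratio > 2
        assert enr.p < 0.05
        assert enr.frac_genes_with_hit > 0.9
        random_ids = [f"g{i}" for i in rng.choice(300, 30, replace=False) if f"g{i}" not in test_ids]
        enr_rand = proximity_enrichment(rs, genes, random_ids, n_random=100, seed=3)
        assert enr_rand.ratio < enr.ratio


def _diff(genes, log2fc, p, fdr=None):
    p = np.asarray(p, dtype=float)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr if fdr is not None else np.minimum(p * 4, 1.0),
            "base_mean": 100.0,
        },
        index=pd.Index(genes, name="region_id"),
    )


class TestClassifyPersistence:
    def test_null_reversal_gives_no_persistent_calls(self):
        ids = [f"r{i}" for i in range(4)]
        dio = _diff(ids, [2, -2, 2, 0], [1e-4, 1e-4, 0.5, 0.9])
        rev = _diff(ids, [1, 1, 1, 1], [0.5, 0.6, 0.7, 0.8])
        res = classify_persistence(dio, rev)
        assert res.class_counts()["putative_persistent"] == 0
        assert res.calls.loc["r0", "persistence_class"] == "reversible"

    def test_concordant_double_significance_is_persistent(self):
        ids = ["r0", "r1", "r2"]
        dio = _diff(ids, [2, 2, 0], [1e-4, 1e-4, 0.9])
        rev = _diff(ids, [2, -2, 2], [1e-3, 1e-3, 1e-3])
        res = classify_persistence(dio, rev)
        cls = res.calls["persistence_class"]
        assert cls.loc["r0"] == "putative_persistent"
        assert cls.loc["r1"] == "reversible"  # discordant sign
        assert cls.loc["r2"] == "weightloss_specific"

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        ids = [f"r{i}" for i in range(500)]
        dio = _diff(ids, rng.normal(size=500), rng.uniform(size=500))
        rev = _diff(ids, rng.normal(size=500), rng.uniform(size=500))
        res = classify_persistence(dio, rev)
        assert set(res.calls["persistence_class"]) <= set(PERSISTENCE_CLASSES)
        assert res.calls["persistence_class"].notna().all()
        assert len(res.calls) == 500

    def test_venn_counts_match_threshold_sets(self, rng):
        ids = [f"r{i}" for i in range(300)]
        dio = _diff(ids, rng.normal(size=300), rng.uniform(size=300))
        rev = _diff(ids, rng.normal(size=300), rng.uniform(size=300))
        res = classify_persistence(dio, rev, p_cut=0.1, fdr_cut=0.5)
        sig_d = dio["p"] < 0.1
        sig_r = rev["p"] < 0.1
        assert res.venn_p["both"] == int((sig_d & sig_r).sum())
        assert res.venn_p["dio_only"] == int((sig_d & ~sig_r).sum())

    def test_mismatched_universes_rejected(self):
        dio = _diff(["a"], [1.0], [0.5])
        rev = _diff(["b"], [1.0], [0.5])
        with pytest.raises(ValueError):
            classify_persistence(dio, rev)


class TestDiagnostics:
    def test_single_region_class_summarised(self, rng):
        ids = [f"r{i}" for i in range(3)]
        dio = _diff(ids, [2, 0, 0], [1e-3, 0.9, 0.9])
        rev = _diff(ids, [2, 0, 0], [1e-3, 0.9, 0.9])
        res = classify_persistence(dio, rev)
        counts = nb_counts(rng, 100.0, 0.05, (3, 6))
        cm = two_group_matrix(counts)
        cm.counts.index = pd.Index(ids, name="feature_id")
        diag = persistence_diagnostics(res, cm)
        assert diag["putative_persistent"]["n"] == 1
        one = diag["putative_persistent"]["fdr_rev"]
        assert one["q1"] == one["median"] == one["q3"]

    def test_empty_class_gives_empty_summary(self, rng):
        ids = ["r0"]
        dio = _diff(ids, [0.0], [0.9])
        rev = _diff(ids, [0.0], [0.9])
        res = classify_persistence(dio, rev)
        counts = nb_counts(rng, 100.0, 0.05, (1, 6))
        cm = two_group_matrix(counts)
        cm.counts.index = pd.Index(ids, name="feature_id")
        diag = persistence_diagnostics(res, cm)
        assert diag["putative_persistent"] == {"n": 0}
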