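"""Kruskal-Wallis screen and bootstrapped LDA effect sizes."""

import numpy as np
import pytest
from scipy import stats

from gutneutral.diffabund import (
    ClassLabels,
    expand_clades,
    kruskal_wallis_screen,
    labels_from_table,
    lda_effect_size,
    scale_per_million,
)
from gutneutral.neutral_sim import make_diffabund_fixture
from gutneutral.otu_io import OtuTable


def _two_class_table(counts, n_a):
    n, k = counts.shape
    sample_ids = [f"A_{i}" for i in range(n_a)] + [f"B_{i}" for i in range(n - n_a)]
    return OtuTable(
        sample_ids=sample_ids,
        otu_ids=[f"O{j}" for j in range(k)],
        counts=counts,
        group={s: s[0] for s in sample_ids},
    )


class TestScalePerMillion:
    def test_simple_row(self):
        out = scale_per_million(np.array([[1, 1]]))
        assert out.tolist() == [[5e5, 5e5]]

    def test_rows_sum_to_million_and_idempotent(self):
        rng = np.random.default_rng(3)
        m = rng.integers(1, 100, size=(8, 30)).astype(float)
        s1 = scale_per_million(m)
        assert np.allclose(s1.sum(axis=1), 1e6, atol=1e-6)
        assert np.allclose(scale_per_million(s1), s1, rtol=1e-12)

    def test_zero_sum_row_rejected(self):
        with pytest.raises(ValueError, match="zero-sum"):
            scale_per_million(np.array([[1, 2], [0, 0]]))


class TestKruskalScreen:
    def test_constant_feature_gets_p_one(self):
        # identical rows: every scaled feature is constant across samples
        t = _two_class_table(np.tile([[5, 5]], (8, 1)), 4)
        res = kruskal_wallis_screen(t, labels_from_table(t))
        assert res["O0"] == (1.0, False)
        assert res["O1"] == (1.0, False)

    def test_disjoint_ranges_highly_significant(self):
        # distinct values, disjoint class ranges, no rank ties after scaling
        low = np.arange(10, 20)[:, None]
        high = np.arange(1000, 1010)[:, None]
        other = np.full((20, 1), 50)
        counts = np.hstack([np.vstack([low, high]), other])
        t = _two_class_table(counts, 10)
        res = kruskal_wallis_screen(t, labels_from_table(t))
        p, sig = res["O0"]
        # brute-force check against the exact rank statistic for fully
        # separated groups: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2
        h = 12 / (20 * 21) * (10 * (5.5 - 10.5) ** 2 + 10 * (15.5 - 10.5) ** 2)
        assert p == pytest.approx(float(stats.chi2.sf(h, 1)), rel=1e-6)
        assert p < 0.001 and sig

    def test_small_class_rejected(self):
        t = _two_class_table(np.ones((5, 3), dtype=int), 2)
        with pytest.raises(ValueError, match="fewer than 3"):
            kruskal_wallis_screen(t, labels_from_table(t))

    def test_type_one_error_calibrated_under_null(self):
        t, _ = make_diffabund_fixture(n_features=2000, n_per_class=(10, 10),
                                      spiked=[], seed=5)
        res = kruskal_wallis_screen(t, labels_from_table(t))
        frac = np.mean([sig for _, sig in res.values()])
        assert 0.03 <= frac <= 0.07


class TestLdaEffectSize:
    def test_stronger_spike_outranks_weaker(self):
        wins = 0
        for rep in range(50):
            t, _ = make_diffabund_fixture(
                n_features=100, n_per_class=(20, 20),
                spiked=[(0, 2.0), (1, 50.0)], seed=100 + rep,
            )
            eff = {e.feature_id: e.lda_score
                   for e in lda_effect_size(t, labels_from_table(t), seed=rep)}
            if "OTU_2" in eff and ("OTU_1" not in eff or eff["OTU_2"] > eff["OTU_1"]):
                wins += 1
        assert wins >= 48  # >= 95% of runs

    def test_null_run_mostly_empty(self):
        t, _ = make_diffabund_fixture(n_features=50, n_per_class=(10, 10),
                                      spiked=[], seed=23)
        eff = lda_effect_size(t, labels_from_table(t), seed=23)
        # a few false positives at alpha = 0.05 are expected; none should dominate
        assert len(eff) <= 8

    def test_enriched_class_identifies_spiked_direction(self):
        t, _ = make_diffabund_fixture(n_features=40, n_per_class=(15, 15),
                                      spiked=[(3, 20.0)], seed=8)
        eff = {e.feature_id: e for e in lda_effect_size(t, labels_from_table(t), seed=8)}
        assert eff["OTU_4"].enriched_class == "B"

    def test_sample_duplication_preserves_enrichment_calls(self):
        t, _ = make_diffabund_fixture(n_features=30, n_per_class=(10, 10),
                                      spiked=[(0, 15.0)], seed=4)
        dup = OtuTable(
            sample_ids=t.sample_ids + [s + "_dup" for s in t.sample_ids],
            otu_ids=t.otu_ids,
            counts=np.vstack([t.counts, t.counts]),
            group={**t.group, **{s + "_dup": g for s, g in t.group.items()}},
        )
        e1 = {e.feature_id: e.enriched_class
              for e in lda_effect_size(t, labels_from_table(t), seed=1)}
        e2 = {e.feature_id: e.enriched_class
              for e in lda_effect_size(dup, labels_from_table(dup), seed=1)}
        shared = set(e1) & set(e2)
        assert shared and all(e1[f] == e2[f] for f in shared)

    def test_deterministic_under_seed_and_order_invariant(self):
        t, _ = make_diffabund_fixture(n_features=40, n_per_class=(12, 12),
                                      spiked=[(0, 10.0)], seed=6)
        a = lda_effect_size(t, labels_from_table(t), seed=9)
        b = lda_effect_size(t, labels_from_table(t), seed=9)
        assert [(e.feature_id, e.lda_score) for e in a] == [
            (e.feature_id, e.lda_score) for e in b
        ]
        # permute feature columns; scores must be unchanged per feature
        rng = np.random.default_rng(0)
        perm = rng.permutation(t.n_otus)
        t2 = OtuTable(
            sample_ids=t.sample_ids,
            otu_ids=[t.otu_ids[j] for j in perm],
            counts=t.counts[:, perm],
            group=dict(t.group),
        )
        c = lda_effect_size(t2, labels_from_table(t2), seed=9)
        assert {e.feature_id: round(e.lda_score, 10) for e in a} == {
            e.feature_id: round(e.lda_score, 10) for e in c
        }

    def test_three_classes_rejected_for_effect_size(self):
        t, _ = make_diffabund_fixture(n_features=10, n_per_class=(6, 6), seed=1)
        labels = ClassLabels(
            {s: ("C" if i % 3 == 0 else t.group[s]) for i, s in enumerate(t.sample_ids)}
        )
        with pytest.raises(ValueError, match="two classes"):
            lda_effect_size(t, labels, seed=0)


class TestCladeExpansion:
    def test_clade_sums_append_lineage_prefixes(self, toy_table):
        matrix, ids = expand_clades(toy_table)
        assert "Bacteria" in ids
        assert "Bacteria;Proteobacteria" in ids
        j_all = ids.index("Bacteria")
        scaled = scale_per_million(toy_table.counts)
        assert np.allclose(matrix[:, j_all], scaled.sum(axis=1))
        j_proteo = ids.index("Bacteria;Proteobacteria")
        assert np.allclose(matrix[:, j_proteo], scaled[:, [0, 2]].sum(axis=1))
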