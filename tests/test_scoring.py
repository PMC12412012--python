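"""Score and discrimination tests: arithmetic, AUC oracles, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import _oracles
from glycomsi.scoring import (
    evaluate_cohorts,
    glyco_msi_score,
    pearson_correlation,
    roc_auc,
    signature_average,
)
from glycomsi.signature import GLYCO_MSI_V1, GeneSignature


def test_default_signature_is_the_five_gene_set():
    assert GLYCO_MSI_V1.name == "glyco_msi_v1"
    assert set(GLYCO_MSI_V1.up_genes) == {"GALNT7", "GALNT1", "HPSE"}
    assert set(GLYCO_MSI_V1.down_genes) == {"GALNT6", "ST6GAL1"}


class TestGlycoMsiScore:
    def test_mean_minus_mean_arithmetic(self):
        mat = pd.DataFrame(
            {"s1": [4.0, 2.0, 1.0, 3.0]},
            index=["u1", "u2", "d1", "d2"],
        )
        sig = GeneSignature(("u1", "u2"), ("d1", "d2"))
        assert glyco_msi_score(mat, sig).scores["s1"] == pytest.approx(1.0)

    def test_constant_matrix_scores_zero(self):
        mat = pd.DataFrame(7.0, index=list(GLYCO_MSI_V1.genes), columns=["a", "b"])
        assert np.allclose(glyco_msi_score(mat, GLYCO_MSI_V1).scores, 0.0)

    def test_shift_invariance(self, rng):
        genes = list(GLYCO_MSI_V1.genes)
        mat = pd.DataFrame(rng.normal(8, 1, (5, 6)), index=genes,
                           columns=[f"s{i}" for i in range(6)])
        s1 = glyco_msi_score(mat, GLYCO_MSI_V1).scores
        s2 = glyco_msi_score(mat + 3.7, GLYCO_MSI_V1).scores
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_matches_brute_force_loop(self, rng):
        genes = [f"g{i}" for i in range(12)]
        mat = pd.DataFrame(rng.normal(0, 1, (12, 9)), index=genes,
                           columns=[f"s{i}" for i in range(9)])
        sig = GeneSignature(("g1", "g4", "g7"), ("g0", "g9"))
        res = glyco_msi_score(mat, sig)
        for s in mat.columns:
            up = np.mean([mat.loc[g, s] for g in sig.up_genes])
            down = np.mean([mat.loc[g, s] for g in sig.down_genes])
            assert res.scores[s] == pytest.approx(up - down, abs=1e-12)

    def test_missing_genes_dropped_and_counted(self, rng):
        mat = pd.DataFrame(rng.normal(8, 1, (3, 4)),
                           index=["GALNT7", "GALNT1", "GALNT6"],
                           columns=list("abcd"))
        res = glyco_msi_score(mat, GLYCO_MSI_V1)
        assert (res.n_up_used, res.n_down_used) == (2, 1)

    def test_whole_arm_missing_is_error(self, rng):
        mat = pd.DataFrame(rng.normal(8, 1, (2, 3)),
                           index=["GALNT7", "HPSE"], columns=list("abc"))
        with pytest.raises(ValueError, match="down-arm"):
            glyco_msi_score(mat, GLYCO_MSI_V1)

    def test_arm_swap_negates_scores(self, rng):
        genes = list(GLYCO_MSI_V1.genes)
        mat = pd.DataFrame(rng.normal(8, 1, (5, 6)), index=genes,
                           columns=[f"s{i}" for i in range(6)])
        s = glyco_msi_score(mat, GLYCO_MSI_V1).scores
        t = glyco_msi_score(mat, GLYCO_MSI_V1.swapped()).scores
        np.testing.assert_allclose(s.to_numpy(), -t.to_numpy(), atol=1e-12)


class TestSignatureAverage:
    def test_single_gene_identity(self, random_matrix):
        mat, _ = random_matrix
        np.testing.assert_allclose(
            signature_average(mat, ["G3"]), mat.loc["G3"], atol=1e-12
        )

    def test_matches_brute_force(self, random_matrix):
        mat, _ = random_matrix
        got = signature_average(mat, ["G1", "G4", "G7", "NOT_PRESENT"])
        expected = (mat.loc["G1"] + mat.loc["G4"] + mat.loc["G7"]) / 3
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_no_genes_present_rejected(self, random_matrix):
        mat, _ = random_matrix
        with pytest.raises(ValueError, match="no gene"):
            signature_average(mat, ["NOPE"])


class TestRocAuc:
    def test_explicit_pair_enumeration_example(self):
        scores = [3.0, 1.0, 2.0, 0.0]
        labels = ["MSI", "MSI", "MSS", "MSS"]
        assert roc_auc(scores, labels).auc == pytest.approx(0.75)

    def test_perfect_separation_and_all_ties(self):
        assert roc_auc([5, 6, 1, 2], ["MSI", "MSI", "MSS", "MSS"]).auc == 1.0
        assert roc_auc([3, 3, 3, 3], ["MSI", "MSI", "MSS", "MSS"]).auc == 0.5

    def test_matches_pairwise_enumeration_randomized(self, rng):
        for _ in range(100):
            n_pos = int(rng.integers(1, 25))
            n_neg = int(rng.integers(1, 25))
            scores = np.round(rng.normal(0, 1, n_pos + n_neg), 1)  # force ties
            labels = np.array(["MSI"] * n_pos + ["MSS"] * n_neg)
            res = roc_auc(scores, labels)
            expected = _oracles.pairwise_auc(scores[:n_pos], scores[n_pos:])
            assert res.auc == pytest.approx(expected, abs=1e-12)
            assert res.auc == pytest.approx(
                res.u_statistic / (res.n_pos * res.n_neg), abs=1e-15
            )

    def test_agrees_with_sklearn_without_ties(self, rng):
        scores = rng.normal(0, 1, 60)
        labels = np.where(rng.random(60) < 0.4, "MSI", "MSS")
        got = roc_auc(scores, labels).auc
        assert got == pytest.approx(
            roc_auc_score((labels == "MSI").astype(int), scores), abs=1e-12
        )

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, vals):
        n = len(vals)
        labels = np.array(["MSI", "MSS"] * (n // 2 + 1))[:n]
        if len(set(labels)) < 2:
            return
        scores = np.array(vals)
        a1 = roc_auc(scores, labels).auc
        # positive scaling is strictly increasing and exact in floats
        a2 = roc_auc(scores * 3.7, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_label_flip_complements(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = np.array(["MSI"] * 15 + ["MSS"] * 25)
        assert roc_auc(scores, labels).auc + roc_auc(
            scores, labels, positive="MSS"
        ).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], ["MSI", "MSI"])


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation([1, 2], [3, 4])


class TestEvaluateCohorts:
    @staticmethod
    def _gaussian_cohort(rng, delta, n=500):
        genes = list(GLYCO_MSI_V1.genes)
        samples = [f"s{i}" for i in range(2 * n)]
        labels = pd.Series(["MSI"] * n + ["MSS"] * n, index=samples)
        mat = pd.DataFrame(rng.normal(8, 1, (5, 2 * n)), index=genes,
                           columns=samples)
        # shift up genes by +delta/2 and down genes by -delta/2 in MSI so the
        # score separation is delta with score sd ~ sqrt(1/3 + 1/2)
        mat.loc[list(GLYCO_MSI_V1.up_genes), labels == "MSI"] += delta / 2
        mat.loc[list(GLYCO_MSI_V1.down_genes), labels == "MSI"] -= delta / 2
        return mat, labels

    def test_gaussian_separation_matches_closed_form(self, rng):
        # score ~ N(+-delta/2 contributions); with unit-variance genes the
        # score sd is sqrt(1/3 + 1/2) per class, so AUC = Phi(sep / (sd*sqrt(2)))
        from scipy.stats import norm

        delta = 2.0
        mat, labels = self._gaussian_cohort(rng, delta)
        res = evaluate_cohorts([("c", mat, labels)], GLYCO_MSI_V1)
        sd = np.sqrt(1 / 3 + 1 / 2)
        expected = norm.cdf(delta / (sd * np.sqrt(2)))
        assert res.loc["c", "auc"] == pytest.approx(expected, abs=0.03)

    def test_shuffled_labels_near_half(self, rng):
        mat, labels = self._gaussian_cohort(rng, 2.0)
        shuffled = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        res = evaluate_cohorts([("c", mat, shuffled)], GLYCO_MSI_V1)
        assert res.loc["c", "auc"] == pytest.approx(0.5, abs=0.05)

    def test_failing_cohort_reported_not_fatal(self, rng):
        mat, labels = self._gaussian_cohort(rng, 1.0, n=20)
        broken = mat.drop(index=list(GLYCO_MSI_V1.down_genes))
        res = evaluate_cohorts(
            [("ok", mat, labels), ("broken", broken, labels)], GLYCO_MSI_V1
        )
        assert np.isfinite(res.loc["ok", "auc"])
        assert np.isnan(res.loc["broken", "auc"])
        assert "down-arm" in res.loc["broken", "error"]

    def test_missing_gene_reduces_count_and_flags(self, rng):
        mat, labels = self._gaussian_cohort(rng, 1.0, n=30)
        partial = mat.drop(index=["ST6GAL1"])
        res = evaluate_cohorts([("c", partial, labels)], GLYCO_MSI_V1)
        assert res.loc["c", "n_down_used"] == 1
        assert np.isfinite(res.loc["c", "auc"])

    def test_empty_cohort_list_rejected(self):
        with pytest.raises(ValueError, match="no cohorts"):
            evaluate_cohorts([], GLYCO_MSI_V1)
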