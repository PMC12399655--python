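"""Heterogeneity scores, quadrants, consensus and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import evosig as es


def _matrix(values: np.ndarray, patients: list[str]) -> es.MultiRegionMatrix:
    cols = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "patient_id": patients,
            "region_id": [f"R{i}" for i in range(len(patients))],
        },
        index=pd.Index(cols, name="sample_id"),
    )
    vals = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=cols
    )
    return es.MultiRegionMatrix(vals, meta)


class TestScores:
    def test_hand_example(self, hand_multiregion):
        # per-patient SDs both sqrt(2) -> intra sqrt(2); means 1 and 5 -> inter 2*sqrt(2)
        scores = es.heterogeneity_scores(hand_multiregion)
        assert scores.loc["g1", "intra"] == pytest.approx(np.sqrt(2))
        assert scores.loc["g1", "inter"] == pytest.approx(2 * np.sqrt(2))

    def test_constant_gene_scores_zero(self):
        data = _matrix(np.full((2, 6), 3.0), ["A"] * 3 + ["B"] * 3)
        scores = es.heterogeneity_scores(data)
        assert (scores == 0).all().all()

    def test_pure_between_patient_variation(self):
        row = np.array([[1.0, 1.0, 1.0, 5.0, 5.0, 5.0]])
        scores = es.heterogeneity_scores(_matrix(row, ["A"] * 3 + ["B"] * 3))
        assert scores.loc["g0", "intra"] == 0
        assert scores.loc["g0", "inter"] > 0

    @settings(max_examples=25, deadline=None)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 20, allow_nan=False),
    )
    def test_shift_invariant_scale_equivariant(self, shift, scale):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, 8))
        pats = ["A"] * 4 + ["B"] * 4
        base = es.heterogeneity_scores(_matrix(vals, pats))
        moved = es.heterogeneity_scores(_matrix(vals * scale + shift, pats))
        np.testing.assert_allclose(moved, base * scale, rtol=1e-9, atol=1e-9)

    def test_min_regions_excludes_thin_patients_from_intra(self):
        # patient C contributes a single region: drops out of intra, stays in inter
        vals = np.array([[0.0, 2.0, 4.0, 6.0, 100.0]])
        pats = ["A", "A", "B", "B", "C"]
        scores = es.heterogeneity_scores(_matrix(vals, pats), min_regions=2)
        assert scores.loc["g0", "intra"] == pytest.approx(np.sqrt(2))
        means = np.array([1.0, 5.0, 100.0])
        assert scores.loc["g0", "inter"] == pytest.approx(means.std(ddof=1))

    def test_too_few_qualifying_patients_refused(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="patients"):
            es.heterogeneity_scores(_matrix(vals, ["A", "A", "B"]), min_regions=2)

    def test_unknown_summary_refused(self, hand_multiregion):
        with pytest.raises(KeyError):
            es.heterogeneity_scores(hand_multiregion, intra_summary="nope")


class TestQuadrants:
    def brute_force(self, scores: pd.DataFrame, q: float) -> list[str]:
        thr_i = np.quantile(np.sort(scores["intra"]), q)
        thr_e = np.quantile(np.sort(scores["inter"]), q)
        out = []
        for _, row in scores.iterrows():
            hi_i, hi_e = row["intra"] > thr_i, row["inter"] > thr_e
            out.append(
                "Q1" if hi_i and hi_e else "Q2" if hi_e else "Q4" if hi_i else "Q3"
            )
        return out

    def test_eight_hand_set_genes_match_brute_force(self):
        scores = pd.DataFrame(
            {
                "intra": [0.1, 0.9, 0.9, 0.2, 0.5, 0.95, 0.3, 0.7],
                "inter": [0.2, 0.8, 0.1, 0.9, 0.5, 0.99, 0.85, 0.4],
            },
            index=[f"g{i}" for i in range(8)],
        )
        got = es.classify_quadrants(scores, q=0.75)
        assert got["quadrant"].tolist() == self.brute_force(scores, 0.75)

    def test_identical_scores_yield_no_q1(self):
        scores = pd.DataFrame({"intra": [1.0] * 6, "inter": [1.0] * 6})
        got = es.classify_quadrants(scores)
        assert (got["quadrant"] == "Q3").all()

    def test_quadrants_partition_and_q1_bounded(self, small_multiregion):
        scores = es.heterogeneity_scores(small_multiregion)
        got = es.classify_quadrants(scores)
        assert set(got["quadrant"]) <= {"Q1", "Q2", "Q3", "Q4"}
        assert got["quadrant"].notna().all()
        n_q1 = (got["quadrant"] == "Q1").sum()
        assert n_q1 <= int(np.ceil(0.25 * len(got)))

    def test_planted_q1_genes_recovered(self):
        truth = es.make_truth(
            n_genes=200, n_signature=5, n_q1_extra=25, n_q2=15, n_q3=25,
            n_q4=15, n_de_extra=0, n_trend_up=0, n_trend_down=0, seed=13,
        )
        data, _ = es.gen_multiregion(50, (5, 5), truth, seed=13)
        got = es.classify_quadrants(es.heterogeneity_scores(data))
        planted = truth.gene_class.index[truth.gene_class == "Q1"]
        frac = (got.loc[planted, "quadrant"] == "Q1").mean()
        assert frac >= 0.90

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2, 1.5])
    def test_quantile_domain(self, q):
        scores = pd.DataFrame({"intra": [1, 2, 3, 4.0], "inter": [1, 2, 3, 4.0]})
        with pytest.raises(ValueError):
            es.classify_quadrants(scores, q=q)


class TestConsensus:
    def _table(self, q1_genes, others):
        genes = list(q1_genes) + list(others)
        return pd.DataFrame(
            {"quadrant": ["Q1"] * len(q1_genes) + ["Q3"] * len(others)},
            index=genes,
        )

    def test_intersection_of_hand_built_lists(self):
        t1 = self._table(["a", "b", "c"], ["x"])
        t2 = self._table(["b", "c", "d"], ["y"])
        t3 = self._table(["c", "d", "e"], ["z"])
        assert es.consensus_evogenes([t1, t2, t3]) == {"c"}

    def test_idempotent_on_identical_tables(self):
        t = self._table(["a", "b"], ["c"])
        assert es.consensus_evogenes([t, t, t]) == {"a", "b"}

    def test_empty_q1_empties_consensus(self):
        t1 = self._table(["a"], ["b"])
        t2 = self._table([], ["a", "b"])
        assert es.consensus_evogenes([t1, t2]) == set()

    def test_adding_a_table_never_enlarges(self):
        t1 = self._table(["a", "b", "c"], [])
        t2 = self._table(["b", "c"], ["a"])
        base = es.consensus_evogenes([t1])
        assert es.consensus_evogenes([t1, t2]) <= base

    def test_empty_list_refused(self):
        with pytest.raises(ValueError):
            es.consensus_evogenes([])


class TestEnrichment:
    def test_printed_worked_example(self):
        res = es.enrichment_odds_ratio(28, 192, 449, 12429)
        assert res.odds_ratio == pytest.approx(4.55, abs=0.01)
        assert not res.continuity_corrected

    def test_equal_proportions_give_unit_odds(self):
        assert es.enrichment_odds_ratio(5, 50, 20, 200).odds_ratio == pytest.approx(1.0)

    def test_hand_computation(self):
        # (2/8)/(10/90) = 2.25
        assert es.enrichment_odds_ratio(2, 10, 10, 100).odds_ratio == pytest.approx(2.25)

    def test_zero_cell_triggers_continuity_flag(self):
        res = es.enrichment_odds_ratio(0, 10, 5, 100)
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio)

    def test_invalid_counts_refused(self):
        with pytest.raises(ValueError):
            es.enrichment_odds_ratio(11, 10, 5, 100)


class TestPrognosticEnrichment:
    def test_random_set_is_null(self):
        rng = np.random.default_rng(5)
        nonsig = 0
        for rep in range(10):
            pvals = pd.Series(
                rng.uniform(size=400), index=[f"g{i}" for i in range(400)]
            )
            chosen = rng.choice(pvals.index, 60, replace=False)
            res = es.prognostic_enrichment(chosen, pvals)
            nonsig += res.shift_p >= 0.05
        assert nonsig >= 9

    def test_planted_prognostic_set_detected(self):
        truth = es.make_truth(
            n_genes=500, n_signature=40, n_q1_extra=0, n_q2=0, n_q3=0,
            n_q4=0, n_de_extra=0, n_trend_up=0, n_trend_down=0,
            signature_beta=0.8, seed=17,
        )
        cohort, _ = es.gen_survival_cohort(500, truth, seed=17)
        screen = es.cox_screen(cohort)
        res = es.prognostic_enrichment(truth.prognostic_genes(), screen["p"])
        assert res.odds_ratio > 1
        assert res.shift_p < 0.05
        assert res.prop_in > res.prop_out

    def test_small_groups_refused(self):
        pvals = pd.Series(np.linspace(0.01, 1, 15), index=[f"g{i}" for i in range(15)])
        with pytest.raises(ValueError):
            es.prognostic_enrichment([f"g{i}" for i in range(8)], pvals)
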