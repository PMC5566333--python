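import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from swathbench.fdr import (
    EXPERIMENT_WIDE,
    GLOBAL,
    consecutive_filter,
    cumulative_detection_curve,
    estimate_qvalues,
    learn_discriminant,
    qvalues_from_scores,
)
from swathbench.simulate import SUB_SCORE_COLS


def _toy_records(n=400, seed=0, separation=4.0):
    """Half targets (shifted on sub-score 1), half decoys (null)."""
    rng = np.random.default_rng(seed)
    decoy = np.repeat([False, True], n // 2)
    sub = rng.normal(0, 1, (n, len(SUB_SCORE_COLS)))
    sub[~decoy, 0] += separation
    df = pd.DataFrame(sub, columns=SUB_SCORE_COLS)
    df["decoy"] = decoy
    df["run_id"] = np.tile([f"r{i}" for i in range(4)], n // 4)
    df["peptide_query_id"] = [("DECOY_" if d else "") + f"q{i}" for i, d in enumerate(decoy)]
    df["protein_id"] = [("DECOY_" if d else "") + f"p{i // 4}" for i, d in enumerate(decoy)]
    return df


class TestDiscriminant:
    def test_separable_subscore_gives_perfect_auroc(self):
        df = _toy_records(separation=8.0)
        _, d = learn_discriminant(df, seed=0)
        assert roc_auc_score(~df["decoy"], d) == 1.0

    def test_weights_invariant_to_record_order(self):
        df = _toy_records()
        w1, _ = learn_discriminant(df, seed=1)
        shuffled = df.sample(frac=1.0, random_state=7)
        w2, _ = learn_discriminant(shuffled, seed=1)
        assert np.allclose(w1, w2)

    def test_subsampled_fit_matches_full_fit_detections(self, small_study):
        pg = small_study.peakgroups
        _, d_full = learn_discriminant(pg, subsample_ratio=1.0, seed=3)
        _, d_sub = learn_discriminant(pg, subsample_ratio=1 / 21, seed=3)
        # top-decile detection sets agree for >= 95% of peak groups
        k = len(pg) // 10
        top_full = set(np.argsort(-d_full)[:k])
        top_sub = set(np.argsort(-d_sub)[:k])
        assert len(top_full & top_sub) / k >= 0.95

    def test_constant_subscore_gets_zero_weight(self):
        df = _toy_records()
        df[SUB_SCORE_COLS[2]] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            w, _ = learn_discriminant(df, seed=0)
        assert w[2] == 0.0

    def test_no_decoys_raises(self):
        df = _toy_records()
        with pytest.raises(ValueError):
            learn_discriminant(df[~df["decoy"]], seed=0)


class TestQValues:
    def test_perfect_separation_gives_zero_qvalues(self):
        q = qvalues_from_scores(np.array([5.0, 6.0, 7.0]), np.array([0.0, 1.0, 2.0]))
        assert np.all(q == 0.0)

    def test_q_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(0)
        t = rng.normal(1, 1, 500)
        d = rng.normal(0, 1, 500)
        q = qvalues_from_scores(t, d)
        order = np.argsort(-t)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_duplicated_dataset_same_qvalues(self):
        rng = np.random.default_rng(1)
        t = rng.normal(1, 1, 200)
        d = rng.normal(0, 1, 200)
        q1 = qvalues_from_scores(t, d)
        q2 = qvalues_from_scores(np.r_[t, t], np.r_[d, d])[:200]
        assert np.allclose(q1, q2)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            qvalues_from_scores(np.ones(3), np.zeros(3), lam=1.5)

    def test_global_context_one_q_per_unit(self):
        df = _toy_records().assign(d_score=lambda x: x[SUB_SCORE_COLS[0]])
        tab = estimate_qvalues(df, context=GLOBAL, level="peptide")
        assert tab["unit_id"].is_unique

    def test_experiment_wide_one_q_per_unit_per_run(self, scored_study):
        _, scored, qtables, _ = scored_study
        rw = qtables["runwise_peptide"]
        assert not rw.duplicated(["unit_id", "run_id"]).any()

    def test_protein_level_uses_best_peptide_score(self):
        df = _toy_records().assign(d_score=lambda x: x[SUB_SCORE_COLS[0]])
        tab = estimate_qvalues(df, context=GLOBAL, level="protein")
        best = df[~df["decoy"]].groupby("protein_id")["d_score"].max()
        merged = tab[~tab["decoy"]].set_index("unit_id")["score"]
        assert np.allclose(best.sort_index(), merged.sort_index())


class TestConsecutiveFilter:
    def _tables(self, scored_study):
        _, scored, qtables, _ = scored_study
        return scored, qtables

    def test_conjunction_semantics(self, scored_study):
        scored, qt = self._tables(scored_study)
        det = consecutive_filter(
            qt["global_peptide"], qt["global_protein"], qt["runwise_peptide"], alpha=0.01, records=scored
        )
        gp = qt["global_peptide"]
        passing_global = set(gp.loc[(~gp["decoy"]) & (gp["q"] <= 0.01), "unit_id"])
        assert set(det.peptide.index) <= passing_global

    def test_alpha_one_equals_presence(self, scored_study):
        scored, qt = self._tables(scored_study)
        det = consecutive_filter(
            qt["global_peptide"], qt["global_protein"], qt["runwise_peptide"], alpha=1.0, records=scored
        )
        targets = scored[~scored["decoy"]]
        present_pairs = set(zip(targets["peptide_query_id"], targets["run_id"]))
        detected_pairs = {
            (u, r) for u, row in det.peptide.iterrows() for r, v in row.items() if v
        }
        assert detected_pairs == present_pairs

    def test_protein_detected_iff_any_query_detected(self, scored_study):
        (_, scored, _, det) = scored_study
        prot_of = (
            scored.loc[~scored["decoy"], ["peptide_query_id", "protein_id"]]
            .drop_duplicates("peptide_query_id")
            .set_index("peptide_query_id")["protein_id"]
        )
        pep_by_prot = det.peptide.groupby(prot_of.reindex(det.peptide.index)).any()
        common = pep_by_prot.index.intersection(det.protein.index)
        pd.testing.assert_frame_equal(pep_by_prot.loc[common], det.protein.loc[common], check_names=False)

    def test_missing_table_raises(self, scored_study):
        scored, qt = self._tables(scored_study)
        with pytest.raises(ValueError):
            consecutive_filter(qt["global_peptide"], None, qt["runwise_peptide"], records=scored)


class TestCumulativeCurve:
    def test_single_run_and_flat_curve(self):
        det = pd.DataFrame({"r1": [True, True, False], "r2": [True, True, False]}, index=list("abc"))
        assert list(cumulative_detection_curve(det[["r1"]], ["r1"])) == [2]
        assert list(cumulative_detection_curve(det, ["r1", "r2"])) == [2, 2]

    def test_order_reversal_same_final_value(self, scored_study):
        (_, _, _, det) = scored_study
        runs = list(det.protein.columns)
        fwd = cumulative_detection_curve(det.protein, runs)
        rev = cumulative_detection_curve(det.protein, runs[::-1])
        assert fwd[-1] == rev[-1]
        assert np.all(np.diff(fwd) >= 0)

    def test_unknown_run_raises(self, scored_study):
        (_, _, _, det) = scored_study
        with pytest.raises(KeyError):
            cumulative_detection_curve(det.protein, ["nope"])


class TestCalibration:
    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_realized_fdp_within_twice_nominal(self, scored_study, alpha):
        small_study, _, qtables, _ = scored_study
        gq = qtables["global_peptide"]
        discovered = gq.loc[(~gq["decoy"]) & (gq["q"] <= alpha), "unit_id"]
        truly_present = set(
            small_study.truth.loc[small_study.truth["protein_present"], "peptide_query_id"]
        )
        fdp = np.mean([u not in truly_present for u in discovered])
        # one small study: allow for the granularity of a ~1e3-unit decoy pool
        assert fdp <= 2 * alpha + 0.015

    def test_detection_matrix_runs_subset_of_global_set(self, scored_study):
        # consecutive filtering guarantees every per-run detected unit passes globally
        _, _, qtables, det = scored_study
        gq = qtables["global_peptide"]
        global_set = set(gq.loc[(~gq["decoy"]) & (gq["q"] <= 0.01), "unit_id"])
        for run in det.peptide.columns:
            assert set(det.peptide.index[det.peptide[run]]) <= global_set
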