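"""Regressor banks, missing-protein flagging, association rules."""

import numpy as np
import pandas as pd
import pytest

from caskit.estimators import EstimatorSpec
from caskit.features import FeatureMatrix
from caskit.imputation import (MissingScoreImputer, association_rules,
                               flag_missing_candidates, impute_then_classify,
                               impute_vector, predict_missing,
                               subtype_protein_support, train_regressor_bank)
from caskit.metrics import mean_absolute_error
from caskit.pipeline import fit
from caskit.simulate import (SimConfig, generate_bitscore_dataset,
                             make_incomplete_cassettes)


def _planted_rule_matrix(seed=0, n=200, noise_sd=0.02):
    """target = 0.5 * driver + noise, plus two nuisance features."""
    r = np.random.default_rng(seed)
    driver = r.uniform(0.2, 1.0, n)
    target = np.clip(0.5 * driver + r.normal(0, noise_sd, n), 0, 1)
    other = r.uniform(0, 1, (n, 2))
    data = pd.DataFrame({"driver": driver, "target": target,
                         "nuis1": other[:, 0], "nuis2": other[:, 1]})
    data.index = pd.Index([f"c{i}" for i in range(n)], name="cassette_id")
    return FeatureMatrix(data)


class TestSupport:
    def test_support_follows_nonzero_columns(self):
        data = pd.DataFrame({"cas1": [0.5, 0.2], "cas2": [0.0, 0.0],
                             "cas3": [0.0, 0.9]})
        data.index.name = "cassette_id"
        m = FeatureMatrix(data, pd.Series(["A", "A"], index=data.index))
        assert subtype_protein_support(m, "A") == ["cas1", "cas3"]
        assert subtype_protein_support(m, "global") == ["cas1", "cas3"]

    def test_family_nonzero_only_elsewhere_excluded(self):
        data = pd.DataFrame({"cas1": [0.5, 0.0], "cas2": [0.0, 0.7]})
        data.index.name = "cassette_id"
        m = FeatureMatrix(data, pd.Series(["A", "B"], index=data.index))
        assert subtype_protein_support(m, "A") == ["cas1"]

    def test_all_zero_scope_rejected(self):
        data = pd.DataFrame({"cas1": [0.0], "cas2": [0.0]})
        data.index.name = "cassette_id"
        m = FeatureMatrix(data, pd.Series(["A"], index=data.index))
        with pytest.raises(ValueError, match="support"):
            subtype_protein_support(m, "A")


class TestBankTraining:
    def test_bank_shape_and_self_exclusion(self):
        matrix = _planted_rule_matrix()
        bank = train_regressor_bank(matrix, "global", seed=0)
        assert len(bank.regressors) == len(bank.support) == 4
        for target in bank.support:
            inputs = bank.inputs_for(target)
            assert target not in inputs and len(inputs) == 3

    def test_planted_rule_cross_validated_mae_small(self):
        matrix = _planted_rule_matrix(seed=1)
        bank = train_regressor_bank(matrix, "global", seed=0)
        assert bank.cv_mae["target"] <= 0.05

    def test_deterministic_given_seed(self):
        matrix = _planted_rule_matrix(seed=2)
        row = matrix.data.iloc[0]
        p1 = train_regressor_bank(matrix, seed=3).predict(row, "target")
        p2 = train_regressor_bank(matrix, seed=3).predict(row, "target")
        assert p1 == p2

    def test_small_scope_rejected(self):
        matrix = _planted_rule_matrix(n=5)
        with pytest.raises(ValueError, match="rows"):
            train_regressor_bank(matrix, "global", seed=0)

    def test_per_subtype_scope(self, separable_matrix):
        matrix, _ = separable_matrix
        bank = train_regressor_bank(matrix, "S1", seed=0)
        assert bank.scope == "S1"
        assert set(bank.support) <= set(matrix.families)


class TestPrediction:
    def test_heldout_predictions_close_to_truth(self):
        train = _planted_rule_matrix(seed=4)
        test = _planted_rule_matrix(seed=5)
        bank = train_regressor_bank(train, "global", seed=0)
        errors = [abs(bank.predict(row, "target") - row["target"])
                  for _, row in test.data.iterrows()]
        assert np.mean(np.asarray(errors) <= 0.1) >= 0.95

    def test_clipped_to_unit_interval(self):
        matrix = _planted_rule_matrix()
        bank = train_regressor_bank(matrix, seed=0)
        vec = pd.Series({"driver": 5.0, "target": 0.0, "nuis1": 3.0, "nuis2": 2.0})
        assert 0.0 <= bank.predict(vec, "target") <= 1.0

    def test_prediction_ignores_families_outside_support(self):
        matrix = _planted_rule_matrix()
        bank = train_regressor_bank(matrix, seed=0)
        vec = matrix.data.iloc[0].copy()
        base = bank.predict(vec, "target")
        vec["unrelated"] = 0.99
        assert bank.predict(vec, "target") == base

    def test_target_outside_support_rejected(self):
        bank = train_regressor_bank(_planted_rule_matrix(), seed=0)
        with pytest.raises(KeyError):
            predict_missing(bank, pd.Series(dtype=float), "cas99")

    def test_mask_and_recover_consistency(self):
        """Masking one nonzero entry and predicting it stays within the
        bank's own cross-validated error plus a small margin."""
        matrix = _planted_rule_matrix(seed=6)
        bank = train_regressor_bank(matrix, "global", seed=0)
        errs = []
        for rid in matrix.data.index[:50]:
            row = matrix.data.loc[rid].copy()
            truth = row["target"]
            row["target"] = 0.0
            errs.append(abs(bank.predict(row, "target") - truth))
        assert np.mean(errs) <= bank.cv_mae["target"] + 0.02


class TestFlagging:
    def test_no_zero_entries_nothing_flagged(self):
        bank = train_regressor_bank(_planted_rule_matrix(), seed=0)
        vec = pd.Series({"driver": 0.8, "target": 0.4, "nuis1": 0.5, "nuis2": 0.5})
        assert flag_missing_candidates(bank, vec) == []

    def test_predictable_zero_flagged_above_threshold(self):
        bank = train_regressor_bank(_planted_rule_matrix(), seed=0)
        vec = pd.Series({"driver": 1.0, "target": 0.0, "nuis1": 0.5, "nuis2": 0.5})
        flags = flag_missing_candidates(bank, vec, evidence_threshold=0.3)
        assert any(f == "target" for f, _ in flags)
        assert flags == sorted(flags, key=lambda t: -t[1])

    def test_impossible_threshold_flags_nothing(self):
        bank = train_regressor_bank(_planted_rule_matrix(), seed=0)
        vec = pd.Series({"driver": 1.0, "target": 0.0, "nuis1": 0.0, "nuis2": 0.0})
        assert flag_missing_candidates(bank, vec, evidence_threshold=1.1) == []


class TestAssociationRules:
    def test_planted_driver_ranks_first(self):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            matrix = _planted_rule_matrix(seed=seed)
            bank = train_regressor_bank(matrix, "global", seed=seed)
            rules = association_rules(bank, targets=["target"], top_k=3)
            hits += (rules["target"][0][0] == "driver")
        assert hits >= 0.95 * n_runs

    def test_importances_normalized_and_clipped(self):
        bank = train_regressor_bank(_planted_rule_matrix(), seed=0)
        rules = association_rules(bank, top_k=10)
        for target, ranked in rules.items():
            assert len(ranked) == 3  # l - 1 inputs < top_k
            assert sum(w for _, w in ranked) == pytest.approx(1.0)

    def test_non_ensemble_bank_rejected(self):
        bank = train_regressor_bank(_planted_rule_matrix(),
                                    spec=EstimatorSpec("decision_tree", task="regression"),
                                    seed=0)
        with pytest.raises(TypeError):
            association_rules(bank)


@pytest.fixture(scope="module")
def redundant_setup():
    """Subtypes with two redundant signature families each, so a masked
    signature is recoverable from its partner."""
    cfg = SimConfig(k_subtypes=3, n_per_subtype=60, m_families=9,
                    background_presence=0.05, seed=77,
                    signature_map={"S1": ["cas1", "cas2"], "S2": ["cas3", "cas4"],
                                   "S3": ["cas5", "cas6"]})
    matrix, truth = generate_bitscore_dataset(cfg)
    clf = fit(EstimatorSpec("randomized_ensemble"), matrix.X, matrix.y, seed=0)
    bank = train_regressor_bank(matrix, "global", seed=0)
    return matrix, truth, clf, bank


class TestImputeThenClassify:
    def test_no_flags_leaves_classification_unchanged(self, redundant_setup):
        matrix, _, clf, bank = redundant_setup
        row = matrix.data.iloc[0]
        res = impute_then_classify(row, bank, clf, evidence_threshold=1.1)
        assert res["subtype"] == clf.predict(row.to_numpy()[None, :])[0]
        assert res["flags"] == []
        assert res["original"].equals(row)

    def test_imputation_recovers_masked_signature(self, redundant_setup):
        matrix, _, clf, bank = redundant_setup
        incomplete, mask = make_incomplete_cassettes(matrix, seed=5)
        recovered = 0
        checked = 0
        for rid, masked_fams in list(mask.items())[:40]:
            fam, truth_val = next(iter(masked_fams.items()))
            if truth_val < 0.5:
                continue
            row = incomplete.data.loc[rid]
            imputed, flags = impute_vector(bank, row, 0.5)
            checked += 1
            recovered += any(f == fam for f, _ in flags)
        assert checked > 10
        assert recovered / checked >= 0.8

    def test_imputation_does_not_hurt_accuracy(self, redundant_setup):
        matrix, _, clf, bank = redundant_setup
        incomplete, _ = make_incomplete_cassettes(matrix, seed=6)
        y = matrix.y
        raw_pred = clf.predict(incomplete.X)
        imp_pred = [impute_then_classify(row, bank, clf)["subtype"]
                    for _, row in incomplete.data.iterrows()]
        assert (np.array(imp_pred) == y).mean() >= (raw_pred == y).mean()

    def test_idempotent_for_deterministic_bank(self, redundant_setup):
        matrix, _, clf, bank = redundant_setup
        incomplete, _ = make_incomplete_cassettes(matrix, seed=7)
        row = incomplete.data.iloc[0]
        once, _ = impute_vector(bank, row, 0.5)
        twice, _ = impute_vector(bank, once, 0.5)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_dimension_mismatch_rejected(self, redundant_setup):
        matrix, _, clf, bank = redundant_setup
        short = matrix.data.iloc[0][:-2]
        with pytest.raises(ValueError, match="families"):
            impute_then_classify(short, bank, clf)


class TestImputerTransformer:
    def test_sklearn_transform_round_trip(self):
        matrix = _planted_rule_matrix(seed=9)
        imputer = MissingScoreImputer(evidence_threshold=0.05, random_state=0)
        imputer.fit(matrix)
        masked = matrix.data.copy()
        masked.iloc[0, masked.columns.get_loc("target")] = 0.0
        out = imputer.transform(FeatureMatrix(masked))
        assert out.data.iloc[0]["target"] > 0.0
        # untouched rows unchanged
        assert np.allclose(out.data.iloc[1:].to_numpy(),
                           matrix.data.iloc[1:].to_numpy())


class TestBankSerialization:
    def test_save_load_round_trip(self, tmp_path):
        matrix = _planted_rule_matrix(seed=12)
        bank = train_regressor_bank(matrix, "global", seed=0)
        path = tmp_path / "bank.joblib"
        bank.save(path)
        from caskit.imputation import RegressorBank

        loaded = RegressorBank.load(path)
        assert loaded.support == bank.support
        assert loaded.spec.algorithm == bank.spec.algorithm
        row = matrix.data.iloc[0]
        assert loaded.predict(row, "target") == bank.predict(row, "target")
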