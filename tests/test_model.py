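import numpy as np
import pandas as pd
import pytest

from lungrp.features import ALL_FEATURE_NAMES
from lungrp.model import (
    DVH_PARAMETERS,
    EnsembleModel,
    Signature,
    SubsetModel,
    feasible_subset_counts,
    fit_dvh_model,
    fit_radiomic_ensemble,
    fit_subset_model,
    partition_balanced_subsets,
    select_dvh_combination,
    select_signature,
)


def _labels(n_pos, n_neg):
    ids = [f"P{i:03d}" for i in range(n_pos + n_neg)]
    return pd.Series([1] * n_pos + [0] * n_neg, index=ids)


class TestPartition:
    def test_22_223_splits_into_7x22_plus_3x23(self):
        subsets = partition_balanced_subsets(_labels(22, 223), k=10, seed=1)
        sizes = sorted(len(s.negative_ids) for s in subsets)
        assert sizes == [22] * 7 + [23] * 3
        assert all(len(s.positive_ids) == 22 for s in subsets)
        assert all(len(s.ids) in (44, 45) for s in subsets)

    def test_negatives_partition_exactly(self):
        labels = _labels(22, 223)
        subsets = partition_balanced_subsets(labels, k=10, seed=2)
        groups = [set(s.negative_ids) for s in subsets]
        union = set().union(*groups)
        assert union == set(labels.index[labels == 0])
        assert sum(len(g) for g in groups) == len(union)  # pairwise disjoint

    def test_small_even_split(self):
        subsets = partition_balanced_subsets(_labels(5, 10), k=2, seed=0)
        assert [len(s.negative_ids) for s in subsets] == [5, 5]

    def test_infeasible_k_lists_alternatives(self):
        with pytest.raises(ValueError, match="feasible k"):
            partition_balanced_subsets(_labels(5, 10), k=4, seed=0)
        assert 10 in feasible_subset_counts(22, 223)

    def test_partition_is_seeded(self):
        a = partition_balanced_subsets(_labels(5, 10), k=2, seed=3)
        b = partition_balanced_subsets(_labels(5, 10), k=2, seed=3)
        c = partition_balanced_subsets(_labels(5, 10), k=2, seed=4)
        assert a == b
        assert a != c


def _planted_table(n=30, n_noise=485, seed=0):
    """One informative feature among noise; labels follow the signal."""
    rng = np.random.default_rng(seed)
    ids = [f"P{i:03d}" for i in range(n)]
    y = pd.Series(([1, 0] * (n // 2 + 1))[:n], index=ids)
    signal = y.to_numpy() * 2.0 + rng.normal(0, 0.5, size=n)
    noise = rng.normal(size=(n, n_noise))
    cols = ["signal"] + [f"noise{i}" for i in range(n_noise)]
    x = pd.DataFrame(np.column_stack([signal, noise]), index=ids, columns=cols)
    return x, y


class TestSelectSignature:
    def test_planted_feature_ranks_first(self):
        x, y = _planted_table(seed=1)
        sig = select_signature(x, y, n_repeats=50, top_k=4, seed=5)
        assert sig.feature_names[0] == "signal"
        assert sig.frequencies[0] >= 45  # selected in nearly every repeat

    def test_default_signature_length_is_four(self):
        x, y = _planted_table(n_noise=40, seed=2)
        sig = select_signature(x, y, n_repeats=10, seed=6)
        assert len(sig.feature_names) == 4
        assert list(sig.frequencies) == sorted(sig.frequencies, reverse=True)

    def test_same_seed_same_signature(self):
        x, y = _planted_table(n_noise=40, seed=3)
        a = select_signature(x, y, n_repeats=10, seed=7)
        b = select_signature(x, y, n_repeats=10, seed=7)
        assert a == b

    def test_needs_two_patients_per_class(self):
        x, y = _planted_table(n_noise=5, seed=4)
        with pytest.raises(ValueError):
            select_signature(x, y.replace({0: 1}), n_repeats=5, seed=0)


def _stub_member(prob):
    """A member whose predicted probability is constant = prob."""
    logit = float(np.log(prob / (1 - prob)))
    sig = Signature(feature_names=("f",), frequencies=(1,))
    return SubsetModel(
        signature=sig,
        coefficients=np.array([0.0]),
        intercept=logit,
        center=np.array([0.0]),
        scale=np.array([1.0]),
    )


class TestEnsemble:
    def test_mean_of_member_probabilities(self):
        features = pd.DataFrame({"f": [0.0, 1.0]})
        ens = EnsembleModel(members=[_stub_member(p) for p in (0.2, 0.4, 0.6)])
        np.testing.assert_allclose(ens.predict_proba(features), [0.4, 0.4])

    def test_identical_members_equal_any_member(self):
        features = pd.DataFrame({"f": [0.3]})
        ens = EnsembleModel(members=[_stub_member(0.7)] * 4)
        np.testing.assert_allclose(ens.predict_proba(features), [0.7])

    def test_missing_signature_feature_named_in_error(self):
        ens = EnsembleModel(members=[_stub_member(0.5)])
        with pytest.raises(KeyError, match="f"):
            ens.predict_proba(pd.DataFrame({"g": [1.0]}))

    def test_default_configuration_has_ten_members(self):
        x, y = _planted_table(n=46, n_noise=20, seed=5)
        # 23 positives / 23 negatives is infeasible for k=10; rebuild labels
        y = pd.Series([1] * 4 + [0] * 42, index=x.index)
        ens = fit_radiomic_ensemble(x, y, n_repeats=5, seed=1)
        assert ens.n_members == 10

    def test_json_round_trip_preserves_predictions(self):
        x, _ = _planted_table(n=20, n_noise=10, seed=6)
        y = pd.Series([1] * 5 + [0] * 15, index=x.index)
        ens = fit_radiomic_ensemble(x, y, k=3, n_repeats=5, seed=2)
        clone = EnsembleModel.from_json(ens.to_json())
        np.testing.assert_allclose(clone.predict_proba(x), ens.predict_proba(x))


class TestSubsetModel:
    def test_single_class_labels_rejected(self):
        x, _ = _planted_table(n=10, n_noise=3, seed=7)
        sig = Signature(feature_names=("signal",), frequencies=(5,))
        with pytest.raises(ValueError):
            fit_subset_model(x, pd.Series(1, index=x.index), sig)

    def test_probabilities_in_unit_interval(self):
        x, y = _planted_table(n=20, n_noise=5, seed=8)
        sig = Signature(feature_names=("signal", "noise0"), frequencies=(5, 3))
        model = fit_subset_model(x, y, sig)
        p = model.predict_proba(x * 100.0)
        assert ((p >= 0) & (p <= 1)).all()

    def test_separable_toy_orders_by_separating_direction(self):
        ids = list("abcdefgh")
        x = pd.DataFrame(
            {"u": [0.0, 0.1, 0.2, 0.3, 1.0, 1.1, 1.2, 1.3], "v": [0.5] * 8}, index=ids
        )
        y = pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=ids)
        sig = Signature(feature_names=("u", "v"), frequencies=(5, 5))
        model = fit_subset_model(x, y, sig)
        p = model.predict_proba(x)
        assert (np.diff(p) >= -1e-12).all()
        assert p[-1] > p[0]


class TestDvhModel:
    def test_candidate_pool_is_the_four_parameters(self):
        assert DVH_PARAMETERS == ("v5", "v10", "v20", "mld")

    def test_mld_selected_when_only_mld_varies(self):
        rng = np.random.default_rng(9)
        n = 24
        ids = [f"P{i:03d}" for i in range(n)]
        y = pd.Series([1, 0] * (n // 2), index=ids)
        mld = y.to_numpy() * 3.0 + rng.normal(0, 0.3, size=n)
        table = pd.DataFrame(
            {"v5": 40.0, "v10": 25.0, "v20": 10.0, "mld": mld}, index=ids
        )
        sig = select_dvh_combination(table, y, n_repeats=20, seed=3)
        assert sig.feature_names == ("mld",)

    def test_ensemble_structure_matches_radiomic_path(self):
        rng = np.random.default_rng(10)
        n_pos, n_neg = 4, 9
        ids = [f"P{i:03d}" for i in range(n_pos + n_neg)]
        y = pd.Series([1] * n_pos + [0] * n_neg, index=ids)
        table = pd.DataFrame(
            rng.normal(size=(n_pos + n_neg, 4)), index=ids, columns=DVH_PARAMETERS
        )
        table["mld"] += y * 3.0
        ens = fit_dvh_model(table, y, k=2, n_repeats=10, seed=4)
        assert ens.n_members == 2
        assert ens.roi == "DVH"
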