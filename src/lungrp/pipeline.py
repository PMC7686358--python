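"""End-to-end study driver: cohorts -> features -> models -> reports.

Wires the stages together under one seeded entry point so a whole
train/test study — synthetic cohorts, LV5 (or any LVx) radiomic
features, DVH parameters, the radiomic and DVH ensembles, and their
train/test evaluation reports — reproduces bit-identically from a
single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dosimetry import dvh_table
from .evaluate import EvalReport, evaluate_train_test
from .features import ALL_FEATURE_NAMES, FeatureConfig, extract_cohort_features
from .model import EnsembleModel, fit_dvh_model, fit_radiomic_ensemble
from .synthetic import CohortSpec, generate_cohort

__all__ = ["StudyResult", "run_rp_study"]


@dataclass
class StudyResult:
    """Everything one study run produces."""

    roi: str
    train_features: pd.DataFrame
    test_features: pd.DataFrame
    train_dvh: pd.DataFrame
    test_dvh: pd.DataFrame
    radiomic_model: EnsembleModel
    dvh_model: EnsembleModel
    radiomic_train: EvalReport
    radiomic_test: EvalReport
    dvh_train: EvalReport
    dvh_test: EvalReport

    def report_table(self) -> pd.DataFrame:
        rows = [
            r.to_dict()
            for r in (self.radiomic_train, self.radiomic_test, self.dvh_train, self.dvh_test)
        ]
        return pd.DataFrame(rows)


def _seeds(master_seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n)]


def run_rp_study(
    n_train_pos: int = 22,
    n_train_neg: int = 223,
    n_test_pos: int = 8,
    n_test_neg: int = 22,
    roi: str = "LV5",
    k: int = 10,
    n_repeats: int = 1000,
    top_k: int = 4,
    seed: int = 0,
    cohort_spec: CohortSpec | None = None,
    feature_config: FeatureConfig = FeatureConfig(),
) -> StudyResult:
    """Run the complete RP prediction study on synthetic cohorts.

    Cohort sizes default to the study design this pipeline emulates
    (22/223 training, 8/22 test). ``cohort_spec``, when given, supplies
    every generative parameter except the class sizes and seeds, which
    are overridden per cohort.
    """
    s_train, s_test, s_model, s_dvh = _seeds(seed, 4)
    base = cohort_spec if cohort_spec is not None else CohortSpec(n_positive=1, n_negative=1)
    train_spec = replace(base, n_positive=n_train_pos, n_negative=n_train_neg, seed=s_train)
    test_spec = replace(base, n_positive=n_test_pos, n_negative=n_test_neg, seed=s_test)

    train_cohort = generate_cohort(train_spec)
    test_cohort = generate_cohort(test_spec)

    train_features = extract_cohort_features(train_cohort, roi_label=roi, config=feature_config)
    test_features = extract_cohort_features(test_cohort, roi_label=roi, config=feature_config)
    train_dvh = dvh_table(train_cohort)
    test_dvh = dvh_table(test_cohort)

    feat_cols = list(ALL_FEATURE_NAMES)
    train_x = train_features[feat_cols]
    train_y = train_features["rp_label"]
    test_x = test_features[feat_cols]
    test_y = test_features["rp_label"]

    radiomic_model = fit_radiomic_ensemble(
        train_x, train_y, k=k, n_repeats=n_repeats, top_k=top_k, seed=s_model, roi=roi
    )
    dvh_model = fit_dvh_model(
        train_dvh, train_dvh["rp_label"], k=k, n_repeats=n_repeats, seed=s_dvh
    )

    rad_train, rad_test = evaluate_train_test(radiomic_model, train_x, train_y, test_x, test_y)
    dvh_train, dvh_test = evaluate_train_test(
        dvh_model,
        train_dvh,
        train_dvh["rp_label"],
        test_dvh,
        test_dvh["rp_label"],
    )

    return StudyResult(
        roi=roi,
        train_features=train_features,
        test_features=test_features,
        train_dvh=train_dvh,
        test_dvh=test_dvh,
        radiomic_model=radiomic_model,
        dvh_model=dvh_model,
        radiomic_train=rad_train,
        radiomic_test=rad_test,
        dvh_train=dvh_train,
        dvh_test=dvh_test,
    )
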