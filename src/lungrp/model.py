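"""RP predictive models: balanced subsets, LASSO signatures, ensembles.

Class imbalance (e.g. 22 RP vs 223 non-RP training patients) is handled
by partitioning the negatives into K disjoint groups of size n_pos or
n_pos + 1, joining each with all positives, and training one model per
balanced subset. Within a subset, a signature is built by repeating an
L1-penalized (LASSO) logistic regression on stratified bootstrap
resamples — the penalty re-chosen by internal cross-validation each
repeat — and ranking features by how often they receive a nonzero
coefficient; the top four features form the signature. The ensemble
prediction is the arithmetic mean of the K member probabilities.

The DVH baseline applies the same machinery to the four dose-volume
histogram parameters (V5, V10, V20, MLD), keeping the most frequently
selected nonzero parameter combination instead of a top-k cut.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "BalancedSubset",
    "Signature",
    "SubsetModel",
    "EnsembleModel",
    "partition_balanced_subsets",
    "select_signature",
    "select_dvh_combination",
    "fit_subset_model",
    "fit_radiomic_ensemble",
    "fit_dvh_model",
    "DVH_PARAMETERS",
]

DVH_PARAMETERS: tuple[str, ...] = ("v5", "v10", "v20", "mld")

_CS = np.logspace(-2.0, 2.0, 5)


@dataclass(frozen=True)
class BalancedSubset:
    """All positives joined with one disjoint draw of negatives."""

    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]
    index: int

    @property
    def ids(self) -> tuple[str, ...]:
        return self.positive_ids + self.negative_ids


@dataclass(frozen=True)
class Signature:
    """Top-k feature names with their selection counts."""

    feature_names: tuple[str, ...]
    frequencies: tuple[int, ...]
    roi: str = ""
    n_repeats: int = 0

    def __post_init__(self) -> None:
        if list(self.frequencies) != sorted(self.frequencies, reverse=True):
            raise ValueError("frequencies must be non-increasing in rank")


@dataclass
class SubsetModel:
    """One L1-logistic model on a subset, restricted to its signature."""

    signature: Signature
    coefficients: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.signature.feature_names if f not in features.columns]
        if missing:
            raise KeyError(f"feature table is missing signature features: {missing}")
        x = features[list(self.signature.feature_names)].to_numpy(dtype=float)
        z = (x - self.center) / self.scale
        logit = z @ self.coefficients + self.intercept
        return expit(logit)


@dataclass
class EnsembleModel:
    """K fitted subset models whose probabilities are averaged."""

    members: list[SubsetModel]
    roi: str = ""

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        if not self.members:
            raise ValueError("ensemble has no members")
        probs = np.stack([m.predict_proba(features) for m in self.members])
        return probs.mean(axis=0)

    def to_json(self) -> str:
        payload = {
            "roi": self.roi,
            "members": [
                {
                    "signature": list(m.signature.feature_names),
                    "frequencies": list(m.signature.frequencies),
                    "n_repeats": m.signature.n_repeats,
                    "coefficients": m.coefficients.tolist(),
                    "intercept": m.intercept,
                    "center": m.center.tolist(),
                    "scale": m.scale.tolist(),
                }
                for m in self.members
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        payload = json.loads(text)
        members = [
            SubsetModel(
                signature=Signature(
                    feature_names=tuple(m["signature"]),
                    frequencies=tuple(m["frequencies"]),
                    roi=payload.get("roi", ""),
                    n_repeats=m.get("n_repeats", 0),
                ),
                coefficients=np.asarray(m["coefficients"], dtype=float),
                intercept=float(m["intercept"]),
                center=np.asarray(m["center"], dtype=float),
                scale=np.asarray(m["scale"], dtype=float),
            )
            for m in payload["members"]
        ]
        return cls(members=members, roi=payload.get("roi", ""))


def feasible_subset_counts(n_pos: int, n_neg: int) -> list[int]:
    """All k for which the negatives split into k groups of n_pos or n_pos+1."""
    out = []
    for k in range(1, n_neg + 1):
        b = n_neg - k * n_pos  # number of (n_pos + 1)-sized groups
        if 0 <= b <= k:
            out.append(k)
    return out


def partition_balanced_subsets(
    labels: pd.Series, k: int = 10, seed: int = 0
) -> list[BalancedSubset]:
    """Disjoint balanced subsets from an imbalanced labeled cohort.

    ``labels`` maps patient id -> binary RP label. The negatives are
    randomly permuted (seeded) and split into k disjoint groups of size
    n_pos or n_pos + 1; each group is joined with all positives.
    """
    pos = tuple(labels.index[labels == 1])
    neg = list(labels.index[labels == 0])
    n_pos, n_neg = len(pos), len(neg)
    if n_pos < 2:
        raise ValueError("need at least 2 positive patients")
    if n_neg < n_pos:
        raise ValueError("need at least as many negatives as positives")
    b = n_neg - k * n_pos
    if not (0 <= b <= k):
        raise ValueError(
            f"cannot split {n_neg} negatives into {k} groups of size "
            f"{n_pos} or {n_pos + 1}; feasible k: {feasible_subset_counts(n_pos, n_neg)}"
        )
    a = k - b
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_neg)
    shuffled = [neg[i] for i in order]
    sizes = [n_pos] * a + [n_pos + 1] * b
    subsets = []
    start = 0
    for idx, size in enumerate(sizes, start=1):
        group = tuple(shuffled[start : start + size])
        start += size
        subsets.append(BalancedSubset(positive_ids=pos, negative_ids=group, index=idx))
    return subsets


def _standardize(x: np.ndarray):
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    keep = scale > 0
    return center, scale, keep


def _lasso_logistic_cv(x: np.ndarray, y: np.ndarray, random_state: int = 0):
    """L1 logistic with penalty chosen by stratified 3-fold CV."""
    n_splits = min(3, int(np.bincount(y).min()))
    model = LogisticRegressionCV(
        Cs=_CS,
        cv=StratifiedKFold(n_splits=n_splits),
        l1_ratios=(1.0,),
        scoring="neg_log_loss",
        solver="liblinear",
        max_iter=2000,
        random_state=random_state,
        use_legacy_attributes=False,
    )
    model.fit(x, y)
    return model


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


def _selection_runs(
    x: np.ndarray, y: np.ndarray, n_repeats: int, seed: int, min_class: int = 2
):
    """Yield the nonzero-coefficient pattern of each bootstrap LASSO fit."""
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        while True:
            idx = _stratified_bootstrap(y, rng)
            yb = y[idx]
            # bootstrap keeps class counts fixed, so both classes present
            if np.bincount(yb, minlength=2).min() >= min_class:
                break
        model = _lasso_logistic_cv(x[idx], yb)
        coef = model.coef_.ravel()
        yield np.abs(coef) > 1e-8, np.abs(coef)


def select_signature(
    features: pd.DataFrame,
    labels: pd.Series,
    n_repeats: int = 1000,
    top_k: int = 4,
    seed: int = 0,
    roi: str = "",
) -> Signature:
    """Selection-frequency signature from repeated bootstrap LASSO.

    Features are z-standardized on the subset; constant columns are
    dropped. Each repeat fits an L1 logistic regression (CV-chosen
    penalty) on a stratified bootstrap resample and records which
    features got nonzero coefficients. Features are ranked by selection
    count, ties broken by mean |coefficient| then name, and the top
    ``top_k`` returned.
    """
    labels = labels.loc[features.index]
    y = labels.to_numpy(dtype=int)
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least 2 patients per class")
    names = np.asarray(features.columns)
    x = features.to_numpy(dtype=float)
    center, scale, keep = _standardize(x)
    if not keep.all():
        logger.info("dropping %d constant feature columns", int((~keep).sum()))
    x = (x[:, keep] - center[keep]) / scale[keep]
    names = names[keep]

    counts = np.zeros(names.size, dtype=int)
    coef_sums = np.zeros(names.size, dtype=float)
    for selected, mags in _selection_runs(x, y, n_repeats, seed):
        counts += selected
        coef_sums += mags
    ever = counts > 0
    if ever.sum() < top_k:
        logger.warning(
            "only %d features were ever selected (< top_k=%d)", int(ever.sum()), top_k
        )
    mean_coef = np.where(counts > 0, coef_sums / np.maximum(counts, 1), 0.0)
    order = sorted(
        np.flatnonzero(ever),
        key=lambda i: (-counts[i], -mean_coef[i], names[i]),
    )[:top_k]
    return Signature(
        feature_names=tuple(names[i] for i in order),
        frequencies=tuple(int(counts[i]) for i in order),
        roi=roi,
        n_repeats=n_repeats,
    )


def select_dvh_combination(
    features: pd.DataFrame,
    labels: pd.Series,
    n_repeats: int = 1000,
    seed: int = 0,
    roi: str = "DVH",
) -> Signature:
    """Most frequently selected nonzero DVH parameter combination.

    Same bootstrap-LASSO scheme as the radiomic signatures, but the
    unit of selection is the whole combination of parameters with
    nonzero coefficients; the most frequent nonempty combination wins
    (ties: higher frequency, then fewer parameters, then name order).
    """
    labels = labels.loc[features.index]
    y = labels.to_numpy(dtype=int)
    names = np.asarray(features.columns)
    x = features.to_numpy(dtype=float)
    center, scale, keep = _standardize(x)
    x = (x[:, keep] - center[keep]) / scale[keep]
    names = names[keep]
    combos: Counter[tuple[str, ...]] = Counter()
    for selected, _ in _selection_runs(x, y, n_repeats, seed):
        combo = tuple(sorted(names[selected]))
        if combo:
            combos[combo] += 1
    if not combos:
        # fully uninformative data: retain the whole candidate pool
        logger.warning("LASSO never selected any DVH parameter; keeping all candidates")
        return Signature(
            feature_names=tuple(names),
            frequencies=(0,) * len(names),
            roi=roi,
            n_repeats=n_repeats,
        )
    best = sorted(combos.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))[0]
    combo, freq = best
    return Signature(
        feature_names=combo,
        frequencies=(freq,) * len(combo),
        roi=roi,
        n_repeats=n_repeats,
    )


def fit_subset_model(
    features: pd.DataFrame, labels: pd.Series, signature: Signature
) -> SubsetModel:
    """L1-penalized logistic fit on the signature columns of one subset.

    The penalty keeps coefficients finite even under perfect separation
    (a warning is logged when the training fit is separable).
    """
    if not signature.feature_names:
        raise ValueError("signature is empty")
    labels = labels.loc[features.index]
    y = labels.to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("labels are single-class; cannot fit")
    x = features[list(signature.feature_names)].to_numpy(dtype=float)
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x - center) / scale
    model = _lasso_logistic_cv(z, y)
    prob = model.predict_proba(z)[:, 1]
    if ((prob > 0.5).astype(int) == y).all():
        logger.warning("subset training data is separable; penalty bounds coefficients")
    return SubsetModel(
        signature=signature,
        coefficients=model.coef_.ravel(),
        intercept=float(model.intercept_[0]),
        center=center,
        scale=scale,
    )


def _subset_seeds(seed: int, k: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(k + 1)]


def fit_radiomic_ensemble(
    features: pd.DataFrame,
    labels: pd.Series,
    k: int = 10,
    n_repeats: int = 1000,
    top_k: int = 4,
    seed: int = 0,
    roi: str = "",
) -> EnsembleModel:
    """Full radiomic pipeline: partition, per-subset signature + fit.

    ``features`` holds only feature columns (no label column), indexed
    by patient id; ``labels`` is the binary RP label per patient.
    """
    seeds = _subset_seeds(seed, k)
    subsets = partition_balanced_subsets(labels, k=k, seed=seeds[0])
    members = []
    for sub, s in zip(subsets, seeds[1:]):
        sub_x = features.loc[list(sub.ids)]
        sub_y = labels.loc[list(sub.ids)]
        sig = select_signature(sub_x, sub_y, n_repeats=n_repeats, top_k=top_k, seed=s, roi=roi)
        members.append(fit_subset_model(sub_x, sub_y, sig))
    return EnsembleModel(members=members, roi=roi)


def fit_dvh_model(
    dvh_table: pd.DataFrame,
    labels: pd.Series,
    k: int = 10,
    n_repeats: int = 1000,
    seed: int = 0,
) -> EnsembleModel:
    """DVH baseline ensemble over the four parameters V5, V10, V20, MLD."""
    missing = [c for c in DVH_PARAMETERS if c not in dvh_table.columns]
    if missing:
        raise KeyError(f"DVH table is missing columns: {missing}")
    features = dvh_table[list(DVH_PARAMETERS)]
    seeds = _subset_seeds(seed, k)
    subsets = partition_balanced_subsets(labels, k=k, seed=seeds[0])
    members = []
    for sub, s in zip(subsets, seeds[1:]):
        sub_x = features.loc[list(sub.ids)]
        sub_y = labels.loc[list(sub.ids)]
        sig = select_dvh_combination(sub_x, sub_y, n_repeats=n_repeats, seed=s)
        members.append(fit_subset_model(sub_x, sub_y, sig))
    return EnsembleModel(members=members, roi="DVH")
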