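"""Testing protocol: R^2 / RMSE, within-range partitioning, repeated 10-fold
cross-validation, and the two one-tailed significance tests.

Cross-validation performance for a configuration is summarised by *pooled*
metrics: within one trial the held-out predictions of all k folds are pooled
and a single R^2 / RMSE computed over them.  Trials differ only in their
random seed (fold shuffling, weight initialisation, dropout).

Because the k folds of a cross-validation share most of their training data,
per-trial scores are positively correlated and a naive paired t-test across
trials is anti-conservative.  The corrected resampled t-test inflates the
variance of the mean score difference by the train/test size ratio
rho = n_test / n_train = 1 / (k - 1):

    t = dbar / sqrt(s_d^2 * (1/n + rho)),   df = n - 1.

Welch's unequal-variance t-test is used for comparisons between independent
(non-CV) groups of trial scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cnn import CNNSpec, StrainCNN, StrainMeasure, TrainingConfig
from .kinematics import VelocityProfile, peak_resultant


@dataclass(frozen=True)
class EvalResult:
    """Pooled metrics for one test set (or one CV trial)."""

    r2: float
    rmse: float
    n_total: int
    n_within: int
    measure: StrainMeasure | None = None
    trial_seed: int | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.n_within > self.n_total:
            raise ValueError("inconsistent evaluation result")


@dataclass(frozen=True)
class CVPlan:
    """Repeated k-fold cross-validation layout."""

    k: int = 10
    n_trials: int = 30
    seeds: tuple = ()

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need k >= 2 folds")
        seeds = tuple(self.seeds) if self.seeds else tuple(range(self.n_trials))
        if len(seeds) != self.n_trials:
            raise ValueError("len(seeds) must equal n_trials")
        object.__setattr__(self, "seeds", seeds)


def r_squared(pred, truth) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    SS_tot is taken about the mean of ``truth``; a constant truth vector has
    no variance to explain and is rejected.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape or len(truth) < 2:
        raise ValueError("need equal-length arrays with at least 2 elements")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant truth")
    ss_res = float(np.sum((pred - truth) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(pred, truth) -> float:
    """Root mean squared error."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape or len(truth) < 1:
        raise ValueError("need equal-length, non-empty arrays")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def peak_magnitudes(data) -> np.ndarray:
    """Peak resultant velocity per item, for profiles or encoded arrays."""
    if isinstance(data, np.ndarray):
        if data.ndim != 3:
            raise ValueError("expected (N, 3, T) encoded array")
        return np.linalg.norm(data, axis=1).max(axis=1)
    return np.array([peak_resultant(p).peak_magnitude for p in data])


def split_within_range(data, v_min: float = 21.9, v_max: float = 40.0):
    """Partition indices by peak resultant velocity strictly inside
    (v_min, v_max); returns (within_idx, outside_idx)."""
    peaks = peak_magnitudes(data)
    within = np.flatnonzero((peaks > v_min) & (peaks < v_max))
    outside = np.flatnonzero(~((peaks > v_min) & (peaks < v_max)))
    return within, outside


def evaluate(pred, truth, data=None, v_min: float = 21.9, v_max: float = 40.0,
             measure=None, trial_seed=None) -> dict:
    """Full-set and within-range metrics for one prediction vector.

    ``data`` (profiles or encoded array) supplies peak magnitudes for the
    within-range partition; without it only full-set metrics are reported.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    out = {"all": EvalResult(r_squared(pred, truth), rmse(pred, truth),
                             len(truth), len(truth), measure, trial_seed)}
    if data is not None:
        within, _ = split_within_range(data, v_min, v_max)
        if len(within) >= 2:
            out["within"] = EvalResult(
                r_squared(pred[within], truth[within]),
                rmse(pred[within], truth[within]),
                len(truth), len(within), measure, trial_seed)
    return out


def kfold_cv(inputs: np.ndarray, labels: np.ndarray, plan: CVPlan,
             measure: StrainMeasure | None = None,
             spec: CNNSpec | None = None,
             config: TrainingConfig | None = None,
             verbose: bool = False) -> list[EvalResult]:
    """Repeated k-fold cross-validation of the CNN; one EvalResult per trial.

    Per trial: shuffle sample indices with the trial seed, split into k
    contiguous folds, train on k-1 folds and predict the held-out fold,
    pool all held-out predictions, and compute pooled R^2 / RMSE.
    """
    inputs = np.asarray(inputs, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    n = len(labels)
    if n < plan.k:
        raise ValueError("dataset smaller than the number of folds")
    spec = spec or CNNSpec()
    config = config or TrainingConfig()
    results = []
    for trial, seed in enumerate(plan.seeds):
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.array_split(order, plan.k)
        pooled_pred = np.empty(n)
        for i, test_idx in enumerate(folds):
            if len(test_idx) < 1:
                raise ValueError("fold with fewer than 1 sample")
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
            model = StrainCNN(inputs[train_idx], labels[train_idx],
                              measure=measure, spec=spec, config=config)
            res = model.fit(seed=int(rng.integers(2 ** 31 - 1)))
            pooled_pred[test_idx] = res.predict(inputs[test_idx])
            if verbose:
                print(f"trial {trial} fold {i}: "
                      f"val MSE {res.history['best_val_loss']:.3e}")
        results.append(EvalResult(
            r_squared(pooled_pred, labels), rmse(pooled_pred, labels),
            n, n, measure, int(seed)))
    return results


def corrected_cv_ttest(scores_a, scores_b, k: int = 10) -> tuple[float, float]:
    """Corrected resampled one-tailed paired t-test for repeated CV scores.

    Tests H1: mean(scores_a) > mean(scores_b).  The variance of the mean
    paired difference is inflated by rho = 1/(k-1) to account for the
    overlap of training sets across folds; df = n - 1.

    Returns (t, one-sided p).  With zero variance: p = 0.5 for a zero mean
    difference, else the 0/1 limit.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need paired score vectors of equal length >= 2")
    d = a - b
    n = len(d)
    dbar = d.mean()
    s2 = d.var(ddof=1)
    rho = 1.0 / (k - 1)
    if s2 == 0:
        if dbar == 0:
            return 0.0, 0.5
        return (np.inf, 0.0) if dbar > 0 else (-np.inf, 1.0)
    t = dbar / np.sqrt(s2 * (1.0 / n + rho))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p


def welch_ttest(a, b) -> tuple[float, float]:
    """Welch's one-tailed t-test for H1: mean(a) > mean(b).

    Unequal variances, Welch-Satterthwaite degrees of freedom.  Returns
    (t, one-sided p); two zero-variance samples with equal means give
    p = 0.5 by convention.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 0.5
        return (np.inf, 0.0) if a.mean() > b.mean() else (-np.inf, 1.0)
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)
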