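"""Auto- vs cross-prediction: how idiosyncratic is a listening strategy?

Each observer's held-out responses are predicted by their own ACI
(auto-prediction, the 10-fold cross-validated deviance) and by every
other observer's final ACI (cross-prediction).  The specificity of a
listener's strategy is the mean cross-prediction deviance of their data
minus their auto-prediction deviance: large values mean a substantial
share of the responses is predictable only by the listener's own map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from acimage.fit import (ACIModel, PROBA_CLIP, balance_indices,
                         classification_rate, deviance, make_folds)


@dataclass
class PredictionMatrix:
    """Cross-prediction deviances for a cohort of N observers.

    ``cross_cvd[j, k]`` is the deviance of model j predicting observer
    k's balanced held-out data; the diagonal carries the auto-
    prediction CVDs by construction.
    """

    observers: list[str]
    auto_cvd: np.ndarray
    cross_cvd: np.ndarray
    auto_rate: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.observers)
        if self.cross_cvd.shape != (n, n):
            raise ValueError("cross_cvd must be N x N")
        if not np.all(np.isfinite(self.cross_cvd)):
            raise ValueError("cross_cvd must be finite")
        if not np.allclose(np.diag(self.cross_cvd), self.auto_cvd):
            raise ValueError("diagonal must equal auto_cvd")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cross_cvd, index=self.observers,
                            columns=self.observers)


@dataclass
class SpecificityResult:
    """Per-observer strategy specificity (mean cross CVD - auto CVD)."""

    observers: list[str]
    specificity: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"observer": self.observers,
                             "specificity": self.specificity})


def cross_predict(model: ACIModel, X_k: np.ndarray, trials_k: pd.DataFrame,
                  folds_k: np.ndarray, seed: int = 0) -> float:
    """Deviance of ``model`` on observer k's balanced test folds.

    The same fold partition and balancing seeds as k's own cross-
    validation are applied, so auto- and cross-prediction deviances are
    sums over identical test sets; the model's stored standardization
    is applied to k's predictors (the model is a fixed decision rule).
    """
    r = trials_k["response"].to_numpy()
    correct = trials_k["correct"].to_numpy(dtype=bool)
    devs = []
    for f in np.unique(folds_k):
        te_idx = np.flatnonzero(folds_k == f)
        te_bal = te_idx[balance_indices(correct[te_idx],
                                        seed=seed * 1000 + 500 + int(f))]
        p = model.predict_proba(X_k[te_bal].astype(np.float64))
        devs.append(deviance(r[te_bal], p))
    return float(np.mean(devs))


def prediction_matrix(models: list[ACIModel],
                      datasets: list[tuple[np.ndarray, pd.DataFrame]],
                      seeds: list[int] | None = None,
                      n_folds: int = 10) -> PredictionMatrix:
    """Full N x N auto/cross-prediction deviance matrix.

    ``datasets[k] = (X_k, trials_k)`` must be the data the k-th model
    was estimated from; ``seeds[k]`` the fold/balance seed used there.
    Off-diagonal entries are computed by :func:`cross_predict`; the
    diagonal carries each model's own cross-validated deviance.
    """
    n = len(models)
    if len(datasets) != n:
        raise ValueError("one dataset per model required")
    if seeds is None:
        seeds = [0] * n
    auto = np.array([m.cvd for m in models], dtype=float)
    if np.any(~np.isfinite(auto)):
        raise ValueError("models must carry their cross-validated "
                         "deviance (cvd)")
    folds = []
    for k, (X_k, trials_k) in enumerate(datasets):
        fa = models[k].fold_assignment
        folds.append(fa if fa is not None
                     else make_folds(len(trials_k), n_folds=n_folds,
                                     seed=seeds[k]))
    cross = np.empty((n, n))
    for k, (X_k, trials_k) in enumerate(datasets):
        for j in range(n):
            if j == k:
                cross[j, k] = auto[k]
            else:
                cross[j, k] = cross_predict(models[j], X_k, trials_k,
                                            folds[k], seed=seeds[k])
    rate = np.array([m.cvr for m in models], dtype=float)
    return PredictionMatrix(observers=[m.label for m in models],
                            auto_cvd=auto, cross_cvd=cross, auto_rate=rate)


def specificity(pm: PredictionMatrix) -> SpecificityResult:
    """spec_k = mean_{j != k} cross_cvd[j, k] - auto_cvd[k]."""
    n = len(pm.observers)
    if n < 2:
        raise ValueError("specificity needs at least 2 observers")
    mask = ~np.eye(n, dtype=bool)
    mean_cross = np.array([pm.cross_cvd[mask[:, k], k].mean()
                           for k in range(n)])
    return SpecificityResult(observers=list(pm.observers),
                             specificity=mean_cross - pm.auto_cvd)
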