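"""Nested (double) cross-validation and model-quality metrics.

The scheme: the samples are split at random into ``n_folds`` (default 4)
near-equal folds.  For each fold the remaining 75% form the training set, on
which a leave-one-out cross-validation (LOOCV) selects the number of latent
variables minimising RMSECV; the model refitted at that complexity then
predicts the held-out 25%, which was never used for any modelling choice.
Rotating the folds, every sample receives exactly one out-of-fold prediction,
from which pooled validation metrics (RMSEP, R^2, slope, relative error) are
computed.

Metrics are computed on the modelling scale (log10 when the response was
log-transformed).  R^2 and slope come from the ordinary least-squares
regression of predicted on observed values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eem_data import EEMDataset
from .npls import CoefficientMap, NPLSRegressor, _as_tensor

__all__ = [
    "FoldPlan",
    "FoldResult",
    "DoubleCVReport",
    "make_fold_plan",
    "loocv_select_lvs",
    "evaluate_predictions",
    "variance_explained_y",
    "run_double_cv",
    "fit_final_model",
]

DEFAULT_MAX_LVS = 12


@dataclass(frozen=True)
class FoldPlan:
    """A seeded random partition of samples into near-equal folds."""

    n_samples: int
    n_folds: int
    seed: int
    assignments: np.ndarray

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.where(self.assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.where(self.assignments != fold)[0]


@dataclass
class FoldResult:
    fold: int
    chosen_lvs: int
    rmsecv: float
    rmsep: float
    r2_train: float
    r2_val: float
    slope_train: float
    slope_val: float
    variance_explained_pct: float
    relative_error_pct: float
    rmsecv_curve: np.ndarray


@dataclass
class DoubleCVReport:
    """Per-fold and pooled results of one double cross-validation run."""

    response_name: str
    fold_plan: FoldPlan
    folds: list[FoldResult]
    oof_predictions: pd.DataFrame  # columns: y_obs, y_pred, fold
    pooled: dict = field(default_factory=dict)

    @property
    def chosen_lvs(self) -> list[int]:
        return [f.chosen_lvs for f in self.folds]

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "n_samples": self.fold_plan.n_samples,
            "n_folds": self.fold_plan.n_folds,
            "seed": self.fold_plan.seed,
            "folds": [
                {
                    "fold": f.fold,
                    "chosen_lvs": f.chosen_lvs,
                    "rmsecv": f.rmsecv,
                    "rmsep": f.rmsep,
                    "r2_train": f.r2_train,
                    "r2_val": f.r2_val,
                    "slope_train": f.slope_train,
                    "slope_val": f.slope_val,
                    "variance_explained_pct": f.variance_explained_pct,
                    "relative_error_pct": f.relative_error_pct,
                    "rmsecv_curve": f.rmsecv_curve.tolist(),
                }
                for f in self.folds
            ],
            "pooled": self.pooled,
        }

    def save(self, json_path: str | Path, csv_path: str | Path | None = None) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        if csv_path is not None:
            self.oof_predictions.to_csv(csv_path, index_label="sample")


def make_fold_plan(n_samples: int, n_folds: int = 4, seed: int = 0) -> FoldPlan:
    """Randomly partition ``n_samples`` into ``n_folds`` folds of near-equal size.

    Fold sizes differ by at most one; the first ``n_samples % n_folds`` folds
    get the extra sample.  With n divisible by the fold count every validation
    fold has exactly n/n_folds samples (92 -> 23, 76 -> 19, 72 -> 18 for the
    default 4 folds).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_samples < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {n_samples}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    assignments = np.empty(n_samples, dtype=int)
    base, extra = divmod(n_samples, n_folds)
    start = 0
    for fold in range(n_folds):
        size = base + (1 if fold < extra else 0)
        assignments[perm[start : start + size]] = fold
        start += size
    return FoldPlan(n_samples=n_samples, n_folds=n_folds, seed=seed, assignments=assignments)


def loocv_select_lvs(
    dataset_train, y_train, max_lvs: int = DEFAULT_MAX_LVS
) -> tuple[int, np.ndarray]:
    """Select the number of LVs by leave-one-out cross-validation.

    For each F in 1..max_lvs the LOOCV predictions are computed by refitting
    on all-but-one samples (a single fit at max F per left-out sample; the
    sequential algorithm makes its F-truncations identical to separate fits).
    Returns the F minimising RMSECV (smallest F on ties) and the full
    RMSECV curve.
    """
    tensor, _, _ = _as_tensor(dataset_train)
    y = np.asarray(y_train, dtype=float).ravel()
    n = tensor.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 training samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response in training set")
    cap = n - 2
    if max_lvs > cap:
        warnings.warn(
            f"max_lvs={max_lvs} clipped to {cap} for training size {n}", stacklevel=2
        )
        max_lvs = cap
    max_lvs = max(1, max_lvs)
    preds = np.full((n, max_lvs), np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NPLSRegressor(n_components=max_lvs).fit(tensor[keep], y[keep])
        for F in range(1, max_lvs + 1):
            Fi = min(F, model.n_components_)
            preds[i, F - 1] = model.predict(tensor[i : i + 1], n_components=Fi)[0]
    # one contiguous reduction per F so the result is bit-identical to a
    # naive per-F refit loop
    rmsecv = np.array(
        [np.sqrt(np.mean(np.ascontiguousarray((preds[:, f] - y) ** 2)))
         for f in range(max_lvs)]
    )
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first (smallest F) on ties
    return chosen, rmsecv


def evaluate_predictions(y_obs, y_pred) -> dict:
    """RMSE, OLS R^2/slope of predicted on observed, and relative error (%).

    ``relative_error_pct = 100 * rmse / mean(y_obs)``. For constant
    observations R^2 and slope are reported as NaN.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise ValueError("y_obs and y_pred must be equal-length vectors of size >= 2")
    rmse = float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))
    if np.ptp(y_obs) == 0:
        r2 = slope = float("nan")
    else:
        res = stats.linregress(y_obs, y_pred)
        slope = float(res.slope)
        r2 = float(res.rvalue**2)
    mean_obs = float(np.mean(y_obs))
    rel = float("nan") if mean_obs == 0 else 100.0 * rmse / mean_obs
    return {"rmse": rmse, "r2": r2, "slope": slope, "relative_error_pct": rel}


def variance_explained_y(model: NPLSRegressor, dataset, y) -> float:
    """Percent of response variance captured: 100*(1 - SS_res/SS_tot)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = model.predict(dataset)
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def _subset(dataset, idx: np.ndarray):
    if isinstance(dataset, EEMDataset):
        return dataset.subset(idx)
    return np.asarray(dataset, dtype=float)[idx]


def run_double_cv(
    dataset,
    y,
    n_folds: int = 4,
    seed: int = 0,
    max_lvs: int = DEFAULT_MAX_LVS,
    response_name: str = "response",
    sample_ids: Sequence[str] | None = None,
) -> DoubleCVReport:
    """Run the full 4-fold double cross-validation with inner LOOCV.

    Deterministic given ``seed``; every sample appears in the external
    validation set exactly once.
    """
    tensor, _, _ = _as_tensor(dataset)
    y = np.asarray(y, dtype=float).ravel()
    n = tensor.shape[0]
    if y.shape[0] != n:
        raise ValueError("response length does not match sample count")
    if sample_ids is None:
        sample_ids = (
            dataset.samples if isinstance(dataset, EEMDataset) else [str(i) for i in range(n)]
        )
    plan = make_fold_plan(n, n_folds=n_folds, seed=seed)
    oof_pred = np.full(n, np.nan)
    folds: list[FoldResult] = []
    for fold in range(n_folds):
        tr, va = plan.train_indices(fold), plan.fold_indices(fold)
        ds_tr, ds_va = _subset(dataset, tr), _subset(dataset, va)
        chosen, curve = loocv_select_lvs(ds_tr, y[tr], max_lvs=max_lvs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=UserWarning)
            model = NPLSRegressor(n_components=chosen).fit(ds_tr, y[tr])
        yhat_tr = model.predict(ds_tr)
        yhat_va = model.predict(ds_va)
        oof_pred[va] = yhat_va
        m_tr = evaluate_predictions(y[tr], yhat_tr)
        m_va = evaluate_predictions(y[va], yhat_va)
        folds.append(
            FoldResult(
                fold=fold,
                chosen_lvs=model.n_components_,
                rmsecv=float(curve[chosen - 1]),
                rmsep=m_va["rmse"],
                r2_train=m_tr["r2"],
                r2_val=m_va["r2"],
                slope_train=m_tr["slope"],
                slope_val=m_va["slope"],
                variance_explained_pct=variance_explained_y(model, ds_tr, y[tr]),
                relative_error_pct=m_va["relative_error_pct"],
                rmsecv_curve=curve,
            )
        )
    pooled = evaluate_predictions(y, oof_pred)
    pooled = {
        "rmsep": pooled["rmse"],
        "r2_val": pooled["r2"],
        "slope_val": pooled["slope"],
        "relative_error_pct": pooled["relative_error_pct"],
    }
    oof = pd.DataFrame(
        {"y_obs": y, "y_pred": oof_pred, "fold": plan.assignments},
        index=list(sample_ids),
    )
    return DoubleCVReport(
        response_name=response_name,
        fold_plan=plan,
        folds=folds,
        oof_predictions=oof,
        pooled=pooled,
    )


def fit_final_model(
    dataset, y, chosen_lvs: int | Sequence[int]
) -> tuple[NPLSRegressor, CoefficientMap]:
    """Fit the production model on 100% of the samples.

    ``chosen_lvs`` may be a single F or the per-fold choices from a
    :class:`DoubleCVReport`; in the latter case the mode is used, ties broken
    toward fewer LVs.
    """
    if not np.isscalar(chosen_lvs):
        counts = pd.Series(list(chosen_lvs)).value_counts()
        top = counts[counts == counts.max()].index
        chosen_lvs = int(min(top))
    model = NPLSRegressor(n_components=int(chosen_lvs)).fit(dataset, y)
    return model, model.coefficient_map()
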