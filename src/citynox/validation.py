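"""10-fold cross-validation with RMSE / MAE / R² between predicted and measured.

Folds partition the records (not the sites); each fold is held out once, the
mixed model is refit on the rest, and the held-out records are predicted as if
their sites were new locations (site intercept = 0) while week intercepts from
the training fit are used.  That mimics the mapping task: predicting at places
never monitored, during weeks that were.

Metrics, with y the predicted and x the measured values over the n held-out
records: RMSE = sqrt(mean((y - x)^2)), MAE = mean(|y - x|), and R²_cv the
squared Pearson correlation between predicted and measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import CrossedLMM


def make_folds(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded record-level fold assignment; sizes differ by at most 1."""
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k
    rng.shuffle(labels)
    return labels


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    d = np.asarray(pred, float) - np.asarray(obs, float)
    return float(np.sqrt(np.mean(d * d)))


def mae(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(pred, float) - np.asarray(obs, float))))


def r2_pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation between predicted and measured values."""
    p = np.asarray(pred, float)
    o = np.asarray(obs, float)
    if np.std(p) == 0 or np.std(o) == 0:
        return 0.0
    return float(np.corrcoef(p, o)[0, 1] ** 2)


@dataclass
class CVResult:
    """Fold assignments, per-fold and pooled metrics, and prediction pairs."""

    folds: np.ndarray
    pairs: pd.DataFrame  # index = original row, columns: predicted, observed, fold
    per_fold: pd.DataFrame  # fold, n, rmse, mae, r2
    rmse: float
    mae: float
    r2_cv: float

    @property
    def n(self) -> int:
        return len(self.pairs)

    def plot_predicted_vs_measured(self, ax=None, **scatter_kwargs):
        """Scatter of held-out predictions against measurements with the 1:1
        line — the standard CV diagnostic figure."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(self.pairs["observed"], self.pairs["predicted"], s=12, alpha=0.6,
                   **scatter_kwargs)
        lim = [0.0, float(self.pairs[["observed", "predicted"]].max().max()) * 1.05]
        ax.plot(lim, lim, color="k", lw=1, ls="--")
        ax.set_xlim(lim)
        ax.set_ylim(lim)
        ax.set_xlabel("measured (µg/m³)")
        ax.set_ylabel("predicted (µg/m³)")
        ax.set_title(f"10-fold CV: R²={self.r2_cv:.2f}, RMSE={self.rmse:.1f}, "
                     f"MAE={self.mae:.1f}")
        return ax


def cross_validate(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    k: int = 10,
    seed: int = 0,
    site_col: str = "site_id",
    week_col: str = "iso_week",
    **model_kwargs,
) -> CVResult:
    """k-fold CV of the crossed mixed model with a frozen predictor set.

    Variable selection is *not* re-run per fold: the predictor list is fixed
    in advance, so the CV evaluates the final model, not the search.  Held-out
    sites get no site BLUP; held-out weeks reuse the training-fold week BLUP
    (weeks recur across sites, so they are almost always observed in
    training).  A held-out month absent from training falls back to the
    reference level, flagged by the underlying predict.
    """
    data = data.reset_index(drop=True)
    folds = make_folds(len(data), k=k, seed=seed)
    pred = np.full(len(data), np.nan)
    per_fold_rows = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        model = CrossedLMM.from_dataframe(
            data.loc[train], response, predictors,
            site_col=site_col, week_col=week_col, **model_kwargs,
        )
        result = model.fit()
        test_df = data.loc[test]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # unknown-month fallback is expected in CV
            p = result.predict(
                test_df[predictors], iso_week=test_df[week_col].to_numpy(), site_id=None
            )
        pred[test] = p
        per_fold_rows.append(
            {
                "fold": fold,
                "n": int(test.sum()),
                "rmse": rmse(p, test_df[response].to_numpy()),
                "mae": mae(p, test_df[response].to_numpy()),
                "r2": r2_pearson(p, test_df[response].to_numpy()),
            }
        )
    obs = data[response].to_numpy(dtype=float)
    pairs = pd.DataFrame({"predicted": pred, "observed": obs, "fold": folds})
    return CVResult(
        folds=folds,
        pairs=pairs,
        per_fold=pd.DataFrame(per_fold_rows),
        rmse=rmse(pred, obs),
        mae=mae(pred, obs),
        r2_cv=r2_pearson(pred, obs),
    )
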