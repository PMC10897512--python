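"""Supervised model building: buffer choice, forward stepwise, VIF pruning.

The selection strategy is the classic supervised land-use-regression recipe:

1. For each candidate variable, keep the single buffer radius whose feature is
   most correlated (|Pearson r|) with the response.
2. Forward stepwise on adjusted R²: at each step the remaining candidate with
   the highest adjusted R² is added, and retained only if its fitted sign
   matches the a-priori direction of association and the adjusted-R² gain is
   at least 1 percentage point.
3. Collinearity screen: variables with VIF > 3 are removed (largest first,
   iteratively) and the model is refit.

Adjusted R² during selection is computed from an OLS fit of the fixed-effects
design (candidates plus any base columns such as calendar-month dummies); the
mixed model is fit once, after selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: |r| below which a chosen buffer is flagged as weakly informative
LOW_CORRELATION = 0.1


@dataclass(frozen=True)
class CandidateVariable:
    """A predictor eligible for selection, with its a-priori sign."""

    name: str
    radii: tuple[float, ...]  # empty tuple = unbuffered variable
    a_priori_sign: str  # "+" or "-"
    category: str = "other"

    def __post_init__(self):
        if self.a_priori_sign not in ("+", "-"):
            raise ValueError(f"a_priori_sign must be '+' or '-', got {self.a_priori_sign!r}")

    def column(self, radius: float | None) -> str:
        return self.name if radius is None else f"{self.name}_{int(radius)}"


@dataclass
class BufferChoice:
    variable: str
    radius: float | None
    column: str
    pearson_r: float
    low_correlation: bool


@dataclass
class StepRecord:
    step: int
    variable: str
    column: str
    adj_r2_before: float
    adj_r2_after: float
    accepted: bool
    reason: str  # accepted | sign_violation | gain_below_threshold | vif_removal


@dataclass
class SelectionTrace:
    """Ordered record of every decision; replays to the final variable set."""

    steps: list[StepRecord] = field(default_factory=list)
    final_columns: list[str] = field(default_factory=list)
    final_adj_r2: float = np.nan
    vif_removed: list[str] = field(default_factory=list)

    def accepted_columns(self) -> list[str]:
        cols = [s.column for s in self.steps if s.accepted]
        return [c for c in cols if c not in self.vif_removed]

    def to_records(self) -> list[dict]:
        return [vars(s) for s in self.steps]


def adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R² of an OLS fit with intercept (X excludes the constant)."""
    n = len(y)
    X1 = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    p = X1.shape[1] - 1
    if n <= p + 1:
        raise ValueError(f"saturated fit: n={n}, predictors={p}")
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _ols_sign(y: np.ndarray, X: np.ndarray, col_index: int) -> float:
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    return float(np.sign(beta[col_index + 1]))


def choose_buffer(
    candidate: CandidateVariable, predictors: pd.DataFrame, response: np.ndarray
) -> BufferChoice | None:
    """Radius maximising |Pearson r| with the response; ties -> smaller radius.

    Returns None (with a warning) when the variable has zero variance at every
    radius.  Choices with |r| below ``LOW_CORRELATION`` are flagged, not
    dropped.
    """
    y = np.asarray(response, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations to choose a buffer")
    radii = candidate.radii or (None,)
    best: BufferChoice | None = None
    for radius in radii:
        col = candidate.column(radius)
        x = predictors[col].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            continue  # e.g. +inf road-distance sentinel
        if np.std(x) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        # strict > keeps the smaller radius on ties (radii are increasing)
        if best is None or abs(r) > abs(best.pearson_r):
            best = BufferChoice(candidate.name, radius, col, r, abs(r) < LOW_CORRELATION)
    if best is None:
        warnings.warn(
            f"candidate {candidate.name!r} has zero variance (or non-finite values) at all "
            "radii; dropped",
            stacklevel=2,
        )
    return best


def forward_stepwise(
    candidates: list[CandidateVariable],
    data: pd.DataFrame,
    response: str,
    gain_threshold: float = 0.01,
    base_columns: list[str] | None = None,
) -> SelectionTrace:
    """Sign-constrained forward stepwise selection on adjusted R².

    ``base_columns`` (e.g. calendar-month dummies) are always in the fit and
    never candidates for removal.  At each step, remaining candidates are
    ranked by the adjusted R² of the model including them; the best-ranked
    candidate that confirms its a-priori sign and gains at least
    ``gain_threshold`` (absolute) is accepted.  A top-ranked candidate whose
    fitted sign contradicts its a-priori direction is permanently rejected and
    the next-ranked tried.  Once the best remaining gain falls below the
    threshold, selection stops.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    y = data[response].to_numpy(dtype=float)
    base = list(base_columns or [])
    pool = {c.name: c for c in candidates}
    chosen = {
        name: bc
        for name, cand in pool.items()
        if (bc := choose_buffer(cand, data, y)) is not None
    }
    trace = SelectionTrace()
    accepted_cols: list[str] = []
    step = 0

    def design(cols: list[str]) -> np.ndarray:
        if not cols:
            return np.empty((len(y), 0))
        return data[cols].to_numpy(dtype=float)

    current_adj = adjusted_r2(y, design(base)) if base else adjusted_r2(y, design([]))
    active = set(chosen)
    while active:
        scored = []
        for name in active:
            cols = base + accepted_cols + [chosen[name].column]
            if len(y) <= len(cols) + 1:
                warnings.warn(
                    f"step refused: adding {name!r} would saturate the fit (n={len(y)})",
                    stacklevel=2,
                )
                continue
            scored.append((adjusted_r2(y, design(cols)), name))
        if not scored:
            break
        scored.sort(key=lambda t: -t[0])
        accepted_this_round = False
        for adj_after, name in scored:
            step += 1
            bc = chosen[name]
            gain = adj_after - current_adj
            if gain < gain_threshold:
                trace.steps.append(
                    StepRecord(step, name, bc.column, current_adj, adj_after, False,
                               "gain_below_threshold")
                )
                active.clear()  # best remaining gain is below threshold: stop
                break
            cols = base + accepted_cols + [bc.column]
            sign = _ols_sign(y, design(cols), len(base) + len(accepted_cols))
            wanted = 1.0 if pool[name].a_priori_sign == "+" else -1.0
            if sign != wanted:
                trace.steps.append(
                    StepRecord(step, name, bc.column, current_adj, adj_after, False,
                               "sign_violation")
                )
                active.discard(name)
                continue
            trace.steps.append(
                StepRecord(step, name, bc.column, current_adj, adj_after, True, "accepted")
            )
            accepted_cols.append(bc.column)
            active.discard(name)
            current_adj = adj_after
            accepted_this_round = True
            break
        if not accepted_this_round and active:
            # every remaining candidate was a sign violation this round
            if all(
                s.reason == "sign_violation"
                for s in trace.steps[-len(scored):]
            ):
                break
    trace.final_columns = base + accepted_cols
    trace.final_adj_r2 = current_adj
    return trace


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R²_k) from regressing
    column k on the remaining columns (with intercept)."""
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 columns")
    out = {}
    for k, name in enumerate(design.columns):
        others = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
        xk = X[:, k]
        beta, *_ = np.linalg.lstsq(others, xk, rcond=None)
        resid = xk - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((xk - xk.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prune(design: pd.DataFrame, threshold: float = 3.0) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively remove the largest-VIF column while any exceeds the threshold.

    Ties (e.g. a perfectly collinear duplicated pair, both VIF = inf) are
    broken by removing the later-added (right-most) column.  Returns the
    pruned design and the removal log in removal order.
    """
    work = design.copy()
    removed: list[str] = []
    while work.shape[1] >= 2:
        v = vif(work)
        worst = float(v.max())
        if not (worst > threshold):
            break
        # right-most among the maximal columns: later-added goes first
        tied = [c for c in work.columns if v[c] == worst]
        drop = tied[-1]
        removed.append(drop)
        work = work.drop(columns=[drop])
    return work, removed
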