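"""Linear mixed model with crossed site and week random intercepts.

The estimation target is

    y_ij = x_ij' beta + b_i + g_j + e_ij,
    b_i ~ N(0, s2_site),  g_j ~ N(0, s2_week),  e_ij ~ N(0, s2_resid),

with sites i and weeks j *crossed*: every record carries one site and one week
label, and the two intercept sets are independent.  Estimation is restricted
maximum likelihood (REML), profiled over the two variance ratios
theta_k = s2_k / s2_resid.  Writing V0 = I + theta_s Zs Zs' + theta_w Zw Zw',
the GLS coefficients, the profiled residual variance and the REML criterion
are all available in closed form given theta, so the optimisation is a smooth
two-dimensional problem.  Solves use the Woodbury identity through the q
(= n_sites + n_weeks) dimensional capacitance matrix, so the cost scales with
n * q**2 rather than n**3 and instances with thousands of records fit in well
under a second.

The public surface follows the statsmodels convention: ``CrossedLMM`` is the
model (data + design), ``fit()`` returns a ``CrossedLMMResults`` carrying
estimates, standard errors, BLUPs, variance components, R² decomposition,
prediction and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .meteorology import month_of_week

_LOG_THETA_FLOOR = -20.0  # ratios below e^-20 are treated as structural zeros


class Standardizer:
    """Column-wise (x - mean) / sd with training-time parameters stored.

    Continuous predictors are standardized on the training sample; the same
    parameters are re-applied at prediction time so that coefficients keep
    their per-SD interpretation.  Sample SD (ddof=1) is used.
    """

    def __init__(self):
        self.params_: dict[str, tuple[float, float]] = {}

    def fit(self, df: pd.DataFrame, columns: list[str]) -> "Standardizer":
        self.params_ = {}
        for c in columns:
            mu = float(df[c].mean())
            sd = float(df[c].std(ddof=1))
            if not np.isfinite(sd) or sd == 0.0:
                raise ValueError(f"cannot standardize column {c!r}: zero or non-finite SD")
            self.params_[c] = (mu, sd)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c, (mu, sd) in self.params_.items():
            out[c] = (df[c] - mu) / sd
        return out

    def fit_transform(self, df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
        return self.fit(df, columns).transform(df)


def month_label(iso_week: str) -> str:
    """Year-month level of a week, e.g. ``2019-07`` (month of the Thursday)."""
    y, m = month_of_week(iso_week)
    return f"{y}-{m:02d}"


class CrossedLMM:
    """Mixed model for weekly pollutant concentrations.

    Parameters
    ----------
    y : response vector (concentrations, µg/m³)
    X : fixed-effects design matrix, intercept included as first column
    site_ids, week_ids : per-record grouping labels (crossed)
    exog_names : column names of X
    standardizer : fitted Standardizer for continuous predictors (optional,
        carried through so Results.predict can transform new data)
    """

    def __init__(self, y, X, site_ids, week_ids, exog_names=None, standardizer=None,
                 predictor_cols=None, reference_month=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        n, p = self.X.shape
        if self.y.shape[0] != n:
            raise ValueError("y and X row counts differ")
        if n <= p:
            raise ValueError(f"need n > p, got n={n}, p={p}")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{k}" for k in range(p)
        ]
        self.site_levels, self.site_idx = np.unique(np.asarray(site_ids), return_inverse=True)
        self.week_levels, self.week_idx = np.unique(np.asarray(week_ids), return_inverse=True)
        if len(self.site_levels) < 2 or len(self.week_levels) < 2:
            raise ValueError("need at least 2 sites and 2 weeks")
        self.standardizer = standardizer
        self.predictor_cols = predictor_cols  # continuous predictor column names
        self.reference_month = reference_month
        self._U = self._incidence()
        # cross-products cached once: every REML evaluation is then O(q^3)
        # in q = n_sites + n_weeks rather than O(n q^2)
        self._UtU = self._U.T @ self._U
        self._UtX = self._U.T @ self.X
        self._Uty = self._U.T @ self.y
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ self.y
        self._yty = float(self.y @ self.y)

    # -- construction ---------------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str,
        predictors: list[str],
        site_col: str = "site_id",
        week_col: str = "iso_week",
        month_effects: bool = True,
        reference_month: str | None = None,
        standardize: bool = True,
    ) -> "CrossedLMM":
        """Build the model from a tidy samples table.

        ``predictors`` are continuous columns (spatial + meteorology); they are
        standardized by default.  Calendar-month fixed effects are derived from
        the ISO week (month of the week's Thursday), dummy-coded against the
        earliest observed month unless ``reference_month`` is given.
        """
        df = df.reset_index(drop=True)
        std = None
        work = df
        if standardize and predictors:
            std = Standardizer()
            work = std.fit_transform(df, predictors)
        cols = [np.ones(len(df))]
        names = ["intercept"]
        for c in predictors:
            cols.append(work[c].to_numpy(dtype=float))
            names.append(c)
        ref = None
        if month_effects:
            months = df[week_col].map(month_label)
            levels = sorted(months.unique())
            ref = reference_month if reference_month is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference month {ref!r} not observed")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((months == lev).to_numpy(dtype=float))
                names.append(f"month[{lev}]")
        X = np.column_stack(cols)
        return cls(
            y=df[response].to_numpy(dtype=float),
            X=X,
            site_ids=df[site_col],
            week_ids=df[week_col],
            exog_names=names,
            standardizer=std,
            predictor_cols=list(predictors),
            reference_month=ref,
        )

    def _incidence(self):
        """n x (n_sites + n_weeks) indicator matrix [Zs | Zw] (dense, float)."""
        n = len(self.y)
        qs, qw = len(self.site_levels), len(self.week_levels)
        U = np.zeros((n, qs + qw))
        U[np.arange(n), self.site_idx] = 1.0
        U[np.arange(n), qs + self.week_idx] = 1.0
        return U

    # -- REML machinery --------------------------------------------------------------

    def _profile(self, log_theta: np.ndarray) -> dict:
        """Closed-form GLS/REML quantities at fixed variance ratios.

        Returns the -2 restricted log-likelihood (with constants) and the
        profiled estimates.  theta components at the floor are treated as 0.
        """
        n, p = self.X.shape
        q = self._U.shape[1]
        qs = len(self.site_levels)
        theta = np.exp(np.clip(log_theta, _LOG_THETA_FLOOR, 30.0))
        active = theta > np.exp(_LOG_THETA_FLOOR + 1e-9)
        d = np.concatenate([np.full(qs, theta[0]), np.full(q - qs, theta[1])])
        keep = np.concatenate([np.full(qs, active[0]), np.full(q - qs, active[1])])
        idx = np.where(keep)[0]
        dk = d[idx]

        if len(idx):
            M = self._UtU[np.ix_(idx, idx)] + np.diag(1.0 / dk)
            cM = cho_factor(M, lower=True)
            # Woodbury through the capacitance matrix M = U'U + D^-1
            AX = cho_solve(cM, self._UtX[idx])
            ay = cho_solve(cM, self._Uty[idx])
            XtVX = self._XtX - self._UtX[idx].T @ AX
            XtVy = self._Xty - self._UtX[idx].T @ ay
            logdet_v0 = 2.0 * np.sum(np.log(np.diag(cM[0]))) + float(np.sum(np.log(dk)))
        else:
            XtVX = self._XtX
            XtVy = self._Xty
            logdet_v0 = 0.0

        cX = cho_factor(XtVX, lower=True)
        beta = cho_solve(cX, XtVy)
        rtr = self._yty - 2.0 * float(beta @ self._Xty) + float(beta @ (self._XtX @ beta))
        utr = self._Uty - self._UtX @ beta  # U'(y - X beta), all q rows
        if len(idx):
            m_utr = cho_solve(cM, utr[idx])
            quad = rtr - float(utr[idx] @ m_utr)
            u_vinv_r = utr - self._UtU[:, idx] @ m_utr
        else:
            quad = rtr
            u_vinv_r = utr
        sigma2 = quad / (n - p)
        crit = (
            (n - p) * (1.0 + np.log(2.0 * np.pi * sigma2))
            + logdet_v0
            + 2.0 * np.sum(np.log(np.diag(cX[0])))
        )
        return {
            "crit": float(crit),
            "theta": theta * active,  # floored components reported as exactly 0
            "beta": beta,
            "sigma2": sigma2,
            "u_vinv_r": u_vinv_r,
            "XtVX": XtVX,
        }

    def reml_neg2loglik(self, theta_site: float, theta_week: float) -> float:
        """-2 restricted log-likelihood at the given variance ratios."""
        with np.errstate(divide="ignore"):
            lt = np.log(np.maximum([theta_site, theta_week], 0.0))
        return self._profile(np.asarray(lt))["crit"]

    def fit(
        self,
        starts=((0.0, 0.0), (-3.0, 2.0), (2.0, -3.0)),
        xatol: float = 1e-10,
        fatol: float = 1e-9,
        maxiter: int = 2000,
    ) -> "CrossedLMMResults":
        """Maximise the profiled REML criterion over the two log variance ratios.

        Nelder-Mead from several starts (the profiled surface is smooth and in
        practice unimodal; multiple starts guard against a boundary basin).
        Raises if no start converges.
        """
        best = None
        converged = False
        for s in starts:
            res = optimize.minimize(
                lambda lt: self._profile(lt)["crit"],
                x0=np.asarray(s, dtype=float),
                method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            converged = converged or res.success
        if not converged:
            raise RuntimeError(
                f"REML optimisation did not converge: last criterion {best.fun:.6g} at "
                f"log-theta {best.x}"
            )
        prof = self._profile(best.x)
        return CrossedLMMResults(self, prof, n_function_evals=int(best.nfev))


@dataclass
class CrossedLMMResults:
    """REML estimates, uncertainties and predictors for a fitted CrossedLMM."""

    model: CrossedLMM
    _prof: dict
    n_function_evals: int = 0

    def __post_init__(self):
        m = self.model
        prof = self._prof
        self.params = pd.Series(prof["beta"], index=m.exog_names)
        cov = np.linalg.inv(prof["XtVX"]) * prof["sigma2"]
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=m.exog_names)
        self.sigma2_resid = float(prof["sigma2"])
        self.sigma2_site = float(prof["theta"][0] * prof["sigma2"])
        self.sigma2_week = float(prof["theta"][1] * prof["sigma2"])
        self.reml_criterion = float(prof["crit"])
        qs = len(m.site_levels)
        # BLUPs: E[b | y] = theta * Z' V0^-1 (y - X beta)
        u_vinv_r = prof["u_vinv_r"]
        bs = prof["theta"][0] * u_vinv_r[:qs]
        bw = prof["theta"][1] * u_vinv_r[qs:]
        self.blup_site = pd.Series(bs, index=pd.Index(m.site_levels, name="site_id"))
        self.blup_week = pd.Series(bw, index=pd.Index(m.week_levels, name="iso_week"))
        self.nobs = len(m.y)
        self.df_model = m.X.shape[1]

    # -- fitted values and R² --------------------------------------------------------

    @property
    def fixed_linear_predictor(self) -> np.ndarray:
        return self.model.X @ self.params.to_numpy()

    @property
    def fittedvalues(self) -> np.ndarray:
        m = self.model
        return (
            self.fixed_linear_predictor
            + self.blup_site.to_numpy()[m.site_idx]
            + self.blup_week.to_numpy()[m.week_idx]
        )

    def r2(self) -> tuple[float, float]:
        """Marginal and conditional R² (variance-decomposition form).

        r2_fixed uses the variance of the fixed-effects linear predictor over
        the estimated total (fixed + site + week + residual variances);
        r2_mixed adds the random-intercept variances to the numerator.
        """
        var_f = float(np.var(self.fixed_linear_predictor, ddof=1))
        total = var_f + self.sigma2_site + self.sigma2_week + self.sigma2_resid
        r2_fixed = var_f / total
        r2_mixed = (var_f + self.sigma2_site + self.sigma2_week) / total
        return r2_fixed, r2_mixed

    # -- prediction -------------------------------------------------------------------

    def predict(
        self,
        X_new: pd.DataFrame,
        iso_week=None,
        site_id=None,
        return_flags: bool = False,
    ):
        """Predict concentrations for new rows.

        ``X_new`` must carry the model's continuous predictor columns on the
        *raw* scale; training standardization parameters are re-applied.  The
        week random intercept is added when the week was observed in training;
        the site intercept only for a training site (unknown site => 0,
        the population-level prediction used for mapping).  Months never seen
        in training fall back to the reference level and are flagged.
        """
        m = self.model
        X_new = X_new.reset_index(drop=True)
        missing = [c for c in (m.predictor_cols or []) if c not in X_new.columns]
        if missing:
            raise KeyError(f"missing predictor column(s): {missing}")
        work = m.standardizer.transform(X_new) if m.standardizer is not None else X_new
        n = len(X_new)
        pred = np.zeros(n)
        flags = {
            "unknown_week": np.zeros(n, dtype=bool),
            "unknown_month": np.zeros(n, dtype=bool),
        }
        beta = self.params
        pred += beta["intercept"]
        for c in m.predictor_cols or []:
            pred += beta[c] * work[c].to_numpy(dtype=float)
        weeks = None
        if iso_week is not None:
            weeks = np.broadcast_to(np.asarray(iso_week, dtype=object), (n,))
            month_names = [f"month[{month_label(w)}]" for w in weeks]
            for i, mn in enumerate(month_names):
                if mn in beta.index:
                    pred[i] += beta[mn]
                elif mn != f"month[{m.reference_month}]":
                    flags["unknown_month"][i] = True  # fall back to reference
            week_lookup = self.blup_week
            for i, w in enumerate(weeks):
                if w in week_lookup.index:
                    pred[i] += week_lookup[w]
                else:
                    flags["unknown_week"][i] = True
        if site_id is not None:
            sites = np.broadcast_to(np.asarray(site_id, dtype=object), (n,))
            for i, s in enumerate(sites):
                if s in self.blup_site.index:
                    pred[i] += self.blup_site[s]
        if flags["unknown_month"].any():
            warnings.warn(
                f"{int(flags['unknown_month'].sum())} prediction(s) in months not observed "
                "in training; month effect fell back to the reference level",
                stacklevel=2,
            )
        if return_flags:
            return pred, flags
        return pred

    # -- reporting --------------------------------------------------------------------

    def variance_components(self) -> pd.Series:
        return pd.Series(
            {
                "sigma2_site": self.sigma2_site,
                "sigma2_week": self.sigma2_week,
                "sigma2_resid": self.sigma2_resid,
            }
        )

    def summary(self) -> str:
        r2f, r2m = self.r2()
        lines = [
            "Crossed random-intercepts linear mixed model (REML)",
            "=" * 60,
            f"No. observations: {self.nobs}    sites: {len(self.model.site_levels)}"
            f"    weeks: {len(self.model.week_levels)}",
            f"REML -2 logLik: {self.reml_criterion:.3f}",
            f"R2 (fixed): {r2f:.3f}    R2 (mixed): {r2m:.3f}",
            "-" * 60,
            f"{'term':<32}{'coef':>10}{'se':>10}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<32}{self.params[name]:>10.3f}{self.bse[name]:>10.3f}")
        lines.append("-" * 60)
        lines.append(
            f"sd(site) = {np.sqrt(self.sigma2_site):.3f}   "
            f"sd(week) = {np.sqrt(self.sigma2_week):.3f}   "
            f"sd(resid) = {np.sqrt(self.sigma2_resid):.3f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON/YAML-serialisable representation of the fitted model."""
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "variance_components": self.variance_components().to_dict(),
            "standardization": dict(self.model.standardizer.params_)
            if self.model.standardizer
            else {},
            "reference_month": self.model.reference_month,
            "blup_site": self.blup_site.to_dict(),
            "blup_week": self.blup_week.to_dict(),
            "reml_criterion": self.reml_criterion,
        }
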