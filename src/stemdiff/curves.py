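"""Differentiation time-course models.

Two fitted curves seed and refine the iterative design loop:

* a three-parameter logistic for the cumulative fraction of differentiated
  cells, p(t) = L / (1 + exp(-k (t - t0))) — the plateau L is the fraction
  that ever differentiates, t0 the inflection (peak differentiation day,
  where the slope is greatest), and k the growth rate. The implied spread of
  commitment times is the SD of the logistic distribution, pi / (k sqrt(3));
* a scaled Gaussian rate a * exp(-(t - mu)^2 / (2 sigma^2)) for per-day
  newly committed counts of a single fate, returning (mu, sigma) as the
  per-lineage peak-day estimate handed to the Bayesian iteration.

Both are exposed as sklearn-style estimators plus thin functional wrappers
operating on daily-count tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin


class FitError(RuntimeError):
    """Raised when a curve fit fails to converge."""


@dataclass(frozen=True)
class DiffCurveFit:
    """Fitted logistic parameters and derived peak-day summary."""

    L: float
    k: float
    t0: float
    peak_day: float
    sd_days: float
    rss: float


@dataclass(frozen=True)
class PeakEstimate:
    """Per-lineage peak differentiation day and its spread."""

    fate: str | None
    mean_day: float
    sd_days: float
    n_replicates: int = 0
    sd_floored: bool = False


def _logistic(t, L, k, t0):
    return L / (1.0 + np.exp(-k * (t - t0)))


class LogisticDifferentiationCurve(RegressorMixin, BaseEstimator):
    """Least-squares logistic fit of cumulative differentiation proportions.

    Parameters
    ----------
    likelihood : {"least_squares", "binomial"}
        Objective: ordinary least squares on proportions (default) or a
        binomial log-likelihood using per-time totals.
    tol, max_iter : solver tolerance and iteration cap.
    """

    def __init__(self, likelihood: str = "least_squares",
                 tol: float = 1e-12, max_iter: int = 10_000):
        self.likelihood = likelihood
        self.tol = tol
        self.max_iter = max_iter

    def _initial_guess(self, t: np.ndarray, p: np.ndarray) -> np.ndarray:
        L0 = min(max(float(p.max()), 1e-3), 1.0)
        dp = np.diff(p) / np.diff(t)
        if dp.size and np.nanmax(dp) > 0:
            i = int(np.nanargmax(dp))
            t0_0 = 0.5 * (t[i] + t[i + 1])
            k0 = max(4.0 * float(np.nanmax(dp)) / L0, 1e-3)
        else:
            t0_0 = float(np.median(t))
            k0 = 1.0
        return np.array([L0, k0, t0_0])

    def fit(self, t, p, n_total=None) -> "LogisticDifferentiationCurve":
        """Fit to times ``t`` and differentiated proportions ``p``.

        ``n_total`` (per-time assay totals) is required for the binomial
        likelihood and ignored otherwise.
        """
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        if np.unique(t).size < 4:
            raise ValueError("need at least 4 distinct time points")
        if not np.any(p > 0):
            raise ValueError("all differentiated counts are zero; nothing to fit")

        x0 = self._initial_guess(t, p)
        lo = np.array([1e-6, 1e-6, t.min() - 10.0])
        hi = np.array([1.0, np.inf, t.max() + 10.0])
        res = optimize.least_squares(
            lambda th: _logistic(t, *th) - p, x0,
            bounds=(lo, hi), xtol=self.tol, ftol=self.tol, gtol=self.tol,
            max_nfev=self.max_iter,
        )
        if not res.success:
            raise FitError(f"logistic fit did not converge: {res.message}")
        theta = res.x

        if self.likelihood == "binomial":
            if n_total is None:
                raise ValueError("binomial likelihood requires n_total")
            n_total = np.asarray(n_total, dtype=float)
            s = p * n_total

            def nll(th):
                mu = np.clip(_logistic(t, *th), 1e-12, 1 - 1e-12)
                return -np.sum(s * np.log(mu) + (n_total - s) * np.log1p(-mu))

            opt = optimize.minimize(
                nll, theta, method="L-BFGS-B",
                bounds=list(zip(lo, np.where(np.isinf(hi), None, hi))),
                options={"maxiter": self.max_iter, "ftol": self.tol},
            )
            if not opt.success:
                raise FitError(f"binomial logistic fit did not converge: {opt.message}")
            theta = opt.x
        elif self.likelihood != "least_squares":
            raise ValueError(f"unknown likelihood {self.likelihood!r}")

        self.L_, self.k_, self.t0_ = (float(v) for v in theta)
        self.peak_day_ = self.t0_
        self.sd_days_ = math.pi / (self.k_ * math.sqrt(3.0))
        self.rss_ = float(np.sum((_logistic(t, *theta) - p) ** 2))
        return self

    def predict(self, t) -> np.ndarray:
        return _logistic(np.asarray(t, dtype=float), self.L_, self.k_, self.t0_)

    def result(self) -> DiffCurveFit:
        return DiffCurveFit(self.L_, self.k_, self.t0_, self.peak_day_,
                            self.sd_days_, self.rss_)


class GaussianPeakModel(RegressorMixin, BaseEstimator):
    """Scaled-Gaussian fit of per-day newly differentiated counts.

    A degenerate input (a single nonzero day) cannot identify the width; the
    SD is then floored at half the sampling interval and flagged via
    ``sd_floored_``.
    """

    def __init__(self, tol: float = 1e-12, max_iter: int = 10_000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, t, counts) -> "GaussianPeakModel":
        t = np.asarray(t, dtype=float)
        c = np.asarray(counts, dtype=float)
        if np.unique(t).size < 3:
            raise ValueError("need at least 3 time points")
        if not np.any(c > 0):
            raise ValueError("all counts are zero; nothing to fit")
        spacing = float(np.min(np.diff(np.unique(t))))
        floor = 0.5 * spacing

        total = c.sum()
        mu0 = float((t * c).sum() / total)
        var0 = float((c * (t - mu0) ** 2).sum() / total)
        self.sd_floored_ = False
        if (c > 0).sum() == 1 or var0 <= 0:
            self.mean_day_ = float(t[np.argmax(c)])
            self.sd_days_ = floor
            self.amplitude_ = float(c.max())
            self.sd_floored_ = True
            self.rss_ = 0.0
            return self

        x0 = np.array([float(c.max()), mu0, max(math.sqrt(var0), floor)])

        def resid(th):
            a, mu, sig = th
            return a * np.exp(-0.5 * ((t - mu) / sig) ** 2) - c

        res = optimize.least_squares(
            resid, x0, bounds=([1e-12, t.min() - 10.0, 1e-6],
                               [np.inf, t.max() + 10.0, np.inf]),
            xtol=self.tol, ftol=self.tol, gtol=self.tol, max_nfev=self.max_iter,
        )
        if not res.success:
            raise FitError(f"Gaussian peak fit did not converge: {res.message}")
        self.amplitude_, self.mean_day_, self.sd_days_ = (float(v) for v in res.x)
        if self.sd_days_ < floor:
            self.sd_days_ = floor
            self.sd_floored_ = True
        self.rss_ = float(np.sum(resid(res.x) ** 2))
        return self

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude_ * np.exp(-0.5 * ((t - self.mean_day_) / self.sd_days_) ** 2)


def _pool_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Pool replicate rows of a daily-counts table by time."""
    cols = {"time", "n_assayed", "n_differentiated"}
    missing = cols - set(counts.columns)
    if missing:
        raise ValueError(f"daily counts missing columns: {sorted(missing)}")
    return counts.groupby("time")[["n_assayed", "n_differentiated"]].sum().reset_index()


def fit_logistic(counts: pd.DataFrame, likelihood: str = "least_squares") -> DiffCurveFit:
    """Fit the cumulative-differentiation logistic to a daily-counts table.

    ``counts`` has columns time, n_assayed, n_differentiated (replicate rows
    are pooled per time).
    """
    pooled = _pool_counts(counts)
    if (pooled["n_differentiated"] > pooled["n_assayed"]).any():
        raise ValueError("n_differentiated exceeds n_assayed")
    p = pooled["n_differentiated"] / pooled["n_assayed"]
    est = LogisticDifferentiationCurve(likelihood=likelihood)
    est.fit(pooled["time"].to_numpy(), p.to_numpy(),
            n_total=pooled["n_assayed"].to_numpy())
    return est.result()


def fit_peak(new_counts: pd.DataFrame, fate: str | None = None,
             n_replicates: int = 0) -> PeakEstimate:
    """Fit the Gaussian commitment-rate peak to per-day new counts.

    ``new_counts`` has columns time and count.
    """
    est = GaussianPeakModel()
    est.fit(new_counts["time"].to_numpy(), new_counts["count"].to_numpy())
    return PeakEstimate(fate, est.mean_day_, est.sd_days_,
                        n_replicates=n_replicates, sd_floored=est.sd_floored_)
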