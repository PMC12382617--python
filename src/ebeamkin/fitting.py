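"""Parameter estimation for the dose-response kinetics.

Two model classes follow the Model/Results idiom: construct the model from a
:class:`~ebeamkin.peak_tables.PeakTable`, call :meth:`fit`, and read the
estimates, standard errors and diagnostics off the results object.

Fitting is sequential (conditional): the parent antibiotic's ``(C0, alpha)``
are estimated first from its own dose series, then each degradation product's
``(beta, D0, k)`` is estimated with the parent law frozen — the product ODE
presumes the parent solution, so the two stages mirror the model structure.

The threshold dose ``D0`` makes the product objective non-smooth, so it is
profiled over a dose grid (default step 0.01 kGy) with local refinement and
smallest-``D0`` tie-breaking; ``beta`` is optimized within each candidate and
``k``, in which the model is linear, is solved in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .exceptions import (
    ConvergenceError,
    InsufficientDataError,
    NoSignalError,
    UnidentifiableError,
)
from .kinetics import AntibioticKinetics, ProductKinetics
from .peak_tables import PeakTable

__all__ = [
    "AntibioticDecayModel",
    "AntibioticDecayResults",
    "ProductFormationModel",
    "ProductFormationResults",
    "InitialConcentrationEstimate",
    "fit_antibiotic",
    "fit_product",
    "reconstruct_initial",
    "goodness_r_corr",
]


def goodness_r_corr(observed, fitted) -> float:
    """Pearson correlation between observed and fitted values, clipped to
    [0, 1] for reporting.

    Returns ``nan`` (the undefined flag) when either input is constant, as
    for a no-decay series.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.size < 2:
        raise InsufficientDataError("need at least 2 points for a correlation")
    if np.ptp(obs) == 0 or np.ptp(fit) == 0:
        return math.nan
    r = float(np.corrcoef(obs, fit)[0, 1])
    return min(max(r, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Parent antibiotic: C_a(D) = C0 exp(-alpha D)


@dataclass(frozen=True)
class AntibioticDecayResults:
    """Estimates for one antibiotic's exponential decay law."""

    kinetics: AntibioticKinetics
    se_alpha: float
    se_c0: float
    r_corr: float  # nan when undefined (constant data)
    nobs: int
    sse: float
    analyte: str
    c0_fixed: bool

    @property
    def alpha(self) -> float:
        return self.kinetics.alpha

    @property
    def c0(self) -> float:
        return self.kinetics.c0

    def predict(self, dose):
        return self.kinetics.concentration(dose)

    def summary(self) -> str:
        r = "n/a" if math.isnan(self.r_corr) else f"{self.r_corr:.4f}"
        c0 = f"{self.c0:.4g}" + (" (fixed)" if self.c0_fixed else f" +/- {self.se_c0:.3g}")
        lines = [
            "Antibiotic decay fit",
            "=" * 44,
            f"analyte:        {self.analyte}",
            f"n obs:          {self.nobs}",
            f"C0 (rel. un.):  {c0}",
            f"alpha (1/kGy):  {self.alpha:.6g} +/- {self.se_alpha:.3g}",
            f"R_corr:         {r}",
            f"SSE:            {self.sse:.6g}",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None, dose_max: float | None = None):
        """Dose-response curve over the fitted range (lazy matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hi = dose_max if dose_max is not None else 7.0
        grid = np.linspace(0, hi, 200)
        ax.plot(grid, self.predict(grid), label=f"{self.analyte} fit")
        ax.set_xlabel("dose (kGy)")
        ax.set_ylabel("concentration (rel. un.)")
        ax.legend()
        return ax


class AntibioticDecayModel:
    """Nonlinear least-squares model for parent-antibiotic decay.

    Parameters
    ----------
    table : PeakTable
        Observations; censored rows enter as zeros.
    analyte : str
        Which analyte to fit.
    fix_c0_at_100 : bool
        If True (default) C0 is frozen at 100 (data on the relative scale);
        otherwise C0 is estimated jointly with alpha.
    """

    def __init__(self, table: PeakTable, analyte: str, fix_c0_at_100: bool = True):
        self.analyte = analyte
        self.fix_c0_at_100 = fix_c0_at_100
        self.dose, self.area = table.arrays(analyte, include_censored=True)
        if self.dose.size == 0:
            raise InsufficientDataError(f"no observations for analyte {analyte!r}")
        distinct = np.unique(self.dose)
        if distinct.size < 3 or 0.0 not in distinct:
            raise InsufficientDataError(
                f"analyte {analyte!r}: need >= 3 distinct doses including 0"
            )
        zero_mask = (self.dose == 0.0) & (self.area > 0)
        if not zero_mask.any():
            raise InsufficientDataError(
                f"analyte {analyte!r}: no non-censored dose-0 observation"
            )

    def _initial_alpha(self) -> float:
        pos = self.area > 0
        if pos.sum() < 2 or np.ptp(self.dose[pos]) == 0:
            return 0.0
        slope = np.polyfit(self.dose[pos], np.log(self.area[pos]), 1)[0]
        return max(-float(slope), 0.0)

    def fit(self) -> AntibioticDecayResults:
        d, y = self.dose, self.area
        alpha0 = self._initial_alpha()
        try:
            if self.fix_c0_at_100:
                popt, pcov = optimize.curve_fit(
                    lambda dd, a: 100.0 * np.exp(-a * dd),
                    d,
                    y,
                    p0=[alpha0],
                    bounds=([0.0], [np.inf]),
                    maxfev=200 * 100,
                    ftol=1e-12,
                    xtol=1e-12,
                )
                c0, alpha = 100.0, float(popt[0])
                se_alpha = float(np.sqrt(max(pcov[0, 0], 0.0)))
                se_c0 = 0.0
            else:
                c0_init = float(np.mean(y[d == 0.0]))
                popt, pcov = optimize.curve_fit(
                    lambda dd, c, a: c * np.exp(-a * dd),
                    d,
                    y,
                    p0=[c0_init, alpha0],
                    bounds=([1e-12, 0.0], [np.inf, np.inf]),
                    maxfev=200 * 100,
                    ftol=1e-12,
                    xtol=1e-12,
                )
                c0, alpha = float(popt[0]), float(popt[1])
                se_c0 = float(np.sqrt(max(pcov[0, 0], 0.0)))
                se_alpha = float(np.sqrt(max(pcov[1, 1], 0.0)))
        except RuntimeError as exc:
            raise ConvergenceError(
                f"antibiotic fit for {self.analyte!r} did not converge "
                f"(alpha0={alpha0:.4g}, n={d.size}): {exc}"
            ) from exc
        kin = AntibioticKinetics(c0=c0, alpha=alpha)
        fitted = kin.concentration(d)
        sse = float(np.sum((y - fitted) ** 2))
        return AntibioticDecayResults(
            kinetics=kin,
            se_alpha=se_alpha,
            se_c0=se_c0,
            r_corr=goodness_r_corr(y, fitted) if np.ptp(y) > 0 else math.nan,
            nobs=int(d.size),
            sse=sse,
            analyte=self.analyte,
            c0_fixed=self.fix_c0_at_100,
        )


def fit_antibiotic(
    table: PeakTable, analyte: str, fix_c0_at_100: bool = True
) -> AntibioticDecayResults:
    """Functional wrapper around :class:`AntibioticDecayModel`."""
    return AntibioticDecayModel(table, analyte, fix_c0_at_100).fit()


# ---------------------------------------------------------------------------
# Degradation product: Heaviside-gated formation/decay


@dataclass(frozen=True)
class ProductFormationResults:
    """Estimates for one degradation product's (beta, D0, k)."""

    kinetics: ProductKinetics
    se_beta: float
    se_d0: float
    se_k: float
    nobs: int
    sse: float
    analyte: str
    r_corr: float

    @property
    def beta(self) -> float:
        return self.kinetics.beta

    @property
    def d0(self) -> float:
        return self.kinetics.d0

    @property
    def k(self) -> float:
        return self.kinetics.k

    def predict(self, dose):
        return self.kinetics.concentration(dose)

    def summary(self) -> str:
        r = "n/a" if math.isnan(self.r_corr) else f"{self.r_corr:.4f}"
        lines = [
            "Degradation-product kinetics fit",
            "=" * 44,
            f"analyte:       {self.analyte}",
            f"n obs:         {self.nobs}",
            f"parent alpha:  {self.kinetics.parent.alpha:.6g} (fixed)",
            f"parent C0:     {self.kinetics.parent.c0:.6g} (fixed)",
            f"beta (1/kGy):  {self.beta:.6g} +/- {self.se_beta:.3g}",
            f"D0 (kGy):      {self.d0:.6g} +/- {self.se_d0:.3g}",
            f"k (1/kGy):     {self.k:.6g} +/- {self.se_k:.3g}",
            f"R_corr:        {r}",
            f"SSE:           {self.sse:.6g}",
        ]
        return "\n".join(lines)


def _unit_shape(d: np.ndarray, beta: float, d0: float, alpha: float, c0: float) -> np.ndarray:
    """Product concentration for k = 1 (model is linear in k)."""
    if beta == alpha:
        vals = c0 * (d - d0) * np.exp(-beta * d)
    else:
        vals = (
            c0
            * np.exp(-beta * d + (beta - alpha) * d0)
            * np.expm1((beta - alpha) * (d - d0))
            / (beta - alpha)
        )
    return np.where(d > d0, vals, 0.0)


class ProductFormationModel:
    """Conditional least-squares model for a degradation product.

    The parent law ``(C0, alpha)`` is frozen (taken from an
    :class:`AntibioticDecayResults` or an :class:`AntibioticKinetics`).
    Censored observations enter as zeros.

    Parameters
    ----------
    table : PeakTable
    analyte : str
    parent : AntibioticDecayResults or AntibioticKinetics
    d0_grid_step : float
        Step of the threshold-dose profile grid in kGy (default 0.01).
    beta_bounds : tuple of float
        Search interval for the product decomposition rate.
    """

    def __init__(
        self,
        table: PeakTable,
        analyte: str,
        parent,
        d0_grid_step: float = 0.01,
        beta_bounds: tuple[float, float] = (1e-4, 100.0),
    ):
        if isinstance(parent, AntibioticDecayResults):
            parent = parent.kinetics
        if not isinstance(parent, AntibioticKinetics):
            raise TypeError("parent must be AntibioticKinetics or AntibioticDecayResults")
        self.parent = parent
        self.analyte = analyte
        self.d0_grid_step = float(d0_grid_step)
        self.beta_bounds = beta_bounds
        self.dose, self.area = table.arrays(analyte, include_censored=True)
        if self.dose.size == 0:
            raise InsufficientDataError(f"no observations for analyte {analyte!r}")
        if not (self.area > 0).any():
            raise NoSignalError(f"analyte {analyte!r}: product signal identically zero")
        if np.unique(self.dose[self.area > 0]).size < 3:
            raise InsufficientDataError(
                f"analyte {analyte!r}: need >= 3 distinct doses with non-zero signal"
            )

    # -- profile machinery --------------------------------------------------

    def _profile_k(self, g: np.ndarray) -> tuple[float, float]:
        """Closed-form k >= 0 minimizing ||y - k g||^2; returns (k, sse)."""
        gg = float(g @ g)
        if gg == 0.0:
            return 0.0, float(self.area @ self.area)
        k = max(float(self.area @ g) / gg, 0.0)
        resid = self.area - k * g
        return k, float(resid @ resid)

    def _profile_beta(self, d0: float) -> tuple[float, float, float]:
        """Best (beta, k, sse) at fixed d0: log-grid scan + Brent refinement."""
        a, c0 = self.parent.alpha, self.parent.c0
        lo, hi = self.beta_bounds

        def sse_of_logb(logb: float) -> float:
            g = _unit_shape(self.dose, math.exp(logb), d0, a, c0)
            return self._profile_k(g)[1]

        grid = np.linspace(math.log(lo), math.log(hi), 81)
        vals = np.array([sse_of_logb(lb) for lb in grid])
        i = int(np.argmin(vals))
        bracket_lo = grid[max(i - 1, 0)]
        bracket_hi = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            sse_of_logb,
            bounds=(bracket_lo, bracket_hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        logb = float(res.x) if res.fun <= vals[i] else float(grid[i])
        beta = math.exp(logb)
        g = _unit_shape(self.dose, beta, d0, a, c0)
        k, sse = self._profile_k(g)
        return beta, k, sse

    def fit(self) -> ProductFormationResults:
        a, c0 = self.parent.alpha, self.parent.c0
        d0_max = float(self.dose.max())
        # the threshold cannot exceed the smallest dose with signal
        first_signal = float(self.dose[self.area > 0].min())
        grid_hi = min(d0_max, first_signal)
        grid = np.arange(0.0, grid_hi + 0.5 * self.d0_grid_step, self.d0_grid_step)
        best: tuple[float, float, float, float] | None = None  # (sse, d0, beta, k)
        for d0 in grid:
            beta, k, sse = self._profile_beta(float(d0))
            if best is None or sse < best[0] - 1e-15:
                # strict improvement keeps the smallest-D0 tie-break
                best = (sse, float(d0), beta, k)
        assert best is not None
        sse_grid, d0_best, beta_best, k_best = best

        # local refinement of D0 between the neighbouring grid points;
        # the objective is guaranteed not to increase.
        lo = max(d0_best - self.d0_grid_step, 0.0)
        hi = min(d0_best + self.d0_grid_step, grid_hi)
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda d0: self._profile_beta(float(d0))[2],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun < sse_grid:
                d0_best = float(res.x)
                beta_best, k_best, sse_grid = self._profile_beta(d0_best)

        kin = ProductKinetics(beta=beta_best, d0=d0_best, k=k_best, parent=self.parent)
        fitted = kin.concentration(self.dose)
        sse = float(np.sum((self.area - fitted) ** 2))
        se_beta, se_d0, se_k = self._standard_errors(beta_best, d0_best, k_best, sse)
        r = goodness_r_corr(self.area, fitted) if np.ptp(self.area) > 0 else math.nan
        return ProductFormationResults(
            kinetics=kin,
            se_beta=se_beta,
            se_d0=se_d0,
            se_k=se_k,
            nobs=int(self.dose.size),
            sse=sse,
            analyte=self.analyte,
            r_corr=r,
        )

    def _standard_errors(
        self, beta: float, d0: float, k: float, sse: float
    ) -> tuple[float, float, float]:
        """Gauss-Newton covariance from a central-difference Jacobian."""
        n = self.dose.size
        dof = n - 3
        if dof <= 0:
            return math.nan, math.nan, math.nan
        a, c0 = self.parent.alpha, self.parent.c0

        def model(p: np.ndarray) -> np.ndarray:
            return p[2] * _unit_shape(self.dose, p[0], p[1], a, c0)

        p = np.array([beta, d0, k], dtype=float)
        J = np.empty((n, 3))
        for j in range(3):
            h = 1e-6 * max(abs(p[j]), 1e-3)
            pp, pm = p.copy(), p.copy()
            pp[j] += h
            pm[j] = max(pm[j] - h, 0.0) if j != 0 else pm[j] - h
            J[:, j] = (model(pp) - model(pm)) / (pp[j] - pm[j])
        s2 = sse / dof
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            return math.nan, math.nan, math.nan
        return float(ses[0]), float(ses[1]), float(ses[2])


def fit_product(
    table: PeakTable,
    analyte: str,
    parent,
    d0_grid_step: float = 0.01,
) -> ProductFormationResults:
    """Functional wrapper around :class:`ProductFormationModel`."""
    return ProductFormationModel(table, analyte, parent, d0_grid_step=d0_grid_step).fit()


# ---------------------------------------------------------------------------
# Marker inversion: reconstruct the initial contamination level


@dataclass(frozen=True)
class InitialConcentrationEstimate:
    """Reconstructed initial antibiotic concentration from a marker series."""

    c0: float
    se: float
    nobs: int
    analyte: str

    def summary(self) -> str:
        return (
            f"Initial-concentration reconstruction from marker {self.analyte!r}: "
            f"C0 = {self.c0:.6g} +/- {self.se:.3g} (n = {self.nobs})"
        )


def reconstruct_initial(
    table: PeakTable,
    analyte: str,
    product: ProductKinetics,
    doses: Sequence[float] | None = None,
) -> InitialConcentrationEstimate:
    """Estimate the parent's initial concentration C0 from a marker product.

    The product model is linear in the parent C0, so with the unit-C0 shape
    ``f_i`` (the model prediction at dose i for C0 = 1) the least-squares
    estimate is the exact linear inversion ``C0_hat = sum(y f) / sum(f^2)``,
    with standard error from the residual variance.

    Parameters
    ----------
    table : PeakTable
        Observed marker peak areas (relative scale).
    analyte : str
        Marker analyte in *table*.
    product : ProductKinetics
        Known marker kinetics (beta, D0, k and the parent's alpha); the
        parent's stored C0 only sets the scale that is divided out.
    doses : sequence of float, optional
        Restrict the inversion to these doses.
    """
    d, y = table.arrays(analyte, include_censored=True)
    if doses is not None:
        mask = np.isin(d, np.asarray(list(doses), dtype=float))
        d, y = d[mask], y[mask]
    if d.size == 0:
        raise InsufficientDataError(f"no observations for analyte {analyte!r}")
    f = np.asarray(product.concentration(d), dtype=float) / product.parent.c0
    ff = float(f @ f)
    if ff == 0.0:
        raise UnidentifiableError(
            "all doses are at or below the threshold D0: C0 is unidentifiable"
        )
    c0_hat = float(y @ f) / ff
    resid = y - c0_hat * f
    dof = d.size - 1
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    se = math.sqrt(s2 / ff)
    return InitialConcentrationEstimate(c0=c0_hat, se=se, nobs=int(d.size), analyte=analyte)
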