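"""Critical power and W' estimation from constant work-rate trials.

The power-duration relationship above critical power is hyperbolic,

    t = W' / (P - CP),

with asymptote CP (W), the highest work rate with an attainable
physiological steady state, and curvature constant W' (J), the finite
work capacity above CP.  Equivalent algebraic rearrangements give two
linear forms that are fitted by ordinary least squares:

* work–time:     W = P·t = CP·t + W'      (slope = CP, intercept = W')
* power–1/time:  P = CP + W'·(1/t)        (intercept = CP, slope = W')

plus the hyperbola itself fitted by nonlinear least squares in the time
domain (trials fix power and measure time, so time is the response) and
an exact two-point solve of the work–time form from the shortest and the
longest trial.  Time to exhaustion at any supra-CP work rate is then
predicted from the fitted pair via the hyperbolic equation.

The surface mirrors statsmodels: build a :class:`CriticalPowerModel`
from data, call :meth:`~CriticalPowerModel.fit`, and read estimates,
standard errors and a :meth:`~CriticalPowerResults.summary` table off
the returned :class:`CriticalPowerResults`.

Notes
-----
"SEE" follows the convention of reporting the standard error of each
parameter estimate as a percentage of the estimate (separately for CP
and W'), not the regression's residual standard error.  The two-point
solve has no residual degrees of freedom, so its SEE and R² are absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    SingularFitError,
)

__all__ = [
    "PredictiveTrial",
    "CriticalPowerModel",
    "CriticalPowerResults",
    "MODEL_NAMES",
    "fit_work_time",
    "fit_inverse_time",
    "fit_hyperbolic",
    "fit_two_point",
    "fit_all",
    "predict_tlim",
]

MODEL_NAMES = ("work_time", "inverse_time", "hyperbolic", "two_point")

#: CP is constrained this many watts below the lowest trial power in the
#: hyperbolic fit (the asymptote must sit below every observed work rate).
CP_MARGIN_W = 1.0


@dataclass(frozen=True)
class PredictiveTrial:
    """One constant work-rate exhaustion trial: power (W) and Tlim (s)."""

    power_W: float
    tlim_s: float

    def __post_init__(self) -> None:
        if not (self.power_W > 0 and np.isfinite(self.power_W)):
            raise InvalidInputError("trial power must be positive")
        if not (self.tlim_s > 0 and np.isfinite(self.tlim_s)):
            raise InvalidInputError("trial Tlim must be positive")

    @property
    def work_J(self) -> float:
        """Total work performed, power × time."""
        return self.power_W * self.tlim_s


class CriticalPowerModel:
    """Power-duration model for one athlete's predictive trials.

    Parameters
    ----------
    power_W, tlim_s : array_like
        Work rates (W) and times to exhaustion (s) of the predictive
        trials, matched element-wise.

    Examples
    --------
    >>> m = CriticalPowerModel([300.0, 266.67, 247.62], [200.0, 300.0, 420.0])
    >>> res = m.fit("hyperbolic")
    >>> round(res.cp_W), round(res.w_prime_J)
    (200, 20000)
    """

    def __init__(self, power_W, tlim_s):
        p = np.atleast_1d(np.asarray(power_W, dtype=float))
        t = np.atleast_1d(np.asarray(tlim_s, dtype=float))
        if p.shape != t.shape or p.ndim != 1:
            raise InvalidInputError("power_W and tlim_s must be matched 1-D arrays")
        if p.size < 2:
            raise InsufficientDataError("at least two trials are required")
        self.trials: tuple[PredictiveTrial, ...] = tuple(
            PredictiveTrial(float(pi), float(ti)) for pi, ti in zip(p, t)
        )
        self.power_W = p
        self.tlim_s = t

    @classmethod
    def from_trials(cls, trials: Iterable[PredictiveTrial]) -> "CriticalPowerModel":
        trials = list(trials)
        return cls([tr.power_W for tr in trials], [tr.tlim_s for tr in trials])

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, power: str = "power_W", tlim: str = "tlim_s"
    ) -> "CriticalPowerModel":
        return cls(data[power].to_numpy(), data[tlim].to_numpy())

    @property
    def nobs(self) -> int:
        return self.power_W.size

    # -- fitting -----------------------------------------------------------

    def fit(
        self, method: str = "hyperbolic", residual_axis: str = "time"
    ) -> "CriticalPowerResults":
        """Estimate (CP, W') by the requested model variant.

        ``method`` is one of ``work_time``, ``inverse_time``,
        ``hyperbolic`` or ``two_point``.  ``residual_axis`` selects the
        response of the hyperbolic fit (``time`` is canonical; ``power``
        minimises power-domain residuals instead).
        """
        if method in ("work_time", "inverse_time"):
            return self._fit_linear(method)
        if method == "hyperbolic":
            return self._fit_hyperbolic(residual_axis)
        if method == "two_point":
            return self._fit_two_point()
        raise InvalidInputError(f"unknown method {method!r}; choose from {MODEL_NAMES}")

    def _require_three(self, method: str) -> None:
        if self.nobs < 3:
            raise InsufficientDataError(
                f"{method} needs at least 3 trials; "
                "use the two_point model for two trials"
            )

    def _fit_linear(self, method: str) -> "CriticalPowerResults":
        self._require_three(method)
        t = self.tlim_s
        if np.unique(t).size < 2:
            raise SingularFitError("all trials share one Tlim; design is singular")
        if method == "work_time":
            X = sm.add_constant(t)
            y = self.power_W * t
            ols = sm.OLS(y, X).fit()
            wp, cp = ols.params
            se_wp, se_cp = ols.bse
        else:
            X = sm.add_constant(1.0 / t)
            y = self.power_W
            ols = sm.OLS(y, X).fit()
            cp, wp = ols.params
            se_cp, se_wp = ols.bse
        return CriticalPowerResults(
            model=self,
            method=method,
            cp_W=float(cp),
            w_prime_J=float(wp),
            se_cp_W=float(se_cp),
            se_wp_J=float(se_wp),
            r2=float(ols.rsquared),
        )

    def _work_time_start(self) -> tuple[float, float]:
        """(CP, W') start values from the work–time OLS, pushed inside bounds."""
        try:
            wt = self._fit_linear("work_time")
            cp0, wp0 = wt.cp_W, wt.w_prime_J
        except SingularFitError:
            cp0, wp0 = 0.75 * float(self.power_W.min()), 15000.0
        hi = float(self.power_W.min()) - CP_MARGIN_W
        cp0 = float(np.clip(cp0, 1.0, hi - 1e-6)) if hi > 1.0 else hi / 2
        wp0 = max(float(wp0), 1.0)
        return cp0, wp0

    def _fit_hyperbolic(self, residual_axis: str = "time") -> "CriticalPowerResults":
        self._require_three("hyperbolic")
        P, t = self.power_W, self.tlim_s
        if np.unique(P).size < 2:
            raise SingularFitError("all trials share one power; design is singular")
        if residual_axis not in ("time", "power"):
            raise InvalidInputError("residual_axis must be 'time' or 'power'")

        cp_hi = float(P.min()) - CP_MARGIN_W

        if residual_axis == "time":
            def resid(x):
                cp, wp = x
                return t - wp / (P - cp)
            response = t
        else:
            def resid(x):
                cp, wp = x
                return P - (cp + wp / t)
            response = P

        x0 = np.asarray(self._work_time_start())
        sol = optimize.least_squares(
            resid,
            x0,
            bounds=([1e-6, 1e-6], [cp_hi, np.inf]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if sol.status <= 0:
            raise FitFailureError(f"hyperbolic fit did not converge: {sol.message}")
        cp, wp = (float(v) for v in sol.x)
        constraint_active = (cp_hi - cp) < 1e-6

        # parameter covariance from the local curvature of the objective
        dof = self.nobs - 2
        rss = float(np.sum(sol.fun**2))
        JtJ = sol.jac.T @ sol.jac
        try:
            cov = (rss / dof) * np.linalg.inv(JtJ)
            se_cp, se_wp = (float(np.sqrt(max(c, 0.0))) for c in np.diag(cov))
        except np.linalg.LinAlgError:
            se_cp = se_wp = float("nan")
        sst = float(np.sum((response - response.mean()) ** 2))
        r2 = 1.0 - rss / sst if sst > 0 else float("nan")
        return CriticalPowerResults(
            model=self,
            method="hyperbolic",
            cp_W=cp,
            w_prime_J=wp,
            se_cp_W=se_cp,
            se_wp_J=se_wp,
            r2=r2,
            residual_axis=residual_axis,
            constraint_active=constraint_active,
        )

    def _fit_two_point(self, form: str = "work_time") -> "CriticalPowerResults":
        """Exact (CP, W') from the lowest- and highest-power trials.

        ``form='work_time'`` solves the 2×2 work–time system;
        ``form='inverse_time'`` the power–1/time system.  The two are
        algebraically identical.
        """
        i = int(np.argmin(self.power_W))
        j = int(np.argmax(self.power_W))
        if i == j:
            j = 1 if i == 0 else 0
        a, b = self.trials[i], self.trials[j]
        if a.power_W == b.power_W and a.tlim_s == b.tlim_s:
            raise InvalidInputError("two-point solve needs two distinct trials")
        if a.tlim_s == b.tlim_s:
            raise SingularFitError("two-point solve needs distinct Tlim values")
        if form == "work_time":
            cp = (b.work_J - a.work_J) / (b.tlim_s - a.tlim_s)
            wp = a.work_J - cp * a.tlim_s
        elif form == "inverse_time":
            wp = (a.power_W - b.power_W) / (1.0 / a.tlim_s - 1.0 / b.tlim_s)
            cp = a.power_W - wp / a.tlim_s
        else:
            raise InvalidInputError("form must be 'work_time' or 'inverse_time'")
        return CriticalPowerResults(
            model=self, method="two_point", cp_W=float(cp), w_prime_J=float(wp)
        )


class CriticalPowerResults:
    """Fitted (CP, W') pair with uncertainties and diagnostics.

    Attributes
    ----------
    cp_W, w_prime_J : float
        Critical power (W) and work capacity above CP (J).
    se_cp_W, se_wp_J : float or None
        Parameter standard errors (absent for the two-point solve).
    r2 : float or None
        Coefficient of determination on the fitted response.
    constraint_active : bool
        True when the hyperbolic CP estimate sits on its upper bound
        (lowest trial power minus the margin) — treat with suspicion.
    """

    def __init__(
        self,
        model: CriticalPowerModel,
        method: str,
        cp_W: float,
        w_prime_J: float,
        se_cp_W: float | None = None,
        se_wp_J: float | None = None,
        r2: float | None = None,
        residual_axis: str | None = None,
        constraint_active: bool = False,
    ):
        self.model = model
        self.method = method
        self.cp_W = cp_W
        self.w_prime_J = w_prime_J
        self.se_cp_W = se_cp_W
        self.se_wp_J = se_wp_J
        self.r2 = r2
        self.residual_axis = residual_axis
        self.constraint_active = constraint_active

    # -- statsmodels-flavoured accessors ----------------------------------

    @property
    def params(self) -> np.ndarray:
        return np.array([self.cp_W, self.w_prime_J])

    @property
    def bse(self) -> np.ndarray | None:
        if self.se_cp_W is None:
            return None
        return np.array([self.se_cp_W, self.se_wp_J])

    @property
    def w_prime_kJ(self) -> float:
        return self.w_prime_J / 1000.0

    @property
    def see_cp_pct(self) -> float | None:
        """SE of CP as a percentage of the estimate."""
        if self.se_cp_W is None:
            return None
        return 100.0 * self.se_cp_W / abs(self.cp_W)

    @property
    def see_wp_pct(self) -> float | None:
        """SE of W' as a percentage of the estimate."""
        if self.se_wp_J is None:
            return None
        return 100.0 * self.se_wp_J / abs(self.w_prime_J)

    def predict(self, power_W):
        """Predicted time to exhaustion t = W'/(P − CP) at supra-CP power."""
        power = np.asarray(power_W, dtype=float)
        if np.any(power <= self.cp_W):
            raise InvalidInputError(
                f"prediction requires power above CP ({self.cp_W:.1f} W); "
                "exhaustion time is unbounded at or below the asymptote"
            )
        out = self.w_prime_J / (power - self.cp_W)
        return float(out) if np.isscalar(power_W) else out

    def summary(self) -> str:
        lines = [
            "Critical power model fit",
            "========================",
            f"method:          {self.method}"
            + (f" ({self.residual_axis}-domain residuals)" if self.residual_axis else ""),
            f"n trials:        {self.model.nobs}",
            f"CP (W):          {self.cp_W:10.2f}"
            + (
                f"   SE {self.se_cp_W:8.2f}  SEE% {self.see_cp_pct:6.2f}"
                if self.se_cp_W is not None
                else ""
            ),
            f"W' (kJ):         {self.w_prime_kJ:10.2f}"
            + (
                f"   SE {self.se_wp_J / 1000:8.2f}  SEE% {self.see_wp_pct:6.2f}"
                if self.se_wp_J is not None
                else ""
            ),
        ]
        if self.r2 is not None:
            lines.append(f"R²:              {self.r2:10.4f}")
        if self.constraint_active:
            lines.append("warning: CP estimate at its upper bound")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CriticalPowerResults {self.method}: CP={self.cp_W:.1f} W, "
            f"W'={self.w_prime_kJ:.1f} kJ>"
        )


# -- functional wrappers over the model/results pair -----------------------


def _as_model(trials: Sequence[PredictiveTrial]) -> CriticalPowerModel:
    return CriticalPowerModel.from_trials(trials)


def fit_work_time(trials: Sequence[PredictiveTrial]) -> CriticalPowerResults:
    """OLS of work on time; slope = CP, intercept = W'."""
    return _as_model(trials).fit("work_time")


def fit_inverse_time(trials: Sequence[PredictiveTrial]) -> CriticalPowerResults:
    """OLS of power on 1/time; intercept = CP, slope = W'."""
    return _as_model(trials).fit("inverse_time")


def fit_hyperbolic(
    trials: Sequence[PredictiveTrial], residual_axis: str = "time"
) -> CriticalPowerResults:
    """Nonlinear least squares on the hyperbola t = W'/(P − CP)."""
    return _as_model(trials).fit("hyperbolic", residual_axis=residual_axis)


def fit_two_point(
    trial_a: PredictiveTrial, trial_b: PredictiveTrial, form: str = "work_time"
) -> CriticalPowerResults:
    """Exact two-trial solve (conventionally the 95% and 110% PPO trials)."""
    return CriticalPowerModel.from_trials([trial_a, trial_b])._fit_two_point(form)


def fit_all(trials: Sequence[PredictiveTrial]) -> dict[str, CriticalPowerResults]:
    """All four model variants; the two-point solve uses the extreme powers."""
    model = _as_model(trials)
    out = {name: model.fit(name) for name in ("work_time", "inverse_time", "hyperbolic")}
    out["two_point"] = model._fit_two_point()
    return out


def predict_tlim(est: CriticalPowerResults, power_W):
    """Time-to-exhaustion prediction from a fitted estimate (hyperbolic form)."""
    return est.predict(power_W)
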