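"""Bland–Altman agreement between actual and predicted exhaustion times.

Differences are taken as predicted − actual, so a positive bias means the
model overestimates exercise tolerance.  Limits of agreement use the
fixed 1.96 multiplier on the sample SD of the differences (not a
t-quantile).  Percent mode divides each difference by the pair mean
before summarising.

Heteroscedasticity — a systematic trend of the differences across the
measurement range — is assessed by regressing the raw differences on the
pair means; the Pearson correlation, its Fisher-z 95% CI and a
two-sided p-value are reported, with p < 0.05 classified heteroscedastic
and |r| bands labelling the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "HeteroscedasticityResult",
    "AgreementResult",
    "bland_altman",
    "heteroscedasticity",
    "agreement_analysis",
    "plot_data",
]

LOA_MULTIPLIER = 1.96
#: |r| bands labelling correlation magnitude (small / moderate / large).
R_BANDS = (0.3, 0.7)


@dataclass(frozen=True)
class HeteroscedasticityResult:
    """Regression of paired differences on pair means."""

    slope: float
    intercept: float
    r: float
    r_ci_low: float
    r_ci_high: float
    p: float
    n: int
    degenerate: bool = False

    @property
    def heteroscedastic(self) -> bool:
        return (not self.degenerate) and self.p < 0.05

    @property
    def magnitude(self) -> str:
        a = abs(self.r)
        if a < R_BANDS[0]:
            return "small"
        return "moderate" if a < R_BANDS[1] else "large"


@dataclass(frozen=True)
class AgreementResult:
    """Bias, SD of differences and 95% limits of agreement."""

    n: int
    mode: str
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    hetero: HeteroscedasticityResult | None = None

    def __post_init__(self) -> None:
        # LoA identity must hold to machine precision for every result
        assert abs(self.loa_low - (self.bias - LOA_MULTIPLIER * self.sd_diff)) < 1e-9
        assert abs(self.loa_high - (self.bias + LOA_MULTIPLIER * self.sd_diff)) < 1e-9

    def summary(self) -> str:
        unit = "s" if self.mode == "raw" else "%"
        lines = [
            f"Bland-Altman agreement (predicted - actual, {self.mode}, n={self.n})",
            f"bias:    {self.bias:8.2f} {unit}",
            f"SD diff: {self.sd_diff:8.2f} {unit}",
            f"95% LoA: [{self.loa_low:.2f}, {self.loa_high:.2f}] {unit}",
        ]
        if self.hetero is not None:
            h = self.hetero
            verdict = "heteroscedastic" if h.heteroscedastic else "homoscedastic"
            lines.append(
                f"diff~mean: r={h.r:.3f} [{h.r_ci_low:.3f}, {h.r_ci_high:.3f}], "
                f"p={h.p:.4f} ({verdict}, {h.magnitude})"
            )
        return "\n".join(lines)


def _pairs(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.atleast_1d(np.asarray(actual, dtype=float))
    p = np.atleast_1d(np.asarray(predicted, dtype=float))
    if a.shape != p.shape or a.ndim != 1:
        raise InvalidInputError("actual and predicted must be matched 1-D arrays")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(p))):
        raise InvalidInputError("pairs must be finite")
    if np.any(a <= 0) or np.any(p <= 0):
        raise InvalidInputError("times must be positive")
    return a, p


def bland_altman(actual, predicted, mode: str = "raw") -> AgreementResult:
    """Bias and 95% limits of agreement of predicted − actual.

    ``mode='percent'`` expresses each difference as a percentage of the
    pair mean (the Bland–Altman convention) before summarising.
    """
    a, p = _pairs(actual, predicted)
    if a.size < 3:
        raise InsufficientDataError("Bland-Altman needs at least 3 pairs")
    if mode not in ("raw", "percent"):
        raise InvalidInputError("mode must be 'raw' or 'percent'")
    diff = p - a
    if mode == "percent":
        diff = 100.0 * diff / ((a + p) / 2.0)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(
        n=int(a.size),
        mode=mode,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
    )


def heteroscedasticity(actual, predicted) -> HeteroscedasticityResult:
    """Regress raw differences on pair means; Pearson r with Fisher-z CI.

    Zero variance in either axis is reported as a degenerate result with
    r = 0 and p = 1 rather than an error.
    """
    a, p = _pairs(actual, predicted)
    n = int(a.size)
    if n < 4:
        raise InsufficientDataError("heteroscedasticity test needs at least 4 pairs")
    mean = (a + p) / 2.0
    diff = p - a
    if np.ptp(mean) == 0 or np.ptp(diff) == 0:
        return HeteroscedasticityResult(
            slope=0.0, intercept=float(diff.mean()), r=0.0,
            r_ci_low=0.0, r_ci_high=0.0, p=1.0, n=n, degenerate=True,
        )
    lr = stats.linregress(mean, diff)
    r = float(np.clip(lr.rvalue, -1.0, 1.0))
    se_z = 1.0 / np.sqrt(n - 3)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    ci = np.tanh([z - LOA_MULTIPLIER * se_z, z + LOA_MULTIPLIER * se_z])
    return HeteroscedasticityResult(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r=r,
        r_ci_low=float(ci[0]),
        r_ci_high=float(ci[1]),
        p=float(lr.pvalue),
        n=n,
    )


def agreement_analysis(actual, predicted, mode: str = "raw") -> AgreementResult:
    """Bland–Altman summary with the heteroscedasticity regression attached.

    The regression always uses raw differences against raw pair means,
    whatever the summary mode.  With exactly 3 pairs the regression is
    omitted (it needs 4).
    """
    ba = bland_altman(actual, predicted, mode=mode)
    a, p = _pairs(actual, predicted)
    hetero = heteroscedasticity(a, p) if a.size >= 4 else None
    return AgreementResult(
        n=ba.n, mode=ba.mode, bias=ba.bias, sd_diff=ba.sd_diff,
        loa_low=ba.loa_low, loa_high=ba.loa_high, hetero=hetero,
    )


def plot_data(actual, predicted) -> pd.DataFrame:
    """(pair mean, difference) table for external Bland–Altman plotting."""
    a, p = _pairs(actual, predicted)
    return pd.DataFrame({"pair_mean": (a + p) / 2.0, "difference": p - a})
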