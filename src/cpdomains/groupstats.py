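"""Within-subject group comparisons.

One-way repeated-measures ANOVA with Greenhouse–Geisser sphericity
correction (Huynh–Feldt available behind a flag), Tukey-corrected
pairwise paired contrasts via the studentized-range distribution, and
Dunnett many-to-one comparisons against a control condition with
family-wise adjustment by seeded Monte Carlo over the joint null
distribution of the maximum |t|, honouring the observed contrast
correlation.

All contrasts are paired: each comparison's standard error comes from
the per-subject difference scores of that comparison (robust to
sphericity violations, matching common software behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "AnovaResult",
    "Comparison",
    "PosthocResult",
    "rm_anova",
    "tukey_pairwise",
    "dunnett_vs_control",
    "dunnett_critical_value",
]


@dataclass(frozen=True)
class AnovaResult:
    """Repeated-measures ANOVA with epsilon-corrected (fractional) dfs."""

    F: float
    df_num: float
    df_den: float
    epsilon: float
    p: float
    correction: str = "greenhouse-geisser"
    degenerate: bool = False

    def summary(self) -> str:
        return (
            f"RM-ANOVA ({self.correction}): "
            f"F({self.df_num:.1f}, {self.df_den:.1f}) = {self.F:.2f}, "
            f"eps = {self.epsilon:.3f}, p = {self.p:.4f}"
        )


@dataclass(frozen=True)
class Comparison:
    label: str
    mean_diff: float
    statistic: float
    df: int
    p_unadjusted: float
    p_adjusted: float
    degenerate: bool = False


@dataclass(frozen=True)
class PosthocResult:
    method: str
    comparisons: tuple[Comparison, ...]
    seed: int | None = None
    n_draws: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison": c.label,
                    "mean_diff": c.mean_diff,
                    "statistic": c.statistic,
                    "df": c.df,
                    "p_unadjusted": c.p_unadjusted,
                    "p_adjusted": c.p_adjusted,
                    "method": self.method,
                    "seed": self.seed,
                }
                for c in self.comparisons
            ]
        )


def _as_table(data, labels: Sequence[str] | None):
    if isinstance(data, pd.DataFrame):
        labels = labels or [str(c) for c in data.columns]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        labels = labels or [f"c{j}" for j in range(X.shape[1] if X.ndim == 2 else 0)]
    if X.ndim != 2:
        raise InvalidInputError("need a subjects x conditions 2-D table")
    n, k = X.shape
    if k < 2:
        raise InsufficientDataError("need at least 2 conditions")
    if n < 3:
        raise InsufficientDataError("need at least 3 subjects")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("table must be complete (finite) cases only")
    if len(labels) != k:
        raise InvalidInputError("labels length must match number of conditions")
    return X, list(labels)


def _gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the double-centered covariance."""
    k = X.shape[1]
    S = np.cov(X, rowvar=False, ddof=1)
    Sdc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    denom = (k - 1) * float(np.sum(Sdc**2))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(Sdc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova(data, labels: Sequence[str] | None = None, correction: str = "gg") -> AnovaResult:
    """One-way within-subject ANOVA with sphericity-corrected p-value.

    ``correction`` is ``'gg'`` (Greenhouse–Geisser, default), ``'hf'``
    (Huynh–Feldt) or ``'none'``.  Degrees of freedom are scaled by the
    epsilon and left fractional.  A table with no within-subject
    variance is reported as F = 0, p = 1 with the ``degenerate`` flag.
    """
    X, _ = _as_table(data, labels)
    n, k = X.shape
    grand = X.mean()
    ss_cond = n * float(np.sum((X.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((X.mean(axis=1) - grand) ** 2))
    ss_tot = float(np.sum((X - grand) ** 2))
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    if ss_err <= 1e-12 * max(ss_tot, 1.0):
        return AnovaResult(
            F=0.0, df_num=float(df_cond), df_den=float(df_err),
            epsilon=1.0, p=1.0, correction=correction, degenerate=True,
        )
    F = (ss_cond / df_cond) / (ss_err / df_err)
    gg = _gg_epsilon(X)
    if correction == "gg":
        eps, name = gg, "greenhouse-geisser"
    elif correction == "hf":
        num = n * df_cond * gg - 2.0
        den = df_cond * (n - 1 - df_cond * gg)
        hf = num / den if den > 0 else 1.0
        eps, name = float(np.clip(hf, 1.0 / df_cond, 1.0)), "huynh-feldt"
    elif correction == "none":
        eps, name = 1.0, "uncorrected"
    else:
        raise InvalidInputError("correction must be 'gg', 'hf' or 'none'")
    dfn, dfd = eps * df_cond, eps * df_err
    p = float(stats.f.sf(F, dfn, dfd))
    return AnovaResult(F=float(F), df_num=dfn, df_den=dfd, epsilon=eps, p=p, correction=name)


def _paired_contrast(d: np.ndarray) -> tuple[float, float, bool]:
    """(mean difference, t statistic, degenerate) of one difference vector."""
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return md, 0.0 if md == 0 else np.inf * np.sign(md), True
    t = md / (sd / np.sqrt(d.size))
    return md, float(t), False


def tukey_pairwise(data, labels: Sequence[str] | None = None) -> PosthocResult:
    """All pairwise paired contrasts, adjusted by the studentized range.

    Each contrast's statistic is q = √2·|t| from its own difference
    scores; the adjusted p comes from the studentized-range distribution
    with k groups and n − 1 degrees of freedom.
    """
    X, labels = _as_table(data, labels)
    n, k = X.shape
    comps = []
    for i, j in combinations(range(k), 2):
        md, t, degen = _paired_contrast(X[:, i] - X[:, j])
        df = n - 1
        if degen:
            p_un = 1.0 if md == 0 else 0.0
            p_adj = p_un
        else:
            p_un = float(2 * stats.t.sf(abs(t), df))
            q = np.sqrt(2.0) * abs(t)
            p_adj = float(stats.studentized_range.sf(q, k, df))
        comps.append(
            Comparison(
                label=f"{labels[i]} - {labels[j]}",
                mean_diff=md, statistic=t, df=df,
                p_unadjusted=p_un, p_adjusted=min(max(p_adj, p_un), 1.0),
                degenerate=degen,
            )
        )
    return PosthocResult(method="tukey", comparisons=tuple(comps))


def _max_abs_t_draws(
    corr: np.ndarray, df: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draws of max_j |T_j| for correlated paired-t statistics."""
    m = corr.shape[0]
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
    Z = rng.standard_normal((n_draws, m)) @ L.T
    scale = np.sqrt(rng.chisquare(df, n_draws) / df)
    return np.abs(Z / scale[:, None]).max(axis=1)


def dunnett_critical_value(
    corr, df: int, alpha: float = 0.05, seed: int = 0, n_draws: int = 100_000
) -> float:
    """Two-sided Dunnett critical value by seeded Monte Carlo.

    ``corr`` is the contrast correlation matrix (equicorrelation 0.5 is
    the balanced textbook case).
    """
    corr = np.asarray(corr, dtype=float)
    draws = _max_abs_t_draws(corr, df, n_draws, np.random.default_rng(seed))
    return float(np.quantile(draws, 1.0 - alpha))


def dunnett_vs_control(
    data,
    control: int = 0,
    labels: Sequence[str] | None = None,
    seed: int = 0,
    n_draws: int = 100_000,
) -> PosthocResult:
    """Each condition vs. a designated control, family-wise adjusted.

    Adjusted p-values are P(max_j |T_j| ≥ |t_observed|) under the joint
    null, evaluated by seeded Monte Carlo with the contrast correlation
    estimated from the per-subject difference scores.  With a single
    comparison the paired-t p is returned exactly.  Adjusted p is never
    below the unadjusted p.
    """
    X, labels = _as_table(data, labels)
    n, k = X.shape
    if not 0 <= control < k:
        raise InvalidInputError(f"control index {control} out of range for k={k}")
    others = [j for j in range(k) if j != control]
    D = X[:, others] - X[:, [control]]
    df = n - 1
    stats_rows = []
    for col, j in enumerate(others):
        md, t, degen = _paired_contrast(D[:, col])
        stats_rows.append((f"{labels[j]} - {labels[control]}", md, t, degen))

    m = len(others)
    live = [i for i, row in enumerate(stats_rows) if not row[3]]
    draws = None
    if m > 1 and len(live) > 1:
        corr = np.corrcoef(D[:, live], rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        draws = _max_abs_t_draws(corr, df, n_draws, np.random.default_rng(seed))

    comps = []
    for i, (label, md, t, degen) in enumerate(stats_rows):
        if degen:
            p_un = 1.0 if md == 0 else 0.0
            p_adj = p_un
        else:
            p_un = float(2 * stats.t.sf(abs(t), df))
            if draws is None:
                p_adj = p_un
            else:
                p_adj = float(np.mean(draws >= abs(t)))
            p_adj = min(max(p_adj, p_un), 1.0)
        comps.append(
            Comparison(
                label=label, mean_diff=md, statistic=t, df=df,
                p_unadjusted=p_un, p_adjusted=p_adj, degenerate=degen,
            )
        )
    return PosthocResult(
        method="dunnett", comparisons=tuple(comps), seed=seed, n_draws=n_draws
    )
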