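"""Locating the severe/extreme exercise-intensity boundary.

The boundary is operationalised through VO2max attainment: a constant
work-rate bout belongs to the severe domain if its highest 15-s VO2
average reaches the athlete's composite VO2max reference minus one
intraindividual SD, and to the extreme domain otherwise.  ``I_HIGH`` is
the highest tested work rate that attains the criterion; the next tested
work rate above it (``I_HIGH+5%``) is the first extreme intensity.

The testing protocol starts at 125% of incremental peak power output and
walks a grid of 5-percentage-point steps up after an attaining bout and
down after a non-attaining one, stopping once an adjacent
attained/non-attained pair brackets the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .breath import BreathSeries, VO2Peak, peak_15s
from .errors import (
    BoundaryNotBracketedError,
    InsufficientDataError,
    ProtocolFailureError,
)

__all__ = [
    "VO2MaxReference",
    "BoundaryResult",
    "vo2max_reference",
    "attained_vo2max",
    "next_test_power",
    "locate_ihigh",
]


@dataclass(frozen=True)
class VO2MaxReference:
    """Composite VO2max with its intraindividual variability.

    ``mean_l_min`` averages the highest VO2 peaks from the incremental and
    the CP predictive trials; ``sd_l_min`` is their sample SD (n − 1).
    The attainment threshold is ``mean − sd``.
    """

    mean_l_min: float
    sd_l_min: float
    n_peaks: int = 2

    def __post_init__(self) -> None:
        if self.mean_l_min <= 0 or self.sd_l_min < 0:
            raise InsufficientDataError("reference requires mean > 0 and sd >= 0")

    @property
    def sd_pct(self) -> float:
        return 100.0 * self.sd_l_min / self.mean_l_min

    @property
    def threshold_l_min(self) -> float:
        return self.mean_l_min - self.sd_l_min


@dataclass(frozen=True)
class BoundaryResult:
    """Per-athlete boundary: I_HIGH, I_HIGH+5% and the evidence for them.

    ``tested`` holds every (power_W, tlim_s, attained) bout considered.
    ``consistent`` is False when a non-attained power sits below an
    attained one (non-monotone attainment pattern).
    """

    i_high_W: float
    i_high_plus5_W: float
    tested: tuple[tuple[float, float, bool], ...]
    consistent: bool = True

    def __post_init__(self) -> None:
        if not self.i_high_plus5_W > self.i_high_W:
            raise BoundaryNotBracketedError("I_HIGH+5% must exceed I_HIGH")

    def _tlim_at(self, power: float) -> float:
        for p, t, _ in self.tested:
            if abs(p - power) < 1e-9:
                return t
        raise KeyError(power)

    @property
    def i_high_tlim_s(self) -> float:
        return self._tlim_at(self.i_high_W)

    @property
    def i_high_plus5_tlim_s(self) -> float:
        return self._tlim_at(self.i_high_plus5_W)


def vo2max_reference(peaks: Iterable[VO2Peak | float]) -> VO2MaxReference:
    """Composite VO2max: mean and sample SD of the contributing peaks."""
    values = np.array(
        [p.value_l_min if isinstance(p, VO2Peak) else float(p) for p in peaks],
        dtype=float,
    )
    if values.size < 2:
        raise InsufficientDataError(
            "at least two VO2 peaks are required for the composite reference"
        )
    return VO2MaxReference(
        mean_l_min=float(values.mean()),
        sd_l_min=float(values.std(ddof=1)),
        n_peaks=int(values.size),
    )


def attained_vo2max(
    series: BreathSeries, ref: VO2MaxReference
) -> tuple[bool, VO2Peak]:
    """Whether a bout attained VO2max (peak ≥ mean − SD, inclusive).

    The comparison carries a one-part-in-10⁹ tolerance so that a peak
    sitting exactly on the threshold counts as attained despite
    floating-point round-off in the bin averaging.
    """
    peak = peak_15s(series)
    tol = 1e-9 * ref.threshold_l_min
    return bool(peak.value_l_min >= ref.threshold_l_min - tol), peak


def _key(pct: float) -> float:
    return round(float(pct), 6)


def next_test_power(
    current_pct_ppo: float,
    attained: bool,
    history: Mapping[float, bool] | None = None,
    step_pct: float = 5.0,
    grid_pct: tuple[float, float] = (100.0, 160.0),
) -> float | None:
    """Next work rate (as % PPO) of the boundary protocol, or None to stop.

    The walk moves up ``step_pct`` after an attaining bout and down after
    a non-attaining one, and stops (returns None) once the accumulated
    history holds an adjacent attained/non-attained pair.  Leaving
    ``grid_pct`` raises :class:`ProtocolFailureError`.
    """
    hist = {_key(p): bool(a) for p, a in (history or {}).items()}
    hist[_key(current_pct_ppo)] = bool(attained)
    for pct, att in hist.items():
        if att and hist.get(_key(pct + step_pct)) is False:
            return None
    nxt = current_pct_ppo + step_pct if attained else current_pct_ppo - step_pct
    if nxt < grid_pct[0] - 1e-9 or nxt > grid_pct[1] + 1e-9:
        raise ProtocolFailureError(
            f"protocol left the configured grid ({grid_pct[0]:g}-{grid_pct[1]:g}% PPO)"
        )
    return float(nxt)


def locate_ihigh(
    tested: Sequence[tuple[float, float, bool]]
) -> BoundaryResult:
    """Boundary work rates from a set of tested bouts.

    ``I_HIGH`` is the highest attained power; ``I_HIGH+5%`` the smallest
    tested power above it.  Requires at least one attained and one
    non-attained bout with a non-attained bout above the highest attained
    one, otherwise the boundary is not bracketed.
    """
    rows = [(float(p), float(t), bool(a)) for p, t, a in tested]
    if not rows:
        raise InsufficientDataError("no tested work rates")
    attained_powers = [p for p, _, a in rows if a]
    missed_powers = [p for p, _, a in rows if not a]
    if not attained_powers or not missed_powers:
        raise BoundaryNotBracketedError(
            "need both an attained and a non-attained work rate"
        )
    i_high = max(attained_powers)
    above = [p for p in missed_powers if p > i_high]
    if not above:
        raise BoundaryNotBracketedError(
            f"no tested work rate above the highest attained power ({i_high:g} W)"
        )
    consistent = min(missed_powers) > i_high
    return BoundaryResult(
        i_high_W=i_high,
        i_high_plus5_W=min(above),
        tested=tuple(sorted(rows)),
        consistent=consistent,
    )
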