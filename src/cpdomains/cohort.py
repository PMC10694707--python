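"""Synthetic cohorts with the data structure the analysis assumes.

The generator emulates a cohort of recreationally trained cyclists
(defaults: CP 213 ± 38 W, W' 19.4 ± 5.4 kJ, VO2max 3.75 ± 0.41 L·min⁻¹,
body mass 77.8 ± 6.2 kg, n = 19) going through the full experimental
design: a staged incremental test, three predictive exhaustion trials at
95/100/110% of PPO, and an iterative boundary search from 125% PPO in
5%-of-PPO steps.

Ground-truth mechanisms
-----------------------
* Exhaustion times follow the hyperbola ``t = usable W' / (P − CP)``
  with multiplicative lognormal noise (CV-parameterised, mean 1).
* Above the true severe/extreme boundary ``i_high_true`` the usable W'
  falls short linearly: ``usable = W'·max(0, 1 − k·(P − i_high_true)/
  i_high_true)`` with shortfall gain ``k``.  ``k = 0`` recovers a pure
  hyperbola at every power; ``k > 0`` makes severe-domain estimates
  overestimate extreme-domain tolerance.
* VO2 traces are a mono-exponential primary phase plus a slow component
  that rises linearly after a delay for supra-CP work, capped at VO2max.
  At powers at or below ``i_high_true`` the slow-component slope is
  raised, if necessary, so the trace reaches VO2max comfortably before
  exhaustion; above the boundary the trace is capped ``extreme_deficit``
  below VO2max.  The attainment criterion is thereby satisfied exactly
  where the ground truth says it should be (this guarantee requires the
  slow component to be enabled, i.e. ``sc_gain > 0``).
* The incremental test depletes a W' balance at rate (P − CP) during
  supra-CP stages; exhaustion occurs when the balance reaches zero and
  PPO interpolates the partial final stage.

All randomness flows through one seed; per-athlete substreams are
spawned deterministically from (seed, athlete index).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import agreement as agr
from . import groupstats as gs
from .boundary import (
    BoundaryResult,
    attained_vo2max,
    locate_ihigh,
    next_test_power,
    vo2max_reference,
)
from .breath import BreathSeries, IncrementalResult, VO2Peak, peak_15s, ppo_from_incremental
from .critpower import MODEL_NAMES, PredictiveTrial, fit_all
from .errors import (
    BoundaryNotBracketedError,
    InvalidInputError,
    ProtocolFailureError,
)

__all__ = [
    "AthleteProfile",
    "CohortConfig",
    "StudyResult",
    "sample_cohort",
    "simulate_tlim",
    "simulate_breath_series",
    "simulate_incremental",
    "run_study",
    "deterministic_ppo",
]


@dataclass(frozen=True)
class AthleteProfile:
    """Ground-truth physiology of one synthetic athlete.

    ``extreme_shortfall_k`` controls how much of W' is unusable above the
    true boundary (0 = pure hyperbola everywhere); ``tlim_noise_cv`` is
    the day-to-day coefficient of variation of exhaustion times;
    ``vo2_day_cv`` is the day-to-day variability of the attainable VO2
    plateau (the source of the intraindividual SD of VO2 peaks across
    trials); ``extreme_deficit_l_min`` is how far below VO2max the
    oxygen-uptake trace plateaus in the extreme domain.
    """

    cp_W: float
    w_prime_J: float
    vo2max_l_min: float
    vo2_baseline_l_min: float
    tau_primary_s: float
    sc_delay_s: float
    sc_gain_l_min_per_W: float
    body_mass_kg: float
    i_high_true_W: float
    extreme_shortfall_k: float = 0.5
    tlim_noise_cv: float = 0.05
    vo2_noise_sd_l_min: float = 0.2
    vo2_day_cv: float = 0.04
    extreme_deficit_l_min: float = 0.25

    def __post_init__(self) -> None:
        positive = (
            self.cp_W, self.w_prime_J, self.vo2max_l_min,
            self.vo2_baseline_l_min, self.tau_primary_s, self.body_mass_kg,
            self.i_high_true_W,
        )
        if any(not (v > 0 and np.isfinite(v)) for v in positive):
            raise InvalidInputError("physiological fields must be positive and finite")
        if self.cp_W >= self.i_high_true_W:
            raise InvalidInputError("the true boundary must lie above CP")
        if self.vo2_baseline_l_min >= self.vo2max_l_min:
            raise InvalidInputError("baseline VO2 must lie below VO2max")
        if min(self.extreme_shortfall_k, self.tlim_noise_cv, self.vo2_day_cv) < 0:
            raise InvalidInputError("noise and shortfall parameters must be >= 0")
        if self.sc_delay_s < 0 or self.sc_gain_l_min_per_W < 0:
            raise InvalidInputError("slow-component parameters must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort distributions ((mean, SD) pairs) and protocol settings.

    Defaults mirror the study conditions: n = 19 cyclists, predictive
    trials at 95/100/110% PPO, incremental stages of 0.5 W·kg⁻¹ every
    180 s, boundary search anchored at 125% PPO with 5-percentage-point
    steps on a 100–160% PPO grid.  ``i_high_ratio`` places the true
    boundary as a multiple of PPO (~1.26 PPO in the study's cohort).
    """

    n: int = 19
    seed: int = 0
    cp_W: tuple[float, float] = (213.0, 38.0)
    w_prime_J: tuple[float, float] = (19400.0, 5400.0)
    vo2max_l_min: tuple[float, float] = (3.75, 0.41)
    vo2_baseline_l_min: tuple[float, float] = (0.90, 0.10)
    tau_primary_s: tuple[float, float] = (25.0, 4.0)
    sc_delay_s: tuple[float, float] = (60.0, 10.0)
    sc_gain_l_min_per_W: tuple[float, float] = (8e-4, 2e-4)
    body_mass_kg: tuple[float, float] = (77.8, 6.2)
    i_high_ratio: tuple[float, float] = (1.27, 0.03)
    extreme_shortfall_k: float = 0.5
    tlim_noise_cv: float = 0.05
    vo2_noise_sd_l_min: float = 0.2
    vo2_day_cv: float = 0.04
    extreme_deficit_l_min: float = 0.25
    # protocol
    stage_w_per_kg: float = 0.5
    stage_s: float = 180.0
    predictive_fracs: tuple[float, ...] = (0.95, 1.0, 1.10)
    boundary_start_pct: float = 125.0
    boundary_step_pct: float = 5.0
    boundary_grid_pct: tuple[float, float] = (100.0, 160.0)
    breath_dt_s: float = 1.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("cohort size must be at least 1")
        for name in (
            "cp_W", "w_prime_J", "vo2max_l_min", "vo2_baseline_l_min",
            "tau_primary_s", "sc_delay_s", "sc_gain_l_min_per_W",
            "body_mass_kg", "i_high_ratio",
        ):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise InvalidInputError(f"{name} SD must be >= 0")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# bounds used when truncating sampled fields to physiological plausibility
_FIELD_BOUNDS = {
    "cp_W": (100.0, 400.0),
    "w_prime_J": (6000.0, 45000.0),
    "vo2max_l_min": (2.2, 6.0),
    "vo2_baseline_l_min": (0.4, 1.6),
    "tau_primary_s": (12.0, 45.0),
    "sc_delay_s": (20.0, 120.0),
    "sc_gain_l_min_per_W": (1e-4, 3e-3),
    "body_mass_kg": (50.0, 110.0),
    "i_high_ratio": (1.10, 1.50),
}


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def deterministic_ppo(
    cp_W: float,
    w_prime_J: float,
    body_mass_kg: float,
    stage_w_per_kg: float = 0.5,
    stage_s: float = 180.0,
    max_stages: int = 60,
) -> tuple[float, list[tuple[float, float]], float]:
    """Noise-free incremental outcome by stagewise W'-balance accounting.

    Returns (PPO, stages as (power, duration), total supra-CP duration).
    """
    inc = stage_w_per_kg * body_mass_kg
    balance = w_prime_J
    stages: list[tuple[float, float]] = []
    supra = 0.0
    for k in range(1, max_stages + 1):
        power = k * inc
        if power > cp_W:
            drain = power - cp_W
            if balance <= drain * stage_s + 1e-12:
                dur = balance / drain
                stages.append((power, dur))
                supra += dur
                ppo = ppo_from_incremental(power - inc, inc, dur, stage_s)
                return ppo, stages, supra
            balance -= drain * stage_s
            supra += stage_s
        stages.append((power, stage_s))
    raise ProtocolFailureError(
        f"no exhaustion within {max_stages} incremental stages (CP {cp_W:g} W)"
    )


def sample_cohort(config: CohortConfig) -> list[AthleteProfile]:
    """Draw a reproducible cohort of athlete profiles.

    Fields are independent truncated normals; the true boundary is
    placed at ``i_high_ratio × PPO`` with PPO computed from the athlete's
    own noise-free incremental test.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 0x0C0)))
    athletes = []
    for _ in range(config.n):
        draw = {
            name: _trunc_normal(rng, *getattr(config, name), *_FIELD_BOUNDS[name])
            for name in _FIELD_BOUNDS
        }
        # keep baseline well below VO2max
        draw["vo2_baseline_l_min"] = min(
            draw["vo2_baseline_l_min"], draw["vo2max_l_min"] - 1.0
        )
        ratio = draw.pop("i_high_ratio")
        ppo, _, _ = deterministic_ppo(
            draw["cp_W"], draw["w_prime_J"], draw["body_mass_kg"],
            config.stage_w_per_kg, config.stage_s,
        )
        athletes.append(
            AthleteProfile(
                i_high_true_W=ratio * ppo,
                extreme_shortfall_k=config.extreme_shortfall_k,
                tlim_noise_cv=config.tlim_noise_cv,
                vo2_noise_sd_l_min=config.vo2_noise_sd_l_min,
                vo2_day_cv=config.vo2_day_cv,
                extreme_deficit_l_min=config.extreme_deficit_l_min,
                **draw,
            )
        )
    return athletes


def simulate_tlim(
    athlete: AthleteProfile, power_W: float, rng: np.random.Generator | None = None
) -> float:
    """Draw a time to exhaustion at a supra-CP work rate.

    Hyperbolic with the usable-W' shortfall above the true boundary and
    multiplicative lognormal noise of the configured CV (unit mean).
    """
    if power_W <= athlete.cp_W:
        raise InvalidInputError("exhaustion is unbounded at or below CP")
    usable = athlete.w_prime_J
    if power_W > athlete.i_high_true_W and athlete.extreme_shortfall_k > 0:
        frac = 1.0 - athlete.extreme_shortfall_k * (
            power_W - athlete.i_high_true_W
        ) / athlete.i_high_true_W
        usable *= max(0.0, frac)
    base = usable / (power_W - athlete.cp_W)
    cv = athlete.tlim_noise_cv
    if cv > 0 and rng is not None:
        sigma = np.sqrt(np.log1p(cv**2))
        base *= rng.lognormal(-0.5 * sigma**2, sigma)
    return max(float(base), 5.0)


# fraction of the VO2max-baseline range the primary phase may cover; the
# remainder is the slow component's job (keeps extreme bouts sub-maximal)
_PRIMARY_CAP = 0.92
#: steady-state O2 cost of cycling above baseline, L·min⁻¹ per W
_DEMAND_GAIN = 0.0103


def simulate_breath_series(
    athlete: AthleteProfile,
    power_W: float,
    tlim_s: float,
    rng: np.random.Generator | None = None,
    dt_s: float = 1.5,
) -> BreathSeries:
    """Breath-by-breath VO2 trace for one constant work-rate bout.

    Primary mono-exponential toward ``min(demand, 0.92·(VO2max −
    baseline))`` plus, for supra-CP work with ``sc_gain > 0``, a linear
    slow component after ``sc_delay``.  Severe bouts (P ≤ i_high_true)
    are guaranteed to plateau at the day's attainable VO2max at least
    ~20 s before exhaustion; extreme bouts are capped ``extreme_deficit``
    below it.  The attainable plateau varies between bouts with CV
    ``vo2_day_cv`` (the source of the intraindividual SD of VO2 peaks),
    and additive Gaussian noise models breath-to-breath scatter; samples
    every ~1.5 s.
    """
    if tlim_s <= 0:
        raise InvalidInputError("tlim_s must be positive")
    vmax, base = athlete.vo2max_l_min, athlete.vo2_baseline_l_min
    if base >= vmax:
        raise InvalidInputError("inconsistent profile: baseline >= VO2max")
    if rng is not None and athlete.vo2_day_cv > 0:
        # day-to-day variation of the attainable plateau, truncated mild
        vmax = vmax * float(np.clip(rng.normal(1.0, athlete.vo2_day_cv), 0.85, 1.15))
        vmax = max(vmax, base + 0.5)
    t = np.arange(dt_s, tlim_s + 1e-9, dt_s)
    if t.size < 2:
        t = np.array([tlim_s / 2.0, tlim_s])
    amp = min(_DEMAND_GAIN * power_W, _PRIMARY_CAP * (vmax - base))
    vo2 = base + amp * (1.0 - np.exp(-t / athlete.tau_primary_s))

    supra = power_W > athlete.cp_W
    if supra and athlete.sc_gain_l_min_per_W > 0:
        severe = power_W <= athlete.i_high_true_W
        rate = athlete.sc_gain_l_min_per_W * (power_W - athlete.cp_W) / 60.0
        delay = athlete.sc_delay_s
        if severe:
            # guarantee VO2max attainment with a full 15-s window to spare
            t_target = tlim_s - 20.0 if tlim_s > 80.0 else 0.75 * tlim_s
            delay = min(delay, 0.3 * tlim_s)
            deficit = vmax - (base + amp * (1.0 - np.exp(-t_target / athlete.tau_primary_s)))
            if deficit > 0:
                rate = max(rate, deficit / max(t_target - delay, 1.0))
        sc = rate * np.clip(t - delay, 0.0, None)
        vo2 = vo2 + sc
        cap = vmax if severe else max(vmax - athlete.extreme_deficit_l_min, base + 0.1)
        vo2 = np.minimum(vo2, cap)
    elif supra:
        vo2 = np.minimum(vo2, vmax)

    if rng is not None and athlete.vo2_noise_sd_l_min > 0:
        vo2 = vo2 + rng.normal(0.0, athlete.vo2_noise_sd_l_min, size=vo2.size)
    return BreathSeries(t, np.clip(vo2, 0.05, None))


def simulate_incremental(
    athlete: AthleteProfile,
    rng: np.random.Generator | None = None,
    stage_w_per_kg: float = 0.5,
    stage_s: float = 180.0,
    dt_s: float = 1.5,
    return_trace: bool = False,
) -> IncrementalResult | tuple[IncrementalResult, BreathSeries]:
    """Staged incremental test to exhaustion with VO2 peak extraction.

    Stage powers are multiples of ``stage_w_per_kg × body mass``; the W'
    balance drains at (P − CP) during supra-CP stages and exhaustion
    interpolates the final stage into PPO.  The VO2 peak is read off a
    simulated trace of the supra-CP portion (severe by construction,
    since the boundary sits above PPO).
    """
    ppo, stages, supra = deterministic_ppo(
        athlete.cp_W, athlete.w_prime_J, athlete.body_mass_kg, stage_w_per_kg, stage_s
    )
    trace = simulate_breath_series(
        athlete, min(ppo, athlete.i_high_true_W), max(supra, 60.0), rng, dt_s
    )
    result = IncrementalResult(ppo_W=ppo, vo2peak=peak_15s(trace), stages=stages)
    return (result, trace) if return_trace else result


# ---------------------------------------------------------------------------
# full study replica


@dataclass
class StudyResult:
    """Bundle of tables produced by one synthetic study run."""

    cohort: pd.DataFrame
    trials: pd.DataFrame
    fits: pd.DataFrame
    boundary: pd.DataFrame
    predictions: pd.DataFrame
    agreement: pd.DataFrame
    anova: dict[str, gs.AnovaResult] = field(default_factory=dict)
    posthoc: dict[str, gs.PosthocResult] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    breath: pd.DataFrame | None = None

    def to_dir(self, path) -> None:
        """Write the bundle as delimited tables plus a JSON manifest."""
        import pathlib

        p = pathlib.Path(path)
        p.mkdir(parents=True, exist_ok=True)
        for name in ("cohort", "trials", "fits", "boundary", "predictions", "agreement"):
            getattr(self, name).to_csv(p / f"{name}.csv", index=False)
        if self.breath is not None:
            self.breath.to_csv(p / "breath.csv", index=False)
        anova_rows = {
            key: {"F": a.F, "df_num": a.df_num, "df_den": a.df_den,
                  "epsilon": a.epsilon, "p": a.p, "correction": a.correction}
            for key, a in self.anova.items()
        }
        with open(p / "anova.json", "w") as fh:
            json.dump(anova_rows, fh, indent=1)
        if self.posthoc:
            pd.concat(
                [r.to_frame().assign(family=key) for key, r in self.posthoc.items()],
                ignore_index=True,
            ).to_csv(p / "posthoc.csv", index=False)
        with open(p / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)


def _athlete_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


def _run_boundary_search(
    athlete: AthleteProfile,
    ppo: float,
    ref,
    rng: np.random.Generator,
    cfg: CohortConfig,
    rows: list,
    athlete_id: str,
    breath_store: list | None = None,
) -> BoundaryResult:
    pct = cfg.boundary_start_pct
    history: dict[float, bool] = {}
    tested = []
    max_steps = int(
        (cfg.boundary_grid_pct[1] - cfg.boundary_grid_pct[0]) / cfg.boundary_step_pct
    ) + 2
    for step in range(max_steps):
        power = pct / 100.0 * ppo
        tlim = simulate_tlim(athlete, power, rng)
        series = simulate_breath_series(athlete, power, tlim, rng, cfg.breath_dt_s)
        att, peak = attained_vo2max(series, ref)
        tested.append((power, tlim, att))
        if breath_store is not None:
            breath_store.append(
                pd.DataFrame(
                    {
                        "athlete_id": athlete_id, "trial_id": f"boundary_{pct:g}",
                        "time_s": series.time_s, "vo2_l_min": series.vo2_l_min,
                    }
                )
            )
        rows.append(
            {
                "athlete_id": athlete_id,
                "trial_id": f"boundary_{pct:g}",
                "kind": "boundary",
                "power_W": power,
                "tlim_s": tlim,
                "vo2peak_l_min": peak.value_l_min,
                "attained": att,
            }
        )
        nxt = next_test_power(
            pct, att, history,
            step_pct=cfg.boundary_step_pct, grid_pct=cfg.boundary_grid_pct,
        )
        history[round(pct, 6)] = att
        if nxt is None:
            break
        pct = nxt
    return locate_ihigh(tested)


def run_study(
    config: CohortConfig,
    stats: Sequence[str] = ("agreement", "anova", "posthoc"),
    keep_breath: bool = False,
) -> StudyResult:
    """Run the full experimental design on a synthetic cohort.

    Per athlete: incremental test → PPO and VO2 peak; predictive trials
    at 95/100/110% PPO; composite VO2max reference; boundary search;
    four CP/W' fits; hyperbolic Tlim predictions at I_HIGH and
    I_HIGH+5%.  Cohort-level: Bland–Altman agreement (raw and percent)
    with the heteroscedasticity regression, repeated-measures ANOVAs and
    Tukey/Dunnett post hocs, as requested via ``stats``.

    Athletes whose boundary protocol fails (leaves the grid or does not
    bracket) are excluded from cohort-level statistics and listed in the
    manifest.  Byte-identical outputs are guaranteed for equal configs.
    """
    athletes = sample_cohort(config)
    cohort_rows, trial_rows, fit_rows, boundary_rows, pred_rows = [], [], [], [], []
    breath_store: list[pd.DataFrame] = []
    excluded: dict[str, str] = {}

    for idx, athlete in enumerate(athletes):
        aid = f"A{idx + 1:02d}"
        rng = _athlete_rng(config.seed, idx)
        cohort_rows.append({"athlete_id": aid, **asdict(athlete)})
        try:
            inc, inc_trace = simulate_incremental(
                athlete, rng, config.stage_w_per_kg, config.stage_s,
                config.breath_dt_s, return_trace=True,
            )
            ppo = inc.ppo_W
            if keep_breath:
                breath_store.append(
                    pd.DataFrame(
                        {
                            "athlete_id": aid, "trial_id": "incremental",
                            "time_s": inc_trace.time_s,
                            "vo2_l_min": inc_trace.vo2_l_min,
                        }
                    )
                )
            trial_rows.append(
                {
                    "athlete_id": aid, "trial_id": "incremental", "kind": "incremental",
                    "power_W": ppo, "tlim_s": sum(d for _, d in inc.stages),
                    "vo2peak_l_min": inc.vo2peak.value_l_min, "attained": None,
                }
            )
            peaks = [inc.vo2peak]
            trials = []
            for frac in config.predictive_fracs:
                power = frac * ppo
                tlim = simulate_tlim(athlete, power, rng)
                series = simulate_breath_series(
                    athlete, power, tlim, rng, config.breath_dt_s
                )
                peak = peak_15s(series)
                peaks.append(peak)
                trials.append(PredictiveTrial(power, tlim))
                trial_rows.append(
                    {
                        "athlete_id": aid, "trial_id": f"cp_{frac * 100:g}",
                        "kind": "predictive", "power_W": power, "tlim_s": tlim,
                        "vo2peak_l_min": peak.value_l_min, "attained": None,
                    }
                )
                if keep_breath:
                    breath_store.append(
                        pd.DataFrame(
                            {
                                "athlete_id": aid, "trial_id": f"cp_{frac * 100:g}",
                                "time_s": series.time_s, "vo2_l_min": series.vo2_l_min,
                            }
                        )
                    )
            ref = vo2max_reference(peaks)
            bres = _run_boundary_search(
                athlete, ppo, ref, rng, config, trial_rows, aid,
                breath_store if keep_breath else None,
            )
        except (ProtocolFailureError, BoundaryNotBracketedError) as err:
            excluded[aid] = f"{type(err).__name__}: {err}"
            # drop the athlete's partial rows so the bundle stays consistent
            trial_rows = [r for r in trial_rows if r["athlete_id"] != aid]
            breath_store = [
                df for df in breath_store if df["athlete_id"].iloc[0] != aid
            ]
            continue

        boundary_rows.append(
            {
                "athlete_id": aid,
                "ppo_W": ppo,
                "vo2max_ref_l_min": ref.mean_l_min,
                "vo2max_sd_l_min": ref.sd_l_min,
                "threshold_l_min": ref.threshold_l_min,
                "i_high_W": bres.i_high_W,
                "i_high_plus5_W": bres.i_high_plus5_W,
                "i_high_tlim_s": bres.i_high_tlim_s,
                "i_high_plus5_tlim_s": bres.i_high_plus5_tlim_s,
                "consistent": bres.consistent,
            }
        )

        fits = fit_all(trials)
        for name, res in fits.items():
            fit_rows.append(
                {
                    "athlete_id": aid, "model": name,
                    "cp_W": res.cp_W, "w_prime_J": res.w_prime_J,
                    "se_cp_W": res.se_cp_W, "se_wp_J": res.se_wp_J,
                    "see_cp_pct": res.see_cp_pct, "see_wp_pct": res.see_wp_pct,
                    "r2": res.r2, "cp_true_W": athlete.cp_W,
                    "w_prime_true_J": athlete.w_prime_J,
                }
            )
        for intensity, power, actual in (
            ("i_high", bres.i_high_W, bres.i_high_tlim_s),
            ("i_high_plus5", bres.i_high_plus5_W, bres.i_high_plus5_tlim_s),
        ):
            for name, res in fits.items():
                if power <= res.cp_W:
                    continue
                pred_rows.append(
                    {
                        "athlete_id": aid, "model": name, "intensity": intensity,
                        "power_W": power, "actual_s": actual,
                        "predicted_s": res.predict(power),
                    }
                )

    cohort_df = pd.DataFrame(cohort_rows)
    trials_df = pd.DataFrame(trial_rows)
    fits_df = pd.DataFrame(fit_rows)
    boundary_df = pd.DataFrame(boundary_rows)
    pred_df = pd.DataFrame(pred_rows)

    agreement_df = (
        _agreement_table(pred_df) if "agreement" in stats and len(pred_df)
        else pd.DataFrame()
    )
    anova_out: dict[str, gs.AnovaResult] = {}
    posthoc_out: dict[str, gs.PosthocResult] = {}
    if "anova" in stats and len(fits_df):
        _model_anovas(fits_df, pred_df, anova_out, posthoc_out,
                      "posthoc" in stats, config.seed)

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_athletes": config.n,
        "excluded": excluded,
    }
    return StudyResult(
        cohort=cohort_df, trials=trials_df, fits=fits_df, boundary=boundary_df,
        predictions=pred_df, agreement=agreement_df, anova=anova_out,
        posthoc=posthoc_out, manifest=manifest,
        breath=pd.concat(breath_store, ignore_index=True) if breath_store else None,
    )


def _agreement_table(pred_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (intensity, model), grp in pred_df.groupby(["intensity", "model"], sort=True):
        if len(grp) < 3:
            continue
        for mode in ("raw", "percent"):
            res = agr.agreement_analysis(
                grp["actual_s"].to_numpy(), grp["predicted_s"].to_numpy(), mode=mode
            )
            h = res.hetero
            rows.append(
                {
                    "intensity": intensity, "model": model, "mode": mode,
                    "n": res.n, "bias": res.bias, "sd_diff": res.sd_diff,
                    "loa_low": res.loa_low, "loa_high": res.loa_high,
                    "hetero_r": h.r if (h and mode == "raw") else np.nan,
                    "hetero_r_ci_low": h.r_ci_low if (h and mode == "raw") else np.nan,
                    "hetero_r_ci_high": h.r_ci_high if (h and mode == "raw") else np.nan,
                    "hetero_p": h.p if (h and mode == "raw") else np.nan,
                    "hetero_slope": h.slope if (h and mode == "raw") else np.nan,
                    "heteroscedastic": h.heteroscedastic if (h and mode == "raw") else None,
                }
            )
    return pd.DataFrame(rows)


def _model_anovas(
    fits_df: pd.DataFrame,
    pred_df: pd.DataFrame,
    anova_out: dict,
    posthoc_out: dict,
    do_posthoc: bool,
    seed: int,
) -> None:
    for measure, col in (("cp", "cp_W"), ("w_prime", "w_prime_J")):
        wide = fits_df.pivot(index="athlete_id", columns="model", values=col)
        wide = wide[[m for m in MODEL_NAMES if m in wide.columns]].dropna()
        if wide.shape[0] >= 3 and wide.shape[1] >= 2:
            anova_out[measure] = gs.rm_anova(wide)
            if do_posthoc:
                posthoc_out[measure] = gs.tukey_pairwise(wide)
    for intensity, grp in pred_df.groupby("intensity"):
        wide = grp.pivot(index="athlete_id", columns="model", values="predicted_s")
        wide.insert(0, "actual", grp.groupby("athlete_id")["actual_s"].first())
        wide = wide.dropna()
        if wide.shape[0] >= 3 and wide.shape[1] >= 2:
            key = f"tlim_{intensity}"
            anova_out[key] = gs.rm_anova(wide)
            if do_posthoc:
                posthoc_out[key] = gs.dunnett_vs_control(
                    wide, control=0, seed=int(seed) % (2**31),
                )
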