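"""Generative model of the two-player cooperative keystroke task.

Each trial both partners respond to a go signal; the dyad wins the trial
when the absolute difference of their response times (RTD) does not exceed
a trial-specific threshold ``T = (RT1 + RT2) / 8``.  Three strategy modes
are modeled:

* ``delayed`` -- partners agree on a shared intended delay before pressing,
  which lengthens both RTs (and therefore the threshold) without increasing
  their difference.
* ``immediate`` -- partners press as fast as possible; RTs are short and the
  threshold small.
* ``none`` -- partners never settled on a common strategy; a sizeable
  fraction of trials are discoordinated, with one partner responding late.

The generative hierarchy is: group-level parameters -> dyad-level latent
effects (mean RT, trial noise scale, lapse offset) -> trial-level draws.
Occasional "lapse" trials (one partner responding off-rhythm) occur in all
modes at a mode-specific rate; they carry most of the losing trials while
leaving the dyad's mean RT unchanged.

Behavioral metrics: winning ratio WR, mean RTD, mean threshold, and the
cooperation coefficient CC = mean threshold - mean RTD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import truncnorm

from . import constants
from .errors import ValidationError

__all__ = [
    "StrategyKind",
    "StrategyParams",
    "DyadEffects",
    "TrialRecord",
    "DyadSession",
    "BehavioralSummary",
    "compute_threshold",
    "score_trial",
    "default_params",
    "draw_dyad_effects",
    "draw_trial_rts",
    "simulate_session",
    "summarize_behavior",
    "simulate_cohort",
    "trials_to_frame",
    "summaries_to_frame",
]

_MIN_RT_S = 0.05  # floor keeping RTs strictly positive after noise
# Dyad-level mean RT cap: keeps 20 trials (cue + RT + feedback + ITI) inside
# a 150 s block.  For the delayed group this truncates a ~3 sigma tail and
# perturbs the printed mean/SD by well under 1%.
_MAX_DYAD_MEAN_RT_S = 2.2


class StrategyKind(str, Enum):
    """The three strategy modes a dyad can adopt."""

    DELAYED = "delayed"
    IMMEDIATE = "immediate"
    NONE = "none"

    @classmethod
    def coerce(cls, value: "StrategyKind | str") -> "StrategyKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ValidationError(f"unknown strategy {value!r}") from exc


@dataclass(frozen=True)
class StrategyParams:
    """Group-level generative parameters for one strategy mode.

    ``dyad_mean_rt_mean`` / ``dyad_mean_rt_sd`` describe the between-dyad
    distribution of mean response time.  ``inconsistency_rate`` is the
    per-trial probability of a lapse (off-rhythm response by one partner)
    of typical size ``lapse_offset_mean`` seconds.  ``noise_heterogeneity``
    is the log-SD of a dyad-level multiplier on ``trial_noise_sd``.
    """

    dyad_mean_rt_mean: float
    dyad_mean_rt_sd: float
    intended_delay_median: float | None = None
    within_dyad_coupling: float = 0.5
    trial_noise_sd: float = 0.08
    inconsistency_rate: float = 0.0
    timeout: float = constants.RESPONSE_TIMEOUT_S
    lapse_offset_mean: float = 0.25
    noise_heterogeneity: float = 0.35

    def __post_init__(self) -> None:
        if self.dyad_mean_rt_mean <= 0:
            raise ValidationError("dyad_mean_rt_mean must be positive")
        if self.dyad_mean_rt_sd < 0 or self.trial_noise_sd < 0:
            raise ValidationError("standard deviations must be nonnegative")
        if not 0.0 <= self.within_dyad_coupling <= 1.0:
            raise ValidationError("within_dyad_coupling must be in [0, 1]")
        if not 0.0 <= self.inconsistency_rate <= 1.0:
            raise ValidationError("inconsistency_rate must be in [0, 1]")
        if self.timeout <= 0:
            raise ValidationError("timeout must be positive")
        if self.lapse_offset_mean < 0 or self.noise_heterogeneity < 0:
            raise ValidationError("lapse parameters must be nonnegative")


# Calibrated so that simulated cohorts reproduce the printed group structure:
# mean RT 0.83/0.30/0.43 s (between-dyad SD 0.44/0.06/0.09), WR ordered
# delayed > immediate > none, near-equal group mean RTDs, and thresholds
# ordered delayed > none > immediate.
_DEFAULTS: dict[StrategyKind, StrategyParams] = {
    StrategyKind.DELAYED: StrategyParams(
        dyad_mean_rt_mean=0.83,
        dyad_mean_rt_sd=0.44,
        intended_delay_median=0.5,
        within_dyad_coupling=0.8,
        trial_noise_sd=0.255,
        inconsistency_rate=0.10,
        lapse_offset_mean=0.35,
        noise_heterogeneity=0.45,
    ),
    StrategyKind.IMMEDIATE: StrategyParams(
        dyad_mean_rt_mean=0.30,
        dyad_mean_rt_sd=0.06,
        within_dyad_coupling=0.3,
        trial_noise_sd=0.047,
        inconsistency_rate=0.32,
        lapse_offset_mean=0.35,
        noise_heterogeneity=0.45,
    ),
    StrategyKind.NONE: StrategyParams(
        dyad_mean_rt_mean=0.43,
        dyad_mean_rt_sd=0.09,
        within_dyad_coupling=0.8,
        trial_noise_sd=0.095,
        inconsistency_rate=0.66,
        lapse_offset_mean=0.20,
        noise_heterogeneity=0.45,
    ),
}


def default_params(strategy: StrategyKind | str) -> StrategyParams:
    """Return the calibrated default :class:`StrategyParams` for a mode."""
    return _DEFAULTS[StrategyKind.coerce(strategy)]


@dataclass(frozen=True)
class DyadEffects:
    """Latent dyad-level draws feeding the trial generator."""

    mean_rt: float
    trial_noise_sd: float
    lapse_offset: float


@dataclass(frozen=True)
class TrialRecord:
    block_index: int
    trial_index: int
    cue_delay: float
    rt1: float
    rt2: float
    threshold: float
    rtd: float
    outcome: int


@dataclass
class DyadSession:
    dyad_id: str
    strategy: StrategyKind
    trials: list[TrialRecord]
    score_trajectory: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def final_score(self) -> int:
        return self.score_trajectory[-1] if self.score_trajectory else 0


@dataclass(frozen=True)
class BehavioralSummary:
    wr: float
    mean_rt: float
    mean_rtd: float
    mean_threshold: float
    cc: float


def compute_threshold(rt1: float, rt2: float) -> float:
    """Trial win threshold ``T = (RT1 + RT2) / 8``."""
    if rt1 <= 0 or rt2 <= 0:
        raise ValidationError("response times must be positive")
    return (rt1 + rt2) / constants.THRESHOLD_DIVISOR


def score_trial(rtd: float, threshold: float, tie_rule: str = "leq") -> int:
    """Score one trial: +1 for a win, -1 for a loss.

    ``tie_rule`` decides an exact tie ``rtd == threshold``: ``"leq"``
    (default) counts it as a win, ``"lt"`` as a loss.
    """
    if rtd < 0 or threshold < 0:
        raise ValidationError("rtd and threshold must be nonnegative")
    if tie_rule not in ("leq", "lt"):
        raise ValidationError(f"unknown tie_rule {tie_rule!r}")
    won = rtd <= threshold if tie_rule == "leq" else rtd < threshold
    return 1 if won else -1


@lru_cache(maxsize=256)
def _truncnorm_matching(mean: float, sd: float, lower: float):
    """Frozen truncated normal on [lower, inf) whose *post-truncation*
    mean and SD equal the requested values."""
    if sd == 0:
        if mean < lower:
            raise ValidationError("degenerate distribution below lower bound")
        return None  # caller treats None as a point mass at `mean`
    if mean <= lower:
        raise ValidationError("target mean must exceed the lower bound")

    def _moments(p):
        loc, log_scale = p
        scale = math.exp(log_scale)
        a = (lower - loc) / scale
        m, v = truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.fsolve(_moments, x0=[mean, math.log(sd)], full_output=False)
    loc, scale = float(sol[0]), math.exp(float(sol[1]))
    a = (lower - loc) / scale
    return truncnorm(a, np.inf, loc=loc, scale=scale)


def draw_dyad_effects(
    strategy: StrategyKind | str,
    params: StrategyParams,
    rng: np.random.Generator,
) -> DyadEffects:
    """Draw the latent dyad-level quantities for one dyad.

    For the delayed mode the dyad mean RT decomposes into a fast base
    component plus a shared intended delay carrying most of the
    between-dyad spread; for the other modes it is drawn directly.
    """
    strategy = StrategyKind.coerce(strategy)
    if strategy is StrategyKind.DELAYED and params.intended_delay_median:
        delay_med = params.intended_delay_median
        base_mean = params.dyad_mean_rt_mean - delay_med
        base_sd = min(0.06, params.dyad_mean_rt_sd)
        delay_sd = math.sqrt(max(params.dyad_mean_rt_sd**2 - base_sd**2, 0.0))
        base_dist = _truncnorm_matching(base_mean, base_sd, _MIN_RT_S)
        delay_dist = _truncnorm_matching(delay_med, delay_sd, 0.0)
        base = base_mean if base_dist is None else float(base_dist.ppf(rng.uniform()))
        delay = delay_med if delay_dist is None else float(delay_dist.ppf(rng.uniform()))
        mean_rt = base + delay
    else:
        dist = _truncnorm_matching(
            params.dyad_mean_rt_mean, params.dyad_mean_rt_sd, _MIN_RT_S
        )
        mean_rt = (
            params.dyad_mean_rt_mean
            if dist is None
            else float(dist.ppf(rng.uniform()))
        )

    mean_rt = min(mean_rt, _MAX_DYAD_MEAN_RT_S)
    tau = params.noise_heterogeneity
    noise_sd = params.trial_noise_sd * math.exp(tau * rng.standard_normal() - tau**2 / 2)
    lapse = max(
        float(rng.normal(params.lapse_offset_mean, 0.25 * params.lapse_offset_mean)),
        0.02,
    )
    return DyadEffects(mean_rt=mean_rt, trial_noise_sd=noise_sd, lapse_offset=lapse)


def draw_trial_rts(
    strategy: StrategyKind | str,
    params: StrategyParams,
    dyad_effects: DyadEffects,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw one trial's (rt1, rt2), clipped to ``(0, timeout]``.

    The within-trial correlation of partner RTs equals
    ``within_dyad_coupling``; with probability ``inconsistency_rate`` one
    randomly chosen partner responds late by the dyad's lapse offset.  The
    expected lapse inflation is subtracted from the trial mean so the
    dyad-level mean RT stays at ``dyad_effects.mean_rt``.
    """
    StrategyKind.coerce(strategy)
    rho = params.within_dyad_coupling
    sigma = dyad_effects.trial_noise_sd
    q = params.inconsistency_rate
    mu = dyad_effects.mean_rt - q * dyad_effects.lapse_offset / 2.0

    shared = rng.standard_normal()
    idio = rng.standard_normal(2)
    noise = sigma * (math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * idio)
    rt = mu + noise
    if q > 0 and rng.uniform() < q:
        rt[rng.integers(2)] += dyad_effects.lapse_offset
    rt = np.clip(rt, _MIN_RT_S, params.timeout)
    return float(rt[0]), float(rt[1])


def simulate_session(
    dyad_id: str,
    strategy: StrategyKind | str,
    params: StrategyParams | None = None,
    seed: int | np.random.Generator = 0,
    tie_rule: str = "leq",
    n_blocks: int = constants.N_BLOCKS,
    trials_per_block: int = constants.TRIALS_PER_BLOCK,
) -> DyadSession:
    """Simulate one dyad's full session (``n_blocks`` x ``trials_per_block``
    trials), deterministic for a given seed."""
    strategy = StrategyKind.coerce(strategy)
    if params is None:
        params = default_params(strategy)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    effects = draw_dyad_effects(strategy, params, rng)

    lo, hi = constants.CUE_DELAY_RANGE_S
    trials: list[TrialRecord] = []
    trajectory: list[int] = []
    score = 0
    for block in range(1, n_blocks + 1):
        for idx in range(1, trials_per_block + 1):
            cue = float(rng.uniform(lo, hi))
            rt1, rt2 = draw_trial_rts(strategy, params, effects, rng)
            thr = compute_threshold(rt1, rt2)
            rtd = abs(rt1 - rt2)
            outcome = score_trial(rtd, thr, tie_rule=tie_rule)
            score += outcome
            trials.append(
                TrialRecord(
                    block_index=block,
                    trial_index=idx,
                    cue_delay=cue,
                    rt1=rt1,
                    rt2=rt2,
                    threshold=thr,
                    rtd=rtd,
                    outcome=outcome,
                )
            )
            trajectory.append(score)
    return DyadSession(
        dyad_id=dyad_id, strategy=strategy, trials=trials, score_trajectory=trajectory
    )


def summarize_behavior(session: DyadSession) -> BehavioralSummary:
    """Session-level metrics: WR, mean RT, mean RTD, mean threshold, CC."""
    if not session.trials:
        raise ValidationError("cannot summarize an empty session")
    rts = np.array([[t.rt1, t.rt2] for t in session.trials])
    rtds = np.array([t.rtd for t in session.trials])
    thrs = np.array([t.threshold for t in session.trials])
    wins = sum(1 for t in session.trials if t.outcome == 1)
    mean_rtd = float(rtds.mean())
    mean_thr = float(thrs.mean())
    return BehavioralSummary(
        wr=wins / len(session.trials),
        mean_rt=float(rts.mean()),
        mean_rtd=mean_rtd,
        mean_threshold=mean_thr,
        cc=mean_thr - mean_rtd,
    )


def simulate_cohort(
    group_sizes: Mapping[StrategyKind | str, int] | None = None,
    params: Mapping[StrategyKind | str, StrategyParams] | None = None,
    seed: int = 0,
    tie_rule: str = "leq",
) -> list[DyadSession]:
    """Simulate a cohort of dyads with per-dyad substreams derived from a
    single master seed.  Default composition is 17 delayed / 16 immediate /
    10 no-strategy dyads."""
    if group_sizes is None:
        group_sizes = dict(constants.DEFAULT_GROUP_SIZES)
    sizes = {StrategyKind.coerce(k): int(v) for k, v in group_sizes.items()}
    if any(v < 0 for v in sizes.values()):
        raise ValidationError("group sizes must be nonnegative")
    param_map: dict[StrategyKind, StrategyParams] = {}
    for strat in sizes:
        if params is not None and any(
            StrategyKind.coerce(k) is strat for k in params
        ):
            key = next(k for k in params if StrategyKind.coerce(k) is strat)
            param_map[strat] = params[key]
        else:
            param_map[strat] = default_params(strat)

    master = np.random.SeedSequence(seed)
    children = master.spawn(sum(sizes.values()))
    sessions: list[DyadSession] = []
    i = 0
    for strat in (StrategyKind.DELAYED, StrategyKind.IMMEDIATE, StrategyKind.NONE):
        for j in range(sizes.get(strat, 0)):
            rng = np.random.default_rng(children[i])
            sessions.append(
                simulate_session(
                    dyad_id=f"dyad{i + 1:03d}",
                    strategy=strat,
                    params=param_map[strat],
                    seed=rng,
                    tie_rule=tie_rule,
                )
            )
            i += 1
    return sessions


def trials_to_frame(sessions: Sequence[DyadSession]) -> pd.DataFrame:
    """One row per trial across the cohort (TSV-ready)."""
    rows = []
    for s in sessions:
        cum = 0
        for t in s.trials:
            cum += t.outcome
            rows.append(
                {
                    "dyad_id": s.dyad_id,
                    "strategy": s.strategy.value,
                    "block": t.block_index,
                    "trial": t.trial_index,
                    "cue_delay_s": t.cue_delay,
                    "rt1_s": t.rt1,
                    "rt2_s": t.rt2,
                    "threshold_s": t.threshold,
                    "rtd_s": t.rtd,
                    "outcome": t.outcome,
                    "cum_score": cum,
                }
            )
    return pd.DataFrame(rows)


def sessions_from_frame(df: pd.DataFrame) -> list[DyadSession]:
    """Rebuild :class:`DyadSession` objects from a trials table produced by
    :func:`trials_to_frame`."""
    required = {"dyad_id", "strategy", "block", "trial", "cue_delay_s", "rt1_s", "rt2_s", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"trials table missing columns: {sorted(missing)}")
    sessions = []
    for dyad_id, grp in df.groupby("dyad_id", sort=False):
        grp = grp.sort_values(["block", "trial"], kind="stable")
        trials = []
        trajectory = []
        score = 0
        for _, row in grp.iterrows():
            thr = compute_threshold(row["rt1_s"], row["rt2_s"])
            score += int(row["outcome"])
            trials.append(
                TrialRecord(
                    block_index=int(row["block"]),
                    trial_index=int(row["trial"]),
                    cue_delay=float(row["cue_delay_s"]),
                    rt1=float(row["rt1_s"]),
                    rt2=float(row["rt2_s"]),
                    threshold=thr,
                    rtd=abs(float(row["rt1_s"]) - float(row["rt2_s"])),
                    outcome=int(row["outcome"]),
                )
            )
            trajectory.append(score)
        sessions.append(
            DyadSession(
                dyad_id=str(dyad_id),
                strategy=StrategyKind.coerce(grp["strategy"].iloc[0]),
                trials=trials,
                score_trajectory=trajectory,
            )
        )
    return sessions


def summaries_to_frame(sessions: Sequence[DyadSession]) -> pd.DataFrame:
    """One row per dyad with the behavioral summary metrics."""
    rows = []
    for s in sessions:
        summ = summarize_behavior(s)
        rows.append(
            {
                "dyad_id": s.dyad_id,
                "strategy": s.strategy.value,
                "wr": summ.wr,
                "mean_rt_s": summ.mean_rt,
                "mean_rtd_s": summ.mean_rtd,
                "mean_threshold_s": summ.mean_threshold,
                "cc_s": summ.cc,
            }
        )
    return pd.DataFrame(rows)
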