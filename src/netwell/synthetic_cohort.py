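"""Synthetic cohort simulator.

Generates communication logs, wearable streams and ordinal survey labels with
the statistical structure the downstream analysis assumes, so every stage is
testable without access to a real study cohort:

* heavy-tailed individual activity — per-person sociability (contact rate) and
  fitness (daily step scale) are lognormal;
* a shared smooth weekly factor ``S_w`` (sinusoids plus drift, scaled to
  [-1, 1]) multiplies both the pair communication rates and daily physical
  activity by ``(1 + coupling_rho * S_w)``, planting the cohort-level
  cross-correlations between network structure and behavior;
* ordinal wellness labels are drawn from a latent-threshold (cumulative)
  model: latent = beta_behavior * z(fitness) + beta_network * z(sociability)
  + noise, cut at quantiles matching realistic Likert level frequencies.

Everything is deterministic given the config seed; independent named
substreams keep the communication, wearable and label draws decoupled.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    ACTIVITY_STATES,
    Channel,
    CommEvent,
    MinuteRecord,
    StudyConfig,
    SurveyRecord,
    ValidationError,
    WELLNESS_ATTRIBUTES,
)

#: Ordinal level frequencies used to place the latent-model cutpoints, chosen
#: to resemble a college cohort's Likert response profile (most mass on the
#: middle levels, thin extremes).
DEFAULT_LEVEL_WEIGHTS: dict[str, tuple[float, ...]] = {
    "stress": (14, 95, 134, 82),
    "happiness": (40, 84, 144, 57),
    "positive_attitude": (2, 23, 65, 160, 75),
    "health": (7, 56, 200, 62),
}

#: Mean heart-rate increment (bpm) of each activity state over resting.
STATE_HR_INCREMENT = {"sedentary": 0.0, "lightly": 10.0, "fairly": 25.0, "very": 45.0}

#: Baseline daily time-budget weights of the four activity states.
STATE_BASE_WEIGHTS = np.array([0.70, 0.20, 0.06, 0.04])


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study.

    Defaults are sized so the full pipeline (simulate through prediction) runs
    in well under two minutes on a single core; ``n_participants=325`` mimics
    the scale of a full semester-long cohort.
    """

    n_participants: int = 60
    n_external: int = 120
    n_weeks: int = 22
    coupling_rho: float = 0.9
    label_beta_behavior: float = 1.0
    label_beta_network: float = 1.0
    noise_sd: float = 1.0
    seed: int = 7
    study_start: dt.date = dt.date(2016, 8, 15)
    #: fraction of participant-days generated with fewer worn minutes than the
    #: wear threshold, to exercise the wear filter
    low_wear_frac: float = 0.10
    #: mean weekly communication events per unit sociability product
    comm_rate: float = 8.0
    base_steps: float = 8000.0
    hr_baseline_mean: float = 70.0
    hr_baseline_sd: float = 4.0
    #: minute heart-rate noise is ``hr_noise_scale * noise_sd`` bpm
    hr_noise_scale: float = 5.0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_external + 1, self.n_weeks) < 1:
            raise ValidationError("counts must be positive")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValidationError("coupling_rho must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            study_start=self.study_start,
            n_weeks=self.n_weeks,
            roster=frozenset(participant_ids(self.n_participants)),
            seed=self.seed,
        )


@dataclasses.dataclass(frozen=True)
class LatentProfile:
    participant: str
    sociability: float  # mean contact-rate multiplier, > 0
    fitness: float  # daily step-scale multiplier, > 0
    gender: str
    wellness_latent: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sociability <= 0 or self.fitness <= 0:
            raise ValidationError("sociability and fitness must be positive")


def participant_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def external_ids(n: int) -> list[str]:
    return [f"X{i:04d}" for i in range(n)]


def _rngs(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    """Named substreams so each generator is reproducible in isolation."""
    seq = np.random.SeedSequence(config.seed)
    names = ("cohort", "comm", "wear", "minutes")
    return {n: np.random.default_rng(s) for n, s in zip(names, seq.spawn(len(names)))}


def weekly_factor(n_weeks: int) -> np.ndarray:
    """Shared smooth weekly factor S_w, scaled to max |S_w| = 1.

    Two sinusoids plus a linear drift: the minimal low-frequency structure
    that makes 22-point weekly mean series co-vary the way semester-long
    activity trends do.
    """
    t = np.arange(n_weeks) / max(n_weeks - 1, 1)
    raw = np.sin(2 * np.pi * t) + 0.6 * np.sin(4 * np.pi * t + 1.3) + 0.8 * (t - 0.5)
    return raw / np.max(np.abs(raw))


# ---------------------------------------------------------------------------
# cohort & labels
# ---------------------------------------------------------------------------

def _cutpoints(weights: Sequence[float], scale: float) -> np.ndarray:
    p = np.asarray(weights, dtype=float)
    cum = np.cumsum(p / p.sum())[:-1]
    return scale * stats.norm.ppf(cum)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[LatentProfile], list[SurveyRecord]]:
    """Draw latent profiles and threshold their latent wellness into labels.

    The latent wellness score for each attribute is
    ``beta_behavior * z_fit + beta_network * z_soc + noise_sd * eps`` where
    ``z_fit``/``z_soc`` are the standard-normal scores behind the lognormal
    fitness/sociability draws; cutpoints are placed at the normal quantiles of
    the default level frequencies so marginal label distributions look like a
    real cohort regardless of the effect sizes.
    """
    rng = _rngs(config)["cohort"]
    n = config.n_participants
    z_soc = rng.standard_normal(n)
    z_fit = rng.standard_normal(n)
    sociability = np.exp(0.6 * z_soc)
    fitness = np.exp(0.4 * z_fit)
    genders = np.where(rng.random(n) < 0.45, "male", "female")

    scale = math.sqrt(
        config.label_beta_behavior**2 + config.label_beta_network**2 + config.noise_sd**2
    )
    latents: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for attr in WELLNESS_ATTRIBUTES:
        eps = rng.standard_normal(n)
        latent = (
            config.label_beta_behavior * z_fit
            + config.label_beta_network * z_soc
            + config.noise_sd * eps
        )
        cuts = _cutpoints(DEFAULT_LEVEL_WEIGHTS[attr], scale if scale > 0 else 1.0)
        labels[attr] = 1 + np.searchsorted(cuts, latent)
        latents[attr] = latent

    ids = participant_ids(n)
    profiles = [
        LatentProfile(
            participant=ids[i],
            sociability=float(sociability[i]),
            fitness=float(fitness[i]),
            gender=str(genders[i]),
            wellness_latent={a: float(latents[a][i]) for a in WELLNESS_ATTRIBUTES},
        )
        for i in range(n)
    ]
    surveys = [
        SurveyRecord(
            participant=ids[i],
            gender=str(genders[i]),
            **{a: int(labels[a][i]) for a in WELLNESS_ATTRIBUTES},
        )
        for i in range(n)
    ]
    return profiles, surveys


# ---------------------------------------------------------------------------
# communication log
# ---------------------------------------------------------------------------

def generate_comm_log(
    profiles: Sequence[LatentProfile], config: GeneratorConfig
) -> list[CommEvent]:
    """Poisson pair-event log over participants and external contacts.

    Weekly event counts for pair (i, j) are Poisson with rate
    ``comm_rate * s_i * s_j / n_nodes * (1 + coupling_rho * S_w)``; external
    contacts draw their sociability from the same lognormal.  Many pairs end
    up with total counts below the spurious-edge threshold, by design.
    """
    rng = _rngs(config)["comm"]
    s_part = np.array([p.sociability for p in profiles])
    s_ext = np.exp(0.6 * rng.standard_normal(config.n_external))
    s = np.concatenate([s_part, s_ext])
    ids = [p.participant for p in profiles] + external_ids(config.n_external)
    n_nodes = len(ids)
    iu, ju = np.triu_indices(n_nodes, k=1)
    base_rate = config.comm_rate * s[iu] * s[ju] / n_nodes
    s_w = weekly_factor(config.n_weeks)

    events: list[CommEvent] = []
    start = dt.datetime.combine(config.study_start, dt.time())
    for w in range(config.n_weeks):
        lam = base_rate * (1.0 + config.coupling_rho * s_w[w])
        counts = rng.poisson(lam)
        nz = np.nonzero(counts)[0]
        if nz.size == 0:
            continue
        pair_idx = np.repeat(nz, counts[nz])
        minutes = rng.integers(0, 7 * 1440, size=pair_idx.size)
        flip = rng.random(pair_idx.size) < 0.5
        is_call = rng.random(pair_idx.size) < 0.3
        durations = np.round(rng.exponential(180.0, size=pair_idx.size), 1)
        answered = rng.random(pair_idx.size) < 0.85
        order = np.argsort(minutes, kind="stable")
        for k in order:
            p = pair_idx[k]
            a, b = ids[iu[p]], ids[ju[p]]
            if flip[k]:
                a, b = b, a
            ts = start + dt.timedelta(days=7 * w, minutes=int(minutes[k]))
            if is_call[k]:
                events.append(
                    CommEvent(ts, a, b, Channel.call, float(durations[k]), bool(answered[k]))
                )
            else:
                events.append(CommEvent(ts, a, b, Channel.text))
    return events


# ---------------------------------------------------------------------------
# wearable stream
# ---------------------------------------------------------------------------

def _state_weights(z_fit: float, rho_sw: float) -> np.ndarray:
    """Daily state time-budget: very/fairly-active share rises with fitness
    and the shared weekly factor."""
    w = STATE_BASE_WEIGHTS.copy()
    w[2] *= math.exp(0.2 * z_fit + 0.3 * rho_sw)
    w[3] *= math.exp(0.4 * z_fit + 0.6 * rho_sw)
    return w / w.sum()


def generate_daily_table(
    profiles: Sequence[LatentProfile], config: GeneratorConfig
) -> pd.DataFrame:
    """Per participant-day aggregates of the minute-level wearable model.

    Draws exactly the minute-level quantities (state multinomial, minute
    heart-rate normals) and aggregates them on the fly, so the default-sized
    study never materialises ~13M minute rows.  Columns match
    :class:`netwell.behavior_features.DayAggregate`.
    """
    rngs = _rngs(config)
    rng = rngs["wear"]
    s_w = weekly_factor(config.n_weeks)
    n_days = 7 * config.n_weeks
    incr = np.array([STATE_HR_INCREMENT[s] for s in ACTIVITY_STATES])

    rows = []
    for prof in profiles:
        z_fit = math.log(prof.fitness) / 0.4
        baseline = config.hr_baseline_mean + config.hr_baseline_sd * rng.standard_normal()
        low = rng.random(n_days) < config.low_wear_frac
        short = rng.integers(300, 1140, size=n_days)
        worn = np.where(low, short, 1440)
        step_noise = np.exp(0.25 * rng.standard_normal(n_days))
        for d in range(n_days):
            week = d // 7
            rho_sw = config.coupling_rho * s_w[week]
            wmin = int(worn[d])
            state_min = rng.multinomial(wmin, _state_weights(z_fit, rho_sw))
            noise = config.hr_noise_scale * config.noise_sd * rng.standard_normal(wmin)
            mu = baseline + np.repeat(incr, state_min)
            hr = mu + noise
            steps = int(
                round(config.base_steps * prof.fitness * (1.0 + rho_sw) * step_noise[d])
            )
            rows.append(
                {
                    "participant": prof.participant,
                    "date": config.study_start + dt.timedelta(days=d),
                    "week": week,
                    "worn_minutes": wmin,
                    "daily_steps": steps,
                    "sedentary": int(state_min[0]),
                    "lightly": int(state_min[1]),
                    "fairly": int(state_min[2]),
                    "very": int(state_min[3]),
                    "hr_sum": float(hr.sum()),
                    "hr_sumsq": float((hr * hr).sum()),
                    "hr_count": wmin,
                }
            )
    return pd.DataFrame(rows)


def generate_wearable_stream(
    profiles: Sequence[LatentProfile], config: GeneratorConfig
) -> list[MinuteRecord]:
    """Full minute-level stream (worn minutes only; non-wear minutes are
    simply absent, as on a device export).

    Intended for small configs and format round-trips; large studies should
    use :func:`generate_daily_table`, which draws from the same model.
    """
    rngs = _rngs(config)
    rng = rngs["wear"]
    alloc = rngs["minutes"]  # minute-layout draws only; keeps `wear` stream aligned
    s_w = weekly_factor(config.n_weeks)
    n_days = 7 * config.n_weeks
    incr = np.array([STATE_HR_INCREMENT[s] for s in ACTIVITY_STATES])

    records: list[MinuteRecord] = []
    for prof in profiles:
        z_fit = math.log(prof.fitness) / 0.4
        baseline = config.hr_baseline_mean + config.hr_baseline_sd * rng.standard_normal()
        low = rng.random(n_days) < config.low_wear_frac
        short = rng.integers(300, 1140, size=n_days)
        worn = np.where(low, short, 1440)
        step_noise = np.exp(0.25 * rng.standard_normal(n_days))
        for d in range(n_days):
            week = d // 7
            rho_sw = config.coupling_rho * s_w[week]
            wmin = int(worn[d])
            state_min = rng.multinomial(wmin, _state_weights(z_fit, rho_sw))
            noise = config.hr_noise_scale * config.noise_sd * rng.standard_normal(wmin)
            states = np.repeat(np.arange(4), state_min)
            hr = baseline + incr[states] + noise
            hr = np.maximum(hr, 30.0)  # physiological floor; keeps hr > 0
            steps_total = int(
                round(config.base_steps * prof.fitness * (1.0 + rho_sw) * step_noise[d])
            )
            # lay the day out: shuffle state order, spread steps over active minutes
            perm = alloc.permutation(wmin)
            states = states[perm]
            hr = hr[perm]
            active = states > 0
            steps = np.zeros(wmin, dtype=int)
            if steps_total > 0:
                weights = np.where(active, 1.0, 0.05)
                steps = alloc.multinomial(steps_total, weights / weights.sum())
            day0 = dt.datetime.combine(
                config.study_start + dt.timedelta(days=d), dt.time()
            )
            for m in range(wmin):
                records.append(
                    MinuteRecord(
                        participant=prof.participant,
                        timestamp=day0 + dt.timedelta(minutes=m),
                        heart_rate=float(round(hr[m], 2)),
                        steps=int(steps[m]),
                        state=ACTIVITY_STATES[int(states[m])],
                    )
                )
    return records


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

def generate_study(config: GeneratorConfig):
    """Generate the whole synthetic study: profiles, surveys, events, daily table."""
    profiles, surveys = generate_cohort(config)
    events = generate_comm_log(profiles, config)
    daily = generate_daily_table(profiles, config)
    return profiles, surveys, events, daily


def write_ground_truth(
    profiles: Sequence[LatentProfile], config: GeneratorConfig, path
) -> None:
    """Ground-truth JSON (profiles, S_w, config) for recovery tests."""
    payload = {
        "config": {
            k: (v.isoformat() if isinstance(v, dt.date) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "weekly_factor": weekly_factor(config.n_weeks).tolist(),
        "profiles": [dataclasses.asdict(p) for p in profiles],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
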