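"""Synthetic transport-episode simulator.

The real cohort (NHS critical-care transport records) is private, so this
module generates stand-in episodes with the same schema: age-dependent
physiological baselines, mean-reverting (discrete Ornstein-Uhlenbeck)
autocorrelated noise, channel-specific cadences and missingness — including
informative missingness of invasive pressures (arterial line) and EtCO2
(invasive ventilation) — and injected deterioration events preceded by
learnable linear precursor drifts. All distributional choices are stand-ins
documented in docs/methods.md; none are estimates of the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .reference import channel_baseline
from .schema import (
    CARE_AREAS,
    CHANNEL_INDEX,
    CHANNEL_NAMES,
    COMORBIDITY_SYSTEMS,
    CV_SUPPORT_AGENTS,
    DIAGNOSIS_CATEGORIES,
    ETHNICITY_CODES,
    PRE_TRANSPORT_INTERVENTIONS,
    RESP_SUPPORT_CATEGORIES,
    Episode,
    EpisodeMetadata,
    EpisodeTimeSeries,
    EventInterval,
)


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


#: Default per-family event effect magnitudes, in reference-SD units.
DEFAULT_EFFECT_SIZES = {
    "spo2": 1.2,  # x6 %  -> ~7 % desaturation depth
    "etco2": 1.5,  # x1.5 kPa
    "rr": 2.0,
    "hr": 2.5,
    "bp": 2.5,
}

#: Default random-dropout probability per channel (chance that any given
#: 60-s span starts a sensor dropout), on top of informative missingness.
DEFAULT_DROPOUT = {name: 0.004 for name in CHANNEL_NAMES}

_INVASIVE_SUPPORT = ("ett", "tracheostomy", "other_airway")

# Cohort composition targets (age-band, diagnosis, PIM3-band, respiratory and
# cardiovascular support frequencies) mirroring the structure of a specialist
# paediatric transport population: neonates over-represented, most patients
# invasively ventilated, ~1/3 on vasoactive support.
_AGE_BANDS = [(0.0, 0.083), (0.083, 1.0), (1.0, 4.0), (4.0, 11.0), (11.0, 18.0)]
_AGE_BAND_P = [0.374, 0.195, 0.174, 0.157, 0.100]
_DIAG_P = {
    "respiratory": 0.328,
    "cardiovascular": 0.240,
    "neurological": 0.149,
    "infection": 0.133,
    "gastroenterology": 0.059,
    "metabolic": 0.028,
    "trauma": 0.014,
    "other": 0.049,
}
_PIM3_BANDS = [(0.0, 0.01), (0.01, 0.03), (0.03, 0.05), (0.05, 0.10),
               (0.10, 0.15), (0.15, 0.30), (0.30, 0.60)]
_PIM3_BAND_P = [0.061, 0.336, 0.341, 0.174, 0.039, 0.030, 0.020]
_RESP_SUPPORT_P = {
    "room_air": 0.169, "supplemental_o2": 0.018, "hfnc": 0.041, "cpap": 0.036,
    "bipap": 0.008, "ett": 0.706, "tracheostomy": 0.013, "other_airway": 0.002,
}
_CV_AGENT_P = {
    "adrenaline": 0.131, "noradrenaline": 0.086, "dobutamine": 0.006,
    "dopamine": 0.090, "milrinone": 0.008, "prostaglandin": 0.03,
    "nitric_oxide": 0.04,
}
_DIAG_TEXT = {
    "respiratory": ["bronchiolitis with respiratory failure", "severe asthma",
                    "pneumonia requiring ventilation"],
    "cardiovascular": ["congenital heart disease post arrest",
                       "myocarditis with shock", "duct dependent lesion"],
    "neurological": ["status epilepticus", "traumatic brain injury",
                     "encephalitis"],
    "infection": ["septic shock", "meningococcal sepsis"],
    "gastroenterology": ["gastrointestinal bleed", "volvulus post laparotomy"],
    "metabolic": ["diabetic ketoacidosis", "inborn error decompensation"],
    "trauma": ["polytrauma road traffic collision"],
    "other": ["post operative airway watch", "unclassified instability"],
}


@dataclass
class SimulationConfig:
    """Study conditions for cohort generation.

    ``duration_minutes_lognormal`` is (median, sigma); the default median of
    113 minutes with sigma 0.56 matches an interquartile range of roughly
    75-160 minutes. ``event_rates`` are baseline expected events/hour per
    kind before acuity scaling. ``arterial_line_prob`` controls informative
    missingness of the invasive-pressure channels.
    """

    n_episodes: int = 100
    duration_minutes_lognormal: tuple[float, float] = (113.0, 0.56)
    input_hz: float = 1.0
    event_rates: dict = field(
        default_factory=lambda: {"respiratory": 0.15, "cardiovascular": 0.20}
    )
    precursor_lead_s: tuple[int, int] = (600, 900)
    event_duration_s: tuple[int, int] = (120, 300)
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    dropout_prob: dict = field(default_factory=lambda: dict(DEFAULT_DROPOUT))
    arterial_line_prob: float = 0.36
    min_duration_minutes: float = 35.0
    max_duration_minutes: float = 360.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_episodes < 1:
            raise ConfigError("n_episodes: must be >= 1")
        if not (0.0 <= self.arterial_line_prob <= 1.0):
            raise ConfigError("arterial_line_prob: must be a probability in [0, 1]")
        for name, p in self.dropout_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"dropout_prob[{name}]: must be in [0, 1]")
        if self.min_duration_minutes < 30:
            raise ConfigError(
                "min_duration_minutes: must be >= 30 so episodes are eligible"
            )
        if self.duration_minutes_lognormal[0] < 30:
            raise ConfigError("duration_minutes_lognormal: median must be >= 30 min")
        if not (0 < self.input_hz <= 1):
            raise ConfigError("input_hz: must be in (0, 1]")
        for kind in ("respiratory", "cardiovascular"):
            if self.event_rates.get(kind, 0) < 0:
                raise ConfigError(f"event_rates[{kind}]: must be >= 0")


@dataclass
class GroundTruth:
    """Injected events and the latent risk trajectory that placed them."""

    episode_id: str
    events: list[EventInterval]
    risk_per_hour: dict


def _norm(ps):
    a = np.asarray(ps, dtype=float)
    return a / a.sum()


def _sample_metadata(i: int, rng: np.random.Generator) -> EpisodeMetadata:
    band = _AGE_BANDS[rng.choice(len(_AGE_BANDS), p=_norm(_AGE_BAND_P))]
    age = float(rng.uniform(*band))
    # weight loosely tracks age (3.5 kg newborn -> ~60 kg adolescent)
    weight = float(np.clip(3.5 + age * 3.0 + rng.normal(0, 2.0), 1.0, 90.0))
    pim_band = _PIM3_BANDS[rng.choice(len(_PIM3_BANDS), p=_norm(_PIM3_BAND_P))]
    pim3 = float(rng.uniform(*pim_band))
    dx = str(rng.choice(list(_DIAG_P), p=_norm(list(_DIAG_P.values()))))
    resp = str(
        rng.choice(list(_RESP_SUPPORT_P), p=_norm(list(_RESP_SUPPORT_P.values())))
    )
    cv = {a: bool(rng.random() < p) for a, p in _CV_AGENT_P.items()}
    comorb = {s: bool(rng.random() < 0.12) for s in COMORBIDITY_SYSTEMS}
    interventions = {
        n: bool(rng.random() < 0.15) for n in PRE_TRANSPORT_INTERVENTIONS
    }
    ethnicity = (
        None if rng.random() < 0.5 else str(rng.choice(list(ETHNICITY_CODES)))
    )
    return EpisodeMetadata(
        episode_id=f"ep{i:05d}",
        age_years=age,
        weight_kg=weight,
        sex=str(rng.choice(["male", "female"], p=[0.543, 0.457])),
        ethnicity=ethnicity,
        pim3=pim3 if rng.random() > 0.003 else None,
        diagnosis_text=str(rng.choice(_DIAG_TEXT[dx])),
        diagnosis_category=dx,
        comorbidity_flags=comorb,
        pre_transport_interventions=interventions,
        resp_support=resp,
        cv_support=cv,
        referring_hospital=f"H{int(rng.integers(1, 25)):02d}",
        destination_hospital=f"D{int(rng.integers(1, 6)):02d}",
        destination_care_area=str(
            rng.choice(list(CARE_AREAS), p=[0.75, 0.12, 0.08, 0.04, 0.01])
        ),
        team_arrival_time=f"{int(rng.integers(0, 24)):02d}:{int(rng.integers(0, 60)):02d}",
    )


def _ou_series(
    n: int, level: float, sd: float, rng: np.random.Generator, tau_s: float = 300.0
) -> np.ndarray:
    """Discrete Ornstein-Uhlenbeck path of length n around ``level``.

    Stationary standard deviation ~= 0.35 * sd (within-patient variability),
    plus a per-episode offset of ~0.5 * sd (between-patient variability) and a
    slow sinusoidal drift so exponentially weighted bands stay non-degenerate.
    """
    theta = 1.0 / tau_s
    stat_sd = 0.35 * sd
    noise_sd = stat_sd * np.sqrt(2 * theta - theta * theta)
    eps = rng.normal(0.0, noise_sd, size=n)
    x0 = rng.normal(0.0, stat_sd)
    # AR(1): x_t = (1-theta) x_{t-1} + eps_t, seeded with x0
    x = lfilter([1.0], [1.0, -(1.0 - theta)], eps)
    x += x0 * (1.0 - theta) ** np.arange(1, n + 1)
    offset = rng.normal(0.0, 0.5 * sd)
    phase = rng.uniform(0, 2 * np.pi)
    period = rng.uniform(1200, 3600)
    drift = 0.2 * sd * np.sin(2 * np.pi * np.arange(n) / period + phase)
    return level + offset + x + drift


def _channel_presence(meta: EpisodeMetadata, rng, arterial_line_prob) -> dict:
    """Deterministic informative missingness: which channels exist at all."""
    arterial = bool(rng.random() < arterial_line_prob)
    invasive = meta.resp_support in _INVASIVE_SUPPORT
    present = {name: True for name in CHANNEL_NAMES}
    for name in ("ibp_sys", "ibp_mean", "ibp_dia"):
        present[name] = arterial
    for name in ("etco2_min", "etco2_max", "rr_airway"):
        present[name] = invasive
    present["temp_oesophageal"] = bool(rng.random() < 0.21)
    present["temp_skin"] = bool(rng.random() < 0.27)
    present["temp_core"] = bool(rng.random() < 0.14)
    present["temp_unspecified"] = bool(rng.random() < 0.36)
    return present


def generate_episode(
    meta: EpisodeMetadata,
    duration_s: int,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
) -> Episode:
    """Generate one episode (no events injected yet).

    Each channel is an age-dependent baseline from the shared reference tables
    plus mean-reverting autocorrelated noise and a slow drift. Non-invasive
    blood pressure is sampled every 180-300 s and absent between samples;
    temperature is sparse; random dropout spans follow the missingness config.
    """
    rng = np.random.default_rng(seed)
    n = duration_s + 1
    t = np.arange(n, dtype=np.int64)
    values = np.full((n, len(CHANNEL_NAMES)), np.nan)
    observed = np.zeros((n, len(CHANNEL_NAMES)), dtype=bool)
    present = _channel_presence(meta, rng, config.arterial_line_prob)

    nibp_interval = int(rng.integers(180, 301))
    for j, name in enumerate(CHANNEL_NAMES):
        if not present[name]:
            continue
        level, sd = channel_baseline(name, meta.age_years)
        path = _ou_series(n, level, sd, rng)
        if name == "spo2":
            path = np.minimum(path, 100.0)
        mask = np.zeros(n, dtype=bool)
        if name.startswith("nibp"):
            mask[::nibp_interval] = True
        elif name.startswith("temp"):
            mask[:: int(rng.integers(240, 361))] = True
        else:
            mask[:] = True  # native 1 Hz channels
        # random sensor-dropout spans
        p = config.dropout_prob.get(name, 0.0)
        if p > 0:
            starts = np.nonzero(rng.random(n // 60 + 1) < p)[0] * 60
            for s0 in starts:
                mask[s0 : s0 + int(rng.integers(30, 91))] = False
        values[mask, j] = path[mask]
        observed[mask, j] = True

    series = EpisodeTimeSeries(t, values, observed)
    return Episode(meta, series, [])


def _smooth_ramp(length: int, ramp: int = 20) -> np.ndarray:
    """0->1 over ``ramp`` samples, plateau at 1, short release."""
    prof = np.ones(length)
    r = min(ramp, max(length // 6, 1))
    prof[:r] = np.linspace(0.0, 1.0, r)
    prof[-r:] = np.minimum(prof[-r:], np.linspace(1.0, 0.3, r))
    return prof


def inject_event(
    episode: Episode,
    kind: str,
    start_s: int,
    duration_s: int,
    effect_sizes: dict | None = None,
    precursor_lead_s: int = 750,
    rng: np.random.Generator | None = None,
) -> EventInterval:
    """Inject one deterioration event in place; returns the exact interval.

    Respiratory: SpO2 pushed below 94 % with a concurrent respiratory-rate and
    EtCO2 excursion, preceded by a linear precursor drift (rising EtCO2,
    sagging SpO2) over ``precursor_lead_s``. Cardiovascular: concurrent
    heart-rate and blood-pressure excursions with a precursor tachycardia
    drift. Effects are added to the underlying signal wherever it is sampled;
    with all effect sizes zero the series is unchanged.
    """
    if duration_s < 60:
        raise ValueError("event duration must be >= 60 s")
    s = episode.series
    n = s.n_seconds
    if not (0 <= start_s and start_s + duration_s <= n):
        raise ValueError("event interval must lie inside the episode")
    for e in episode.events_of(kind, "injected"):
        if e.overlaps(start_s, start_s + duration_s):
            raise ValueError(
                f"interval [{start_s}, {start_s + duration_s}) overlaps an "
                f"existing injected {kind} event"
            )
    eff = dict(DEFAULT_EFFECT_SIZES)
    eff.update(effect_sizes or {})
    rng = rng or np.random.default_rng(start_s)
    age = episode.meta.age_years

    end_s = start_s + duration_s
    prof = _smooth_ramp(duration_s)
    lead0 = max(0, start_s - precursor_lead_s)
    pre = np.linspace(0.0, 1.0, start_s - lead0) if start_s > lead0 else np.zeros(0)

    def add(channel: str, delta_event: float, delta_pre: float = 0.0):
        j = CHANNEL_INDEX[channel]
        s.values[start_s:end_s, j] += delta_event * prof
        if delta_pre:
            if len(pre):
                s.values[lead0:start_s, j] += delta_pre * pre
            # the precursor level persists through the event itself
            s.values[start_s:end_s, j] += delta_pre

    if kind == "respiratory":
        spo2_drop = eff["spo2"] * 6.0
        add("spo2", -spo2_drop, -0.4 * 6.0 * min(eff["spo2"], 1.0))
        for ch in ("etco2_min", "etco2_max"):
            _, sd = channel_baseline(ch, age)
            add(ch, eff["etco2"] * 1.5, 0.8 * 1.5 * min(eff["etco2"], 1.0))
        for ch in ("rr_airway", "rr_impedance"):
            _, sd = channel_baseline(ch, age)
            add(ch, eff["rr"] * sd)
        # keep the floor physical
        j = CHANNEL_INDEX["spo2"]
        s.values[:, j] = np.clip(s.values[:, j], 40.0, 100.0)
    elif kind == "cardiovascular":
        _, hr_sd = channel_baseline("hr", age)
        add("hr", eff["hr"] * hr_sd, 0.8 * hr_sd * min(eff["hr"], 1.0))
        sign = -1.0  # hypotension with compensatory tachycardia
        for ch in ("nibp_sys", "nibp_mean", "nibp_dia",
                   "ibp_sys", "ibp_mean", "ibp_dia"):
            _, sd = channel_baseline(ch, age)
            add(ch, sign * eff["bp"] * sd)
        # cuff cycled more often around instability: extra NIBP samples so the
        # excursion is actually measured on episodes without an arterial line
        if eff["bp"] > 0:
            for ch in ("nibp_sys", "nibp_mean", "nibp_dia"):
                j = CHANNEL_INDEX[ch]
                if not s.observed[:, j].any():
                    continue
                extra = np.arange(max(0, lead0 - 60), end_s, 45)
                newly = extra[~s.observed[extra, j]]
                base_level, base_sd = channel_baseline(ch, age)
                fill = np.isnan(s.values[newly, j])
                s.values[newly[fill], j] = base_level + rng.normal(
                    0, 0.3 * base_sd, fill.sum()
                )
                # re-apply the event excursion at the new sample times
                in_ev = (newly >= start_s) & (newly < end_s)
                s.values[newly[in_ev & fill], j] += sign * eff["bp"] * base_sd
                s.observed[newly, j] = True
    else:
        raise ValueError(f"unknown event kind {kind!r}")

    interval = EventInterval(kind, start_s, end_s, "injected")
    episode.events.append(interval)
    return interval


def _risk_multiplier(meta: EpisodeMetadata) -> float:
    """Event-rate scaling: risk grows with PIM3 and with vasoactive support."""
    pim3 = meta.pim3 if meta.pim3 is not None else 0.04
    mult = 1.0 + 6.0 * pim3
    if any(meta.cv_support.values()):
        mult *= 1.5
    return mult


def _place_events(
    duration_s: int, rate_per_hour: float, cfg: SimulationConfig,
    existing: list[tuple[int, int]], rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Poisson placement of non-overlapping (start, duration) pairs."""
    lead_max = cfg.precursor_lead_s[1]
    lo = lead_max + 360  # room for precursor + pre-flank
    hi = duration_s - cfg.event_duration_s[1] - 360
    if hi <= lo:
        return []
    n_ev = rng.poisson(rate_per_hour * duration_s / 3600.0)
    placed: list[tuple[int, int]] = []
    for _ in range(n_ev):
        for _attempt in range(20):
            start = int(rng.integers(lo, hi))
            dur = int(rng.integers(*cfg.event_duration_s))
            # enforce clear separation so flanks stay clean
            ok = all(
                start + dur + 600 <= s0 or s0 + d0 + 600 <= start
                for s0, d0 in placed + existing
            )
            if ok:
                placed.append((start, dur))
                break
    return placed


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[Episode], dict[str, GroundTruth]]:
    """Generate a cohort of eligible episodes with injected ground truth.

    Reproducible given ``config.seed``. Event probability increases with PIM3
    and with cardiovascular support (learnable static signal); invasive
    pressures are present iff the arterial-line flag is drawn, EtCO2 iff
    invasively ventilated.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    episode_seeds = root.spawn(config.n_episodes)

    episodes: list[Episode] = []
    truths: dict[str, GroundTruth] = {}
    med, sigma = config.duration_minutes_lognormal
    for i in range(config.n_episodes):
        meta = _sample_metadata(i, meta_rng)
        dur_min = float(np.clip(
            np.exp(meta_rng.normal(np.log(med), sigma)),
            config.min_duration_minutes, config.max_duration_minutes,
        ))
        duration_s = int(round(dur_min * 60))
        ep_rng = np.random.default_rng(episode_seeds[i])
        ep = generate_episode(meta, duration_s, config, episode_seeds[i])

        mult = _risk_multiplier(meta)
        risk = {k: config.event_rates[k] * mult for k in config.event_rates}
        existing: list[tuple[int, int]] = []
        for kind in ("respiratory", "cardiovascular"):
            for start, dur in _place_events(
                duration_s, risk[kind], config, existing, ep_rng
            ):
                lead = int(ep_rng.integers(*config.precursor_lead_s))
                inject_event(
                    ep, kind, start, dur, config.effect_sizes, lead, ep_rng
                )
                existing.append((start, dur))
        truths[meta.episode_id] = GroundTruth(
            meta.episode_id, list(ep.events), risk
        )
        episodes.append(ep)
    return episodes, truths
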