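"""Dynamic-threshold (Bollinger-band) deterioration labelling.

Minute-mean vitals in native units are tracked with a recursive exponentially
weighted moving average (EMA) and standard deviation (EWMSTD), producing
patient-specific upper/lower thresholds ``ema +/- max(k * ewmstd, floor *
ema)``. The floor (5 % of the EMA generically, 2.5 % for SpO2) keeps bands
from collapsing during stable periods. Respiratory deterioration: SpO2 below
min(94 %, dynamic lower bound) with a concurrent abnormality in at least one
other respiratory parameter (either respiratory rate or EtCO2). Cardiovascular
deterioration: simultaneous heart-rate and blood-pressure deviations. Events
must persist >= 1 minute and be flanked by 5 minutes of continuous data in the
channels that triggered them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schema import CHANNEL_INDEX, CHANNEL_NAMES, Episode, EpisodeTimeSeries, EventInterval

#: Secondary respiratory parameters (any one abnormal qualifies).
RESP_SECONDARY = ("rr_impedance", "rr_airway", "etco2_min", "etco2_max")

TRUE, FALSE, INDET = np.int8(1), np.int8(0), np.int8(-1)


@dataclass(frozen=True)
class BandParams:
    """Labeller configuration (native units, minute grid)."""

    ema_halflife_minutes: float = 10.0
    band_multiplier: float = 2.0
    generic_floor: float = 0.05
    spo2_floor: float = 0.025
    spo2_fixed_threshold: float = 94.0
    min_event_s: int = 60
    flank_s: int = 300
    warmup_minutes: int = 10

    def __post_init__(self):
        if self.ema_halflife_minutes <= 0:
            raise ValueError("ema_halflife_minutes: must be positive")
        if self.band_multiplier <= 0:
            raise ValueError("band_multiplier: must be positive")
        for name in ("generic_floor", "spo2_floor"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name}: must be in (0, 1)")
        if self.min_event_s <= 0 or self.flank_s <= 0:
            raise ValueError("min_event_s and flank_s must be positive")

    @property
    def alpha(self) -> float:
        """Per-minute EMA decay weight derived from the halflife."""
        return 1.0 - 0.5 ** (1.0 / self.ema_halflife_minutes)


@dataclass
class BandState:
    """Per-channel, per-minute EMA/EWMSTD and band thresholds (NaN before the
    first observed minute)."""

    minute_mean: np.ndarray  # (n_minutes, n_channels)
    ema: np.ndarray
    ewmstd: np.ndarray
    upper: np.ndarray
    lower: np.ndarray


@dataclass
class DeviationFlags:
    """Per-minute tri-state flags: 1 deviating, 0 not, -1 indeterminate."""

    spo2_low: np.ndarray
    resp_secondary: dict[str, np.ndarray]
    hr_deviate: np.ndarray
    bp_deviate: np.ndarray
    bp_channel: str


def minute_aggregate(series: EpisodeTimeSeries) -> np.ndarray:
    """Per-channel minute means over observed samples only.

    Minute m covers seconds [60m, 60(m+1)); only complete minutes are kept; a
    minute with zero observed samples is NaN.
    """
    n_min = series.n_seconds // 60
    vals = series.values[: n_min * 60].reshape(n_min, 60, -1)
    obs = series.observed[: n_min * 60].reshape(n_min, 60, -1)
    cnt = obs.sum(axis=1)
    tot = np.where(obs, vals, 0.0)
    tot = np.nan_to_num(tot).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return out


def _floor_for(channel: str, params: BandParams) -> float:
    return params.spo2_floor if channel == "spo2" else params.generic_floor


def compute_bands(
    minute_series: np.ndarray,
    params: BandParams,
    channels: tuple[str, ...] | None = None,
) -> BandState:
    """Recursive EMA/EWMSTD bands per channel on the minute grid.

    The state initialises at the first non-missing minute (EMA = that mean,
    EWMSTD = 0) and updates as an adjust-free exponentially weighted mean m
    and mean-of-squares s (variance = s - m^2). Each minute is judged against
    the band derived from the *previous* state, and a minute falling outside
    that band contributes only its winsorised (band-edge-clipped) value to the
    update — the evolving baseline tracks genuine level shifts at a bounded
    rate without absorbing the short anomalies it is there to flag. Missing
    minutes freeze the state. Raw half-width ``k * ewmstd`` is floored at
    ``floor * ema`` (2.5 % of the EMA for SpO2, 5 % otherwise).

    ``upper``/``lower`` at minute i are the judging thresholds (prior state);
    ``ema``/``ewmstd`` at minute i are the post-update state, which always
    lies inside the judging band.
    """
    x = np.asarray(minute_series, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n_min, n_ch = x.shape
    if channels is None:
        channels = CHANNEL_NAMES[:n_ch] if n_ch == len(CHANNEL_NAMES) else ("",) * n_ch
    a = params.alpha
    k = params.band_multiplier
    ema = np.full_like(x, np.nan)
    std = np.full_like(x, np.nan)
    upper = np.full_like(x, np.nan)
    lower = np.full_like(x, np.nan)
    for j in range(n_ch):
        floor = _floor_for(channels[j], params)
        m = s = np.nan
        started = False
        for i in range(n_min):
            if started:
                prior_std = np.sqrt(max(s - m * m, 0.0))
                half = max(k * prior_std, floor * abs(m))
                upper[i, j] = m + half
                lower[i, j] = m - half
            xi = x[i, j]
            if np.isfinite(xi):
                if not started:
                    m, s, started = xi, xi * xi, True
                else:
                    xu = min(max(xi, lower[i, j]), upper[i, j])
                    m = (1 - a) * m + a * xu
                    s = (1 - a) * s + a * xu * xu
            if started:
                ema[i, j] = m
                std[i, j] = np.sqrt(max(s - m * m, 0.0))
    return BandState(x, ema, std, upper, lower)


def _tri_flag(
    mean: np.ndarray, lower: np.ndarray, upper: np.ndarray, warmup: int,
    mode: str = "outside", fixed_low: float | None = None,
) -> np.ndarray:
    """Tri-state deviation flags on the minute grid.

    ``outside``: deviating iff strictly outside [lower, upper].
    ``low``: deviating iff strictly below min(fixed_low, lower).
    Warmup minutes and minutes without a mean or band are indeterminate.
    """
    n = len(mean)
    flags = np.full(n, INDET, dtype=np.int8)
    defined = np.isfinite(mean) & np.isfinite(lower) & np.isfinite(upper)
    defined[: min(warmup, n)] = False
    with np.errstate(invalid="ignore"):
        if mode == "low":
            thr = np.minimum(fixed_low, lower)
            dev = mean < thr
        else:
            dev = (mean < lower) | (mean > upper)
    flags[defined] = np.where(dev[defined], TRUE, FALSE)
    return flags


def pick_bp_channel(series: EpisodeTimeSeries) -> str:
    """Authoritative pressure: invasive mean arterial if the episode has any
    invasive-pressure data, else non-invasive mean arterial."""
    if series.channel_observed("ibp_mean").any():
        return "ibp_mean"
    return "nibp_mean"


def flag_deviations(
    minute_series: np.ndarray, bands: BandState, params: BandParams,
    bp_channel: str = "nibp_mean",
) -> DeviationFlags:
    """Per-minute deviation flags for the channels the event rules consume."""
    w = params.warmup_minutes

    def ch(name):
        j = CHANNEL_INDEX[name]
        return minute_series[:, j], bands.lower[:, j], bands.upper[:, j]

    m, lo, up = ch("spo2")
    spo2_low = _tri_flag(m, lo, up, w, "low", params.spo2_fixed_threshold)
    secondary = {}
    for name in RESP_SECONDARY:
        m, lo, up = ch(name)
        secondary[name] = _tri_flag(m, lo, up, w)
    m, lo, up = ch("hr")
    hr = _tri_flag(m, lo, up, w)
    m, lo, up = ch(bp_channel)
    bp = _tri_flag(m, lo, up, w)
    return DeviationFlags(spo2_low, secondary, hr, bp, bp_channel)


def _runs(candidate: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open minute intervals [start, end)."""
    runs = []
    start = None
    for i, c in enumerate(candidate):
        if c and start is None:
            start = i
        elif not c and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(candidate)))
    return runs


def _flank_clean(
    minute_mean: np.ndarray, channels: list[str], start_m: int, end_m: int,
    flank_m: int,
) -> bool:
    """True iff the flank minutes before start and after end have no missing
    minute-mean in any triggering channel (flanks beyond the series fail)."""
    n = minute_mean.shape[0]
    pre = range(start_m - flank_m, start_m)
    post = range(end_m, end_m + flank_m)
    for m in list(pre) + list(post):
        if m < 0 or m >= n:
            return False
        for name in channels:
            if not np.isfinite(minute_mean[m, CHANNEL_INDEX[name]]):
                return False
    return True


def label_events(
    flags: DeviationFlags, bands: BandState, params: BandParams
) -> list[EventInterval]:
    """Turn minute flags into detected EventIntervals.

    Respiratory candidates: SpO2 low AND any secondary respiratory parameter
    abnormal. Cardiovascular candidates: heart rate AND blood pressure both
    deviating. Maximal candidate runs (>= 1 minute) become events; an event is
    kept only if the 5 minutes before and after are continuous in the channels
    that triggered it. Adjacent runs separated by a non-candidate minute stay
    separate.
    """
    flank_m = params.flank_s // 60
    events: list[EventInterval] = []

    sec_any = np.full_like(flags.spo2_low, FALSE)
    for arr in flags.resp_secondary.values():
        sec_any = np.maximum(sec_any, (arr == TRUE).astype(np.int8))
    resp_cand = (flags.spo2_low == TRUE) & (sec_any == TRUE)
    for start_m, end_m in _runs(resp_cand):
        fired = [
            name
            for name, arr in flags.resp_secondary.items()
            if (arr[start_m:end_m] == TRUE).any()
        ]
        # continuity is required in SpO2 and in at least one secondary
        # parameter that triggered the event
        ok = _flank_clean(bands.minute_mean, ["spo2"], start_m, end_m, flank_m) and any(
            _flank_clean(bands.minute_mean, [f], start_m, end_m, flank_m)
            for f in fired
        )
        if ok:
            events.append(
                EventInterval("respiratory", start_m * 60, end_m * 60, "detected")
            )

    cv_cand = (flags.hr_deviate == TRUE) & (flags.bp_deviate == TRUE)
    for start_m, end_m in _runs(cv_cand):
        trig = ["hr", flags.bp_channel]
        if _flank_clean(bands.minute_mean, trig, start_m, end_m, flank_m):
            events.append(
                EventInterval("cardiovascular", start_m * 60, end_m * 60, "detected")
            )
    return events


def label_episode(
    episode: Episode, params: BandParams | None = None
) -> dict[str, list[EventInterval]]:
    """Full labelling pass on a cleaned episode (native units).

    Deterministic composition: carry-forward of the sparse channels -> minute
    aggregation -> band computation ->
    deviation flags -> event extraction. Returns detected intervals by kind;
    they are also appended to ``episode.events``.
    """
    from .preprocess import carry_forward

    params = params or BandParams()
    series = carry_forward(episode.series)
    mm = minute_aggregate(series)
    bands = compute_bands(mm, params)
    bp_channel = pick_bp_channel(series)
    flags = flag_deviations(mm, bands, params, bp_channel)
    events = label_events(flags, bands, params)
    episode.events = [e for e in episode.events if e.source != "detected"] + events
    return {
        "respiratory": [e for e in events if e.kind == "respiratory"],
        "cardiovascular": [e for e in events if e.kind == "cardiovascular"],
    }


def recovery_rate(
    injected: list[EventInterval], detected: list[EventInterval],
    min_overlap: float = 0.5,
) -> float:
    """Fraction of injected events matched by a detected event of the same
    kind with interval overlap >= ``min_overlap`` of the injected duration."""
    if not injected:
        return float("nan")
    hit = 0
    for inj in injected:
        for det in detected:
            if det.kind != inj.kind:
                continue
            ov = min(inj.end_s, det.end_s) - max(inj.start_s, det.start_s)
            if ov >= min_overlap * inj.duration_s:
                hit += 1
                break
    return hit / len(injected)
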