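"""Independent straight-line reimplementations used as oracles.

These share no code with the package: explicit exponential reweighting of all
history for the band state, pandas forward-fill, and plain python run/flank
logic for the event rules.
"""

import itertools

import numpy as np
import pandas as pd

from pcct_ews.labelling import BandParams
from pcct_ews.schema import CHANNEL_INDEX, CHANNEL_NAMES


def oracle_band_channel(x, params: BandParams, channel: str):
    """Explicit-weight recomputation of the EW state at every minute.

    At minute t (counting only updates), the adjust-free recursion equals the
    reweighting m_t = (1-a)^t x_0 + sum_i a (1-a)^(t-i) x_i over the
    winsorised history; the judging band at each minute comes from the state
    before that minute's update.
    """
    a = 1.0 - 0.5 ** (1.0 / params.ema_halflife_minutes)
    k = params.band_multiplier
    floor = params.spo2_floor if channel == "spo2" else params.generic_floor
    accepted: list[float] = []

    def state():
        t = len(accepted) - 1
        w = np.array([(1 - a) ** t] + [a * (1 - a) ** (t - i) for i in range(1, t + 1)])
        vals = np.array(accepted)
        m = float(w @ vals)
        s = float(w @ (vals * vals))
        return m, np.sqrt(max(s - m * m, 0.0))

    ema = np.full(len(x), np.nan)
    std = np.full(len(x), np.nan)
    upper = np.full(len(x), np.nan)
    lower = np.full(len(x), np.nan)
    for i, xi in enumerate(x):
        if accepted:
            m, sd = state()
            half = max(k * sd, floor * abs(m))
            upper[i], lower[i] = m + half, m - half
        if np.isfinite(xi):
            if not accepted:
                accepted.append(float(xi))
            else:
                accepted.append(float(np.clip(xi, lower[i], upper[i])))
        if accepted:
            ema[i], std[i] = state()
    return ema, std, upper, lower


def oracle_label_episode(episode, params: BandParams):
    """Straight-line labeller reimplementation on pandas structures."""
    s = episode.series
    df = pd.DataFrame(np.where(s.observed, s.values, np.nan), columns=CHANNEL_NAMES)
    locf = ("nibp_sys", "nibp_mean", "nibp_dia", "temp_oesophageal",
            "temp_skin", "temp_core", "temp_unspecified")
    for ch in locf:
        df[ch] = df[ch].ffill()
    n_min = len(df) // 60
    mm = pd.DataFrame(
        {ch: [df[ch].iloc[60 * m : 60 * (m + 1)].mean() for m in range(n_min)]
         for ch in CHANNEL_NAMES}
    )
    bands = {ch: oracle_band_channel(mm[ch].to_numpy(), params, ch) for ch in CHANNEL_NAMES}

    def deviate(ch, m, low_rule=False):
        x = mm[ch].iloc[m]
        _, _, up, lo = bands[ch]
        if m < params.warmup_minutes or not np.isfinite([x, up[m], lo[m]]).all():
            return None
        if low_rule:
            return bool(x < min(params.spo2_fixed_threshold, lo[m]))
        return bool(x < lo[m] or x > up[m])

    secondary = ("rr_impedance", "rr_airway", "etco2_min", "etco2_max")
    bp = "ibp_mean" if s.observed[:, CHANNEL_INDEX["ibp_mean"]].any() else "nibp_mean"
    events = []
    flank = params.flank_s // 60

    def clean(ch, m0, m1):
        rng = list(range(m0 - flank, m0)) + list(range(m1, m1 + flank))
        return all(0 <= m < n_min and np.isfinite(mm[ch].iloc[m]) for m in rng)

    # respiratory
    cand = [
        bool(deviate("spo2", m, low_rule=True))
        and any(deviate(ch, m) for ch in secondary)
        for m in range(n_min)
    ]
    for val, grp in itertools.groupby(enumerate(cand), key=lambda t: t[1]):
        if not val:
            continue
        ms = [m for m, _ in grp]
        m0, m1 = ms[0], ms[-1] + 1
        fired = [ch for ch in secondary if any(deviate(ch, m) for m in ms)]
        if clean("spo2", m0, m1) and any(clean(ch, m0, m1) for ch in fired):
            events.append(("respiratory", m0 * 60, m1 * 60))
    # cardiovascular
    cand = [
        bool(deviate("hr", m)) and bool(deviate(bp, m)) for m in range(n_min)
    ]
    for val, grp in itertools.groupby(enumerate(cand), key=lambda t: t[1]):
        if not val:
            continue
        ms = [m for m, _ in grp]
        m0, m1 = ms[0], ms[-1] + 1
        if clean("hr", m0, m1) and clean(bp, m0, m1):
            events.append(("cardiovascular", m0 * 60, m1 * 60))
    return sorted(events)


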