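"""Window construction and episode-level stratified splitting.

Each eligible episode is tiled into consecutive, non-overlapping 15-minute
blocks anchored at episode start. Every block with a complete preceding block
yields one sample: the model reads the preceding 15 minutes at high resolution
(plus up to 120 minutes of 5-minute-averaged context) and predicts whether a
detected event of the task's kind overlaps the label block. No feature may use
data at or after the label-block start t0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import (
    BaselineVector,
    DiagnosisEmbedding,
    clean_vitals,
    carry_forward,
    impute_and_mask,
    standardise,
)
from .schema import Episode, EpisodeTimeSeries, EventInterval

WINDOW_S = 900  # 15-minute blocks
CONTEXT_ROWS = 24  # 120 min of history in 5-min bins
CONTEXT_BIN_S = 300
CONTEXT_WIDTH = 21  # 18 channel means + 2 event flags + 1 validity


@dataclass
class WindowSample:
    """One model input/label unit."""

    episode_id: str
    window_index: int
    t0: int  # label-block start, seconds
    input_matrix: np.ndarray  # (T, 36) fine features over [t0-900, t0)
    context_matrix: np.ndarray  # (24, 21) over [t0-8100, t0-900)
    baseline: BaselineVector
    dx: DiagnosisEmbedding
    labels: dict[str, int]


def event_flag_channels(
    n_seconds: int, events: list[EventInterval]
) -> np.ndarray:
    """(n, 2) per-second prior-event flags from detected events."""
    flags = np.zeros((n_seconds, 2))
    for e in events:
        if e.source != "detected":
            continue
        col = 0 if e.kind == "respiratory" else 1
        flags[max(0, e.start_s) : min(n_seconds, e.end_s), col] = 1.0
    return flags


def preprocess_episode(
    episode: Episode,
) -> tuple[np.ndarray, "EpisodeTimeSeries"]:
    """Clean -> carry-forward -> standardise -> impute+mask.

    Returns the (n, 36) feature matrix and the standardised series (whose
    observedness matrix the context builder consumes)."""
    s = clean_vitals(episode.series)
    s = carry_forward(s)
    s = standardise(s, episode.meta.age_years)
    flags = event_flag_channels(s.n_seconds, episode.events)
    return impute_and_mask(s, flags), s


def build_context(
    feature_matrix: np.ndarray,
    observed: np.ndarray,
    events: list[EventInterval],
    t0: int,
) -> np.ndarray:
    """(24, 21) context matrix covering [t0-8100, t0-900) in 5-min bins.

    Row r covers [t0-900-300*(24-r), t0-900-300*(23-r)); rows that begin
    before episode start are zeroed with validity 0. Columns: per-channel mean
    of the standardised values over observed samples (0 when none observed),
    then respiratory/cardiovascular event-occurrence flags, then validity.
    """
    if t0 < WINDOW_S:
        raise ValueError("t0 must be >= 900 (one full input block)")
    ctx = np.zeros((CONTEXT_ROWS, CONTEXT_WIDTH))
    values = feature_matrix[:, :18]
    detected = [e for e in events if e.source == "detected"]
    for r in range(CONTEXT_ROWS):
        start = t0 - WINDOW_S - CONTEXT_BIN_S * (CONTEXT_ROWS - r)
        end = start + CONTEXT_BIN_S
        if start < 0:
            continue
        vals = values[start:end]
        obs = observed[start:end]
        cnt = obs.sum(axis=0)
        means = np.where(cnt > 0, (vals[:, :16] * obs).sum(axis=0) / np.maximum(cnt, 1), 0.0)
        ctx[r, :16] = means
        # the two flag channels are always defined: plain mean
        ctx[r, 16:18] = vals[:, 16:18].mean(axis=0)
        for e in detected:
            if e.overlaps(start, end):
                col = 18 if e.kind == "respiratory" else 19
                ctx[r, col] = 1.0
        ctx[r, 20] = 1.0
    return ctx


def make_windows(
    episode: Episode,
    baseline: BaselineVector,
    dx: DiagnosisEmbedding,
    input_hz: float = 1.0,
    no_context: bool = False,
) -> list[WindowSample]:
    """Tile one labelled, preprocessed episode into WindowSamples.

    ``input_hz`` < 1 strides the fine input matrix (window semantics stay in
    minutes). ``no_context`` zeroes all context validity (history ablation).
    """
    n = episode.series.n_seconds
    n_blocks = n // WINDOW_S
    if n_blocks < 2:
        warnings.warn(
            f"episode {episode.episode_id} shorter than 30 min; no windows"
        )
        return []
    feature_matrix, std_series = preprocess_episode(episode)
    stride = max(1, int(round(1.0 / input_hz)))
    detected = [e for e in episode.events if e.source == "detected"]

    samples = []
    for b in range(1, n_blocks):
        t0 = b * WINDOW_S
        fine = feature_matrix[t0 - WINDOW_S : t0 : stride].copy()
        ctx = build_context(feature_matrix, std_series.observed, detected, t0)
        if no_context:
            ctx = np.zeros_like(ctx)
        labels = {
            kind: int(
                any(
                    e.kind == kind and e.overlaps(t0, t0 + WINDOW_S)
                    for e in detected
                )
            )
            for kind in ("respiratory", "cardiovascular")
        }
        samples.append(
            WindowSample(
                episode.episode_id, b - 1, t0, fine, ctx, baseline, dx, labels
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Stratified episode-level split


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # episode_id -> train | tune | test
    stratum: dict[str, str]  # episode_id -> none | resp_only | cv_only | both

    def ids(self, split: str) -> list[str]:
        return [e for e, s in self.assignment.items() if s == split]


def episode_stratum(events: list[EventInterval]) -> str:
    """Deterioration stratum from detected events."""
    resp = any(e.kind == "respiratory" and e.source == "detected" for e in events)
    cv = any(e.kind == "cardiovascular" and e.source == "detected" for e in events)
    if resp and cv:
        return "both"
    if resp:
        return "resp_only"
    if cv:
        return "cv_only"
    return "none"


def stratify_and_split(
    episodes: list[Episode],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Episode-level 80/10/10 split within each of the four deterioration
    strata (none / respiratory-only / cardiovascular-only / both).

    Within each stratum episodes are shuffled (seeded) and allocated by
    largest-remainder rounding, so per-stratum proportions are within one
    episode of exact. All windows of an episode inherit its split.
    """
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    stratum_of: dict[str, str] = {}
    for ep in episodes:
        s = episode_stratum(ep.events)
        stratum_of[ep.episode_id] = s
        strata.setdefault(s, []).append(ep.episode_id)

    assignment: dict[str, str] = {}
    names = ("train", "tune", "test")
    for s in sorted(strata):
        ids = sorted(strata[s])
        rng.shuffle(ids)
        n = len(ids)
        if n < 3:
            warnings.warn(
                f"stratum {s!r} has only {n} episode(s); allocating to train first"
            )
        exact = np.array(ratios) * n
        base = np.floor(exact).astype(int)
        rem = n - base.sum()
        order = np.argsort(-(exact - base), kind="stable")
        for k in order[:rem]:
            base[k] += 1
        i = 0
        for k, split in enumerate(names):
            for eid in ids[i : i + base[k]]:
                assignment[eid] = split
            i += base[k]
    return SplitAssignment(assignment, stratum_of)


def stack_samples(samples: list[WindowSample]) -> dict[str, np.ndarray]:
    """Stack WindowSamples into dense model-ready arrays."""
    return {
        "fine": np.stack([s.input_matrix for s in samples]),
        "context": np.stack([s.context_matrix for s in samples]),
        "baseline": np.stack([s.baseline.values for s in samples]),
        "dx": np.stack([s.dx.vector for s in samples]),
        "y_respiratory": np.array([s.labels["respiratory"] for s in samples]),
        "y_cardiovascular": np.array(
            [s.labels["cardiovascular"] for s in samples]
        ),
        "episode_id": np.array([s.episode_id for s in samples]),
    }
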