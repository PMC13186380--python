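"""Integrated Gradients explanations at cohort, window and per-second level.

The attribution baseline defaults to the all-zero input with all-zero masks —
the model's "fully imputed / no information" reference, which coincides with
the mean-imputation convention. Attributions satisfy the completeness axiom:
their sum approximates F(x) - F(baseline), with the gap reported and shrinking
as the path resolution grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .models import Model
from .preprocess import FEATURE_CHANNELS

COMPONENTS = ("fine", "context", "baseline", "dx")


@dataclass
class AttributionResult:
    """Per-element attributions, congruent with the model's full input."""

    attributions: dict[str, np.ndarray]
    steps: int
    f_x: float
    f_baseline: float
    completeness_gap: float

    @property
    def total(self) -> float:
        return float(sum(a.sum() for a in self.attributions.values()))


def integrated_gradients(
    model: Model,
    window: dict[str, np.ndarray],
    steps: int = 50,
    baseline_input: dict[str, np.ndarray] | None = None,
) -> AttributionResult:
    """Riemann-midpoint path integral of gradients from baseline to input.

    ``window`` holds single-sample arrays (fine (T, 36), context (24, 21),
    baseline (B,), dx (768,)). All path points are evaluated as one batch.
    """
    x = {k: np.asarray(window[k], dtype=float) for k in COMPONENTS}
    b = (
        {k: np.zeros_like(v) for k, v in x.items()}
        if baseline_input is None
        else {k: np.asarray(baseline_input[k], dtype=float) for k in COMPONENTS}
    )
    alphas = (np.arange(steps) + 0.5) / steps  # midpoint rule

    inputs = {}
    for k in COMPONENTS:
        path = b[k][None] + alphas.reshape((-1,) + (1,) * x[k].ndim) * (x[k] - b[k])[None]
        inputs[k] = Tensor(path, requires_grad=True)
    out = model.forward(inputs)
    out.sum().backward()

    attributions = {}
    for k in COMPONENTS:
        g = inputs[k].grad
        if g is None or not np.all(np.isfinite(g)):
            bad = k if g is None else f"{k}[{np.argwhere(~np.isfinite(g))[0]}]"
            raise FloatingPointError(f"non-finite gradient for input element {bad}")
        attributions[k] = g.mean(axis=0) * (x[k] - b[k])

    f_x = float(model.forward({k: v[None] for k, v in x.items()}).data[0])
    f_b = float(model.forward({k: v[None] for k, v in b.items()}).data[0])
    total = float(sum(a.sum() for a in attributions.values()))
    return AttributionResult(
        attributions, steps, f_x, f_b, abs(total - (f_x - f_b))
    )


# ---------------------------------------------------------------------------
# Grouping and cohort aggregation

#: Display groups: channels merged per modality; each fine value column and
#: its mask column belong to the channel's group; context channel-mean columns
#: join the same groups; diagnosis embedding is one block.
_CHANNEL_GROUP = {
    "spo2": "spo2",
    "hr": "heart_rate",
    "etco2_min": "etco2",
    "etco2_max": "etco2",
    "rr_airway": "respiratory_rate",
    "rr_impedance": "respiratory_rate",
    "nibp_sys": "nibp",
    "nibp_mean": "nibp",
    "nibp_dia": "nibp",
    "ibp_sys": "ibp",
    "ibp_mean": "ibp",
    "ibp_dia": "ibp",
    "temp_oesophageal": "temperature",
    "temp_skin": "temperature",
    "temp_core": "temperature",
    "temp_unspecified": "temperature",
    "prior_respiratory_event": "prior_respiratory_events",
    "prior_cardiovascular_event": "prior_cardiovascular_events",
}


def default_grouping(baseline_dim: int) -> dict[str, dict[str, list[int]]]:
    """Partition of all input elements into named display groups."""
    groups: dict[str, dict[str, list[int]]] = {}

    def add(group, component, idx):
        groups.setdefault(group, {c: [] for c in COMPONENTS})[component].append(idx)

    for j, ch in enumerate(FEATURE_CHANNELS):
        g = _CHANNEL_GROUP[ch]
        add(g, "fine", j)
        add(g, "fine", j + 18)  # the channel's mask column
        add(g, "context", j)  # 5-min channel means
    add("prior_respiratory_events", "context", 18)
    add("prior_cardiovascular_events", "context", 19)
    add("context_validity", "context", 20)
    for j in range(baseline_dim):
        add("baseline", "baseline", j)
    for j in range(768):
        add("diagnosis", "dx", j)
    return groups


def _check_partition(grouping: dict, shapes: dict[str, int]):
    for comp, width in shapes.items():
        seen: list[int] = []
        for g in grouping.values():
            seen.extend(g.get(comp, []))
        if sorted(seen) != list(range(width)):
            raise ValueError(
                f"grouping does not partition component {comp!r} "
                f"({len(seen)} indices over width {width})"
            )


@dataclass
class FeatureGroupImportance:
    """Mean absolute attribution per named group, overall and by predicted
    class. Groups partition the input; importances are >= 0."""

    overall: dict[str, float]
    predicted_positive: dict[str, float]
    predicted_negative: dict[str, float]
    n_windows: int


def aggregate_cohort(
    results: list[AttributionResult],
    grouping: dict[str, dict[str, list[int]]],
    predictions: np.ndarray,
) -> FeatureGroupImportance:
    """Cohort-level importance: per group, the mean over windows of the summed
    absolute attribution of the group's elements."""
    if not results:
        raise ValueError("need at least one attribution result")
    shapes = {
        "fine": results[0].attributions["fine"].shape[-1],
        "context": results[0].attributions["context"].shape[-1],
        "baseline": results[0].attributions["baseline"].shape[-1],
        "dx": results[0].attributions["dx"].shape[-1],
    }
    _check_partition(grouping, shapes)
    predictions = np.asarray(predictions, dtype=bool)
    if len(predictions) != len(results):
        raise ValueError("predictions must align with results")

    per_window = {g: np.empty(len(results)) for g in grouping}
    for i, r in enumerate(results):
        for g, comps in grouping.items():
            tot = 0.0
            for comp, idx in comps.items():
                if not idx:
                    continue
                a = np.abs(r.attributions[comp])
                tot += a[..., idx].sum()
            per_window[g][i] = tot

    def summarise(mask):
        if mask.sum() == 0:
            return {g: float("nan") for g in grouping}
        return {g: float(per_window[g][mask].mean()) for g in grouping}

    return FeatureGroupImportance(
        overall=summarise(np.ones(len(results), dtype=bool)),
        predicted_positive=summarise(predictions),
        predicted_negative=summarise(~predictions),
        n_windows=len(results),
    )


def temporal_trace(result: AttributionResult, channel: str) -> np.ndarray:
    """Per-timestep attribution magnitude for one named channel.

    Value and mask column magnitudes are summed; the trace aligns 1:1 with the
    window's fine input rows for plotting against the raw signal.
    """
    if channel not in FEATURE_CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    j = FEATURE_CHANNELS.index(channel)
    a = np.abs(result.attributions["fine"])
    return a[:, j] + a[:, j + 18]
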