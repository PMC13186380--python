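"""Domain types, episode bundle I/O, validation and eligibility filtering.

An *episode* is one interhospital transport: an episode-level metadata record
plus a multichannel vital-sign time series on a strict 1-second grid, with a
parallel boolean observedness matrix (``True`` only for sensor-originated
samples, never for carried-forward or imputed values).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: Closed set of primary-diagnosis categories.
DIAGNOSIS_CATEGORIES = (
    "respiratory",
    "cardiovascular",
    "neurological",
    "infection",
    "gastroenterology",
    "metabolic",
    "trauma",
    "other",
)

#: Organ systems for pre-existing comorbidity flags.
COMORBIDITY_SYSTEMS = (
    "respiratory",
    "cardiac",
    "renal",
    "genetic",
    "metabolic_endocrine",
    "haematological_oncological",
    "other",
)

#: Intra-transport respiratory support categories.
RESP_SUPPORT_CATEGORIES = (
    "room_air",
    "supplemental_o2",
    "hfnc",
    "cpap",
    "bipap",
    "ett",
    "tracheostomy",
    "other_airway",
)

#: Intra-transport cardiovascular support agents (named boolean flags).
CV_SUPPORT_AGENTS = (
    "adrenaline",
    "noradrenaline",
    "dobutamine",
    "dopamine",
    "milrinone",
    "prostaglandin",
    "nitric_oxide",
)

#: Destination care areas.
CARE_AREAS = ("picu", "nicu", "hdu", "ward", "other")

#: Pre-transport interventions by the local team (named boolean flags).
PRE_TRANSPORT_INTERVENTIONS = (
    "intubation",
    "mechanical_ventilation",
    "suctioning",
    "chest_drain",
    "vascular_access",
    "vasoactive_support",
    "blood_products",
    "urinary_catheter",
    "gastric_tube",
    "ct_imaging",
    "cspine_immobilisation",
    "osmotherapy",
    "cpr_defibrillation",
    "ecmo",
    "icp_monitoring",
    "arterial_line",
    "central_line",
)

ETHNICITY_CODES = ("white", "asian", "black", "mixed", "other")


@dataclass(frozen=True)
class ChannelSpec:
    """One vital-sign channel: unit, expected cadence and plausibility bounds.

    Bounds are exclusive: a sample is removed by cleaning iff it is strictly
    below ``plausible_min`` or strictly above ``plausible_max``.
    """

    name: str
    unit: str
    native_cadence: int  # seconds between expected sensor samples
    plausible_min: float
    plausible_max: float
    family: str  # standardisation family: spo2|hr|rr|bp|etco2|temp

    def __post_init__(self):
        if not self.plausible_min < self.plausible_max:
            raise ValueError(f"{self.name}: plausible_min must be < plausible_max")


def _c(name, unit, cadence, lo, hi, family):
    return ChannelSpec(name, unit, cadence, lo, hi, family)


#: The 16 vital-sign channels. Cleaning bounds follow the published
#: plausibility rules (HR <30 or >300 bpm, SpO2 <10 or >100 %, EtCO2 >15 kPa,
#: BP <5 mmHg, temperature <25 or >45 degC); channels without a published rule
#: get wide bounds that remove nothing physically recordable.
CHANNELS: tuple[ChannelSpec, ...] = (
    _c("spo2", "%", 1, 10.0, 100.0, "spo2"),
    _c("hr", "bpm", 1, 30.0, 300.0, "hr"),
    _c("etco2_min", "kPa", 1, 0.0, 15.0, "etco2"),
    _c("etco2_max", "kPa", 1, 0.0, 15.0, "etco2"),
    _c("rr_airway", "breaths/min", 1, 0.0, 250.0, "rr"),
    _c("rr_impedance", "breaths/min", 1, 0.0, 250.0, "rr"),
    _c("nibp_sys", "mmHg", 240, 5.0, 400.0, "bp"),
    _c("nibp_mean", "mmHg", 240, 5.0, 400.0, "bp"),
    _c("nibp_dia", "mmHg", 240, 5.0, 400.0, "bp"),
    _c("ibp_sys", "mmHg", 1, 5.0, 400.0, "bp"),
    _c("ibp_mean", "mmHg", 1, 5.0, 400.0, "bp"),
    _c("ibp_dia", "mmHg", 1, 5.0, 400.0, "bp"),
    _c("temp_oesophageal", "degC", 300, 25.0, 45.0, "temp"),
    _c("temp_skin", "degC", 300, 25.0, 45.0, "temp"),
    _c("temp_core", "degC", 300, 25.0, 45.0, "temp"),
    _c("temp_unspecified", "degC", 300, 25.0, 45.0, "temp"),
)

CHANNEL_NAMES: tuple[str, ...] = tuple(c.name for c in CHANNELS)
CHANNEL_INDEX: dict[str, int] = {c.name: i for i, c in enumerate(CHANNELS)}
CHANNEL_BY_NAME: dict[str, ChannelSpec] = {c.name: c for c in CHANNELS}

#: Channels filled by last-observation-carried-forward between sparse samples.
LOCF_CHANNELS = (
    "nibp_sys",
    "nibp_mean",
    "nibp_dia",
    "temp_oesophageal",
    "temp_skin",
    "temp_core",
    "temp_unspecified",
)


@dataclass
class EpisodeMetadata:
    """Episode-level record: demographics, diagnosis, support and logistics."""

    episode_id: str
    age_years: float
    weight_kg: float
    sex: str = "missing"  # male | female | missing
    ethnicity: str | None = None
    pim3: float | None = None
    diagnosis_text: str = ""
    diagnosis_category: str = "other"
    comorbidity_flags: dict[str, bool] = field(default_factory=dict)
    pre_transport_interventions: dict[str, bool] = field(default_factory=dict)
    resp_support: str = "room_air"
    cv_support: dict[str, bool] = field(default_factory=dict)
    referring_hospital: str = "unknown"
    destination_hospital: str = "unknown"
    destination_care_area: str = "picu"
    team_arrival_time: str = "12:00"  # HH:MM clock time

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EpisodeMetadata":
        return cls(**d)


@dataclass
class EpisodeTimeSeries:
    """1 Hz multichannel series with per-sample observedness.

    ``values`` and ``observed`` are (n_seconds, 16) arrays ordered as
    :data:`CHANNEL_NAMES`. Unobserved cells hold NaN. ``carried`` marks cells
    filled by LOCF (provenance; such cells count as observed for modelling).
    """

    t: np.ndarray  # int seconds since episode start, step 1
    values: np.ndarray  # float, NaN where unobserved
    observed: np.ndarray  # bool
    carried: np.ndarray | None = None  # bool, LOCF provenance

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.carried is None:
            self.carried = np.zeros_like(self.observed)

    @property
    def duration_seconds(self) -> int:
        return int(self.t[-1] - self.t[0]) if len(self.t) else 0

    @property
    def n_seconds(self) -> int:
        return len(self.t)

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, CHANNEL_INDEX[name]]

    def channel_observed(self, name: str) -> np.ndarray:
        return self.observed[:, CHANNEL_INDEX[name]]

    def copy(self) -> "EpisodeTimeSeries":
        return EpisodeTimeSeries(
            self.t.copy(), self.values.copy(), self.observed.copy(), self.carried.copy()
        )


@dataclass(frozen=True)
class EventInterval:
    """A labelled deterioration interval, half-open ``[start_s, end_s)``."""

    kind: str  # respiratory | cardiovascular
    start_s: int
    end_s: int
    source: str  # injected | detected

    def __post_init__(self):
        if self.kind not in ("respiratory", "cardiovascular"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.source not in ("injected", "detected"):
            raise ValueError(f"unknown event source {self.source!r}")

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s

    def overlaps(self, start_s: int, end_s: int) -> bool:
        return self.start_s < end_s and start_s < self.end_s

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "start_s": int(self.start_s),
            "end_s": int(self.end_s),
            "source": self.source,
        }


@dataclass
class Episode:
    """Metadata + time series + (optionally) labelled event intervals."""

    meta: EpisodeMetadata
    series: EpisodeTimeSeries
    events: list[EventInterval] = field(default_factory=list)

    @property
    def episode_id(self) -> str:
        return self.meta.episode_id

    def events_of(self, kind: str, source: str | None = None) -> list[EventInterval]:
        return [
            e
            for e in self.events
            if e.kind == kind and (source is None or e.source == source)
        ]


class BundleError(IOError):
    """An episode bundle on disk is unreadable or structurally incomplete."""


class SchemaVersionError(BundleError):
    """Bundle written with an incompatible schema version."""


def validate_episode(episode: Episode) -> list[str]:
    """Check all type invariants; return a list of violations (empty if valid).

    Each violation names the offending field and the rule it breaks.
    """
    v: list[str] = []
    m, s = episode.meta, episode.series

    if not (0 <= m.age_years <= 18):
        v.append(f"age_years: must be in [0, 18], got {m.age_years}")
    if m.pim3 is not None and not (0 <= m.pim3 <= 1):
        v.append(f"pim3: must be in [0, 1] when present, got {m.pim3}")
    if m.diagnosis_category not in DIAGNOSIS_CATEGORIES:
        v.append(f"diagnosis_category: {m.diagnosis_category!r} not in closed set")
    if m.sex not in ("male", "female", "missing"):
        v.append(f"sex: {m.sex!r} not in {{male, female, missing}}")
    if m.weight_kg is not None and not math.isnan(m.weight_kg) and m.weight_kg <= 0:
        v.append(f"weight_kg: must be positive, got {m.weight_kg}")

    if s.values.ndim != 2 or s.values.shape[1] != len(CHANNELS):
        v.append(
            f"values: channel set must equal the {len(CHANNELS)}-channel registry, "
            f"got shape {s.values.shape}"
        )
    if s.observed.shape != s.values.shape:
        v.append("observed: shape must match values")
    if len(s.t) != s.values.shape[0]:
        v.append("t: length must match values rows")
    if len(s.t) > 1:
        steps = np.diff(s.t)
        if not np.all(steps == 1):
            bad = int(np.argmax(steps != 1))
            v.append(
                f"t: time step must be exactly 1 s (gap of {int(steps[bad])} s "
                f"after t={int(s.t[bad])})"
            )
    if s.observed.shape == s.values.shape and np.any(
        s.observed & ~np.isfinite(s.values)
    ):
        v.append("values: every observed=true cell must hold a finite value")

    for e in episode.events:
        if e.end_s <= e.start_s:
            v.append(f"events: interval [{e.start_s}, {e.end_s}) is empty or reversed")
        if e.source == "detected" and e.duration_s < 60:
            v.append(
                f"events: detected {e.kind} event of {e.duration_s}s "
                "violates >=60 s persistence"
            )
    for kind in ("respiratory", "cardiovascular"):
        for source in ("injected", "detected"):
            ivs = sorted(
                episode.events_of(kind, source), key=lambda e: (e.start_s, e.end_s)
            )
            for a, b in zip(ivs, ivs[1:]):
                if b.start_s < a.end_s:
                    v.append(f"events: overlapping {source} {kind} intervals")
    return v


def eligible(episode: Episode) -> bool:
    """Inclusion rule: age <= 18 years and >= 30 minutes of recorded vitals."""
    return episode.meta.age_years <= 18 and episode.series.duration_seconds >= 1800


def write_episode(episode: Episode, path: str | Path) -> Path:
    """Write an episode bundle: timeseries.parquet, observed.parquet,
    meta.json and events.json under ``path/<episode_id>/``."""
    root = Path(path) / episode.episode_id
    root.mkdir(parents=True, exist_ok=True)
    s = episode.series

    ts = pd.DataFrame(s.values, columns=list(CHANNEL_NAMES))
    ts.insert(0, "t", s.t)
    ts.to_parquet(root / "timeseries.parquet", index=False)

    obs = pd.DataFrame(s.observed, columns=list(CHANNEL_NAMES))
    obs["__carried__"] = [row.tobytes().hex() for row in np.packbits(s.carried, axis=1)]
    obs.to_parquet(root / "observed.parquet", index=False)

    meta = {"schema_version": SCHEMA_VERSION, "meta": episode.meta.to_dict()}
    (root / "meta.json").write_text(json.dumps(meta, indent=1))
    (root / "events.json").write_text(
        json.dumps([e.to_dict() for e in episode.events], indent=1)
    )
    return root


def read_episode(path: str | Path) -> Episode:
    """Read an episode bundle written by :func:`write_episode`."""
    root = Path(path)
    for part in ("meta.json", "timeseries.parquet", "observed.parquet", "events.json"):
        if not (root / part).exists():
            raise BundleError(f"bundle {root} is missing component {part}")
    try:
        meta_doc = json.loads((root / "meta.json").read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"unreadable meta.json in {root}: {exc}") from exc
    if meta_doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"bundle {root} has schema_version {meta_doc.get('schema_version')}, "
            f"expected {SCHEMA_VERSION}"
        )
    meta = EpisodeMetadata.from_dict(meta_doc["meta"])

    ts = pd.read_parquet(root / "timeseries.parquet")
    t = ts["t"].to_numpy(np.int64)
    values = ts[list(CHANNEL_NAMES)].to_numpy(np.float64)

    obs_df = pd.read_parquet(root / "observed.parquet")
    observed = obs_df[list(CHANNEL_NAMES)].to_numpy(bool)
    packed = np.array(
        [np.frombuffer(bytes.fromhex(h), dtype=np.uint8) for h in obs_df["__carried__"]]
    )
    carried = np.unpackbits(packed, axis=1)[:, : len(CHANNELS)].astype(bool)

    events = [
        EventInterval(**e) for e in json.loads((root / "events.json").read_text())
    ]
    series = EpisodeTimeSeries(t, values, observed, carried)
    return Episode(meta, series, events)


def write_cohort_manifest(
    path: str | Path, episode_ids: list[str], split: dict[str, str] | None = None
) -> Path:
    """Write a cohort manifest JSON listing episode ids and split assignment."""
    p = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "episodes": list(episode_ids),
        "split": split or {},
    }
    p.write_text(json.dumps(doc, indent=1))
    return p


def read_cohort_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
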