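"""Cleaning, carry-forward, standardisation, imputation-with-mask, and
encoding of baseline and diagnosis features.

Standardisation rules: SpO2 -> (x-97)/6, EtCO2 -> (x-5.25)/1.5, temperature ->
(x-36.75)/1.5; heart rate, respiratory rates and blood pressures are z-scored
against the packaged age-reference grid (shared with the simulator).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import reference
from .schema import (
    CARE_AREAS,
    CHANNELS,
    CHANNEL_INDEX,
    CHANNEL_NAMES,
    COMORBIDITY_SYSTEMS,
    CV_SUPPORT_AGENTS,
    DIAGNOSIS_CATEGORIES,
    ETHNICITY_CODES,
    LOCF_CHANNELS,
    PRE_TRANSPORT_INTERVENTIONS,
    RESP_SUPPORT_CATEGORIES,
    EpisodeMetadata,
    EpisodeTimeSeries,
)

#: Names of the 18 feature channels: 16 vitals + 2 prior-event flag channels.
FEATURE_CHANNELS: tuple[str, ...] = CHANNEL_NAMES + (
    "prior_respiratory_event",
    "prior_cardiovascular_event",
)

EMBEDDING_DIM = 768


def clean_vitals(series: EpisodeTimeSeries) -> EpisodeTimeSeries:
    """Mark physiologically implausible samples unobserved.

    Bounds are exclusive (a value strictly outside [plausible_min,
    plausible_max] is removed; boundary values are retained). Idempotent.
    """
    out = series.copy()
    for j, spec in enumerate(CHANNELS):
        col = out.values[:, j]
        with np.errstate(invalid="ignore"):
            bad = out.observed[:, j] & (
                (col < spec.plausible_min) | (col > spec.plausible_max)
            )
        out.values[bad, j] = np.nan
        out.observed[bad, j] = False
        out.carried[bad, j] = False
    return out


def carry_forward(
    series: EpisodeTimeSeries, channels: tuple[str, ...] = LOCF_CHANNELS
) -> EpisodeTimeSeries:
    """Last observation carried forward on the sparse channels.

    Filled cells are marked observed (the mask encodes sensor dropout, not
    cadence) while ``carried`` records their provenance. Nothing is filled
    before the first observation, and a channel with zero observations stays
    entirely unobserved.
    """
    out = series.copy()
    n = out.n_seconds
    idx_range = np.arange(n)
    for name in channels:
        j = CHANNEL_INDEX[name]
        obs = out.observed[:, j]
        if not obs.any():
            continue
        # index of most recent observation at or before each second
        last = np.where(obs, idx_range, -1)
        last = np.maximum.accumulate(last)
        fill = (last >= 0) & ~obs
        out.values[fill, j] = out.values[last[fill], j]
        out.observed[fill, j] = True
        out.carried[fill, j] = True
    return out


@dataclass(frozen=True)
class StandardisationTables:
    """Per-channel rule: affine (centre, scale) or age-referenced z-score."""

    affine: dict = None
    age_grid: np.ndarray = None

    @classmethod
    def default(cls) -> "StandardisationTables":
        return cls(affine=dict(reference.AFFINE_RULES), age_grid=reference.AGE_GRID)

    def rule(self, channel: str, age_years: float) -> tuple[float, float]:
        """(centre, scale) for a channel at an age; scale always > 0."""
        if channel in self.affine:
            return self.affine[channel]
        return reference.age_reference(channel, age_years)


def standardise(
    series: EpisodeTimeSeries,
    age_years: float,
    tables: StandardisationTables | None = None,
) -> EpisodeTimeSeries:
    """Transform every channel to standardised units.

    Affine channels apply their printed formula exactly; z-score channels use
    the age-interpolated (mean, SD). Ages outside the reference grid are
    clamped to the nearest grid point.
    """
    tables = tables or StandardisationTables.default()
    out = series.copy()
    for j, name in enumerate(CHANNEL_NAMES):
        centre, scale = tables.rule(name, age_years)
        out.values[:, j] = (out.values[:, j] - centre) / scale
    return out


def unstandardise(
    series: EpisodeTimeSeries,
    age_years: float,
    tables: StandardisationTables | None = None,
) -> EpisodeTimeSeries:
    """Inverse of :func:`standardise` (exact for affine channels)."""
    tables = tables or StandardisationTables.default()
    out = series.copy()
    for j, name in enumerate(CHANNEL_NAMES):
        centre, scale = tables.rule(name, age_years)
        out.values[:, j] = out.values[:, j] * scale + centre
    return out


def impute_and_mask(
    series: EpisodeTimeSeries, event_flags: np.ndarray
) -> np.ndarray:
    """Build the per-second (n, 36) feature matrix.

    Columns 0..17 are the 18 standardised feature channels (16 vitals + the
    two prior-event flag channels supplied in ``event_flags``); columns 18..35
    are their observedness flags (1 observed, 0 imputed). Unobserved cells are
    mean-imputed, i.e. set to zero post-standardisation.
    """
    n = series.n_seconds
    event_flags = np.asarray(event_flags, dtype=np.float64)
    if event_flags.shape != (n, 2):
        raise ValueError(f"event_flags must have shape ({n}, 2)")
    vals = np.where(series.observed, series.values, 0.0)
    vals = np.nan_to_num(vals, nan=0.0, posinf=0.0, neginf=0.0)
    feats = np.concatenate([vals, event_flags], axis=1)
    mask = np.concatenate(
        [series.observed.astype(np.float64), np.ones((n, 2))], axis=1
    )
    out = np.concatenate([feats, mask], axis=1)
    assert out.shape[1] == 36
    return out


# ---------------------------------------------------------------------------
# Baseline encodings


def _minmax(x: float | None, lo: float, hi: float) -> float:
    """Scale to [0, 1] over a fixed a-priori range; missing -> -1."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return -1.0
    return float((x - lo) / (hi - lo))


def _onehot(value: str | None, categories: tuple[str, ...], prefix: str) -> dict:
    """One-hot block with an explicit other/unknown slot; never drops."""
    cats = list(categories)
    if "other" not in cats:
        cats.append("other")
    block = {f"{prefix}:{c}": 0.0 for c in cats}
    key = value if value in categories else "other"
    if value is not None:
        block[f"{prefix}:{key}"] = 1.0
    return block


@dataclass
class BaselineVector:
    """Ordered named numeric encoding of episode metadata."""

    configuration: str  # reduced | full
    names: tuple[str, ...]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))


#: The 9 reduced-configuration variable groups.
REDUCED_GROUPS = (
    "age", "weight", "sex", "pim3", "destination_care_area",
    "primary_diagnosis", "comorbidities", "resp_support", "cv_support",
)

#: The 30 full-configuration variable groups: the 9 reduced groups plus
#: ethnicity, referring and destination hospital, day/night flag, and the 17
#: named pre-transport intervention flags.
FULL_GROUPS = REDUCED_GROUPS + (
    "ethnicity", "referring_hospital", "destination_hospital", "day_night",
) + tuple(f"intervention:{n}" for n in PRE_TRANSPORT_INTERVENTIONS)


def _is_night(hhmm: str) -> float:
    hour = int(hhmm.split(":")[0])
    return 1.0 if (hour >= 20 or hour < 8) else 0.0


def encode_baseline(
    meta: EpisodeMetadata,
    configuration: str = "reduced",
    hospital_counts: dict[str, int] | None = None,
) -> BaselineVector:
    """Encode metadata into a fixed-order numeric vector.

    Age, weight and PIM3 are min-max scaled over fixed a-priori ranges
    ([0, 18] years, [1, 90] kg, [0, 1]) with missing values imputed as -1; sex
    is binary encoded; categorical fields are one-hot with explicit
    other/unknown slots. The full configuration additionally one-hot encodes
    ethnicity and hospitals (hospitals with <10 retrievals in the cohort are
    grouped as "other") and appends a day/night flag and the pre-transport
    intervention flags.
    """
    if configuration not in ("reduced", "full"):
        raise ValueError(f"unknown configuration {configuration!r}")
    entries: dict[str, float] = {}
    entries["age"] = _minmax(meta.age_years, 0.0, 18.0)
    entries["weight"] = _minmax(meta.weight_kg, 1.0, 90.0)
    entries["sex"] = {"male": 1.0, "female": 0.0}.get(meta.sex, -1.0)
    entries["pim3"] = _minmax(meta.pim3, 0.0, 1.0)
    entries.update(
        _onehot(meta.destination_care_area, CARE_AREAS, "care_area")
    )
    entries.update(_onehot(meta.diagnosis_category, DIAGNOSIS_CATEGORIES, "dx"))
    for s in COMORBIDITY_SYSTEMS:
        entries[f"comorb:{s}"] = float(bool(meta.comorbidity_flags.get(s)))
    entries.update(_onehot(meta.resp_support, RESP_SUPPORT_CATEGORIES, "resp"))
    for a in CV_SUPPORT_AGENTS:
        entries[f"cv:{a}"] = float(bool(meta.cv_support.get(a)))

    if configuration == "full":
        entries.update(_onehot(meta.ethnicity, ETHNICITY_CODES, "ethnicity"))
        counts = hospital_counts or {}

        def hospital_slot(h: str) -> str:
            return h if counts.get(h, 0) >= 10 else "other"

        known_ref = tuple(sorted(h for h, c in counts.items() if c >= 10))
        entries.update(
            _onehot(hospital_slot(meta.referring_hospital), known_ref, "ref_hosp")
        )
        entries.update(
            _onehot(hospital_slot(meta.destination_hospital), known_ref, "dest_hosp")
        )
        entries["night_shift"] = _is_night(meta.team_arrival_time)
        for n in PRE_TRANSPORT_INTERVENTIONS:
            entries[f"intervention:{n}"] = float(
                bool(meta.pre_transport_interventions.get(n))
            )

    names = tuple(entries)
    return BaselineVector(configuration, names, np.array(list(entries.values())))


# ---------------------------------------------------------------------------
# Diagnosis embedding


@dataclass(frozen=True)
class DiagnosisEmbedding:
    vector: np.ndarray
    provider: str

    def __post_init__(self):
        if self.vector.shape != (EMBEDDING_DIM,):
            raise ValueError(f"embedding must have length {EMBEDDING_DIM}")


class HashingEmbeddingProvider:
    """Deterministic offline 768-d text embedding via hashed token n-grams.

    Each word uni/bi-gram is hashed (blake2b) to an index and sign; the
    resulting sparse count vector is L2-normalised. Fully offline and
    deterministic for a given text. An external clinical language model can be
    plugged in through the same ``embed`` interface.
    """

    provider_id = "hashing-ngram-v1"

    def __init__(self, dim: int = EMBEDDING_DIM, cache_dir: str | Path | None = None):
        self.dim = dim
        self.cache_dir = Path(cache_dir) if cache_dir else None
        if self.cache_dir:
            self.cache_dir.mkdir(parents=True, exist_ok=True)

    def _tokens(self, text: str) -> list[str]:
        words = re.findall(r"[a-z0-9]+", text.lower())
        return words + [" ".join(p) for p in zip(words, words[1:])]

    def embed(self, text: str) -> DiagnosisEmbedding:
        if not text or not text.strip():
            import warnings

            warnings.warn("empty diagnosis text; returning zero embedding")
            return DiagnosisEmbedding(np.zeros(self.dim), self.provider_id)
        cached = self._cache_load(text)
        if cached is not None:
            return DiagnosisEmbedding(cached, self.provider_id)
        v = np.zeros(self.dim)
        for tok in self._tokens(text):
            h = hashlib.blake2b(tok.encode(), digest_size=8).digest()
            idx = int.from_bytes(h[:4], "little") % self.dim
            sign = 1.0 if h[4] % 2 == 0 else -1.0
            v[idx] += sign
        norm = np.linalg.norm(v)
        if norm > 0:
            v /= norm
        self._cache_store(text, v)
        return DiagnosisEmbedding(v, self.provider_id)

    def _cache_key(self, text: str) -> str:
        th = hashlib.sha256(text.encode()).hexdigest()[:24]
        return f"{self.provider_id}-{th}.json"

    def _cache_load(self, text: str) -> np.ndarray | None:
        if not self.cache_dir:
            return None
        p = self.cache_dir / self._cache_key(text)
        if p.exists():
            return np.array(json.loads(p.read_text()))
        return None

    def _cache_store(self, text: str, v: np.ndarray) -> None:
        if self.cache_dir:
            p = self.cache_dir / self._cache_key(text)
            p.write_text(json.dumps(v.tolist()))


def embed_diagnosis(
    text: str, provider: HashingEmbeddingProvider | None = None
) -> DiagnosisEmbedding:
    """Embed free-text diagnosis into a deterministic 768-d unit vector."""
    provider = provider or HashingEmbeddingProvider()
    return provider.embed(text)


def hospital_frequency_table(metas: list[EpisodeMetadata]) -> dict[str, int]:
    """Cohort-level hospital retrieval counts (for the <10 grouping rule)."""
    counts: dict[str, int] = {}
    for m in metas:
        for h in (m.referring_hospital, m.destination_hospital):
            counts[h] = counts.get(h, 0) + 1
    return counts
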