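"""Shared fixtures: small deterministic cohorts and one desk-scale trained
model stack reused by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from pcct_ews import labelling, models, preprocess, simulate, windows


@pytest.fixture(scope="session")
def tiny_cohort():
    """10 short episodes, fast to generate, validated downstream."""
    cfg = simulate.SimulationConfig(
        n_episodes=10,
        duration_minutes_lognormal=(60.0, 0.3),
        max_duration_minutes=90.0,
        seed=42,
    )
    return simulate.generate_cohort(cfg)


def label_cohort(episodes):
    """Clean + label every episode in place (detected events appended)."""
    for ep in episodes:
        ep.series = preprocess.clean_vitals(ep.series)
        labelling.label_episode(ep)
    return episodes


def windows_from(episodes, input_hz=0.2, no_context=False):
    provider = preprocess.HashingEmbeddingProvider()
    samples = []
    for ep in episodes:
        base = preprocess.encode_baseline(ep.meta, "reduced")
        dx = provider.embed(ep.meta.diagnosis_text)
        samples.extend(
            windows.make_windows(ep, base, dx, input_hz=input_hz, no_context=no_context)
        )
    return samples


def split_data(episodes, samples, seed):
    split = windows.stratify_and_split(episodes, seed=seed)
    data = windows.stack_samples(samples)
    split_of = np.array([split.assignment[e] for e in data["episode_id"]])

    def sub(name):
        m = split_of == name
        return {k: v[m] for k, v in data.items()}

    return {"train": sub("train"), "tune": sub("tune"), "test": sub("test")}


@pytest.fixture(scope="session")
def labelled_tiny(tiny_cohort):
    episodes, truth = tiny_cohort
    return label_cohort(list(episodes)), truth


@pytest.fixture(scope="session")
def study_cohort():
    """The default study conditions: 200 episodes, default simulator config."""
    cfg = simulate.SimulationConfig(n_episodes=200, seed=11)
    episodes, truth = simulate.generate_cohort(cfg)
    return label_cohort(episodes), truth


@pytest.fixture(scope="session")
def study_splits(study_cohort):
    episodes, _ = study_cohort
    samples = windows_from(episodes, input_hz=0.2)
    return split_data(episodes, samples, seed=11)


@pytest.fixture(scope="session")
def trained_transformer(study_splits):
    """Combined transformer (vector diagnosis, reduced baseline) trained on
    the study cohort for the respiratory task."""
    tr, tu = study_splits["train"], study_splits["tune"]
    dims = models.FeatureDims(baseline=tr["baseline"].shape[1])
    hp = models.HyperParams(epochs=4, seed=0)
    model = models.build_model("combined_transformer_vector_reduced", hp, dims)
    models.train(model, tr, tu, "respiratory")
    return model
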