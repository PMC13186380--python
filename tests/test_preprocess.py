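"""Cleaning rules, LOCF, standardisation formulas, imputation masks and the
baseline/diagnosis encoders."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcct_ews import preprocess
from pcct_ews.preprocess import (
    FEATURE_CHANNELS,
    FULL_GROUPS,
    REDUCED_GROUPS,
    HashingEmbeddingProvider,
    carry_forward,
    clean_vitals,
    embed_diagnosis,
    encode_baseline,
    impute_and_mask,
    standardise,
    unstandardise,
)
from pcct_ews.schema import CHANNELS, CHANNEL_INDEX, EpisodeMetadata, EpisodeTimeSeries


def _series(n=600, fill=None):
    values = np.full((n, len(CHANNELS)), np.nan)
    observed = np.zeros((n, len(CHANNELS)), dtype=bool)
    if fill:
        for name, v in fill.items():
            values[:, CHANNEL_INDEX[name]] = v
            observed[:, CHANNEL_INDEX[name]] = True
    return EpisodeTimeSeries(np.arange(n), values, observed)


@pytest.mark.parametrize(
    "channel, value, kept",
    [
        ("hr", 25.0, False),     # below 30
        ("hr", 30.0, True),      # boundary retained
        ("hr", 301.0, False),
        ("spo2", 100.0, True),   # removal only above 100
        ("spo2", 9.9, False),
        ("etco2_max", 15.0, True),
        ("etco2_max", 15.1, False),
        ("nibp_mean", 4.9, False),
        ("temp_skin", 24.9, False),
        ("temp_skin", 25.0, True),
        ("temp_skin", 45.0, True),
    ],
)
def test_cleaning_bounds_are_exclusive(channel, value, kept):
    s = _series(fill={channel: value})
    out = clean_vitals(s)
    assert out.channel_observed(channel).all() == kept


def test_cleaning_is_idempotent():
    s = _series(fill={"hr": 25.0, "spo2": 97.0})
    once = clean_vitals(s)
    twice = clean_vitals(once)
    np.testing.assert_array_equal(once.observed, twice.observed)
    np.testing.assert_array_equal(
        np.nan_to_num(once.values), np.nan_to_num(twice.values)
    )


def test_locf_fills_between_nibp_samples_and_records_provenance():
    s = _series(n=400)
    j = CHANNEL_INDEX["nibp_mean"]
    s.values[[0, 300], j] = [70.0, 75.0]
    s.observed[[0, 300], j] = True
    out = carry_forward(s)
    assert np.all(out.values[1:300, j] == 70.0)
    assert np.all(out.values[301:, j] == 75.0)
    assert out.observed[:, j].all()
    assert out.carried[1:300, j].all() and not out.carried[0, j]


def test_locf_never_fills_before_first_observation_or_empty_channel():
    s = _series(n=200)
    j = CHANNEL_INDEX["temp_core"]
    s.values[100, j] = 37.0
    s.observed[100, j] = True
    out = carry_forward(s)
    assert not out.observed[:100, j].any()
    assert not out.observed[:, CHANNEL_INDEX["temp_skin"]].any()


def test_locf_leaves_one_hz_channels_untouched():
    s = _series(fill={"hr": 120.0})
    s.observed[5, CHANNEL_INDEX["hr"]] = False
    out = carry_forward(s)
    assert not out.observed[5, CHANNEL_INDEX["hr"]]


@pytest.mark.parametrize(
    "channel, raw, expected",
    [
        ("spo2", 97.0, 0.0),
        ("spo2", 91.0, -1.0),
        ("etco2_min", 5.25, 0.0),
        ("temp_core", 38.25, 1.0),
        ("temp_core", 36.75, 0.0),
    ],
)
def test_affine_standardisation_formulas(channel, raw, expected):
    s = _series(fill={channel: raw})
    out = standardise(s, age_years=5.0)
    np.testing.assert_allclose(out.channel(channel), expected, atol=1e-12)


def test_zscore_channel_at_reference_mean_maps_to_zero():
    from pcct_ews.reference import age_reference

    mean, _ = age_reference("hr", 5.0)
    s = _series(fill={"hr": mean})
    out = standardise(s, age_years=5.0)
    np.testing.assert_allclose(out.channel("hr"), 0.0, atol=1e-12)


@given(age=st.floats(min_value=-2.0, max_value=25.0))
@settings(max_examples=30, deadline=None)
def test_affine_standardisation_is_invertible(age):
    s = _series(fill={"spo2": 95.0, "hr": 110.0, "etco2_max": 5.0})
    back = unstandardise(standardise(s, age), age)
    np.testing.assert_allclose(
        np.nan_to_num(back.values), np.nan_to_num(s.values), atol=1e-9
    )


def test_feature_matrix_shape_and_mask_semantics():
    s = _series(n=120, fill={"hr": 120.0})
    s.observed[10, CHANNEL_INDEX["hr"]] = False
    s.values[10, CHANNEL_INDEX["hr"]] = np.nan
    std = standardise(clean_vitals(s), 5.0)
    flags = np.zeros((120, 2))
    fm = impute_and_mask(std, flags)
    assert fm.shape == (120, 36)
    assert len(FEATURE_CHANNELS) == 18
    assert set(np.unique(fm[:, 18:])) <= {0.0, 1.0}
    # imputed cells are exactly (0, 0) pairs
    j = CHANNEL_INDEX["hr"]
    assert fm[10, j] == 0.0 and fm[10, 18 + j] == 0.0
    assert np.isfinite(fm).all()


def test_feature_matrix_finite_across_simulator_seeds(labelled_tiny):
    from pcct_ews.windows import preprocess_episode

    episodes, _ = labelled_tiny
    for ep in episodes:
        fm, _ = preprocess_episode(ep)
        assert fm.shape[1] == 36
        assert np.isfinite(fm).all()


# -- baseline encoding -------------------------------------------------------


def _meta(**kw):
    base = dict(
        episode_id="m", age_years=9.0, weight_kg=30.0, sex="female",
        pim3=0.04, diagnosis_category="respiratory",
        destination_care_area="picu", resp_support="ett",
    )
    base.update(kw)
    return EpisodeMetadata(**base)


def test_reduced_baseline_covers_exactly_nine_groups():
    assert len(REDUCED_GROUPS) == 9
    assert len(FULL_GROUPS) == 30


def test_minmax_scaling_and_missing_imputation():
    v = encode_baseline(_meta()).as_dict()
    assert v["age"] == pytest.approx(0.5)  # 9 years over [0, 18]
    assert v["pim3"] == pytest.approx(0.04)
    missing = encode_baseline(_meta(pim3=None, sex="missing")).as_dict()
    assert missing["pim3"] == -1.0
    assert missing["sex"] == -1.0


def test_one_hot_blocks_sum_to_at_most_one():
    v = encode_baseline(_meta(), "reduced")
    for prefix in ("care_area", "dx", "resp"):
        block = [x for n, x in zip(v.names, v.values) if n.startswith(prefix + ":")]
        assert sum(block) <= 1.0


def test_unknown_category_maps_to_other_slot_never_dropped():
    v = encode_baseline(_meta(destination_care_area="submarine")).as_dict()
    assert v["care_area:other"] == 1.0


def test_full_baseline_groups_rare_hospitals_as_other():
    counts = {"H01": 25, "H02": 4}
    v = encode_baseline(
        _meta(referring_hospital="H02"), "full", hospital_counts=counts
    ).as_dict()
    assert v["ref_hosp:other"] == 1.0
    assert v["ref_hosp:H01"] == 0.0


def test_day_night_flag_from_team_arrival_time():
    night = encode_baseline(_meta(team_arrival_time="02:30"), "full", {}).as_dict()
    day = encode_baseline(_meta(team_arrival_time="14:00"), "full", {}).as_dict()
    assert night["night_shift"] == 1.0 and day["night_shift"] == 0.0


def test_reduced_and_full_orderings_are_stable():
    a = encode_baseline(_meta(), "full", {"H01": 12})
    b = encode_baseline(_meta(weight_kg=10.0), "full", {"H01": 12})
    assert a.names == b.names


# -- diagnosis embedding -----------------------------------------------------


def test_embedding_is_768d_unit_norm_and_deterministic():
    a = embed_diagnosis("severe asthma exacerbation")
    b = embed_diagnosis("severe asthma exacerbation")
    assert a.vector.shape == (768,)
    np.testing.assert_allclose(np.linalg.norm(a.vector), 1.0)
    np.testing.assert_array_equal(a.vector, b.vector)


def test_distinct_texts_embed_below_identity_similarity():
    a = embed_diagnosis("bronchiolitis with respiratory failure").vector
    b = embed_diagnosis("traumatic brain injury").vector
    assert a @ b < 0.99


def test_empty_text_warns_and_returns_zero_vector():
    with pytest.warns(UserWarning, match="empty"):
        e = embed_diagnosis("   ")
    assert not e.vector.any()


def test_embedding_cache_roundtrip(tmp_path):
    p1 = HashingEmbeddingProvider(cache_dir=tmp_path)
    v1 = p1.embed("septic shock").vector
    p2 = HashingEmbeddingProvider(cache_dir=tmp_path)
    v2 = p2.embed("septic shock").vector
    np.testing.assert_array_equal(v1, v2)
    assert len(list(tmp_path.iterdir())) == 1
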