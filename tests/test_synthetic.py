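import numpy as np
import pytest

from eplff.synthetic import (
    BatchSpec,
    DriftState,
    OdorantProfile,
    advance_drift,
    aging_drift,
    generate_dataset,
    make_distractor,
    make_profiles,
    pairwise_angle_deg,
    profiles_from_yaml,
    profiles_to_yaml,
    sample_response,
)


def test_profile_response_monotone_in_concentration():
    p = make_profiles(1, seed=0)[0]
    resp = np.stack([p.response(c) for c in (10.0, 100.0, 1000.0)])
    assert np.all(np.diff(resp, axis=0) >= 0)


def test_power_law_response_exact():
    p = OdorantProfile(label="x", affinities=np.array([1.0, 0.5]), hill=0.5)
    np.testing.assert_allclose(p.response(400.0), np.array([1.0, 0.5]) * 2.0)


def test_profile_validation():
    with pytest.raises(ValueError):
        OdorantProfile(label="x", affinities=np.zeros(3))
    with pytest.raises(ValueError):
        OdorantProfile(label="x", affinities=np.ones(3), hill=0.0)
    with pytest.raises(ValueError):
        OdorantProfile(label="x", affinities=np.ones(3), half_max=np.zeros(3))


@pytest.mark.parametrize("seed", [0, 5])
def test_make_profiles_separation(seed):
    profiles = make_profiles(4, min_pairwise_angle=30.0, seed=seed)
    for i in range(4):
        for j in range(i + 1, 4):
            ang = pairwise_angle_deg(profiles[i].affinities, profiles[j].affinities)
            assert ang >= 30.0 - 1e-9


def test_make_profiles_deterministic():
    a = make_profiles(3, seed=11)
    b = make_profiles(3, seed=11)
    for p, q in zip(a, b):
        np.testing.assert_array_equal(p.affinities, q.affinities)


def test_make_profiles_unreachable_angle_raises():
    with pytest.raises(ValueError):
        make_profiles(2, min_pairwise_angle=95.0)


def test_make_distractor_angle(small_profiles):
    d = make_distractor(small_profiles, min_angle=60.0, seed=4)
    for p in small_profiles:
        assert pairwise_angle_deg(d.affinities, p.affinities) >= 60.0 - 1e-9


def test_drift_state_validation():
    with pytest.raises(ValueError):
        DriftState(gain=np.array([1.0, 0.0]))
    with pytest.raises(ValueError):
        DriftState(gain=np.ones(2), noise_sd=-1.0)


def test_advance_drift_gain_decay():
    d = DriftState.fresh(4, decay_per_month=0.9)
    aged = advance_drift(d, 2.0)
    np.testing.assert_allclose(aged.gain, 0.81)
    np.testing.assert_array_equal(d.gain, np.ones(4))  # original untouched


def test_advance_drift_zero_months_is_identity():
    d = DriftState.fresh(4, rotation_strength=0.1)
    aged = advance_drift(d, 0.0)
    assert aged.rotation is None
    np.testing.assert_array_equal(aged.gain, d.gain)


def test_advance_drift_rotation_is_orthogonal():
    d = DriftState.fresh(6, rotation_strength=0.05)
    aged = advance_drift(d, 10.0)
    R = aged.rotation
    np.testing.assert_allclose(R @ R.T, np.eye(6), atol=1e-10)


def test_advance_drift_negative_months():
    with pytest.raises(ValueError):
        advance_drift(DriftState.fresh(2), -1.0)


def test_aging_drift_heterogeneous():
    d = aging_drift(16, seed=3)
    decay = np.asarray(d.decay_per_month)
    assert decay.shape == (16,)
    # the nominal spread is always fully realized, in seeded random order
    assert decay.min() == pytest.approx(0.96)
    assert decay.max() == pytest.approx(1.0)
    assert np.unique(decay).size == 16
    assert not np.all(np.diff(decay) >= 0)
    assert d.rotation_strength == pytest.approx(0.015)


def test_aging_drift_invalid_range():
    with pytest.raises(ValueError):
        aging_drift(decay_range=(1.1, 1.2))


def test_sample_response_noiseless_is_deterministic():
    p = make_profiles(1, seed=2)[0]
    a = sample_response(p, 100.0, seed=1)
    b = sample_response(p, 100.0, seed=99)  # seed irrelevant without noise
    np.testing.assert_array_equal(a.features, b.features)
    np.testing.assert_allclose(a.features, p.response(100.0) * 100.0)


def test_sample_response_rejects_bad_concentration():
    p = make_profiles(1, seed=2)[0]
    with pytest.raises(ValueError):
        sample_response(p, 0.0)


def test_sample_response_clamps_negative_noise():
    p = make_profiles(1, seed=2)[0]
    drift = DriftState.fresh(16, noise_sd=1e4)
    s = sample_response(p, 100.0, drift, seed=0)
    assert np.all(s.features >= 0)


def test_generate_dataset_structure():
    profiles = make_profiles(3, seed=1, labels=["a", "b", "c"])
    specs = [
        BatchSpec(n_samples=30, conc_range=(10.0, 1000.0), months=0.0, batch_id=1),
        BatchSpec(n_samples=12, months=5.0, batch_id=2),
    ]
    batches = generate_dataset(profiles, specs, seed=9)
    assert [len(b) for b in batches] == [30, 12]
    labels = batches[0].labels()
    assert all(labels.count(lab) == 10 for lab in ("a", "b", "c"))
    concs = batches[0].concentrations()
    assert np.all((concs >= 10.0) & (concs <= 1000.0))


def test_generate_dataset_deterministic():
    profiles = make_profiles(2, seed=1)
    specs = [BatchSpec(n_samples=8, batch_id=1)]
    a = generate_dataset(profiles, specs, seed=4)[0]
    b = generate_dataset(profiles, specs, seed=4)[0]
    np.testing.assert_array_equal(a.feature_matrix(), b.feature_matrix())


def test_generate_dataset_months_must_be_nondecreasing():
    profiles = make_profiles(1, seed=1)
    specs = [BatchSpec(n_samples=2, months=5.0, batch_id=1), BatchSpec(n_samples=2, months=1.0, batch_id=2)]
    with pytest.raises(ValueError, match="non-decreasing"):
        generate_dataset(profiles, specs)


def test_profiles_yaml_roundtrip(tmp_path, small_profiles):
    path = tmp_path / "p.yaml"
    profiles_to_yaml(small_profiles, path)
    back = profiles_from_yaml(path)
    for p, q in zip(small_profiles, back):
        assert p.label == q.label
        np.testing.assert_allclose(p.affinities, q.affinities)
        np.testing.assert_allclose(p.half_max, q.half_max)
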