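"""Synthetic chemosensor-array generator.

Emulates the statistical structure the classifier relies on: per-odorant
sensor affinity profiles, a monotone saturating concentration-response
curve, additive sensor noise, and slow multiplicative/rotational drift of
the sensor array across batches.  It makes no attempt to model the physics
of any particular sensor technology; its purpose is to provide data whose
generative parameters are known exactly, so every pipeline stage can be
tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.linalg import expm

from .datasets import Batch, SensorSample, SYNTHETIC

#: multiplies the dimensionless affinity x response product into
#: sensor-unit territory (order of the real dataset's steady-state values).
DEFAULT_RESPONSE_SCALE = 100.0


@dataclass(frozen=True)
class OdorantProfile:
    """Per-odorant sensor tuning.

    ``affinities`` are relative sensitivities in [0, 1]; ``half_max`` holds
    per-sensor half-saturation concentrations (ppmv) of a Hill response, or
    ``None`` for a pure power-law response ``(C / conc_ref) ** hill`` that
    never saturates (useful when an exactly invertible concentration-sum
    relation is wanted, e.g. ``hill=0.5`` makes the summed response scale
    as sqrt(C)).
    """

    label: str
    affinities: np.ndarray
    half_max: np.ndarray | None = None
    hill: float = 1.0
    conc_ref: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "affinities", np.asarray(self.affinities, dtype=float))
        if self.half_max is not None:
            object.__setattr__(self, "half_max", np.asarray(self.half_max, dtype=float))
            if np.any(self.half_max <= 0):
                raise ValueError("half_max entries must be positive")
        if not np.any(self.affinities > 0):
            raise ValueError("profile needs at least one positive affinity")
        if self.hill <= 0:
            raise ValueError("hill exponent must be positive")

    @property
    def n_sensors(self) -> int:
        return self.affinities.shape[0]

    def response(self, concentration: float) -> np.ndarray:
        """Noise- and drift-free sensor response direction at ``concentration``."""
        c = float(concentration)
        if self.half_max is None:
            r = (c / self.conc_ref) ** self.hill
            return self.affinities * r
        ch = c**self.hill
        return self.affinities * ch / (ch + self.half_max**self.hill)


def pairwise_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cos = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


_SEPARATION_CHECK_CONC = 1000.0


def _separation_ok(
    cand: "OdorantProfile",
    others: Sequence["OdorantProfile"],
    min_angle: float,
) -> bool:
    """True when ``cand`` subtends at least ``min_angle`` degrees with every
    profile in ``others``, both as raw affinity vectors and as high-
    concentration response vectors after per-sensor max scaling.

    The second check matters because the pipeline scales each sensor by its
    observed maximum response: that diagonal transform does not preserve
    angles, and a pair well separated in affinity space can collapse onto
    each other after scaling.  Evaluating responses near the top of the
    concentration range (where per-odorant saturation differences are
    largest) emulates the empirical scale fit, keeping the nominal
    separation meaningful in the coordinates the network actually sees.
    """
    if not others:
        return True
    responses = np.stack(
        [p.response(_SEPARATION_CHECK_CONC) for p in list(others) + [cand]]
    )
    col_max = responses.max(axis=0)
    col_max = np.where(col_max > 0, col_max, 1.0)
    scaled = responses / col_max
    cand_w = scaled[-1]
    for k, other in enumerate(others):
        if pairwise_angle_deg(cand.affinities, other.affinities) < min_angle:
            return False
        if pairwise_angle_deg(cand_w, scaled[k]) < min_angle:
            return False
    return True


def _draw_profile(
    rng: np.random.Generator,
    n_sensors: int,
    n_active: int,
    baseline: float,
    half_max_range: tuple[float, float] | None,
    hill: float,
    label: str,
    per_sensor_half_max: bool = False,
    active_probs: np.ndarray | None = None,
) -> OdorantProfile:
    affin = np.full(n_sensors, baseline)
    active = rng.choice(n_sensors, size=n_active, replace=False, p=active_probs)
    affin[active] = rng.uniform(0.4, 1.0, size=n_active)
    if half_max_range is None:
        half_max = None
    else:
        lo, hi = half_max_range
        size = n_sensors if per_sensor_half_max else None
        draw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))
        half_max = np.broadcast_to(np.atleast_1d(draw), (n_sensors,)).copy()
    return OdorantProfile(label=label, affinities=affin, half_max=half_max, hill=hill)


def make_profiles(
    n_classes: int,
    n_sensors: int = 16,
    min_pairwise_angle: float = 30.0,
    seed: int | np.random.Generator = 0,
    n_active: int = 6,
    baseline: float = 0.1,
    half_max_range: tuple[float, float] | None = (50.0, 500.0),
    hill: float = 1.0,
    labels: Sequence[str] | None = None,
    max_retries: int = 2000,
    per_sensor_half_max: bool = False,
) -> list[OdorantProfile]:
    """Draw ``n_classes`` affinity profiles, resampling until every pair is
    separated by at least ``min_pairwise_angle`` degrees — both as raw
    affinity vectors and after per-sensor max scaling (see
    :func:`_separation_ok`).

    Each profile is strongly sensitive on a random ``n_active``-sensor
    subset and weakly (``baseline``) sensitive everywhere else, mimicking
    broadly tuned, poorly selective chemosensors; the nonzero baseline
    keeps every sensor responsive to every odorant, so no sensor's
    empirical scale collapses toward zero.  By default every sensor
    shares one per-odorant half-saturation concentration, so the clean
    response direction is concentration-invariant (the regime the
    sum-normalization preprocessor is designed for);
    ``per_sensor_half_max=True`` lets saturation warp the profile across
    concentrations instead.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if not 0 <= min_pairwise_angle < 90:
        raise ValueError("min_pairwise_angle must be in [0, 90)")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"odorant_{i + 1}" for i in range(n_classes)]
    profiles: list[OdorantProfile] = []
    for label in labels[:n_classes]:
        for _ in range(max_retries):
            cand = _draw_profile(
                rng, n_sensors, n_active, baseline, half_max_range, hill, label,
                per_sensor_half_max=per_sensor_half_max,
            )
            if _separation_ok(cand, profiles, min_pairwise_angle):
                profiles.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place profile {label!r} with pairwise angle >= "
                f"{min_pairwise_angle} deg after {max_retries} tries; "
                "reduce min_pairwise_angle or n_classes"
            )
    return profiles


def make_distractor(
    profiles: Sequence[OdorantProfile],
    min_angle: float = 60.0,
    seed: int | np.random.Generator = 0,
    label: str = "distractor",
    n_active: int = 6,
    baseline: float = 0.05,
    max_retries: int = 20000,
) -> OdorantProfile:
    """Draw a held-out odorant profile at least ``min_angle`` degrees from
    every trained profile, for none-of-the-above testing.

    Candidate active sensors are proposed preferentially where the trained
    profiles are weakest (a genuinely novel odorant excites the under-used
    corners of the array); the angle requirement is still verified
    explicitly against every profile before a candidate is accepted.
    """
    rng = np.random.default_rng(seed)
    ref = profiles[0]
    usage = np.sum([p.affinities for p in profiles], axis=0)
    inv = 1.0 / (usage + 1e-9)
    active_probs = inv / inv.sum()
    for _ in range(max_retries):
        cand = _draw_profile(
            rng,
            ref.n_sensors,
            n_active,
            baseline,
            None if ref.half_max is None else (50.0, 500.0),
            ref.hill,
            label,
            active_probs=active_probs,
        )
        if _separation_ok(cand, list(profiles), min_angle):
            return cand
    raise RuntimeError(
        f"could not place a distractor >= {min_angle} deg from all profiles"
    )


@dataclass
class DriftState:
    """Multiplicative + rotational sensor degradation.

    ``gain`` multiplies each sensor's response (fresh sensors: all ones);
    ``decay_per_month`` compounds the gains down as months pass;
    ``rotation_strength`` (radians/month) grows a random orthogonal mixing
    of the response axes, emulating selectivity drift; ``noise_sd`` is
    additive Gaussian sensor noise (sensor units) and ``noise_relative``
    multiplicative Gaussian noise (fraction of the clean response) — real
    chemosensor noise grows with the response, so a "5% noise" condition
    maps to ``noise_relative=0.05`` rather than to 5% of full scale.
    """

    gain: np.ndarray
    noise_sd: float = 0.0
    noise_relative: float = 0.0
    decay_per_month: np.ndarray | float = 1.0
    rotation_strength: float = 0.0
    rotation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if np.any(self.gain <= 0):
            raise ValueError("gain entries must be positive")
        if self.noise_sd < 0 or self.rotation_strength < 0 or self.noise_relative < 0:
            raise ValueError("noise terms and rotation_strength must be >= 0")

    @classmethod
    def fresh(cls, n_sensors: int, **kwargs) -> "DriftState":
        return cls(gain=np.ones(n_sensors), **kwargs)

    def apply(self, clean: np.ndarray) -> np.ndarray:
        mixed = clean if self.rotation is None else self.rotation @ clean
        return self.gain * mixed


def aging_drift(
    n_sensors: int = 16,
    noise_relative: float = 0.05,
    decay_range: tuple[float, float] = (0.96, 1.0),
    rotation_per_month: float = 0.015,
    seed: int = 0,
) -> DriftState:
    """Canonical sensor-aging condition for drift studies.

    Each sensor gets its own monthly decay factor: the factors are evenly
    spaced across ``decay_range`` and assigned to sensors in seeded random
    order.  Heterogeneous decay is what makes aging damaging — a uniform
    gain loss is a pure rescaling that the concentration-tolerance
    normalization removes, whereas sensors fading at different rates warp
    the response *directions* the classifier relies on.  The even spacing
    guarantees every realization exhibits the nominal spread (i.i.d. draws
    can by chance land nearly uniform, producing an almost harmless
    condition).  ``rotation_per_month`` adds a slow random mixing of the
    response axes (selectivity drift) on top.
    """
    rng = np.random.default_rng(seed)
    lo, hi = decay_range
    if not 0 < lo <= hi <= 1:
        raise ValueError("decay_range must satisfy 0 < lo <= hi <= 1")
    decay = rng.permutation(np.linspace(lo, hi, n_sensors))
    return DriftState.fresh(
        n_sensors,
        noise_relative=noise_relative,
        decay_per_month=decay,
        rotation_strength=rotation_per_month,
        seed=seed + 1,
    )


def advance_drift(drift: DriftState, months: float) -> DriftState:
    """Age the sensor array by ``months``: gains decay multiplicatively and
    the response axes receive a random rotation of magnitude
    ``rotation_strength * months`` radians.  ``months=0`` is the identity."""
    if months < 0:
        raise ValueError("months must be >= 0")
    if months == 0:
        return replace(drift)
    gain = drift.gain * np.asarray(drift.decay_per_month, dtype=float) ** months
    rotation = drift.rotation
    if drift.rotation_strength > 0:
        rng = np.random.default_rng(drift.seed)
        n = drift.gain.shape[0]
        a = rng.standard_normal((n, n))
        skew = a - a.T
        skew *= drift.rotation_strength * months / np.linalg.norm(skew, 2)
        step = expm(skew)  # orthogonal: exp of a skew-symmetric matrix
        rotation = step if rotation is None else step @ rotation
    return replace(drift, gain=gain, rotation=rotation, seed=drift.seed + 1)


def sample_response(
    profile: OdorantProfile,
    concentration: float,
    drift: DriftState | None = None,
    seed: int | np.random.Generator = 0,
    scale: float = DEFAULT_RESPONSE_SCALE,
    batch_id: int | str = SYNTHETIC,
) -> SensorSample:
    """One noisy sensor-array reading of ``profile`` at ``concentration``.

    features_i = gain_i * [R (affinities * response(C))]_i * scale
                 + N(0, noise_sd), clamped at 0.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    clean = profile.response(concentration) * scale
    if drift is None:
        drift = DriftState.fresh(profile.n_sensors)
    feats = drift.apply(clean)
    if drift.noise_relative > 0:
        feats = feats * (1.0 + rng.normal(0.0, drift.noise_relative, size=feats.shape))
    if drift.noise_sd > 0:
        feats = feats + rng.normal(0.0, drift.noise_sd, size=feats.shape)
    feats = np.maximum(feats, 0.0)
    return SensorSample(
        features=feats,
        label=profile.label,
        concentration=float(concentration),
        batch_id=batch_id,
    )


@dataclass
class BatchSpec:
    """Per-batch generation recipe: sample count, concentration range
    (ppmv, sampled log-uniformly) and the array's age in months."""

    n_samples: int
    conc_range: tuple[float, float] = (10.0, 1000.0)
    months: float = 0.0
    batch_id: int | str = SYNTHETIC


def generate_batch(
    profiles: Sequence[OdorantProfile],
    spec: BatchSpec,
    drift: DriftState,
    rng: np.random.Generator,
    scale: float = DEFAULT_RESPONSE_SCALE,
) -> Batch:
    lo, hi = spec.conc_range
    # as-balanced-as-possible class assignment, order shuffled
    reps = int(np.ceil(spec.n_samples / len(profiles)))
    idx = np.tile(np.arange(len(profiles)), reps)[: spec.n_samples]
    rng.shuffle(idx)
    concs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_samples))
    samples = [
        sample_response(
            profiles[i], c, drift, seed=rng, scale=scale, batch_id=spec.batch_id
        )
        for i, c in zip(idx, concs)
    ]
    return Batch(batch_id=spec.batch_id, samples=samples)


def generate_dataset(
    profiles: Sequence[OdorantProfile],
    batches_spec: Sequence[BatchSpec],
    seed: int | np.random.Generator = 0,
    base_drift: DriftState | None = None,
    scale: float = DEFAULT_RESPONSE_SCALE,
) -> list[Batch]:
    """Generate a reproducible multi-batch dataset; each batch's drift state
    is the base state aged to that batch's ``months``."""
    rng = np.random.default_rng(seed)
    if base_drift is None:
        base_drift = DriftState.fresh(profiles[0].n_sensors)
    batches = []
    current = base_drift
    elapsed = 0.0
    for spec in batches_spec:
        if spec.months < elapsed:
            raise ValueError("batch months must be non-decreasing")
        current = advance_drift(current, spec.months - elapsed)
        elapsed = spec.months
        batches.append(generate_batch(profiles, spec, current, rng, scale=scale))
    return batches


# ---------------------------------------------------------------------------
# YAML config round-trip for generator setups
# ---------------------------------------------------------------------------

def profiles_to_yaml(profiles: Sequence[OdorantProfile], path) -> None:
    data = [
        {
            "label": p.label,
            "affinities": p.affinities.tolist(),
            "half_max": None if p.half_max is None else p.half_max.tolist(),
            "hill": p.hill,
            "conc_ref": p.conc_ref,
        }
        for p in profiles
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def profiles_from_yaml(path) -> list[OdorantProfile]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [
        OdorantProfile(
            label=d["label"],
            affinities=np.array(d["affinities"]),
            half_max=None if d["half_max"] is None else np.array(d["half_max"]),
            hill=d["hill"],
            conc_ref=d.get("conc_ref", 100.0),
        )
        for d in data
    ]
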