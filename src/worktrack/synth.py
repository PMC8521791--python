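"""Synthetic 9-channel wrist-IMU sessions for the telework protocol.

No recordings of the original 12-subject experiment are publicly available,
so this module generates labeled surrogate sessions with the same protocol
structure (ten episodes: walking, standing/sitting neutral, and two rounds
of reading/typing/writing, 48 min total) and the qualitative class geometry
reported for the real data: walking is by far the most distinct class, the
three working classes resemble one another, standing-neutral sits close to
typing, and lying has its own attitude baseline.

Signal model per channel::

    x(t) = baseline + posture_offset            (attitude channels only)
         + amplitude_mult * sum_k A_k sin(2*pi*f_k*pace*t + phi_k) * gate(t)
         + correlated Gaussian noise

``gate(t)`` is a Bernoulli bout process on 0.5-s blocks with per-class duty
cycle ("burstiness") — typing is bursty and fast, reading slow and sparse.
Inter-subject variation is dominated by a pace multiplier on all oscillation
frequencies, with secondary amplitude and wrist-posture random effects, so
leave-one-subject-out validation is measurably harder than sample-level
cross-validation.

Reproducibility is hierarchical: a cohort seed spawns per-subject seeds,
which spawn per-episode seeds, so any subject or episode can be regenerated
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidCountError, InvalidDurationError, InvalidRateError
from .streams import ACTIVITY_CLASSES, DEFAULT_RATE_HZ, N_CHANNELS, SensorStream

#: Attitude channel indices (yaw, roll, pitch) in canonical order.
ATTITUDE_IDX = (3, 4, 5)

#: Duration of one Bernoulli bout block, seconds.
BOUT_BLOCK_S = 0.5


@dataclass(frozen=True)
class ClassSignalSpec:
    """Signal recipe for one activity class.

    ``components`` is a tuple of ``(frequency_hz, amplitudes)`` oscillators,
    amplitudes being per-channel 9-vectors in the channel's native unit.
    ``burstiness`` is the fraction of 0.5-s blocks in which the oscillators
    are active.  ``mixing`` is an invertible 9x9 matrix whose rows are
    normalized at sampling time so that each channel's noise SD equals
    ``noise_sd`` while off-diagonal structure induces cross-channel
    correlation (the substrate of the cooperativity feature).
    """

    label: str
    baseline: np.ndarray
    components: tuple[tuple[float, np.ndarray], ...]
    burstiness: float
    noise_sd: np.ndarray
    mixing: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline", np.asarray(self.baseline, dtype=float))
        object.__setattr__(self, "noise_sd", np.asarray(self.noise_sd, dtype=float))
        object.__setattr__(self, "mixing", np.asarray(self.mixing, dtype=float))
        comps = tuple((float(f), np.asarray(a, dtype=float)) for f, a in self.components)
        object.__setattr__(self, "components", comps)
        if self.baseline.shape != (N_CHANNELS,):
            raise ValueError("baseline must be a 9-vector")
        if self.noise_sd.shape != (N_CHANNELS,) or np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be a nonnegative 9-vector")
        if not 0.0 <= self.burstiness <= 1.0:
            raise ValueError("burstiness must lie in [0, 1]")
        for f, a in self.components:
            if f < 0 or a.shape != (N_CHANNELS,) or np.any(a < 0):
                raise ValueError("oscillator frequency/amplitudes must be nonnegative 9-vectors")
        if self.mixing.shape != (N_CHANNELS, N_CHANNELS) or abs(np.linalg.det(self.mixing)) < 1e-12:
            raise ValueError("mixing must be an invertible 9x9 matrix")


@dataclass(frozen=True)
class SubjectProfile:
    """Random effects of one simulated subject.

    ``pace_multiplier`` scales every oscillation frequency (the dominant
    inter-subject effect for the working activities); ``amplitude_multiplier``
    scales oscillation amplitudes; ``posture_offsets_rad`` perturbs the
    attitude baselines (yaw/roll/pitch).
    """

    subject_id: str
    pace_multiplier: float = 1.0
    amplitude_multiplier: float = 1.0
    posture_offsets_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pace_multiplier <= 0 or self.amplitude_multiplier <= 0:
            raise ValueError("pace and amplitude multipliers must be positive")


@dataclass(frozen=True)
class Episode:
    locomotion: str
    limb_movement: str
    duration_min: float
    label: str


@dataclass(frozen=True)
class Protocol:
    """Ordered sequence of labeled episodes."""

    episodes: tuple[Episode, ...]

    @property
    def total_minutes(self) -> float:
        return sum(e.duration_min for e in self.episodes)


def default_protocol() -> Protocol:
    """The 10-episode, 48-min session: walking, neutral postures, and two
    rounds of reading/typing/writing (standing then sitting)."""
    rows = [
        ("walking", "neutral", 10, "W_N"),
        ("standing", "neutral", 5, "St_N"),
        ("standing", "reading", 3, "Re"),
        ("standing", "typing", 3, "Ty"),
        ("standing", "writing", 3, "Wr"),
        ("sitting", "neutral", 5, "Si_N"),
        ("sitting", "reading", 3, "Re"),
        ("sitting", "typing", 3, "Ty"),
        ("sitting", "writing", 3, "Wr"),
        ("lying", "neutral", 10, "L_N"),
    ]
    return Protocol(tuple(Episode(*r) for r in rows))


def _mixing(couples: list[tuple[int, int, float]]) -> np.ndarray:
    m = np.eye(N_CHANNELS)
    for i, j, w in couples:
        m[i, j] = w
    return m


def default_class_specs() -> dict[str, ClassSignalSpec]:
    """Default signal recipes for the seven classes.

    Calibrated so that (a) walking carries large ~1.8 Hz oscillation on the
    acceleration and rotation-rate channels and is the most distinct class
    in feature space, (b) standing-neutral lies closer to typing than to
    walking, (c) lying has a clearly different attitude baseline, and
    (d) the three working classes differ mainly in burstiness, dominant
    frequency and which channels their motion loads on (typing: vertical
    acceleration + z rotation; writing: lateral acceleration + x rotation;
    reading: slow attitude rocking + y rotation).
    """
    z = np.zeros(N_CHANNELS)

    def amps(ax=0.0, ay=0.0, az=0.0, yaw=0.0, roll=0.0, pitch=0.0, rx=0.0, ry=0.0, rz=0.0):
        return np.array([ax, ay, az, yaw, roll, pitch, rx, ry, rz])

    def base(yaw, roll, pitch):
        return amps(yaw=yaw, roll=roll, pitch=pitch)

    specs = {
        "W_N": ClassSignalSpec(
            label="W_N",
            baseline=base(0.0, -0.3, 0.1),
            components=(
                (1.8, amps(0.25, 0.15, 0.30, 0.10, 0.30, 0.15, 1.5, 1.0, 2.2)),
                (3.6, amps(0.08, 0.05, 0.10, 0.02, 0.06, 0.03, 0.4, 0.3, 0.6)),
            ),
            burstiness=1.0,
            noise_sd=z + 0.03,
            mixing=_mixing([(0, 2, 0.6), (6, 8, 0.7), (4, 6, 0.5)]),
        ),
        "St_N": ClassSignalSpec(
            label="St_N",
            baseline=base(0.10, -0.50, 0.20),
            components=((0.3, amps(0.008, 0.008, 0.012, 0.010, 0.020, 0.015, 0.04, 0.03, 0.05)),),
            burstiness=1.0,
            noise_sd=z + 0.010,
            mixing=_mixing([(3, 4, 0.4)]),
        ),
        "Re": ClassSignalSpec(
            label="Re",
            baseline=base(0.15, -0.55, 0.35),
            components=((0.6, amps(0.010, 0.015, 0.010, 0.030, 0.050, 0.040, 0.08, 0.20, 0.06)),),
            burstiness=0.35,
            noise_sd=z + 0.012,
            mixing=_mixing([(4, 7, 0.5), (3, 5, 0.3)]),
        ),
        "Ty": ClassSignalSpec(
            label="Ty",
            baseline=base(0.05, -0.50, 0.25),
            components=((4.0, amps(0.015, 0.015, 0.045, 0.012, 0.020, 0.030, 0.06, 0.08, 0.30)),),
            burstiness=0.80,
            noise_sd=z + 0.015,
            mixing=_mixing([(2, 8, 0.6), (5, 8, 0.4)]),
        ),
        "Wr": ClassSignalSpec(
            label="Wr",
            baseline=base(0.20, -0.45, 0.30),
            components=((2.2, amps(0.040, 0.012, 0.015, 0.050, 0.030, 0.020, 0.35, 0.06, 0.08)),),
            burstiness=0.60,
            noise_sd=z + 0.012,
            mixing=_mixing([(0, 6, 0.6), (3, 6, 0.4)]),
        ),
        "Si_N": ClassSignalSpec(
            label="Si_N",
            baseline=base(0.30, -0.20, 0.50),
            components=((0.25, amps(0.005, 0.005, 0.008, 0.008, 0.012, 0.010, 0.02, 0.02, 0.03)),),
            burstiness=1.0,
            noise_sd=z + 0.008,
            mixing=_mixing([(4, 5, 0.3)]),
        ),
        "L_N": ClassSignalSpec(
            label="L_N",
            baseline=base(0.90, 0.80, -0.50),
            components=((0.2, amps(0.003, 0.004, 0.005, 0.006, 0.008, 0.008, 0.015, 0.015, 0.02)),),
            burstiness=1.0,
            noise_sd=z + 0.006,
            mixing=_mixing([(3, 4, 0.3)]),
        ),
    }
    assert set(specs) == set(ACTIVITY_CLASSES)
    return specs


def simulate_episode(
    spec: ClassSignalSpec,
    profile: SubjectProfile,
    duration_s: float,
    rate: float = DEFAULT_RATE_HZ,
    seed: int = 0,
    t0: float = 0.0,
) -> SensorStream:
    """Simulate one constant-activity episode of ``floor(duration*rate)`` samples."""
    if duration_s <= 0:
        raise InvalidDurationError(f"duration must be positive, got {duration_s}")
    if rate <= 0:
        raise InvalidRateError(f"rate must be positive, got {rate}")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_s * rate))
    t = np.arange(n) / rate

    sig = np.tile(spec.baseline, (n, 1))
    sig[:, ATTITUDE_IDX] += np.asarray(profile.posture_offsets_rad)

    # Bernoulli bout gate on 0.5-s blocks, shared by all oscillators.
    block = max(1, int(round(BOUT_BLOCK_S * rate)))
    n_blocks = -(-n // block)
    if spec.burstiness >= 1.0:
        gate = np.ones(n)
    else:
        active = rng.random(n_blocks) < spec.burstiness
        gate = np.repeat(active.astype(float), block)[:n]

    for f, amp in spec.components:
        phase = rng.uniform(0.0, 2.0 * np.pi, N_CHANNELS)
        osc = np.sin(2.0 * np.pi * f * profile.pace_multiplier * t[:, None] + phase)
        sig += profile.amplitude_multiplier * amp * osc * gate[:, None]

    # Row-normalized mixing keeps per-channel noise SD at noise_sd while
    # inducing the class-specific cross-channel correlation.
    rows = spec.mixing / np.linalg.norm(spec.mixing, axis=1, keepdims=True)
    white = rng.standard_normal((n, N_CHANNELS))
    sig += (white @ rows.T) * spec.noise_sd

    return SensorStream(
        subject_id=profile.subject_id,
        timestamps=t0 + t,
        values=sig,
        nominal_rate=rate,
        labels=np.full(n, spec.label, dtype=object),
    )


def simulate_protocol_session(
    profile: SubjectProfile,
    protocol: Protocol | None = None,
    rate: float = DEFAULT_RATE_HZ,
    seed: int | None = None,
    class_specs: dict[str, ClassSignalSpec] | None = None,
) -> SensorStream:
    """Simulate a full protocol session: concatenated labeled episodes with
    per-sample episode indices.

    ``seed`` defaults to the profile's own seed; per-episode seeds are
    spawned from it so each episode is independently reproducible.
    """
    protocol = protocol or default_protocol()
    if not protocol.episodes:
        raise ValueError("protocol must contain at least one episode")
    class_specs = class_specs or default_class_specs()
    root = np.random.SeedSequence(profile.seed if seed is None else seed)
    children = root.spawn(len(protocol.episodes))

    parts, labels, episode_ids = [], [], []
    t0 = 0.0
    for i, (ep, child) in enumerate(zip(protocol.episodes, children)):
        ep_seed = int(child.generate_state(1)[0])
        stream = simulate_episode(
            class_specs[ep.label], profile, ep.duration_min * 60.0, rate, ep_seed, t0=t0
        )
        parts.append(stream)
        labels.append(stream.labels)
        episode_ids.append(np.full(stream.n_samples, i, dtype=int))
        t0 += stream.n_samples / rate

    return SensorStream(
        subject_id=profile.subject_id,
        timestamps=np.concatenate([p.timestamps for p in parts]),
        values=np.concatenate([p.values for p in parts]),
        nominal_rate=rate,
        labels=np.concatenate(labels),
        episode_ids=np.concatenate(episode_ids),
    )


@dataclass(frozen=True)
class CohortRandomEffects:
    """Scales of the inter-subject random-effect distributions.

    Pace and amplitude multipliers are lognormal (log-SD below); posture
    offsets are normal in radians.  Defaults put most of the between-subject
    variance into pace, the dominant real-world difference for the working
    activities.
    """

    pace_log_sd: float = 0.15
    amplitude_log_sd: float = 0.20
    posture_sd_rad: float = 0.05


def draw_profiles(
    n_subjects: int,
    cohort_seed: int,
    effects: CohortRandomEffects | None = None,
) -> list[SubjectProfile]:
    """Draw ``n_subjects`` profiles with hierarchical seeding."""
    if n_subjects < 1:
        raise InvalidCountError(f"n_subjects must be >= 1, got {n_subjects}")
    effects = effects or CohortRandomEffects()
    root = np.random.SeedSequence(cohort_seed)
    children = root.spawn(n_subjects)
    profiles = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                pace_multiplier=float(np.exp(rng.normal(0.0, effects.pace_log_sd))),
                amplitude_multiplier=float(np.exp(rng.normal(0.0, effects.amplitude_log_sd))),
                posture_offsets_rad=tuple(rng.normal(0.0, effects.posture_sd_rad, 3)),
                seed=int(child.generate_state(1)[0]),
            )
        )
    return profiles


def simulate_cohort(
    n_subjects: int = 12,
    cohort_seed: int = 0,
    protocol: Protocol | None = None,
    rate: float = DEFAULT_RATE_HZ,
    effects: CohortRandomEffects | None = None,
    class_specs: dict[str, ClassSignalSpec] | None = None,
) -> list[SensorStream]:
    """Simulate a cohort of protocol sessions (default 12 subjects)."""
    profiles = draw_profiles(n_subjects, cohort_seed, effects)
    return [
        simulate_protocol_session(p, protocol, rate, class_specs=class_specs) for p in profiles
    ]
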