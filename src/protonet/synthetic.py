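"""Synthetic free-living cohort generator.

Emulates the statistical structure a wrist-worn accelerometer sees during
unscripted daily life of a mixed cohort (patients with rest tremor, patients
without tremor, controls):

* gravity (1 g) with piecewise-linear orientation drift,
* seven non-tremor activity sub-classes ``N1..N7`` — gait (~1.8 Hz periodic
  with harmonics), broadband postural transitions, running (~2.5-3 Hz, high
  amplitude), biking (~1 Hz plus vibration), "suspicious" periodic 3-5 Hz
  arm movement (a deliberate tremor confuser), other band-limited upper-limb
  activity, and rest (noise floor only),
* seven tremor movement sub-classes ``T1..T7`` with a stable per-subject
  fundamental frequency in 4-7 Hz plus a 2f harmonic, an Ornstein-Uhlenbeck
  log-amplitude envelope (bursty, non-stationary episodes), per-sub-class
  axis mixing, and gait superposed for the tremor-during-gait sub-class,
* white measurement noise,
* full interval annotations; the first clean interval of every sub-class
  per subject (plus a configurable extra fraction) is flagged as a
  prototypical example.

All randomness derives deterministically from a single master seed through
per-subject counter-based seed derivation, so cohorts are pure functions of
``(config, master_seed)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import (
    AnnotationTrack,
    Interval,
    RawRecording,
    TREMOR_SUBCLASSES,
    NONTREMOR_SUBCLASSES,
)

RAW_RATE_HZ = 200.0

# axis mixing (x, y, z) per tremor sub-class: wrist/finger flexion-extension
# concentrates on one axis, elbow flexion-extension on another,
# pronation-supination spreads over two axes, T7 rides on gait.
_TREMOR_AXIS_MIX = {
    "T1": (1.00, 0.15, 0.10),
    "T2": (0.90, 0.30, 0.15),
    "T3": (0.15, 1.00, 0.10),
    "T4": (0.25, 0.90, 0.20),
    "T5": (0.70, 0.10, 0.70),
    "T6": (0.10, 0.70, 0.70),
    "T7": (1.00, 0.25, 0.25),
}

#: correlation time (s) of the Ornstein-Uhlenbeck log-amplitude envelope
_OU_TAU_S = 5.0
_OU_SD = 0.35


@dataclass
class SubjectProfile:
    """Generation parameters for one synthetic subject.

    ``schedule`` holds ``(duration_s, kind)`` entries where ``kind`` is an
    activity token ``N1..N7`` or a tremor sub-class token ``T1..T7``; tremor
    entries may only appear when ``has_tremor`` is set.
    """

    subject_id: str
    has_tremor: bool
    tremor_freq_hz: float
    tremor_amp_g: float
    harmonic_ratio: float
    schedule: list[tuple[float, str]]
    drift_rate: float = 0.01  # rad/s scale of orientation drift slopes
    noise_sd_g: float = 0.02
    prototype_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.has_tremor and not (4.0 <= self.tremor_freq_hz <= 7.0):
            raise ValueError("tremor fundamental must lie in 4-7 Hz")
        if not self.schedule or sum(d for d, _ in self.schedule) <= 0:
            raise ValueError("schedule must have positive total duration")
        for dur, kind in self.schedule:
            if dur <= 0:
                raise ValueError(f"schedule entry with non-positive duration {dur}")
            if kind not in TREMOR_SUBCLASSES + NONTREMOR_SUBCLASSES:
                raise ValueError(f"unknown schedule kind {kind!r}")
            if kind in TREMOR_SUBCLASSES and not self.has_tremor:
                raise ValueError("tremor episodes scheduled for a non-tremor subject")


@dataclass
class CohortConfig:
    """Cohort composition and signal-level parameters.

    Default subject counts mirror the study population this generator stands
    in for: 8 patients with tremor, 16 patients without tremor, 24 controls.
    """

    n_tremor: int = 8
    n_pd_no_tremor: int = 16
    n_controls: int = 24
    duration_s: float = 600.0
    tremor_fraction: float = 0.30
    tremor_amp_range_g: tuple[float, float] = (0.08, 0.15)
    harmonic_ratio_range: tuple[float, float] = (0.1, 0.5)
    noise_sd_g: float = 0.02
    drift_rate: float = 0.01
    include_n5: bool = True
    confuser_freq_band_hz: tuple[float, float] = (3.0, 5.0)
    prototype_fraction: float = 0.4

    @property
    def n_subjects(self) -> int:
        return self.n_tremor + self.n_pd_no_tremor + self.n_controls

    @property
    def activities(self) -> tuple[str, ...]:
        acts = list(NONTREMOR_SUBCLASSES)
        if not self.include_n5:
            acts.remove("N5")
        return tuple(acts)


@dataclass
class SyntheticCohort:
    subjects: list[tuple[RawRecording, AnnotationTrack]]
    config: CohortConfig
    master_seed: int

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# per-kind signal synthesis (all return (n, 3) arrays in g)


def _periodic(t, rng, f0, amps, amp, axis_mix):
    """Sum of harmonics at f0 with random phases, mixed across axes."""
    out = np.zeros((len(t), 3))
    base = np.zeros(len(t))
    for h, a in enumerate(amps, start=1):
        base += a * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
    mix = np.asarray(axis_mix, dtype=float)
    mix = mix / np.linalg.norm(mix)
    return amp * base[:, None] * mix[None, :] + out


def _lowpass_noise(t, rng, cutoff_hz, amp):
    x = rng.standard_normal((len(t), 3))
    if len(t) > 30:
        b, a = sps.butter(2, cutoff_hz / (RAW_RATE_HZ / 2))
        x = sps.filtfilt(b, a, x, axis=0)
        x /= max(np.std(x), 1e-12)
    return amp * x


def _ou_envelope(t, rng, tau_s=_OU_TAU_S, sd=_OU_SD):
    """Exponentiated Ornstein-Uhlenbeck process: slowly varying log-normal
    amplitude modulation with correlation time ``tau_s``."""
    dt = 1.0 / RAW_RATE_HZ
    n = len(t)
    z = np.empty(n)
    z[0] = rng.standard_normal() * sd
    decay = 1.0 - dt / tau_s
    scale = sd * np.sqrt(2.0 * dt / tau_s)
    eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        z[i] = z[i - 1] * decay + scale * eps[i - 1]
    return np.exp(z - 0.5 * sd**2)


def _activity_component(kind, t, rng, cfg_band=(3.0, 5.0)):
    if kind == "N1":  # gait
        f0 = rng.uniform(1.7, 1.9)
        return _periodic(t, rng, f0, (1.0, 0.5, 0.25), 0.25, rng.uniform(0.4, 1.0, 3))
    if kind == "N2":  # postural transitions: broadband low-frequency transients
        return _lowpass_noise(t, rng, 1.5, 0.30)
    if kind == "N3":  # running / exercising
        f0 = rng.uniform(2.5, 3.0)
        return _periodic(t, rng, f0, (1.0, 0.6, 0.3), 0.8, rng.uniform(0.5, 1.0, 3))
    if kind == "N4":  # biking: ~1 Hz pedalling plus road vibration
        f0 = rng.uniform(0.9, 1.1)
        ped = _periodic(t, rng, f0, (1.0, 0.4), 0.15, rng.uniform(0.3, 1.0, 3))
        vib = _lowpass_noise(t, rng, 20.0, 0.04) - _lowpass_noise(t, rng, 8.0, 0.04)
        return ped + vib
    if kind == "N5":  # suspicious periodic upper-limb activity (confuser)
        f0 = rng.uniform(*cfg_band)
        env = _ou_envelope(t, rng)
        comp = _periodic(t, rng, f0, (1.0, 0.3), 0.12, rng.uniform(0.3, 1.0, 3))
        return comp * env[:, None]
    if kind == "N6":  # other upper-limb activity: band-limited noise bursts
        x = _lowpass_noise(t, rng, 6.0, 0.15)
        burst = _ou_envelope(t, rng, tau_s=3.0, sd=0.8)
        return x * burst[:, None]
    if kind == "N7":  # rest: noise floor only
        return np.zeros((len(t), 3))
    raise ValueError(f"unknown activity {kind!r}")


def _tremor_component(sub_class, t, rng, freq_hz, amp_g, harmonic_ratio):
    env = _ou_envelope(t, rng)
    phase0 = rng.uniform(0, 2 * np.pi)
    phase1 = rng.uniform(0, 2 * np.pi)
    osc = np.sin(2 * np.pi * freq_hz * t + phase0)
    osc = osc + harmonic_ratio * np.sin(2 * np.pi * 2 * freq_hz * t + phase1)
    mix = np.asarray(_TREMOR_AXIS_MIX[sub_class], dtype=float)
    mix = mix / np.linalg.norm(mix)
    return amp_g * (env * osc)[:, None] * mix[None, :]


def _gravity(t, rng, drift_rate):
    """Unit-gravity vector with piecewise-linear orientation drift."""
    n = len(t)
    n_breaks = max(2, int(t[-1] / 30.0) + 2)
    knots_t = np.linspace(0.0, t[-1] + 1.0 / RAW_RATE_HZ, n_breaks)
    theta0, phi0 = rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)
    dtheta = np.cumsum(rng.uniform(-1, 1, n_breaks) * drift_rate * 30.0)
    dphi = np.cumsum(rng.uniform(-1, 1, n_breaks) * drift_rate * 30.0)
    theta = np.interp(t, knots_t, theta0 + dtheta)
    phi = np.interp(t, knots_t, phi0 + dphi)
    return np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )


# ---------------------------------------------------------------------------
# subject / cohort generation


def generate_subject(profile: SubjectProfile) -> tuple[RawRecording, AnnotationTrack]:
    """Synthesize one subject's 200 Hz recording plus its annotation track.

    The signal is ``gravity(with drift) + activity + tremor + white noise``;
    every schedule entry becomes one annotated interval. Per sub-class, the
    first interval and a ``prototype_fraction`` random share of the rest are
    flagged as prototypical examples.
    """
    rng = np.random.default_rng(profile.seed)
    total = sum(d for d, _ in profile.schedule)
    n = int(round(total * RAW_RATE_HZ))
    t = np.arange(n) / RAW_RATE_HZ
    acc = _gravity(t, rng, profile.drift_rate)
    acc += profile.noise_sd_g * rng.standard_normal((n, 3))

    intervals: list[Interval] = []
    cursor = 0.0
    seen_subclass: dict[str, int] = {}
    for dur, kind in profile.schedule:
        i0 = int(round(cursor * RAW_RATE_HZ))
        i1 = min(int(round((cursor + dur) * RAW_RATE_HZ)), n)
        tt = t[i0:i1] - t[i0]
        if kind in TREMOR_SUBCLASSES:
            acc[i0:i1] += _tremor_component(
                kind, tt, rng, profile.tremor_freq_hz,
                profile.tremor_amp_g, profile.harmonic_ratio,
            )
            if kind == "T7":  # tremor during gait
                acc[i0:i1] += _activity_component("N1", tt, rng)
            label = "tremor"
        else:
            acc[i0:i1] += _activity_component(kind, tt, rng)
            label = "non_tremor"
        count = seen_subclass.get(kind, 0)
        proto = count == 0 or rng.uniform() < profile.prototype_fraction
        seen_subclass[kind] = count + 1
        intervals.append(
            Interval(cursor, cursor + dur, label, sub_class=kind, prototype=bool(proto))
        )
        cursor += dur

    rec = RawRecording(
        subject_id=profile.subject_id, side="right", rate_hz=RAW_RATE_HZ, t=t, acc=acc
    )
    track = AnnotationTrack(subject_id=profile.subject_id, intervals=intervals)
    return rec, track


def _subject_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _build_schedule(
    rng: np.random.Generator,
    duration_s: float,
    activities: Sequence[str],
    tremor_subclasses: Sequence[str],
    tremor_fraction: float,
) -> list[tuple[float, str]]:
    """Alternate shuffled activity passes with tremor episodes.

    Every activity token appears at least once per pass; tremor episodes are
    assigned round-robin over ``tremor_subclasses`` so that all of them are
    covered once enough episodes fit.
    """
    schedule: list[tuple[float, str]] = []
    tremor_budget = duration_s * tremor_fraction if tremor_subclasses else 0.0
    activity_budget = duration_s - tremor_budget
    # tremor episodes: at least one per sub-class when the budget allows
    episodes: list[tuple[float, str]] = []
    if tremor_budget > 0:
        n_ep = max(len(tremor_subclasses), int(tremor_budget / 18.0))
        durs = rng.uniform(12.0, 25.0, n_ep)
        durs *= tremor_budget / durs.sum()
        order = [tremor_subclasses[i % len(tremor_subclasses)] for i in range(n_ep)]
        episodes = list(zip(durs.tolist(), order))
    acts: list[tuple[float, str]] = []
    remaining = activity_budget
    while remaining > 1.0:
        for kind in rng.permutation(list(activities)):
            dur = float(min(rng.uniform(15.0, 40.0), remaining))
            acts.append((dur, str(kind)))
            remaining -= dur
            if remaining <= 1.0:
                break
    # interleave: tremor episodes spread between activity blocks
    schedule = []
    step = max(1, len(acts) // (len(episodes) + 1)) if episodes else len(acts)
    ei = 0
    for i, entry in enumerate(acts):
        schedule.append(entry)
        if ei < len(episodes) and (i + 1) % step == 0:
            schedule.append(episodes[ei])
            ei += 1
    schedule.extend(episodes[ei:])
    return schedule


def generate_cohort(config: CohortConfig, master_seed: int) -> SyntheticCohort:
    """Generate a full annotated cohort as a pure function of
    ``(config, master_seed)``."""
    if config.n_tremor == 0 and config.prototype_fraction > 0:
        warnings.warn(
            "cohort has no tremor subjects: tremor prototypes unavailable",
            stacklevel=2,
        )
    subjects = []
    groups = (
        [("tremor", i) for i in range(config.n_tremor)]
        + [("pd_no_tremor", i) for i in range(config.n_pd_no_tremor)]
        + [("control", i) for i in range(config.n_controls)]
    )
    for idx, (group, gi) in enumerate(groups):
        seed = _subject_seed(master_seed, idx)
        rng = np.random.default_rng(seed)
        has_tremor = group == "tremor"
        if has_tremor:
            # round-robin offset so tremor sub-classes are covered cohort-wide
            subs = tuple(
                TREMOR_SUBCLASSES[(gi + k) % 7] for k in range(7)
            )
        else:
            subs = ()
        schedule = _build_schedule(
            rng,
            config.duration_s,
            config.activities,
            subs,
            config.tremor_fraction if has_tremor else 0.0,
        )
        profile = SubjectProfile(
            subject_id=f"{group}_{gi:02d}",
            has_tremor=has_tremor,
            tremor_freq_hz=float(rng.uniform(4.0, 7.0)),
            tremor_amp_g=float(rng.uniform(*config.tremor_amp_range_g)),
            harmonic_ratio=float(rng.uniform(*config.harmonic_ratio_range)),
            schedule=schedule,
            drift_rate=config.drift_rate,
            noise_sd_g=config.noise_sd_g,
            prototype_fraction=config.prototype_fraction,
            seed=seed,
        )
        subjects.append(generate_subject(profile))
    return SyntheticCohort(subjects=subjects, config=config, master_seed=master_seed)


def difficulty_presets(name: str) -> CohortConfig:
    """Named cohort difficulty presets.

    ``easy``: strong tremor relative to the noise floor and no "suspicious"
    N5 confuser activity. ``hard``: tremor amplitude lowered toward the noise
    floor, with N5 confusers at tremor-adjacent frequencies present.
    """
    if name == "easy":
        return CohortConfig(
            tremor_amp_range_g=(0.12, 0.20),
            include_n5=False,
        )
    if name == "hard":
        return CohortConfig(
            tremor_amp_range_g=(0.035, 0.06),
            noise_sd_g=0.025,
            include_n5=True,
            confuser_freq_band_hz=(3.5, 5.0),
        )
    raise ValueError(f"unknown preset {name!r}; use 'easy' or 'hard'")
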