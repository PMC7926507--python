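"""Synthetic sessions emulating the wheelchair activity-routine protocol.

The generator reproduces the statistical structure the analysis assumes:
20 participants each perform a routine of 10 five-minute activities
(three Sedentary, four Housework, three Locomotion) separated by 60-second
rests, recorded by an arm-worn triaxial accelerometer at 50 Hz together
with breath-like VO₂ measurements every 5 s.

Each activity's triaxial signal is a slowly drifting unit-norm gravity
orientation plus an amplitude-modulated sinusoid at the activity's dominant
movement frequency (independent per-axis phases and per-axis amplitude
weights) plus white sensor noise.  Activity intensities are ordered
Sedentary < Housework < Locomotion.  The white-noise level is specified as
a *fraction* of the oscillation amplitude and varies across activities:
varying the noise-to-oscillation mix varies the within-window amplitude
distribution shape, which decorrelates otherwise near-proportional
features (e.g. the IQR/SD ratio is 2 for a pure sinusoid but ≈1.35 for
pure Gaussian noise) and makes the generating predictors identifiable.

Observed VO₂ is coupled to the signal: for every activity minute the 55
features are extracted from the generated samples and a known ground-truth
linear model (by default the published all-variables equation) is applied,
plus Gaussian noise, floored at zero — so the linear-model assumption holds
exactly and parameter recovery is a meaningful end-to-end check.  A
``misspecified`` switch adds a quadratic term to probe robustness.

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` sub-streams, so outputs are byte-identical
across runs with the same seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .features import MinuteWindow, compute_features
from .modeling import LinearModel, predict, published_models
from .signal_io import AccelRecording, ActivityAnnotation, Session, Vo2Series

REST_VO2 = 3.0  # mL·kg⁻¹·min⁻¹, resting uptake emitted during rest gaps

#: Participant body-mass distribution (kg): mean and SD of the study cohort.
MASS_MEAN_KG = 74.8
MASS_SD_KG = 18.05


@dataclass(frozen=True)
class ActivityProfile:
    """Signal-generation parameters of one routine activity.

    ``amplitude_g`` is the nominal oscillation amplitude (g) of the arm
    movement; ``frequency_hz`` its dominant frequency; ``jitter`` the
    fractional amplitude modulation across 5-s blocks; ``noise_ratio`` the
    white-noise SD as a fraction of the oscillation amplitude;
    ``baseline_vo2`` a descriptive nominal uptake used only to order the
    default profiles by intensity (observed VO₂ is generated from the
    ground-truth model, not from this field).
    """

    label: str
    type: str
    amplitude_g: float
    frequency_hz: float
    jitter: float
    baseline_vo2: float
    noise_ratio: float
    duration_s: float = 300.0

    def __post_init__(self) -> None:
        if self.amplitude_g < 0:
            raise ValueError("amplitude must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """The generating VO₂ model and its observation-noise level."""

    model: LinearModel = None  # type: ignore[assignment]
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model is None:
            object.__setattr__(self, "model", published_models()["all"])
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_profiles() -> list[ActivityProfile]:
    """The 10-activity routine with invented signal intensities ordered
    Sedentary < Housework < Locomotion."""
    rows = [
        # label, type, amp (g), freq (Hz), jitter, baseline VO2, noise ratio
        ("Lying down", "Sedentary", 0.015, 0.25, 0.15, 3.0, 0.90),
        ("Watching TV", "Sedentary", 0.030, 0.30, 0.20, 3.2, 0.70),
        ("Working on a computer", "Sedentary", 0.068, 1.50, 0.30, 3.6, 0.50),
        ("Moving items", "Housework", 0.180, 0.80, 0.40, 6.5, 0.35),
        ("Mopping the floor", "Housework", 0.225, 0.90, 0.30, 7.0, 0.25),
        ("Cleaning the windows", "Housework", 0.210, 1.20, 0.35, 6.8, 0.45),
        ("Ironing", "Housework", 0.135, 1.00, 0.30, 5.5, 0.60),
        ("Arm-ergometry exercise", "Locomotion", 0.330, 1.10, 0.15, 9.5, 0.15),
        ("Slow propulsion", "Locomotion", 0.255, 0.70, 0.25, 8.0, 0.30),
        ("Fast propulsion", "Locomotion", 0.420, 1.00, 0.20, 11.0, 0.20),
    ]
    return [ActivityProfile(label=l, type=ty, amplitude_g=a, frequency_hz=f,
                            jitter=j, baseline_vo2=v, noise_ratio=nr)
            for l, ty, a, f, j, v, nr in rows]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _activity_signal(profile: ActivityProfile, rate: float, rest_s: float,
                     rng: np.random.Generator) -> np.ndarray:
    """One activity block followed by its rest gap; shape (n, 3), units g."""
    n_act = round(profile.duration_s * rate)
    n_rest = round(rest_s * rate)
    n = n_act + n_rest
    t = np.arange(n) / rate

    # slowly drifting unit-norm gravity orientation, one node per second
    n_sec = int(math.ceil(n / rate)) + 1
    v0 = rng.normal(size=3)
    walk = v0 + np.cumsum(rng.normal(0.0, 0.02, size=(n_sec, 3)), axis=0)
    g_nodes = _unit(walk)
    sec = np.arange(n_sec, dtype=float)
    gravity = np.column_stack([np.interp(t, sec, g_nodes[:, ax]) for ax in range(3)])

    # Per-axis oscillation: independent amplitude weights, phases and 5-s
    # block amplitude modulation per axis.  Axis independence matters: it is
    # what keeps single-axis dispersion features (Y_SD, Y_VAR) from being
    # collinear with resultant-vector dispersion across windows, so the
    # generating predictors stay identifiable to the selection step.
    weights = np.array([0.9, 1.0, 0.7]) * np.exp(rng.normal(0.0, 0.55, size=3))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    n_nodes = int(math.ceil(profile.duration_s / 5.0)) + 1
    node_t = np.arange(n_nodes) * 5.0

    # Intermittency: real activity comes in strokes and pauses, so movement
    # is gated on/off in 5-s blocks with an activity-level duty cycle.  The
    # gate is common-mode across axes (the arm pauses as a whole) and, like
    # the noise-to-oscillation mix, it varies the *shape* of each window's
    # amplitude distribution — quantiles, IQR and SD respond differently to
    # burstiness, which keeps these otherwise proxy-like features mutually
    # distinguishable.
    duty = rng.uniform(0.25, 1.0)
    gate = np.interp(t[:n_act], node_t,
                     (rng.uniform(size=n_nodes) < duty).astype(float))

    # MEMS bias: phone accelerometers carry per-axis zero-g offsets of tens
    # of mg that drift with temperature, so each activity block gets its own
    # constant per-axis bias.  Percentile features absorb this as location
    # noise; location-invariant features (IQR, SD, VAR) cancel it exactly.
    bias = rng.normal(0.0, 0.05, size=3)

    sig = gravity + bias
    for ax in range(3):
        am_nodes = np.clip(1.0 + profile.jitter * rng.normal(size=n_nodes), 0.05, None)
        am = np.interp(t[:n_act], node_t, am_nodes)
        # cap the per-axis oscillation at 0.5 g so the per-axis dispersion
        # stays in the range where the published equations are plausible
        amp = min(profile.amplitude_g * weights[ax], 0.50)
        osc = amp * am * np.sin(2.0 * np.pi * profile.frequency_hz * t[:n_act] + phases[ax])
        move_noise = max(profile.noise_ratio * amp * math.exp(rng.normal(0.0, 0.5)), 0.0)
        sig[:n_act, ax] += gate * (osc + rng.normal(0.0, 1.0, size=n_act) * move_noise)
        # sensor noise floor, present throughout activity and rest
        sig[:, ax] += rng.normal(0.0, 0.004, size=n)

    # Impact transients (wheel strikes, objects set down): sparse
    # single-sample spikes whose rate varies by activity instance.  Spikes
    # load the tails, so they inflate SD/VAR much more than the IQR —
    # another shape axis that keeps dispersion features mutually
    # distinguishable.
    spike_rate = rng.uniform(0.0, 0.15)  # events per second while active
    n_spikes = rng.poisson(spike_rate * profile.duration_s)
    if n_spikes:
        pos = rng.integers(0, n_act, size=n_spikes)
        mag = profile.amplitude_g * rng.uniform(1.0, 1.8, size=(n_spikes, 3))
        sign = rng.choice([-1.0, 1.0], size=(n_spikes, 3))
        np.add.at(sig, pos, gate[pos, None] * mag * sign)
    return sig


def generate_session(participant_id: str, profiles=None, truth: GroundTruth | None = None,
                     rate: float = 50.0, seed=0, rest_s: float = 60.0,
                     vo2_cadence_s: float = 5.0, mass_kg: float = MASS_MEAN_KG,
                     misspecified: bool = False) -> Session:
    """Generate one participant's full routine session.

    Deterministic for a fixed ``seed`` (an int or a
    ``numpy.random.SeedSequence``).  The activity schedule places activity
    i at t = i × (duration + rest) seconds, so one-minute windows anchored
    at activity starts align with the generator's internal minute grid.
    """
    if rate <= 0 or not float(rate * 60).is_integer():
        raise ValueError("rate must be positive with an integer number of samples per minute")
    profiles = list(profiles) if profiles is not None else default_profiles()
    truth = truth if truth is not None else GroundTruth()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    act_streams = ss.spawn(len(profiles) + 1)
    rng_vo2 = np.random.default_rng(act_streams[-1])

    blocks, annotations = [], []
    t0 = 0.0
    for prof, child in zip(profiles, act_streams):
        rng = np.random.default_rng(child)
        blocks.append(_activity_signal(prof, rate, rest_s, rng))
        annotations.append(ActivityAnnotation(label=prof.label, type=prof.type,
                                              start=t0, end=t0 + prof.duration_s))
        t0 += prof.duration_s + rest_s

    sig = np.vstack(blocks)
    n_total = sig.shape[0]
    time = np.arange(n_total) / rate
    total_s = n_total / rate
    accel = AccelRecording(time=time, x=sig[:, 0], y=sig[:, 1], z=sig[:, 2],
                           nominal_rate=rate)

    # per-minute VO2 from the ground-truth model applied to this minute's
    # features; rest minutes carry the resting value
    spm = int(rate * 60)
    n_minutes = n_total // spm
    minute_vo2 = np.empty(n_minutes)
    active_minutes: dict[int, ActivityAnnotation] = {}
    for a in annotations:
        m0 = int(a.start // 60)
        for j in range(int((a.end - a.start) // 60)):
            active_minutes[m0 + j] = a
    rv = np.sqrt(np.sum(sig**2, axis=1))
    needed = list(truth.model.predictors)
    if misspecified and "RV_75-25" not in needed:
        needed.append("RV_75-25")
    for mi in range(n_minutes):
        ann = active_minutes.get(mi)
        if ann is None:
            v = REST_VO2 + rng_vo2.normal(0.0, 0.3 * truth.noise_sd)
        else:
            i0, i1 = mi * spm, (mi + 1) * spm
            w = MinuteWindow(x=sig[i0:i1, 0], y=sig[i0:i1, 1], z=sig[i0:i1, 2],
                             rv=rv[i0:i1], label=ann.label, type=ann.type,
                             vo2=float("nan"), participant_id=participant_id,
                             start_s=mi * 60.0)
            fv = compute_features(w, needed)
            v = predict(truth.model, fv)
            if misspecified:
                v += 4.0 * fv["RV_75-25"] ** 2
            v += rng_vo2.normal(0.0, truth.noise_sd)
        minute_vo2[mi] = max(v, 0.0)

    vo2_t = np.arange(0.0, total_s + 1e-9, vo2_cadence_s)
    idx = np.minimum((vo2_t // 60.0).astype(int), n_minutes - 1)
    vo2 = Vo2Series(time=vo2_t, vo2=minute_vo2[idx], mass_kg=mass_kg)

    return Session(participant_id=participant_id, accel=accel, vo2=vo2,
                   annotations=annotations)


def generate_dataset(n_participants: int = 20, seed=0, rate: float = 50.0,
                     noise_sd: float = 1.0, truth: GroundTruth | None = None,
                     misspecified: bool = False) -> list[Session]:
    """Generate the full cohort: ``n_participants`` sessions with seeded
    per-participant perturbations of amplitude, frequency, jitter, noise
    mix and body mass.  Defaults give 20 sessions × 50 windows = 1000
    one-minute windows after segmentation.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    truth = truth if truth is not None else GroundTruth(noise_sd=noise_sd)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    base = default_profiles()
    sessions = []
    for p, child in enumerate(ss.spawn(n_participants)):
        perturb_ss, session_ss = child.spawn(2)
        rng = np.random.default_rng(perturb_ss)
        mass = float(np.clip(rng.normal(MASS_MEAN_KG, MASS_SD_KG), 45.0, 125.0))
        global_amp = math.exp(rng.normal(0.0, 0.15))
        profiles = []
        for prof in base:
            profiles.append(replace(
                prof,
                amplitude_g=prof.amplitude_g * global_amp * math.exp(rng.normal(0.0, 0.12)),
                frequency_hz=prof.frequency_hz * math.exp(rng.normal(0.0, 0.10)),
                jitter=float(np.clip(prof.jitter * math.exp(rng.normal(0.0, 0.20)), 0.05, 0.8)),
                noise_ratio=float(np.clip(prof.noise_ratio * math.exp(rng.normal(0.0, 0.25)),
                                          0.05, 1.2)),
            ))
        sessions.append(generate_session(
            participant_id=f"P{p + 1:02d}", profiles=profiles, truth=truth,
            rate=rate, seed=session_ss, mass_kg=mass, misspecified=misspecified,
        ))
    return sessions


# ---------------------------------------------------------------------------
# serialization (Physics Toolbox dialect)


def write_session(session: Session, directory) -> Path:
    """Write a session bundle readable by :mod:`accelvo2.signal_io` without
    loss: ``accel.csv`` (physics_toolbox dialect), ``vo2.csv`` (already
    weight-normalized), ``annotations.csv`` and ``meta.json``.

    Floats are printed with 17 significant digits so the write→read round
    trip is exact; output bytes are deterministic.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    acc = session.accel
    np.savetxt(d / "accel.csv",
               np.column_stack([acc.time, acc.x, acc.y, acc.z]),
               fmt="%.17g", delimiter=",", comments="",
               header="time,gFx,gFy,gFz")
    np.savetxt(d / "vo2.csv",
               np.column_stack([session.vo2.time, session.vo2.vo2]),
               fmt="%.17g", delimiter=",", comments="", header="time,vo2")
    with open(d / "annotations.csv", "w") as fh:
        fh.write("label,type,start_s,end_s\n")
        for a in session.annotations:
            fh.write(f"{a.label},{a.type},{a.start:.17g},{a.end:.17g}\n")
    meta = {
        "participant_id": session.participant_id,
        "mass_kg": session.vo2.mass_kg,
        "nominal_rate": acc.nominal_rate,
        "already_normalized": True,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return d


def write_dataset(sessions, directory, truth: GroundTruth | None = None,
                  extra_meta: dict | None = None) -> Path:
    """Write one sub-directory per session plus a ``manifest.json``
    recording the ground-truth model and any extra provenance metadata."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        write_session(s, d / s.participant_id)
    manifest = {
        "participants": [s.participant_id for s in sessions],
        "truth": None if truth is None else {
            "model": truth.model.to_dict(), "noise_sd": truth.noise_sd,
        },
    }
    if extra_meta:
        manifest.update(extra_meta)
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return d
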