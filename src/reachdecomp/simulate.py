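"""Synthetic finger-to-nose-test (FNT) cohort generator.

Produces raw wrist-accelerometer-like recordings for healthy, ataxic
(graded severity on a BARS-like 0-30 scale), and parkinsonism-like
participants.  The generative model is built from discrete velocity
lobes:

* Each reach between the nose and the target is one (or, with
  increasing severity, several) minimum-jerk-like velocity lobes on the
  anteroposterior (AP) axis, with scaled companions on the mediolateral
  (ML) and rostrocaudal (RC) axes.
* Every generated lobe obeys a speed-distance power law
  ``vbar = v_p * (D / d_p)**alpha`` pivoted at a small distance ``d_p``
  so that at severity 0 it reduces to ``vbar = k * D**(2/3)`` (the
  two-thirds power law of unimpaired reaching) while a lower exponent
  produces *slower* large movements.
* Severity injects dysmetria: reaches split into lognormally shrinking
  sub-lobes, small direction reversals appear near endpoints, hold
  periods fill with chains of small alternating "micro" lobes, and lobe
  shapes become skewed / multi-peaked.
* Parkinsonism-like recordings are slow and small but smooth: single
  lobes per reach, no extra segmentation.

The body-frame velocity is differentiated to acceleration, rotated by a
small per-participant sensor-mount rotation, gravity is added on the
rostrocaudal axis, and white accelerometer noise is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

GRAVITY_MS2 = 9.81

GROUPS = ("healthy", "ataxia", "parkinsonism")
HANDS = ("left", "right")

# body-frame axis order used throughout this module
AX_AP, AX_ML, AX_RC = 0, 1, 2


@dataclass
class SimParams:
    """All tunable constants of the generator.

    The defaults define the reference study conditions: a 40-s task per
    hand at 128 Hz, a 0.45-m anteroposterior reach, and severity
    mechanics calibrated so a default healthy participant yields on the
    order of 450 retained movement elements after decomposition.
    """

    sampling_rate_hz: float = 128.0
    task_duration_s: float = 40.0
    reach_distance_m: float = 0.45
    target_switch_s: float = 10.0
    severity: float = 0.0  # BARS-like, 0-30
    group: str = "healthy"
    pediatric_flag: bool = False
    noise_sd_ms2: float = 0.03
    seed: int = 0

    # kinematic law: vbar = law_pivot**(2/3) * (D/law_pivot)**alpha(severity)
    speed_gain: float = 1.0
    alpha_healthy: float = 2.0 / 3.0
    alpha_floor: float = 0.4  # generation exponent at severity 30
    law_pivot_m: float = 0.05
    duration_jitter_sd: float = 0.08  # lognormal sd on lobe durations

    # reach geometry / scheduling
    ml_fraction: float = 0.30
    rc_fraction: float = 0.20
    reach_overshoot: float = 0.01
    distance_jitter_sd: float = 0.02
    hold_s: float = 0.35
    inter_lobe_gap_s: float = 0.06
    start_delay_s: float = 0.25
    max_reach_s: float = 3.0

    # hold-period micro-movements (physiological jitter / dysmetric wobble)
    micro_rate: float = 1.3  # mean lobes per hold at severity 0
    micro_rate_sev: float = 0.18  # additional mean lobes per severity point
    micro_distance_m: float = 0.005  # median micro distance at severity 0
    micro_distance_sev: float = 0.02  # log-shrink per severity point
    micro_distance_sd: float = 0.5  # lognormal sigma

    # severity mechanics (ataxia only)
    split_rate: float = 0.09  # mean extra sub-lobes per reach per severity pt
    split_shrink: float = 0.9  # decay of successive sub-lobe weights
    split_weight_sd: float = 0.4
    reversal_rate: float = 0.06  # mean endpoint reversals per reach per pt
    reversal_distance_m: float = 0.008
    reversal_distance_sd: float = 0.5

    # lobe morphology
    shape_noise_sd: float = 0.25  # sd of profile-exponent perturbation
    shape_noise_sev: float = 0.06  # relative increase per severity point
    multipeak_base: float = 0.03
    multipeak_prob_sev: float = 0.02  # extra multi-peak probability per pt
    practice_effect: bool = True
    practice_severity_cutoff: float = 8.0
    practice_factor: float = 0.35  # 2nd-half shape-noise multiplier

    # parkinsonism contrast group
    parkinsonism_amplitude_factor: float = 0.6
    parkinsonism_speed_factor: float = 0.6

    # sensor mounting / labels
    mount_rotation_sd_deg: float = 6.0
    pediatric_amplitude_factor: float = 0.8
    rater_noise_sd: float = 1.0

    def validate(self) -> None:
        if self.sampling_rate_hz <= 0 or self.task_duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        n = self.sampling_rate_hz * self.task_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "sampling_rate_hz * task_duration_s must be an integer "
                f"sample count, got {n}"
            )
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (0.0 <= self.severity <= 30.0):
            raise ValueError("severity must lie in [0, 30]")
        if self.group == "healthy" and self.severity != 0:
            raise ValueError("healthy participants must have severity 0")
        if self.reach_distance_m <= 0 or self.target_switch_s <= 0:
            raise ValueError("reach distance and target switch must be positive")
        if self.noise_sd_ms2 < 0:
            raise ValueError("noise_sd_ms2 must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.task_duration_s))


@dataclass
class InertialRecording:
    """Raw tri-axial acceleration in the sensor frame (gravity present)."""

    participant_id: str
    visit_id: str
    hand: str
    time_s: np.ndarray  # (n,)
    acc: np.ndarray  # (n, 3) m/s^2, sensor frame
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if len(self.time_s) == 0:
            raise ValueError("recording must be non-empty")
        dt = np.diff(self.time_s)
        if not np.allclose(dt, 1.0 / self.sampling_rate_hz, rtol=1e-6, atol=1e-9):
            raise ValueError("timestamps must increase at fixed 1/fs steps")


@dataclass
class ParticipantRecord:
    participant_id: str
    visit_id: str
    group: str
    clinical_score: float
    score_scale: str  # "bars" (healthy/ataxia) or "updrs" (parkinsonism)
    pediatric_flag: bool
    handedness: str
    severity: float  # generating severity (latent truth)
    recordings: dict  # hand -> InertialRecording
    upper_limb_score: float | None = None  # summed upper-limb subscore, 0-8

    def __post_init__(self) -> None:
        if set(self.recordings) != set(HANDS):
            raise ValueError("exactly one recording per hand required")


# ---------------------------------------------------------------------------
# lobe primitives


def _alpha(params: SimParams) -> float:
    if params.group == "parkinsonism":
        return params.alpha_healthy
    s = params.severity
    return params.alpha_healthy - (params.alpha_healthy - params.alpha_floor) * s / 30.0


def _mean_speed(distance: float, alpha: float, params: SimParams) -> float:
    """Severity-pivoted power law; equals k*D^(2/3) at healthy alpha."""
    d_p = params.law_pivot_m
    return params.speed_gain * d_p ** params.alpha_healthy * (distance / d_p) ** alpha


def _lobe_profile(
    n: int,
    rng: np.random.Generator,
    shape_sd: float,
    multipeak_prob: float,
) -> np.ndarray:
    """Non-negative velocity shape on n samples with unit peak order.

    The base is the minimum-jerk speed curve tau^2 (1-tau)^2; shape
    noise perturbs the two exponents (skew), and with some probability a
    sinusoidal modulation adds extra peaks. The caller rescales to a
    target signed distance.
    """
    tau = np.linspace(0.0, 1.0, n)
    a = max(0.6, 2.0 + rng.normal(0.0, shape_sd))
    b = max(0.6, 2.0 + rng.normal(0.0, shape_sd))
    shape = tau**a * (1.0 - tau) ** b
    if rng.random() < multipeak_prob:
        cycles = rng.integers(2, 4)
        depth = rng.uniform(0.3, 0.7)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        shape = shape * (1.0 + depth * np.sin(2.0 * math.pi * cycles * tau + phase))
        shape = np.clip(shape, 0.0, None)
    return shape


def _place_lobe(
    v: np.ndarray,
    start: int,
    n: int,
    signed_distance: float,
    fs: float,
    rng: np.random.Generator,
    shape_sd: float,
    multipeak_prob: float,
) -> None:
    """Add a lobe of exactly `signed_distance` integral into v[start:start+n]."""
    n = max(3, n)
    end = min(start + n, len(v))
    n_eff = end - start
    if n_eff < 3:
        return
    shape = _lobe_profile(n_eff, rng, shape_sd, multipeak_prob)
    area = np.trapezoid(shape, dx=1.0 / fs)
    if area <= 0:
        return
    v[start:end] += shape * (signed_distance / area)


# ---------------------------------------------------------------------------
# per-hand velocity synthesis


class _HandBuilder:
    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.fs = params.sampling_rate_hz
        self.n = params.n_samples
        self.v = np.zeros((self.n, 3))  # AP, ML, RC body-frame velocity

    # -- helpers ----------------------------------------------------------
    def _shape_params(self, t0: float) -> tuple[float, float]:
        p = self.p
        sd = p.shape_noise_sd * (1.0 + p.severity * p.shape_noise_sev)
        peak = p.multipeak_base + p.severity * p.multipeak_prob_sev
        practising = (
            p.practice_effect
            and p.group != "parkinsonism"
            and p.severity < p.practice_severity_cutoff
        )
        if practising and t0 >= p.task_duration_s / 2.0:
            sd *= p.practice_factor
            peak *= p.practice_factor
        return sd, min(peak, 0.9)

    def _duration(self, distance: float, alpha: float) -> float:
        vbar = _mean_speed(distance, alpha, self.p)
        t = distance / vbar
        t *= math.exp(self.rng.normal(0.0, self.p.duration_jitter_sd))
        return max(t, 3.0 / self.fs)

    def _add_lobe(self, axis: int, t0: float, dur: float, signed_d: float) -> None:
        sd, peak = self._shape_params(t0)
        start = int(round(t0 * self.fs))
        if start >= self.n:
            return
        _place_lobe(
            self.v[:, axis], start, int(round(dur * self.fs)), signed_d,
            self.fs, self.rng, sd, peak,
        )

    # -- building blocks --------------------------------------------------
    def reach(self, t0: float, direction: float, ml_sign: float) -> float:
        """Place one (possibly fragmented) reach starting at t0; return end."""
        p, rng = self.p, self.rng
        alpha = _alpha(p)
        amp = 1.0
        if p.group == "parkinsonism":
            amp *= p.parkinsonism_amplitude_factor
        if p.pediatric_flag:
            amp *= p.pediatric_amplitude_factor
        d_total = p.reach_distance_m * amp
        # outward reaches overshoot slightly so the single largest element is
        # reliably directed towards the tablet
        if direction > 0:
            d_total *= 1.0 + p.reach_overshoot + abs(rng.normal(0.0, p.distance_jitter_sd))
        else:
            d_total *= 1.0 - p.reach_overshoot

        # severity splits the reach into lognormally shrinking sub-lobes
        n_sub = 1
        if p.group == "ataxia":
            n_sub += int(rng.poisson(p.split_rate * p.severity))
        weights = np.exp(
            -p.split_shrink * np.arange(n_sub)
            + rng.normal(0.0, p.split_weight_sd, n_sub)
        )
        weights = np.sort(weights)[::-1]
        sub_d = d_total * weights / weights.sum()

        speed_scale = (
            p.parkinsonism_speed_factor if p.group == "parkinsonism" else 1.0
        )
        t = t0
        deadline = t0 + p.max_reach_s
        for i, d_ap in enumerate(sub_d):
            dur_ap = self._duration(d_ap, alpha) / speed_scale
            self._add_lobe(AX_AP, t, dur_ap, direction * d_ap)
            for axis, frac, sign in (
                (AX_ML, p.ml_fraction, ml_sign),
                (AX_RC, p.rc_fraction, 1.0),
            ):
                d_ax = frac * d_ap
                dur_ax = self._duration(d_ax, alpha) / speed_scale
                self._add_lobe(axis, t, min(dur_ax, dur_ap), direction * sign * d_ax)
            t += dur_ap
            if i < n_sub - 1:
                t += p.inter_lobe_gap_s
            if t >= deadline:
                break

        # dysmetric endpoint reversals: small alternating AP lobes
        if p.group == "ataxia":
            n_rev = int(rng.poisson(p.reversal_rate * p.severity))
            rev_sign = -direction
            for _ in range(n_rev):
                d_rev = p.reversal_distance_m * math.exp(
                    rng.normal(0.0, p.reversal_distance_sd)
                )
                dur = self._duration(d_rev, alpha)
                self._add_lobe(AX_AP, t, dur, rev_sign * d_rev)
                t += dur
                rev_sign = -rev_sign
        return t

    def hold(self, t0: float) -> float:
        """Fill a hold period with micro-lobe chains on each axis."""
        p, rng = self.p, self.rng
        alpha = _alpha(p)
        rate = p.micro_rate + p.micro_rate_sev * (
            p.severity if p.group == "ataxia" else 0.0
        )
        med = p.micro_distance_m * math.exp(-p.micro_distance_sev * p.severity)
        t_end = t0 + p.hold_s
        for axis in (AX_AP, AX_ML, AX_RC):
            n_micro = int(rng.poisson(rate))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            t = t0 + rng.uniform(0.0, 0.05)
            for _ in range(n_micro):
                d = med * math.exp(rng.normal(0.0, p.micro_distance_sd))
                dur = self._duration(d, alpha)
                self._add_lobe(axis, t, dur, sign * d)
                t += dur
                sign = -sign
            t_end = max(t_end, t + 0.05)
        return t_end

    def build(self) -> np.ndarray:
        p = self.p
        t = p.start_delay_s
        direction = 1.0
        while t < p.task_duration_s - 0.5:
            # which side of the tablet the target currently occupies
            ml_sign = 1.0 if int(t // p.target_switch_s) % 2 == 0 else -1.0
            t = self.reach(t, direction, ml_sign)
            t = self.hold(t)
            direction = -direction
        return self.v


# ---------------------------------------------------------------------------
# public operations


def _body_velocity(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    return _HandBuilder(params, rng).build()


def _to_sensor_frame(
    v_body: np.ndarray,
    params: SimParams,
    rotation: Rotation,
    rng: np.random.Generator,
) -> np.ndarray:
    fs = params.sampling_rate_hz
    acc_body = np.gradient(v_body, 1.0 / fs, axis=0)
    acc_body[:, AX_RC] += GRAVITY_MS2
    acc_sensor = rotation.apply(acc_body)
    if params.noise_sd_ms2 > 0:
        acc_sensor = acc_sensor + rng.normal(0.0, params.noise_sd_ms2, acc_sensor.shape)
    return acc_sensor


def _round_half(x: float) -> float:
    return round(x * 2.0) / 2.0


def simulate_participant(
    params: SimParams,
    participant_id: str = "P000",
    visit_id: str = "v1",
) -> ParticipantRecord:
    """Simulate one two-hand FNT session.

    Deterministic given ``params`` (including ``params.seed``).
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    meta_ss, left_ss, right_ss = ss.spawn(3)
    meta_rng = np.random.default_rng(meta_ss)

    # one small random sensor-mount rotation per participant
    angle = math.radians(params.mount_rotation_sd_deg) * meta_rng.normal()
    axis = meta_rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rotation = Rotation.from_rotvec(angle * axis)

    time_s = np.arange(params.n_samples) / params.sampling_rate_hz
    recordings = {}
    for hand, hand_ss in (("left", left_ss), ("right", right_ss)):
        rng = np.random.default_rng(hand_ss)
        v_body = _body_velocity(params, rng)
        acc = _to_sensor_frame(v_body, params, rotation, rng)
        recordings[hand] = InertialRecording(
            participant_id=participant_id,
            visit_id=visit_id,
            hand=hand,
            time_s=time_s,
            acc=acc,
            sampling_rate_hz=params.sampling_rate_hz,
        )

    upper_limb = None
    if params.group == "parkinsonism":
        score = float(round(meta_rng.uniform(10.0, 50.0)))
        scale = "updrs"
    else:
        score = _round_half(
            float(np.clip(params.severity + meta_rng.normal(0.0, params.rater_noise_sd), 0.0, 30.0))
        )
        scale = "bars"
        upper_limb = _round_half(
            float(
                np.clip(
                    params.severity * 8.0 / 30.0
                    + meta_rng.normal(0.0, params.rater_noise_sd * 8.0 / 30.0),
                    0.0,
                    8.0,
                )
            )
        )
    handedness = "right" if meta_rng.random() < 0.9 else "left"

    return ParticipantRecord(
        participant_id=participant_id,
        visit_id=visit_id,
        group=params.group,
        clinical_score=score,
        score_scale=scale,
        pediatric_flag=params.pediatric_flag,
        handedness=handedness,
        severity=params.severity,
        recordings=recordings,
        upper_limb_score=upper_limb,
    )


def simulate_cohort(
    n_healthy: int,
    n_ataxia: int,
    n_parkinsonism: int,
    seed: int = 0,
    severity_range: tuple[float, float] = (3.0, 24.0),
    pediatric_fraction: float = 0.15,
    repeat_visits: int = 0,
    visit_drift_mean: float = 0.5,
    visit_drift_sd: float = 1.0,
    base_params: SimParams | None = None,
) -> list[ParticipantRecord]:
    """Simulate a cohort of participants, deterministic given ``seed``.

    Ataxia severities are drawn uniformly from ``severity_range``; a
    ``pediatric_fraction`` of ataxia participants is flagged pediatric;
    the first ``repeat_visits`` ataxia participants receive a second
    visit whose severity drifts by N(visit_drift_mean, visit_drift_sd).
    """
    if min(n_healthy, n_ataxia, n_parkinsonism) < 0:
        raise ValueError("cohort counts must be non-negative")
    if repeat_visits > n_ataxia:
        raise ValueError("repeat_visits cannot exceed n_ataxia")
    base = base_params if base_params is not None else SimParams()
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    def child_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    records: list[ParticipantRecord] = []
    for i in range(n_healthy):
        params = replace(base, group="healthy", severity=0.0, pediatric_flag=False,
                         seed=child_seed())
        records.append(simulate_participant(params, f"HC{i:03d}"))
    for i in range(n_ataxia):
        sev = float(rng.uniform(*severity_range))
        ped = bool(rng.random() < pediatric_fraction)
        params = replace(base, group="ataxia", severity=sev, pediatric_flag=ped,
                         seed=child_seed())
        records.append(simulate_participant(params, f"AT{i:03d}"))
        if i < repeat_visits:
            sev2 = float(np.clip(sev + rng.normal(visit_drift_mean, visit_drift_sd), 0.0, 30.0))
            params2 = replace(params, severity=sev2, seed=child_seed())
            records.append(simulate_participant(params2, f"AT{i:03d}", visit_id="v2"))
    for i in range(n_parkinsonism):
        params = replace(base, group="parkinsonism", severity=0.0, pediatric_flag=False,
                         seed=child_seed())
        records.append(simulate_participant(params, f"PD{i:03d}"))
    return records


# ---------------------------------------------------------------------------
# file output


def write_recording_csv(recording: InertialRecording, path: str | Path) -> Path:
    path = Path(path)
    data = np.column_stack([recording.time_s, recording.acc])
    header = "time_s,ax,ay,az"
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.9g")
    return path


def write_cohort(records: Sequence[ParticipantRecord], out_dir: str | Path) -> Path:
    """Write one CSV per recording plus a cohort manifest CSV; returns manifest path."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for hand, recording in rec.recordings.items():
            fname = f"{rec.participant_id}_{rec.visit_id}_{hand}.csv"
            write_recording_csv(recording, out_dir / fname)
            rows.append(
                dict(
                    participant_id=rec.participant_id,
                    visit_id=rec.visit_id,
                    group=rec.group,
                    clinical_score=rec.clinical_score,
                    score_scale=rec.score_scale,
                    severity=rec.severity,
                    pediatric_flag=rec.pediatric_flag,
                    handedness=rec.handedness,
                    hand=hand,
                    file=fname,
                )
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_recording_csv(
    path: str | Path,
    participant_id: str = "",
    visit_id: str = "v1",
    hand: str = "right",
) -> InertialRecording:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    time_s = data[:, 0]
    fs = 1.0 / float(np.median(np.diff(time_s)))
    return InertialRecording(
        participant_id=participant_id,
        visit_id=visit_id,
        hand=hand,
        time_s=time_s,
        acc=data[:, 1:4],
        sampling_rate_hz=round(fs, 6),
    )
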