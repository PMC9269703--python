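"""Synthetic b&r cohort generator with analytic ground truth.

Emulates the statistical structure of the instrumented bending-and-return
test that the analysis pipeline assumes, without pretending to be a forward
biomechanical simulation:

* quasi-periodic movement cycles (~42 per 60 s; period 1.43 ± 0.15 s);
* a dominant flexion/extension angular-velocity channel built from smooth
  biphasic per-cycle pulses -A_k sin(2*pi*s), s in [0,1): a negative flexion
  lobe followed by a positive return lobe, with per-cycle amplitude and
  duration jitter (Gyr Y on SENS1/SENS2; SENS3 carries an attenuated copy of
  the pelvis pattern on -Gyr Z, matching its rotated mounting);
* a gravity-projection Acc Z on SENS1 with one pronounced minimum per cycle
  at deep flexion, so the segmentation algorithm applies as on real data;
* structured additive noise: a mix of white and AR(1)-correlated
  perturbations whose mixing weight ("complexity weight") controls the
  sample entropy of the channels — an emergent property, not a direct
  target;
* group contrasts matching the clinical directions: the chronic low back
  pain (CLBP) preset has a lower peak flexion/return angular velocity and a
  lower complexity weight (more stereotyped movement) than the healthy
  (NLBP) preset.

Every subject is deterministic given its seed; cohorts derive per-subject
seeds from a base seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imu_io import Group, Recording, SensorFrame, SensorId

__all__ = [
    "SynthParams",
    "GroundTruth",
    "nlbp_params",
    "clbp_params",
    "generate_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class SynthParams:
    """Generator settings for one clinical group.

    Peak velocities are in deg/s, periods in seconds, accelerations in g.
    ``white_frac`` is the complexity weight: the fraction of white (vs
    AR(1)-correlated) variance in both the additive noise and the
    cycle-to-cycle perturbations; higher values yield higher sample entropy.
    ``noise_sd_frac`` scales the additive gyroscope noise SD as a fraction
    of the subject's peak velocity.
    """

    duration: float = 70.0
    fs: float = 100.0
    period_mean: float = 1.43
    period_sd: float = 0.15          # cycle-to-cycle
    period_between_sd: float = 0.08  # subject-to-subject
    peak_velocity_mean: float = 120.0
    peak_velocity_between_sd: float = 12.0
    peak_cycle_jitter: float = 0.08  # fractional per-cycle amplitude SD
    white_frac: float = 0.7
    noise_sd_frac: float = 0.03
    tremor_sd: float = 0.06          # shared multiplicative amplitude tremor
    ar_phi: float = 0.97
    flexion_depth: float = 0.8       # Acc Z dip at deep flexion, g
    acc_noise_sd: float = 0.02       # accelerometer noise floor, g

    def __post_init__(self) -> None:
        for name in ("period_sd", "period_between_sd", "peak_velocity_between_sd",
                     "peak_cycle_jitter", "noise_sd_frac", "tremor_sd",
                     "acc_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.period_mean <= 0:
            raise ValueError("period_mean must be > 0")
        if not 0 <= self.white_frac <= 1:
            raise ValueError("white_frac must lie in [0, 1]")


def nlbp_params(**overrides) -> SynthParams:
    """Healthy-group preset: brisk movement, high complexity weight."""
    return replace(SynthParams(), **overrides)


def clbp_params(**overrides) -> SynthParams:
    """Chronic low back pain preset: slower peak velocity, more
    stereotyped (correlation-dominated) variability."""
    base = SynthParams(
        peak_velocity_mean=92.0,
        white_frac=0.25,
    )
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic subject.

    Times are seconds from the start of the full recording.  ``minima_times``
    are the deep-flexion instants (the Acc Z minima the segmentation hunts
    for); ``boundary_times`` their consecutive midpoints — the cycle limits
    a perfect segmentation would return.
    """

    minima_times: np.ndarray
    boundary_times: np.ndarray
    cycle_peak_velocities: np.ndarray
    params: SynthParams

    def boundary_samples(self, t0: float, t1: float, fs: float) -> np.ndarray:
        """True cycle limits as sample indices into the [t0, t1) window."""
        inside = self.boundary_times[
            (self.boundary_times >= t0) & (self.boundary_times < t1)
        ]
        return np.round((inside - t0) * fs).astype(int)


def _colored(n: int, white_frac: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance mix of white and AR(1) noise (complexity control)."""
    white = rng.standard_normal(n)
    ar = np.empty(n)
    innov = rng.standard_normal(n) * np.sqrt(1.0 - phi**2)
    ar[0] = rng.standard_normal()
    for t in range(1, n):
        ar[t] = phi * ar[t - 1] + innov[t]
    mix = np.sqrt(white_frac) * white + np.sqrt(1.0 - white_frac) * ar
    sd = mix.std()
    return mix / sd if sd > 0 else mix


def _cycle_grid(p: SynthParams, rng: np.random.Generator):
    """Cycle start times, durations and per-sample (cycle index, phase)."""
    subj_period = p.period_mean + p.period_between_sd * rng.standard_normal()
    subj_period = max(subj_period, 0.4 * p.period_mean)
    durations = []
    total = 0.0
    while total < p.duration + subj_period:
        d = subj_period + p.period_sd * rng.standard_normal()
        d = float(np.clip(d, 0.5 * subj_period, 1.8 * subj_period))
        durations.append(d)
        total += d
    durations = np.array(durations)
    starts = np.concatenate(([0.0], np.cumsum(durations)))[:-1]
    t = np.arange(int(round(p.duration * p.fs))) / p.fs
    k = np.searchsorted(starts, t, side="right") - 1
    phase = (t - starts[k]) / durations[k]
    return starts, durations, k, phase


def _per_cycle_amplitudes(
    n_cycles: int, base: float, p: SynthParams, rng: np.random.Generator
) -> np.ndarray:
    eps = _colored(n_cycles, p.white_frac, 0.8, rng)
    return base * (1.0 + p.peak_cycle_jitter * eps)


def generate_subject(
    params: SynthParams,
    group: Group | str,
    subject_id: str = "synth",
    seed: int | np.random.SeedSequence = 0,
) -> tuple[Recording, GroundTruth]:
    """One synthetic 3-sensor, 70 s recording plus its ground truth."""
    rng = np.random.default_rng(seed)
    p = params
    n = int(round(p.duration * p.fs))

    starts, durations, k, phase = _cycle_grid(p, rng)
    n_cycles = len(durations)
    subj_peak = p.peak_velocity_mean + p.peak_velocity_between_sd * rng.standard_normal()
    subj_peak = max(subj_peak, 0.3 * p.peak_velocity_mean)

    # Per-cycle amplitudes per sensor: the trunk (SENS1) swings further than
    # the pelvis (SENS2); the thigh (SENS3) follows attenuated.
    amp2 = _per_cycle_amplitudes(n_cycles, subj_peak, p, rng)
    amp1 = _per_cycle_amplitudes(n_cycles, 1.35 * subj_peak, p, rng)
    amp3 = _per_cycle_amplitudes(n_cycles, 0.60 * subj_peak, p, rng)

    pulse = -np.sin(2.0 * np.pi * phase)  # flexion lobe then return lobe
    # Shared multiplicative tremor: movement-level variability common to the
    # whole kinematic chain, so it largely cancels in sensor differences.
    tremor = 1.0 + p.tremor_sd * _colored(n, p.white_frac, 0.9, rng)
    v1 = amp1[k] * pulse * tremor
    v2 = amp2[k] * pulse * tremor
    v3 = amp3[k] * pulse * tremor

    noise_sd = p.noise_sd_frac * subj_peak

    def gyr_noise() -> np.ndarray:
        return noise_sd * _colored(n, p.white_frac, p.ar_phi, rng)

    def acc_noise() -> np.ndarray:
        return p.acc_noise_sd * _colored(n, p.white_frac, p.ar_phi, rng)

    # Gravity projection: Acc Z (in g) dips at deep flexion (phase 0.5).
    dip = np.sin(np.pi * phase) ** 4
    acc_z1 = 1.0 - p.flexion_depth * dip + acc_noise()

    minima_times = starts + durations / 2.0
    minima_times = minima_times[minima_times < p.duration]
    boundary_times = (minima_times[:-1] + minima_times[1:]) / 2.0

    def frame(sid: SensorId, main_gyr: dict[str, np.ndarray],
              main_acc: dict[str, np.ndarray]) -> SensorFrame:
        channels: dict[str, np.ndarray] = {}
        for axis in ("X", "Y", "Z"):
            name = f"Acc {axis}"
            channels[name] = main_acc.get(
                name, 0.15 * dip * (1 if axis == "X" else -1) + acc_noise()
            )
            name = f"Gyr {axis}"
            channels[name] = main_gyr.get(
                name, 0.2 * noise_sd * _colored(n, p.white_frac, p.ar_phi, rng)
                + 0.1 * subj_peak * pulse
            )
        return SensorFrame(sensor_id=sid, channels=channels, fs=p.fs)

    sensors = {
        SensorId.SENS1: frame(
            SensorId.SENS1,
            main_gyr={"Gyr Y": v1 + gyr_noise()},
            main_acc={"Acc Z": acc_z1},
        ),
        SensorId.SENS2: frame(
            SensorId.SENS2,
            main_gyr={"Gyr Y": v2 + gyr_noise()},
            main_acc={"Acc X": 0.25 * dip + acc_noise()},
        ),
        SensorId.SENS3: frame(
            SensorId.SENS3,
            # Rotated mounting: -Gyr Z carries the flexion pattern.
            main_gyr={"Gyr Z": -(v3 + gyr_noise())},
            main_acc={},
        ),
    }
    rec = Recording(
        subject_id=subject_id, group=Group(group), sensors=sensors, fs=p.fs
    )
    truth = GroundTruth(
        minima_times=minima_times,
        boundary_times=boundary_times,
        cycle_peak_velocities=amp2[: len(minima_times)],
        params=p,
    )
    return rec, truth


def generate_cohort(
    params_nlbp: SynthParams | None = None,
    params_clbp: SynthParams | None = None,
    n_per_group: int = 20,
    seed: int = 0,
) -> tuple[list[Recording], list[GroundTruth]]:
    """n NLBP + n CLBP subjects with per-subject seeds spawned from *seed*."""
    params_nlbp = params_nlbp or nlbp_params()
    params_clbp = params_clbp or clbp_params()
    children = np.random.SeedSequence(seed).spawn(2 * n_per_group)
    recs: list[Recording] = []
    truths: list[GroundTruth] = []
    for i in range(n_per_group):
        rec, tr = generate_subject(
            params_nlbp, Group.NLBP, subject_id=f"NLBP{i:02d}", seed=children[i]
        )
        recs.append(rec)
        truths.append(tr)
    for i in range(n_per_group):
        rec, tr = generate_subject(
            params_clbp, Group.CLBP, subject_id=f"CLBP{i:02d}",
            seed=children[n_per_group + i],
        )
        recs.append(rec)
        truths.append(tr)
    return recs, truths
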