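"""Seedable synthetic sEMG + knee-angle recordings.

Emulates the statistical structure of a four-electrode lower-limb protocol
(vastus medialis, semitendinosus, biceps femoris, rectus femoris, plus a
knee goniometer): per-class kinematic angle templates, and band-limited
(20-460 Hz) Gaussian carriers amplitude-modulated by rectified functions of
the angle and its velocity with channel-specific gains.  No transition
phases between movements are generated.

Angle convention: degrees, clipped to [0, 120]; extension increases the
angle, flexion decreases it.  Walking oscillates mid-range; sitting with
knee extension ramps up from a flexed baseline; standing with knee flexion
dips down from a near-straight baseline.  Amplitudes are arbitrary units.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .dataio import Recording
from .movements import MovementClass

ANGLE_MAX = 120.0  # physiological cap, degrees


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic acquisition.

    Per-class entries are indexed by the MovementClass integer code
    (walking, sitting-knee-extension, standing-knee-flexion).
    """

    fs: float = 1000.0
    duration_s: float = 10.0
    n_channels: int = 4
    band: tuple[float, float] = (20.0, 460.0)
    #: (low, high) angle excursion per class, degrees
    angle_range: tuple[tuple[float, float], ...] = (
        (35.0, 85.0),   # walking: mid-range flexion-extension oscillation
        (15.0, 100.0),  # sitting: extension ramps from a flexed baseline
        (30.0, 110.0),  # standing: flexion dips from a near-straight leg
    )
    #: movement cycle rate per class, Hz
    cycle_rate: tuple[float, ...] = (1.0, 0.4, 0.5)
    #: per-channel coupling of the envelope to |d(angle)/dt| (agonist burst)
    velocity_gain: tuple[float, ...] = (0.9, 0.5, 0.7, 0.4)
    #: per-channel coupling of the envelope to angle/ANGLE_MAX (tonic hold)
    angle_gain: tuple[float, ...] = (0.4, 1.0, 0.6, 0.9)
    #: per-class x per-channel recruitment multipliers for the electrode
    #: sites (vm, st, bf, rf): walking recruits all four phasically,
    #: sitting knee extension is quadriceps-dominant (vm, rf), standing
    #: knee flexion is hamstrings-dominant (st, bf)
    recruitment: tuple[tuple[float, ...], ...] = (
        (1.0, 0.9, 0.8, 1.0),
        (1.3, 0.3, 0.35, 1.2),
        (0.3, 1.3, 1.2, 0.35),
    )
    #: relative amplitude of the unmodulated background activity
    noise_floor: float = 0.08
    #: multiplicative amplitude step between consecutive classes
    class_separation: float = 1.3
    seed: int = 0

    def __post_init__(self):
        low, high = self.band
        if not (0.0 < low < high < self.fs / 2.0):
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < fs/2"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if len(self.velocity_gain) < self.n_channels or \
                len(self.angle_gain) < self.n_channels:
            raise ValueError("need a gain per channel")
        if any(len(row) < self.n_channels for row in self.recruitment):
            raise ValueError("need a recruitment multiplier per channel")
        for lo, hi in self.angle_range:
            if not (0.0 <= lo < hi <= ANGLE_MAX):
                raise ValueError(
                    f"angle range ({lo}, {hi}) outside [0, {ANGLE_MAX}]"
                )


def _bandpass_sos(cfg: SimConfig):
    return sps.butter(6, cfg.band, btype="bandpass", fs=cfg.fs, output="sos")


def _carrier(n: int, sos, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (zero-phase filtering)."""
    x = rng.standard_normal(n)
    y = sps.sosfiltfilt(sos, x)
    return y / y.std()


def _angle_template(cls: MovementClass, cfg: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Class kinematic template with small per-trial rate/phase/amplitude
    jitter so trials are distinct but the class pattern is preserved."""
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    lo, hi = cfg.angle_range[int(cls)]
    rate = cfg.cycle_rate[int(cls)] * rng.uniform(0.9, 1.1)
    phase = rng.uniform(0.0, 1.0)
    amp_jit = rng.uniform(0.9, 1.0)
    span = (hi - lo) * amp_jit
    if cls == MovementClass.WALKING:
        mid = (lo + hi) / 2.0
        angle = mid + (span / 2.0) * np.sin(2.0 * np.pi * (rate * t + phase))
    else:
        # smooth repeated ramp-and-return pulses, 0 -> 1 -> 0 per cycle
        pulse = np.sin(np.pi * ((rate * t + phase) % 1.0)) ** 2
        if cls == MovementClass.SITTING_KNEE_EXTENSION:
            angle = lo + span * pulse          # extension raises the angle
        else:
            angle = hi - span * pulse          # flexion dips it
    return np.clip(angle, 0.0, ANGLE_MAX)


def _envelopes(angle: np.ndarray, cls: MovementClass,
               cfg: SimConfig) -> np.ndarray:
    """Per-channel activation envelopes: velocity burst + tonic hold terms."""
    vel = np.abs(np.gradient(angle) * cfg.fs)  # deg/s
    vmax = vel.max()
    vel_n = vel / vmax if vmax > 0 else vel
    pos_n = angle / ANGLE_MAX
    recruit = np.asarray(cfg.recruitment[int(cls)][:cfg.n_channels], float)
    # recruitment shapes the channel pattern only; normalizing its mean to 1
    # leaves class_separation as the sole between-class amplitude scaler
    recruit = recruit / recruit.mean()
    env = np.empty((angle.shape[0], cfg.n_channels))
    for c in range(cfg.n_channels):
        env[:, c] = recruit[c] * (cfg.velocity_gain[c] * vel_n
                                  + cfg.angle_gain[c] * pos_n)
    return env * (cfg.class_separation ** int(cls))


def gen_recording(cls: MovementClass, cfg: SimConfig | None = None) -> Recording:
    """Generate one synthetic trial for a movement class.

    The sEMG channels are band-limited Gaussian carriers modulated by
    class- and channel-specific envelopes plus an unmodulated noise floor.
    Identical ``cfg`` (including the seed) gives bit-identical output.
    """
    cfg = cfg or SimConfig()
    cls = MovementClass.from_any(cls)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(cls)]))
    sos = _bandpass_sos(cfg)
    angle = _angle_template(cls, cfg, rng)
    env = _envelopes(angle, cls, cfg)
    n = angle.shape[0]
    emg = np.empty((n, cfg.n_channels))
    for c in range(cfg.n_channels):
        emg[:, c] = (env[:, c] + cfg.noise_floor) * _carrier(n, sos, rng)
    return Recording(
        emg=emg, angle=angle, fs=cfg.fs, cls=cls,
        subject_id=f"syn-{cls.name.lower()}", cohort="synthetic",
    )


def gen_dataset(n_trials_per_class: int,
                cfg: SimConfig | None = None) -> list[Recording]:
    """Balanced synthetic dataset: ``3 * n_trials_per_class`` recordings.

    Per-trial seeds are derived deterministically from ``cfg.seed`` so the
    whole dataset is reproducible and trials are mutually independent.
    """
    if n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    cfg = cfg or SimConfig()
    out: list[Recording] = []
    for cls in MovementClass:
        for trial in range(n_trials_per_class):
            child = int(
                np.random.SeedSequence(
                    [int(cfg.seed), 1 + int(cls), trial]
                ).generate_state(1)[0] % (2 ** 31)
            )
            rec = gen_recording(cls, dataclasses.replace(cfg, seed=child))
            rec.subject_id = f"syn-{cls.name.lower()}-t{trial}"
            out.append(rec)
    return out
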