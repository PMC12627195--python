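"""Synthetic continuous-report experiments with serial-bias structure.

Generates complete datasets — trial sequences, report errors, movement-onset
latencies, and mouse trajectories — mimicking a two-task color study:

* a perceptual matching task (the target stays visible; one report per trial),
* a delayed working-memory task (one consolidation report right after mask
  offset and one retrieval report after a delay; 400 trials per participant).

The previous-to-current target color offset steps through the nine values
-144:-36:+144 in shuffled balanced blocks, with a uniformly drawn "random"
target roughly every tenth trial (flagged, excluded from binned analysis).
Report errors are von Mises around a DoG of the relative color; report-type
amplitudes default to a repulsive perceptual bias and attractive
consolidation/retrieval biases. Mouse trajectories move radially out to the
response wheel while their angular bias follows a time-varying DoG amplitude
(a decaying early component plus a rising late component), then home in on
the trial's report error so that the final click equals the recorded
response. For consolidation reports the default early component is repulsive
and the late component attractive, producing a within-movement
repulsion-to-attraction crossover; the crossover is coupled to movement-onset
latency (late-onset movements start with the attractive component already
engaged).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .circular import dog, wrap_angle, wrap_signed

__all__ = [
    "REPORT_TYPES",
    "STEP_OFFSETS",
    "BiasProfile",
    "TrajectoryConfig",
    "OnsetConfig",
    "SimConfig",
    "TrajectorySamples",
    "SimulatedDataset",
    "generate_target_sequence",
    "simulate_errors",
    "simulate_trajectory",
    "simulate_experiment",
]

REPORT_TYPES = ("perceptual", "consolidation", "retrieval")

#: The nine relative-color step conditions, degrees.
STEP_OFFSETS = tuple(range(-144, 145, 36))


@dataclass(frozen=True)
class BiasProfile:
    """Time-varying DoG amplitude over normalized movement time u in [0, 1].

    alpha_eff(u) = early_amp * (1 - sigmoid((u - early_mid)/slope))
                 + late_amp  *      sigmoid((u - late_mid)/slope)

    ``early_amp`` dominates right after movement onset and decays;
    ``late_amp`` rises toward the click. Units: degrees of bias amplitude.
    """

    early_amp: float
    late_amp: float
    early_mid: float = 0.45
    late_mid: float = 0.55
    slope: float = 0.12

    def alpha_eff(self, u):
        u = np.asarray(u, dtype=float)
        decay = 1.0 - _sigmoid((u - self.early_mid) / self.slope)
        rise = _sigmoid((u - self.late_mid) / self.slope)
        out = self.early_amp * decay + self.late_amp * rise
        return out if out.ndim else float(out)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _default_profiles():
    # Early components: residual sensory adaptation (repulsive) for the
    # perceptual and consolidation reports; an initial mnemonic overshoot
    # (extra attraction) for retrieval. Late components converge on the
    # report-level amplitudes so the click error matches the report model.
    return {
        "perceptual": BiasProfile(early_amp=-4.0, late_amp=-0.8),
        "consolidation": BiasProfile(early_amp=-3.0, late_amp=+1.6),
        "retrieval": BiasProfile(early_amp=+9.0, late_amp=+6.2, late_mid=0.40),
    }


@dataclass
class TrajectoryConfig:
    """Geometry and noise of simulated cursor paths."""

    n_move_samples: int = 80
    n_pre_samples: int = 5
    wheel_radius_px: float = 300.0
    motor_noise_sd_px: float = 2.0
    pre_onset_jitter_px: float = 1.0
    move_duration_ms: float = 700.0
    move_duration_sigma: float = 0.2  # log-normal spread of duration
    profiles: dict = field(default_factory=_default_profiles)
    #: profile used for consolidation movements that start late (after the
    #: median onset latency): the attractive component is engaged from the
    #: start and the early repulsive residue has faded.
    consolidation_late_onset: BiasProfile = field(
        default_factory=lambda: BiasProfile(early_amp=0.0, late_amp=+1.6, late_mid=0.30)
    )


@dataclass
class OnsetConfig:
    """Log-normal movement-onset latency: median exp(mu) ms, shape sigma."""

    median_ms: float = 300.0
    sigma: float = 0.4

    def draw(self, rng, size=None):
        return np.exp(rng.normal(np.log(self.median_ms), self.sigma, size=size))


def _default_alpha():
    return {"perceptual": -0.8, "consolidation": +1.6, "retrieval": +6.2}


def _default_kappa():
    # Von Mises concentrations per report type (circular SDs of about
    # 3.6, 9.1, and 12.8 degrees). The perceptual task has the target visible,
    # so its trial errors are limited mainly by wheel-click precision; memory
    # reports degrade with consolidation and retention demands. The values are
    # chosen to put the population posterior precision of the bias amplitude
    # in the regime the analyses are designed for.
    return {"perceptual": 250.0, "consolidation": 40.0, "retrieval": 20.0}


@dataclass
class SimConfig:
    """Generating truth for one synthetic experiment."""

    n_participants: int = 20
    n_perceptual_trials: int = 150
    n_wm_trials: int = 400
    alpha_true: dict = field(default_factory=_default_alpha)
    w_true: float = 0.02
    beta_true: float = 0.0
    kappa: dict = field(default_factory=_default_kappa)
    random_trial_period: int = 10
    onset: OnsetConfig = field(default_factory=OnsetConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    include_trajectories: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.n_participants, self.n_perceptual_trials, self.n_wm_trials) <= 0:
            raise ValueError("counts must be positive")
        if self.w_true <= 0:
            raise ValueError("w_true must be > 0")
        if isinstance(self.kappa, (int, float)):
            self.kappa = {rt: float(self.kappa) for rt in REPORT_TYPES}
        missing = [rt for rt in REPORT_TYPES if rt not in self.alpha_true]
        if missing:
            raise ValueError(f"alpha_true missing report types: {missing}")
        if any(k <= 0 for k in self.kappa.values()):
            raise ValueError("kappa must be > 0")
        if self.random_trial_period < 2:
            raise ValueError("random_trial_period must be >= 2")


@dataclass
class TrajectorySamples:
    """Raw cursor path of one response, from response-screen onset to click."""

    timestamps: np.ndarray  # ms, strictly increasing, first sample at t=0
    xs: np.ndarray  # px, screen-centered
    ys: np.ndarray  # px
    target_angle: float  # wheel angle of the true target color, degrees

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        n = self.timestamps.size
        if not (self.xs.size == n and self.ys.size == n):
            raise ValueError("timestamps, xs, ys must have equal length")
        if n < 3:
            raise ValueError("a trajectory needs at least 3 samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def click_index(self) -> int:
        return self.timestamps.size - 1


@dataclass
class SimulatedDataset:
    """Trials, trajectories, and the generating configuration."""

    trials: pd.DataFrame
    trajectories: dict  # (participant, report_type, trial_index) -> TrajectorySamples
    truth: SimConfig


def generate_target_sequence(n_trials: int, period: int, rng):
    """Target angles plus random-condition flags for one task block.

    Non-random trials step from the previous target by one of the nine
    offsets -144:36:+144, drawn from shuffled balanced blocks; within each
    consecutive window of ``period`` trials one trial's target is instead
    drawn uniformly on the wheel and flagged random. Returns
    ``(targets, is_random)`` arrays of length ``n_trials``.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if period < 2:
        raise ValueError("period must be >= 2")
    is_random = np.zeros(n_trials, dtype=bool)
    for start in range(0, n_trials, period):
        block = np.arange(start, min(start + period, n_trials))
        # never make the very first trial the random one: it has no
        # previous target, so the flag would be unobservable downstream
        block = block[block > 0]
        if block.size:
            is_random[rng.choice(block)] = True

    steps = np.array(STEP_OFFSETS, dtype=float)
    bag: list = []
    targets = np.empty(n_trials)
    targets[0] = rng.uniform(0.0, 360.0)
    for i in range(1, n_trials):
        if is_random[i]:
            targets[i] = rng.uniform(0.0, 360.0)
            continue
        if not bag:
            bag = list(rng.permutation(steps))
        targets[i] = wrap_angle(targets[i - 1] + bag.pop())
    return targets, is_random


def simulate_errors(targets, is_random, report_type: str, config: SimConfig, rng,
                    *, participant=0, task=None, trial_index_start: int = 0) -> pd.DataFrame:
    """Trial records with von Mises report errors around the DoG bias.

    The error mean for each trial is ``dog(x)`` where ``x`` is the previous
    target's signed offset from the current target; the first trial has no
    previous target (NaN) and an unbiased error.
    """
    if report_type not in REPORT_TYPES:
        raise ValueError(f"unknown report type {report_type!r}")
    targets = np.asarray(targets, dtype=float)
    n = targets.size
    is_random = np.asarray(is_random, dtype=bool)
    prev = np.full(n, np.nan)
    prev[1:] = targets[:-1]
    x = np.full(n, np.nan)
    x[1:] = wrap_signed(prev[1:] - targets[1:])
    mean_err = np.where(
        np.isnan(x),
        config.beta_true,
        dog(np.nan_to_num(x), config.alpha_true[report_type], config.w_true, config.beta_true),
    )
    kappa = config.kappa[report_type]
    noise = rng.vonmises(0.0, kappa, size=n)
    err = wrap_signed(mean_err + np.rad2deg(noise))
    if task is None:
        task = "perceptual" if report_type == "perceptual" else "wm"
    return pd.DataFrame(
        {
            "participant": participant,
            "task": task,
            "report_type": report_type,
            "trial_index": np.arange(trial_index_start, trial_index_start + n),
            "target_deg": targets,
            "prev_target_deg": prev,
            "response_deg": wrap_angle(targets + err),
            "is_random": is_random,
        }
    )


def _wheel_xy(angle_deg, radius):
    """Screen position of a wheel angle (measured clockwise from vertical)."""
    rad = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return radius * np.sin(rad), radius * np.cos(rad)


def simulate_trajectory(x_offset: float, target_angle: float, response_error: float,
                        report_type: str, onset_latency_ms: float,
                        config: SimConfig, rng) -> TrajectorySamples:
    """One cursor path: center dwell, radial movement, click on the wheel.

    The cursor's wheel angle during movement is
    ``target + dog(x; alpha_eff(u), w) + homing ramp + motor noise``, where
    ``alpha_eff(u)`` is the report type's bias profile over normalized time
    and the linear homing ramp makes the final click land exactly at
    ``target + response_error``. Off-grid trials (``x_offset`` NaN, i.e.
    first/random trials) use a zero bias profile.
    """
    tc = config.trajectory
    profile = tc.profiles[report_type]
    if report_type == "consolidation" and onset_latency_ms > config.onset.median_ms:
        profile = tc.consolidation_late_onset

    n_move = tc.n_move_samples
    u = np.linspace(0.0, 1.0, n_move)
    if np.isnan(x_offset):
        path_bias = np.zeros(n_move)
    else:
        path_bias = dog(x_offset, 1.0, config.w_true, 0.0) * profile.alpha_eff(u)
    # homing ramp: distribute the gap between the profile's endpoint bias and
    # the trial's actual report error linearly over the movement
    angle = target_angle + path_bias + u * (response_error - path_bias[-1])
    radius = u * tc.wheel_radius_px
    mx, my = _wheel_xy(angle, radius)
    if tc.motor_noise_sd_px > 0 and n_move > 2:
        mx[1:-1] += rng.normal(0.0, tc.motor_noise_sd_px, n_move - 2)
        my[1:-1] += rng.normal(0.0, tc.motor_noise_sd_px, n_move - 2)

    n_pre = tc.n_pre_samples
    pre_t = np.linspace(0.0, onset_latency_ms, n_pre + 1)[:-1]
    pre_x = np.zeros(n_pre)
    pre_y = np.zeros(n_pre)
    if tc.pre_onset_jitter_px > 0 and n_pre > 1:
        pre_x[1:] = rng.normal(0.0, tc.pre_onset_jitter_px, n_pre - 1)
        pre_y[1:] = rng.normal(0.0, tc.pre_onset_jitter_px, n_pre - 1)

    duration = tc.move_duration_ms * np.exp(rng.normal(0.0, tc.move_duration_sigma))
    move_t = onset_latency_ms + u * duration
    return TrajectorySamples(
        timestamps=np.concatenate([pre_t, move_t]),
        xs=np.concatenate([pre_x, mx]),
        ys=np.concatenate([pre_y, my]),
        target_angle=float(target_angle),
    )


def _simulate_task(config, rng, participant, task, n_trials, report_types, trajectories):
    targets, is_random = generate_target_sequence(n_trials, config.random_trial_period, rng)
    frames = []
    for rt in report_types:
        df = simulate_errors(targets, is_random, rt, config, rng,
                             participant=participant, task=task)
        if config.include_trajectories:
            lat = config.onset.draw(rng, n_trials)
            err = wrap_signed(df["response_deg"].to_numpy() - df["target_deg"].to_numpy())
            prev = df["prev_target_deg"].to_numpy()
            x = wrap_signed(np.nan_to_num(prev) - df["target_deg"].to_numpy())
            x[0] = np.nan
            x[is_random] = np.nan  # random trials: bias profile off
            for i in range(n_trials):
                trajectories[(participant, rt, i)] = simulate_trajectory(
                    x[i], targets[i], err[i], rt, lat[i], config, rng
                )
        frames.append(df)
    return frames


def simulate_experiment(config: SimConfig) -> SimulatedDataset:
    """Full synthetic study: all participants, both tasks, all reports.

    Deterministic given ``config.seed``. Each participant contributes one
    perceptual task block (one report per trial) and one working-memory
    block (a consolidation and a retrieval report per trial, sharing the
    target sequence).
    """
    root = np.random.default_rng(config.seed)
    seeds = root.spawn(config.n_participants)
    frames = []
    trajectories: dict = {}
    for p, prng in enumerate(seeds):
        frames += _simulate_task(
            config, prng, p, "perceptual", config.n_perceptual_trials,
            ("perceptual",), trajectories,
        )
        frames += _simulate_task(
            config, prng, p, "wm", config.n_wm_trials,
            ("consolidation", "retrieval"), trajectories,
        )
    trials = pd.concat(frames, ignore_index=True)
    return SimulatedDataset(trials=trials, trajectories=trajectories,
                            truth=copy.deepcopy(config))
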