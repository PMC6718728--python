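"""Synthetic session generator with known failure ground truth.

Emulates the study conditions of the grasp-carry-release experiment: each
task has a rest / power-grasp / rest intent script; the 4-channel prediction
trace follows that intent with band-limited noise kept clear of the
actuation threshold; instability events are injected as oscillatory
transients that drive one channel across the threshold *contrary* to the
intent; the hand electromechanics turn predictions into digit statuses; and
an unreliable human reporter turns failures into (some) button presses.

Every random draw comes from generators derived deterministically from the
configured seed, so a session is bit-reproducible from its config.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .session import (
    CHANNEL_DIGITS,
    DIGIT_CHANNEL,
    N_CHANNELS,
    N_DIGITS,
    ButtonEvent,
    DigitStatus,
    DigitStatusTrace,
    FailureEvent,
    FailureKind,
    PredictionTrace,
    Session,
    TaskTimeline,
    Zone,
)

ZONES = (Zone.PRE_GRASP, Zone.GRASP, Zone.POST_GRASP)

#: Fixed stream keys for the per-subsystem random generators.
_STREAM_DURATIONS = 1
_STREAM_FAILURES = 2
_STREAM_NOISE = 3
_STREAM_BUTTONS = 4


class ConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of the session simulator.

    Defaults encode the study conditions: 20 carrying tasks, a 0.3
    actuation threshold, a Post-Grasp zone that is the longest on average
    and carries most of the instability (Pre : Grasp : Post failure
    intensity 1 : 1 : 2.5, about three failures per task in total), and a
    button reporter with a structural delay of the order of seconds, a
    refractory period after each press, and a non-zero miss probability.
    """

    seed: int = 0
    n_tasks: int = 20
    sample_rate: float = 100.0
    #: mean zone durations (pre-grasp, grasp, post-grasp), seconds
    zone_duration_means: tuple[float, float, float] = (5.0, 8.0, 12.0)
    zone_duration_sd_frac: float = 0.15
    #: expected failures per task in each zone (pre, grasp, post)
    failure_intensity: tuple[float, float, float] = (0.65, 0.65, 1.7)
    oscillation_amplitude: float = 0.5
    oscillation_freq: float = 3.0  # Hz
    oscillation_duration: float = 1.0  # s
    actuation_threshold: float = 0.3
    digit_speed: float = 1.0  # full travel fraction per second
    stall_during_grasp: bool = True
    contact_position: float = 0.6  # closure fraction where the mug blocks
    button_delay_mean: float = 1.5  # s
    button_delay_sd: float = 0.5  # s
    button_miss_prob: float = 0.2
    button_refractory: float = 3.0  # s
    rest_level: float = 0.05
    grasp_level: float = 0.7
    noise_sd: float = 0.02
    ramp_time: float = 0.3  # s, intended grasp on/off transition
    inter_task_gap: float = 2.0  # s, seated pause between tasks
    subject_id: str = "SIM"

    def validate(self) -> None:
        if any(d <= 0 for d in self.zone_duration_means):
            raise ConfigError("zone durations must be positive")
        if any(i < 0 for i in self.failure_intensity):
            raise ConfigError("failure intensities must be non-negative")
        if not 0.0 < self.actuation_threshold < 1.0:
            raise ConfigError("actuation threshold must lie in (0, 1)")
        for p in (self.button_miss_prob,):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.sample_rate <= 0 or self.n_tasks < 1:
            raise ConfigError("sample_rate and n_tasks must be positive")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # One logical RNG per subsystem, keyed by (stream, seed) so streams are
    # independent but fully determined by the config seed.
    return np.random.default_rng([stream, cfg.seed])


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _draw_timelines(cfg: SimConfig) -> list[TaskTimeline]:
    rng = _rng(cfg, _STREAM_DURATIONS)
    tasks = []
    t = cfg.inter_task_gap / 2.0
    for _ in range(cfg.n_tasks):
        durs = []
        for m in cfg.zone_duration_means:
            d = rng.normal(m, cfg.zone_duration_sd_frac * m)
            durs.append(max(d, 0.5 * m, 1.0))  # truncate short draws
        t_start = t
        t_grasp = t_start + durs[0]
        t_release = t_grasp + durs[1]
        t_end = t_release + durs[2]
        tasks.append(TaskTimeline(t_start, t_grasp, t_release, t_end))
        t = t_end + cfg.inter_task_gap
    return tasks


def _intent_signal(cfg: SimConfig, tasks: list[TaskTimeline], times: np.ndarray) -> np.ndarray:
    """Noise-free prediction following the scripted intent.

    Flexion channels (thumb, index, coupled fingers) rise to the grasp
    level during each GRASP zone with smooth ramps; the thumb-rotation
    channel stays at rest throughout.
    """
    clean = np.full((N_CHANNELS, times.size), cfg.rest_level)
    span = cfg.grasp_level - cfg.rest_level
    for task in tasks:
        up = _smoothstep((times - task.t_grasp) / cfg.ramp_time)
        down = _smoothstep((times - task.t_release) / cfg.ramp_time)
        bump = span * (up - down)
        for ch in range(3):  # flexion channels only
            clean[ch] += bump
    return clean


def _draw_failure_times(cfg: SimConfig, tasks: list[TaskTimeline]) -> list[tuple[float, Zone]]:
    """Poisson counts per task and zone; times clear of zone edges so the
    injected transient fits inside the zone.  Post-Grasp draws concentrate
    mid-zone (Beta(2, 2)); the other zones are uniform."""
    rng = _rng(cfg, _STREAM_FAILURES)
    # Keep transients clear of zone edges: the crossing must not fall in the
    # intended-actuation window around t_grasp / t_release, and the whole
    # transient must fit inside its zone.
    edge = max(0.75 * cfg.oscillation_duration, 2.0 * cfg.ramp_time + 0.2)
    tail = max(1.5 * cfg.oscillation_duration, 2.0 * cfg.ramp_time + 0.2)
    out: list[tuple[float, Zone]] = []
    for task in tasks:
        for zone, lam in zip(ZONES, cfg.failure_intensity):
            z0, z1 = task.zone_bounds(zone)
            lo, hi = z0 + edge, z1 - tail
            if lam <= 0 or hi <= lo:
                continue
            for _ in range(rng.poisson(lam)):
                u = rng.beta(2.0, 2.0) if zone is Zone.POST_GRASP else rng.uniform()
                out.append((lo + u * (hi - lo), zone))
    out.sort(key=lambda p: p[0])
    return out


def generate_session(cfg: SimConfig) -> Session:
    """Simulate one full session: traces, timelines, failures, buttons."""
    cfg.validate()
    rate = cfg.sample_rate
    thr = cfg.actuation_threshold

    tasks = _draw_timelines(cfg)
    total = tasks[-1].t_end + cfg.inter_task_gap / 2.0
    n = int(round(total * rate)) + 1
    times = np.arange(n) / rate

    clean = _intent_signal(cfg, tasks, times)

    # Band-limited noise, then clipped so that intent-conforming samples
    # stay clear of the threshold: only injected transients (and the
    # intended grasp ramps) may cross it.
    noise_rng = _rng(cfg, _STREAM_NOISE)
    noise = gaussian_filter1d(
        noise_rng.normal(0.0, 1.0, size=(N_CHANNELS, n)), sigma=0.05 * rate, axis=1
    )
    sd = noise.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    noisy = clean + cfg.noise_sd * noise / sd

    low_margin, high_margin = 0.03, 0.05
    at_rest = clean <= cfg.rest_level + 1e-9
    at_grasp = clean >= cfg.grasp_level - 1e-9
    noisy[at_rest] = np.clip(noisy[at_rest], 0.0, thr - low_margin)
    noisy[at_grasp] = np.clip(noisy[at_grasp], thr + high_margin, 1.0)

    # Inject oscillatory transients contrary to intent.
    fail_rng = _rng(cfg, _STREAM_FAILURES + 100)
    dur_samples = int(round(cfg.oscillation_duration * rate))
    tau = np.arange(dur_samples) / rate
    envelope = np.sin(np.pi * tau / cfg.oscillation_duration) ** 2
    wave = cfg.oscillation_amplitude * np.sin(
        2.0 * np.pi * cfg.oscillation_freq * tau
    ) * envelope

    planned = _draw_failure_times(cfg, tasks)
    injected: list[tuple[int, int, FailureKind]] = []  # (start idx, ch, kind)
    for t_f, zone in planned:
        i0 = int(round(t_f * rate))
        if i0 + dur_samples >= n:
            continue
        if zone is Zone.GRASP:
            kind = FailureKind.SPURIOUS_OPEN
            ch = int(fail_rng.integers(0, 3))  # a flexion channel dips
            noisy[ch, i0 : i0 + dur_samples] -= np.abs(wave)
        else:
            kind = FailureKind.SPURIOUS_CLOSE
            ch = int(fail_rng.integers(0, N_CHANNELS))  # any channel rises
            noisy[ch, i0 : i0 + dur_samples] += np.abs(wave)
        injected.append((i0, ch, kind))

    np.clip(noisy, 0.0, 1.0, out=noisy)

    # Ground-truth failure time: first sample of the transient at which the
    # channel actually crosses the threshold (samples at the threshold
    # count as below).
    above = noisy > thr
    failures: list[FailureEvent] = []
    for i0, ch, kind in injected:
        want = kind is FailureKind.SPURIOUS_CLOSE  # looking for below->above
        idx = None
        for i in range(max(i0, 1), min(i0 + dur_samples, n)):
            if above[ch, i] != above[ch, i - 1] and above[ch, i] == want:
                idx = i
                break
        if idx is None:  # overlapping transients cancelled the crossing
            continue
        failures.append(
            FailureEvent(time=idx / rate, channel=ch + 1, kind=kind)
        )
    failures.sort(key=lambda f: f.time)

    prediction = PredictionTrace(sample_rate=rate, values=noisy)

    contact_limit = np.ones((N_DIGITS, n))
    if cfg.stall_during_grasp:
        for task in tasks:
            i0 = int(round(task.t_grasp * rate))
            i1 = int(round(task.t_release * rate))
            contact_limit[:5, i0:i1] = cfg.contact_position  # mug blocks digits
    digit_status = simulate_hand(prediction, contact_limit, cfg)

    buttons = simulate_buttons(failures, cfg)

    return Session(
        prediction=prediction,
        digit_status=digit_status,
        tasks=tasks,
        failures=failures,
        buttons=buttons,
        subject_id=cfg.subject_id,
    )


def simulate_hand(
    prediction: PredictionTrace,
    contact_limit: np.ndarray,
    cfg: SimConfig,
) -> DigitStatusTrace:
    """Electromechanical hand model producing per-digit status flags.

    Below the actuation threshold each digit is driven toward the fully
    open home configuration; above it the closing speed is proportional to
    the excess over the threshold.  ``contact_limit`` (6 x T, closure
    fraction) caps how far each digit can close at each sample — a digit
    commanded to close beyond its limit reports STALLED.
    """
    thr = cfg.actuation_threshold
    cmd = prediction.values[list(DIGIT_CHANNEL), :]
    n = prediction.n_samples
    if contact_limit.shape != (N_DIGITS, n):
        raise ValueError(
            f"contact_limit must be ({N_DIGITS}, {n}), got {contact_limit.shape}"
        )
    dt = 1.0 / prediction.sample_rate

    pos = np.zeros(N_DIGITS)
    statuses = np.empty((N_DIGITS, n), dtype=np.int8)
    for t in range(n):
        c = cmd[:, t]
        closing = c > thr
        speed = np.where(
            closing, cfg.digit_speed * (c - thr) / (1.0 - thr), -cfg.digit_speed
        )
        new = pos + speed * dt
        limit = contact_limit[:, t]
        st = np.empty(N_DIGITS, dtype=np.int8)

        blocked = closing & (new >= limit) & (limit < 1.0)
        at_top = closing & (new >= 1.0) & ~blocked
        still_closing = closing & ~blocked & ~at_top
        at_bottom = ~closing & (new <= 0.0)
        still_opening = ~closing & ~at_bottom

        new = np.where(blocked, limit, new)
        new = np.where(at_top, 1.0, new)
        new = np.where(at_bottom, 0.0, new)

        st[blocked] = DigitStatus.STALLED
        st[at_top] = DigitStatus.CLOSED
        st[still_closing] = DigitStatus.CLOSING
        st[at_bottom] = DigitStatus.OPEN
        st[still_opening] = DigitStatus.OPENING
        pos = new
        statuses[:, t] = st
    return DigitStatusTrace(sample_rate=prediction.sample_rate, statuses=statuses)


def simulate_buttons(failures: list[FailureEvent], cfg: SimConfig) -> list[ButtonEvent]:
    """Unreliable human failure reporting.

    Each failure is noticed with probability ``1 - button_miss_prob``; a
    noticed failure produces a press after a positive structural delay
    (Normal truncated at zero).  Failures occurring before the previous
    press's refractory window has elapsed are absorbed and produce no
    press, which covers the can't-signal-again, delay and
    failures-during-delay behaviors.
    """
    rng = _rng(cfg, _STREAM_BUTTONS)
    presses: list[ButtonEvent] = []
    last_press = -np.inf
    for ev in sorted(failures, key=lambda f: f.time):
        if ev.time < last_press + cfg.button_refractory:
            continue
        if rng.uniform() < cfg.button_miss_prob:
            continue
        if cfg.button_delay_sd > 0:
            a = (0.0 - cfg.button_delay_mean) / cfg.button_delay_sd
            delay = float(
                truncnorm.rvs(
                    a, np.inf, loc=cfg.button_delay_mean,
                    scale=cfg.button_delay_sd, random_state=rng,
                )
            )
        else:
            delay = max(cfg.button_delay_mean, 0.0)
        t_press = ev.time + delay
        presses.append(ButtonEvent(time=t_press))
        last_press = t_press
    return presses


def contrary_crossings(session: Session, threshold: float = 0.3, ramp_time: float = 0.3) -> list[tuple[float, int]]:
    """Scan a session for threshold crossings contrary to the scripted intent.

    Returns (time, 1-based channel) pairs.  A crossing is contrary when a
    channel rises above the threshold while the intent calls for rest, or
    when a flexion channel falls below it while the intent calls for grasp.
    Crossings within ``ramp_time`` of the intended grasp/release
    transitions are the intended actuation edges and are ignored.
    """
    x = session.prediction.values
    above = x > threshold
    changes = np.argwhere(above[:, 1:] != above[:, :-1])
    out: list[tuple[float, int]] = []
    for ch, i in changes:
        t = (i + 1) / session.sample_rate
        task = session.task_of(t)
        if task is None:
            continue
        if (
            abs(t - task.t_grasp) <= 2 * ramp_time
            or abs(t - task.t_release) <= 2 * ramp_time
        ):
            continue
        zone = zone_of_safe(t, task)
        grasp_intent = zone is Zone.GRASP and ch < 3
        rising = above[ch, i + 1]
        if (rising and not grasp_intent) or (not rising and grasp_intent):
            out.append((t, int(ch) + 1))
    return out


def zone_of_safe(t: float, task: TaskTimeline) -> Zone:
    from .session import zone_of

    return zone_of(min(max(t, task.t_start), task.t_end), task)
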