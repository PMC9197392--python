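"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its configuration and seed:
identical inputs give bit-identical outputs.  Spike trains are drawn from
a piecewise-constant-rate (inhomogeneous) Poisson process — a homogeneous
baseline plus a stimulus-locked rate increment inside a region-specific
latency window — which is exactly the statistical structure the evoked-
response quantification assumes.  Refractoriness is deliberately omitted,
so baseline interspike intervals are exponential (CV of the interspike
interval near 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults as d
from .gait import GaitMetrics
from .types import (
    FootprintSequence,
    SpikeTrain,
    StimProtocol,
    Trajectory,
    WaveformSet,
)


def _rng(seed):
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Stimulation protocols
# ---------------------------------------------------------------------------

def gen_protocol(kind: str, total_duration: float,
                 start: float = 0.0) -> StimProtocol:
    """Build a stimulation schedule.

    ``low_freq``: 100 ms pulses every 4 s (0.25 Hz) filling
    ``total_duration``.  ``theta_burst``: two 40 s trains of 20 ms pulses
    at 8.33 Hz (333 pulses per train) separated by a 2 min pause;
    ``total_duration`` must cover the full schedule.
    """
    if kind == "low_freq":
        if total_duration < d.LOW_FREQ_PULSE_S:
            raise ValueError("total_duration shorter than one pulse")
        n = int(np.floor((total_duration - d.LOW_FREQ_PULSE_S)
                         / d.LOW_FREQ_PERIOD_S)) + 1
        onsets = start + np.arange(n) * d.LOW_FREQ_PERIOD_S
        return StimProtocol(onsets, d.LOW_FREQ_PULSE_S, kind)
    if kind == "theta_burst":
        per_train = int(np.floor(d.THETA_TRAIN_S * d.THETA_RATE_HZ))  # 333
        span = ((d.THETA_N_TRAINS - 1) * (d.THETA_TRAIN_S + d.THETA_PAUSE_S)
                + (per_train - 1) / d.THETA_RATE_HZ + d.THETA_PULSE_S)
        if total_duration < span:
            raise ValueError(
                f"theta_burst schedule spans {span:.2f} s; "
                f"total_duration {total_duration} s is too short"
            )
        trains = [
            start + t * (d.THETA_TRAIN_S + d.THETA_PAUSE_S)
            + np.arange(per_train) / d.THETA_RATE_HZ
            for t in range(d.THETA_N_TRAINS)
        ]
        return StimProtocol(np.concatenate(trains), d.THETA_PULSE_S, kind)
    raise ValueError(f"unknown protocol kind {kind!r}")


# ---------------------------------------------------------------------------
# Evoked spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EphysSimConfig:
    """Parameters of the evoked-train simulator.

    Rates are per region; the three multipliers model genotype-dependent
    excitability, pharmacological state, and pre/post theta-burst gain.
    All values are simulation choices, not measured ones.
    """

    baseline_rate: dict = field(default_factory=lambda: dict(d.BASELINE_RATE_HZ))
    evoked_delta: dict = field(default_factory=lambda: dict(d.EVOKED_DELTA_HZ))
    response_latency: dict = field(
        default_factory=lambda: dict(d.RESPONSE_LATENCY_S))
    response_window: dict = field(
        default_factory=lambda: dict(d.RESPONSE_WINDOW_S))
    genotype_gain: float = 1.0
    state_rate_factor: float = 1.0
    plasticity_gain: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name, table in (("baseline_rate", self.baseline_rate),
                            ("evoked_delta", self.evoked_delta)):
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{name} must be non-negative")
        for m in (self.genotype_gain, self.state_rate_factor,
                  self.plasticity_gain):
            if m <= 0:
                raise ValueError("multipliers must be positive")
        for r, lat in self.response_latency.items():
            win = self.response_window[r]
            if not (0 <= lat and win > 0):
                raise ValueError("invalid latency/window for region " + r)


def gen_evoked_train(cfg: EphysSimConfig, protocol: StimProtocol,
                     region: str, duration: float, unit_id: str = "u0"):
    """Simulate one unit's spike train plus its ground-truth record.

    Baseline rate ``b = baseline_rate[region] * state_rate_factor``
    applies everywhere; inside ``[onset+latency, onset+latency+window)``
    the rate is ``b + evoked_delta[region] * genotype_gain *
    plasticity_gain``.  Returns ``(SpikeTrain, truth_dict)``.
    """
    if duration < protocol.onsets[-1] + protocol.pulse_duration:
        raise ValueError("duration does not cover the protocol")
    b = cfg.baseline_rate[region] * cfg.state_rate_factor
    delta = (cfg.evoked_delta[region] * cfg.genotype_gain
             * cfg.plasticity_gain)
    lat = cfg.response_latency[region]
    win = cfg.response_window[region]
    if lat + win > protocol.pulse_duration + 1e-12:
        # evoked window is allowed to extend past short pulses only if the
        # config says so explicitly; clamp to the pulse span considered
        win = max(protocol.pulse_duration - lat, 0.0)
    if b < 0 or b + delta < 0:
        raise ValueError("negative resulting rate")
    rng = _rng(cfg.seed)

    n_base = rng.poisson(b * duration)
    times = rng.uniform(0.0, duration, n_base)
    if win > 0 and delta != 0:
        starts = protocol.onsets + lat
        if delta > 0:
            extra_counts = rng.poisson(delta * win, protocol.n_pulses)
            extra = np.concatenate([
                s + rng.uniform(0.0, win, c)
                for s, c in zip(starts, extra_counts)
            ]) if extra_counts.sum() else np.empty(0)
            times = np.concatenate([times, extra])
        else:
            # thin baseline spikes inside the windows to reach rate b+delta
            idx = np.searchsorted(starts, times) - 1
            idx = np.clip(idx, 0, len(starts) - 1)
            inside = (times >= starts[idx]) & (times < starts[idx] + win)
            keep_p = (b + delta) / b if b > 0 else 0.0
            drop = inside & (rng.uniform(size=times.size) >= keep_p)
            times = times[~drop]
    times = np.unique(times)
    times = times[(times >= 0) & (times < duration)]
    train = SpikeTrain(unit_id, region, times, 0.0, duration)
    truth = {
        "unit_id": unit_id,
        "region": region,
        "true_baseline_rate": b,
        "true_evoked_delta": delta,
        "latency": lat,
        "window": win,
    }
    return train, truth


# ---------------------------------------------------------------------------
# Waveform mixtures
# ---------------------------------------------------------------------------

def _unit_templates(k: int, n_samples: int, separation: float) -> np.ndarray:
    """k distinct templates: a common biphasic shape plus orthonormal
    harmonic perturbations scaled by ``separation`` (pairwise template
    distance = separation * sqrt(2))."""
    t = np.arange(n_samples, dtype=float)
    base = (-5.0 * np.exp(-((t - n_samples * 0.3) / (n_samples * 0.06)) ** 2)
            + 2.5 * np.exp(-((t - n_samples * 0.5) / (n_samples * 0.1)) ** 2))
    harmonics = np.array([
        np.sin(np.pi * (i + 1) * (t + 0.5) / n_samples) for i in range(k)
    ])
    harmonics /= np.linalg.norm(harmonics, axis=1, keepdims=True)
    return base + separation * harmonics


def gen_waveform_set(k: int, n_per_unit: int, separation: float,
                     noise_sd: float, seed: int, n_samples: int = 32,
                     sample_rate: float = 25_000.0):
    """Simulate a multi-unit snippet mixture; returns (WaveformSet, labels)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if separation < 0 or noise_sd < 0:
        raise ValueError("separation and noise_sd must be non-negative")
    rng = _rng(seed)
    templates = _unit_templates(k, n_samples, separation)
    labels = np.repeat(np.arange(k), n_per_unit)
    rng.shuffle(labels)
    snippets = templates[labels]
    if noise_sd > 0:
        snippets = snippets + rng.normal(0.0, noise_sd, snippets.shape)
    times = np.arange(k * n_per_unit) * 2e-3
    return WaveformSet(snippets, sample_rate, times), labels


# ---------------------------------------------------------------------------
# Gait footprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitSimConfig:
    n_steps: int = 11          # prints emitted (rounded up to odd)
    step_length: float = 5.0   # cm of forward travel per print
    gait_width: float = 3.0    # cm between left and right print lines
    step_noise_sd: float = 0.0
    heading_drift_sd: float = 0.0  # degrees per step
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 4:
            raise ValueError("n_steps must be >= 4")
        if min(self.step_noise_sd, self.heading_drift_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.step_length <= 0 or self.gait_width < 0:
            raise ValueError("step_length > 0 and gait_width >= 0 required")


def gen_footprints(cfg: GaitSimConfig):
    """Simulate alternating L/R hind prints along a (possibly drifting)
    heading; returns ``(FootprintSequence, GaitMetrics)``.

    The print count is rounded up to an odd number so the first and last
    prints share a side; with zero noise the analysis metrics then equal
    the returned ground truth exactly.  The ground-truth record is the
    zero-noise closed form of the configured geometry.
    """
    n = cfg.n_steps + (cfg.n_steps % 2 == 0)
    rng = _rng(cfg.seed)
    drift = np.deg2rad(cfg.heading_drift_sd)
    heading = np.zeros(n)
    if drift > 0:
        heading[1:] = np.cumsum(rng.normal(0.0, drift, n - 1))
    mid = np.zeros((n, 2))
    for i in range(1, n):
        u = np.array([np.cos(heading[i]), np.sin(heading[i])])
        mid[i] = mid[i - 1] + cfg.step_length * u
    perp = np.column_stack([-np.sin(heading), np.cos(heading)])
    sides = np.where(np.arange(n) % 2 == 0, "L", "R")
    sign = np.where(sides == "L", 1.0, -1.0)
    pts = mid + (cfg.gait_width / 2.0) * sign[:, None] * perp
    if cfg.step_noise_sd > 0:
        pts = pts + rng.normal(0.0, cfg.step_noise_sd, pts.shape)
    fp = FootprintSequence(pts[:, 0], pts[:, 1], sides)
    truth = GaitMetrics(
        step_length=cfg.step_length,
        sigma=0.0,
        gait_width=cfg.gait_width,
        alternation_coefficient=0.0,
        linearity=0.0,
        stride_length=2.0 * cfg.step_length,
        hind_base_width=float(np.hypot(cfg.step_length, cfg.gait_width)),
    )
    return fp, truth


# ---------------------------------------------------------------------------
# Open-field trajectories and video
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySimConfig:
    duration: float = d.OPENFIELD_DURATION_S
    fps: float = 25.0
    #: piecewise-constant speed profile: ((start_s, cm_per_s), ...)
    speed_profile: tuple = ((0.0, 5.0),)
    wall_bias: float = 0.0
    arena_radius: float = d.ARENA_RADIUS_CM
    turn_sd: float = 0.3  # heading random-walk step (rad/frame)
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for _, v in self.speed_profile):
            raise ValueError("speeds must be non-negative")
        if not 0.0 <= self.wall_bias <= 1.0:
            raise ValueError("wall_bias must lie in [0, 1]")
        if self.duration <= 0 or self.fps <= 0 or self.arena_radius <= 0:
            raise ValueError("duration, fps and arena_radius must be positive")


def _speed_at(profile, t: np.ndarray) -> np.ndarray:
    starts = np.array([s for s, _ in profile])
    speeds = np.array([v for _, v in profile])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
    return speeds[idx]


def gen_trajectory(cfg: TrajectorySimConfig):
    """Simulate a centroid trajectory; returns ``(Trajectory, truth)``.

    A heading random walk with per-frame displacement exactly
    ``speed * dt``, reflected at the wall (0.95 R) and — when
    ``wall_bias > 0`` — at an inner boundary ``0.9 R * wall_bias``, so
    ``wall_bias = 1`` confines the path to the outer annulus.
    """
    rng = _rng(cfg.seed)
    dt = 1.0 / cfg.fps
    n = int(round(cfg.duration * cfg.fps)) + 1
    ts = np.arange(n) * dt
    v = _speed_at(cfg.speed_profile, ts[:-1])
    r_outer = 0.95 * cfg.arena_radius
    r_inner = 0.9 * cfg.arena_radius * cfg.wall_bias
    r0 = np.sqrt(rng.uniform(r_inner ** 2, r_outer ** 2))
    a0 = rng.uniform(0, 2 * np.pi)
    pos = np.zeros((n, 2))
    pos[0] = r0 * np.array([np.cos(a0), np.sin(a0)])
    heading = rng.uniform(0, 2 * np.pi)
    turns = rng.normal(0.0, cfg.turn_sd, n - 1)
    for i in range(n - 1):
        heading += turns[i]
        step = v[i] * dt
        for _ in range(3):  # reflect until inside the annulus
            u = np.array([np.cos(heading), np.sin(heading)])
            cand = pos[i] + step * u
            r = np.hypot(*cand)
            if r > r_outer or (r_inner > 0 and r < r_inner):
                rhat = pos[i] / max(np.hypot(*pos[i]), 1e-12)
                refl = u - 2 * (u @ rhat) * rhat
                heading = np.arctan2(refl[1], refl[0])
            else:
                break
        else:
            cand = pos[i]  # stuck in a corner case: stay put
        pos[i + 1] = cand
    traj = Trajectory(ts, pos, arena_center=(0.0, 0.0),
                      arena_radius=cfg.arena_radius)
    truth = {
        "total_distance": float(np.sum(v) * dt),
        "speeds": v,
        "median_speed": float(np.median(v)),
    }
    return traj, truth


def gen_video(traj: Trajectory, frame_size=(64, 64), blob_radius_px=6.0,
              noise_sd: float = 0.0, seed: int = 0, background: int = 220,
              blob_intensity: int = 30, cable: bool = False):
    """Render a trajectory as a dark disc on a light background.

    Frames are 8-bit grayscale; the disc is drawn with sub-pixel area
    coverage so its binary centroid matches the trajectory position.
    ``cable`` adds a thin dark distractor line from the top edge towards
    the blob (the headstage cable the tracking must reject).  Returns
    ``(list_of_frames, positions_px)`` where positions are (col, row).
    """
    rng = _rng(seed)
    h, w = frame_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    frames = []
    centers = []
    for x_cm, y_cm in traj.positions:
        col = cx + (x_cm - traj.arena_center[0]) * traj.px_per_cm
        row = cy + (y_cm - traj.arena_center[1]) * traj.px_per_cm
        dist = np.hypot(rows - row, cols - col)
        cov = np.clip(blob_radius_px + 0.5 - dist, 0.0, 1.0)
        img = background + (blob_intensity - background) * cov
        if cable:
            c = int(round(col))
            top = int(max(0, round(row - blob_radius_px - 3)))
            img[:top, min(max(c, 0), w - 1)] = 110.0
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
        centers.append((col, row))
    return frames, np.array(centers)
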