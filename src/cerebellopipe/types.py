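"""Shared domain types for the cerebello-thalamo-cortical analysis pipeline.

All times are seconds, all coordinates centimeters (arena frame, origin at
the arena center) unless a field name says otherwise.  Image-frame
quantities are pixels, row-major with origin top-left; conversion between
the two frames goes through a single ``px_per_cm`` scale factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Recorded structures: dentate nucleus (cerebellar output), ventrolateral
#: and centrolateral thalamus, primary motor cortex, dorsolateral striatum.
REGIONS = ("DN", "VAL", "CL", "M1", "DLS")
GENOTYPES = ("WT", "GNAL")
STATES = ("naive_saline", "oxo", "post_oxo_saline")
EPOCHS = ("pre_burst", "post_burst")
STIM_KINDS = ("low_freq", "theta_burst")
SIDES = ("L", "R")


class FormatError(ValueError):
    """A tabular input file does not match the expected schema."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's spike times on ``[t_start, t_end)`` with a region label."""

    unit_id: str
    region: str
    spike_times: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self):
        times = _as_float_array(self.spike_times, "spike_times")
        object.__setattr__(self, "spike_times", times)
        if self.region not in REGIONS:
            raise ValueError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )
        if not (np.isfinite(self.t_start) and np.isfinite(self.t_end)):
            raise ValueError("t_start/t_end must be finite")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < self.t_start or times[-1] >= self.t_end:
                raise ValueError(
                    "spike times must lie in [t_start, t_end)"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class StimProtocol:
    """Optogenetic pulse schedule: onset times, pulse width, protocol kind.

    ``low_freq`` is the probing protocol (100 ms pulses at 0.25 Hz);
    ``theta_burst`` is the plasticity-inducing protocol (20 ms pulses at
    8.33 Hz in two 40 s trains separated by a 2 min pause).
    """

    onsets: np.ndarray
    pulse_duration: float
    kind: str

    def __post_init__(self):
        onsets = _as_float_array(self.onsets, "onsets")
        object.__setattr__(self, "onsets", onsets)
        if self.kind not in STIM_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if not (np.isfinite(self.pulse_duration) and self.pulse_duration > 0):
            raise ValueError("pulse_duration must be positive")
        if onsets.size == 0:
            raise ValueError("protocol needs at least one pulse")
        gaps = np.diff(onsets)
        if np.any(gaps <= 0):
            raise ValueError("onsets must be strictly ascending")
        if np.any(gaps < self.pulse_duration):
            raise ValueError("pulses overlap: onset gap below pulse_duration")

    @property
    def n_pulses(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class RecordingSession:
    """A set of simultaneously recorded units plus the stimulation schedule."""

    session_id: str
    genotype: str
    state: str
    epoch: str
    trains: list
    protocol: StimProtocol

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.trains:
            t0 = self.trains[0].t_start
            t1 = self.trains[0].t_end
            for tr in self.trains:
                if tr.t_start != t0 or tr.t_end != t1:
                    raise ValueError("all trains must share [t_start, t_end)")
            on = self.protocol.onsets
            if on[0] < t0 or on[-1] >= t1:
                raise ValueError("protocol onsets fall outside the session")


@dataclass(frozen=True)
class WaveformSet:
    """Spike waveform snippets (n_spikes x n_samples, arbitrary voltage units)."""

    snippets: np.ndarray
    sample_rate: float
    spike_times: np.ndarray

    def __post_init__(self):
        snip = np.asarray(self.snippets, dtype=float)
        times = _as_float_array(self.spike_times, "spike_times")
        if snip.ndim != 2:
            raise ValueError("snippets must be 2-D (n_spikes x n_samples)")
        if snip.shape[0] != times.size:
            raise ValueError("n_spikes must equal len(spike_times)")
        if not np.all(np.isfinite(snip)):
            raise ValueError("snippets contain non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "snippets", snip)
        object.__setattr__(self, "spike_times", times)

    @property
    def n_spikes(self) -> int:
        return int(self.snippets.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.snippets.shape[1])


@dataclass(frozen=True)
class FootprintSequence:
    """Ordered hind-paw prints along an alley walk.

    ``x``/``y`` are print coordinates in cm; ``sides`` labels each print
    'L' or 'R'.  Travel direction is implicit in print order.  Sides need
    not strictly alternate (real animals double-step).
    """

    x: np.ndarray
    y: np.ndarray
    sides: np.ndarray

    def __post_init__(self):
        x = _as_float_array(self.x, "x")
        y = _as_float_array(self.y, "y")
        sides = np.asarray(self.sides)
        if not (x.size == y.size == sides.size):
            raise ValueError("x, y and sides must have equal length")
        if not np.all(np.isin(sides, SIDES)):
            raise ValueError("sides must be 'L' or 'R'")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "sides", sides.astype("U1"))

    @property
    def n_prints(self) -> int:
        return int(self.x.size)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class Trajectory:
    """Timestamped 2-D positions of the animal's centroid in the arena frame."""

    timestamps: np.ndarray
    positions: np.ndarray
    arena_center: tuple = (0.0, 0.0)
    arena_radius: float = 19.0  # 38 cm diameter arena
    px_per_cm: float = 1.0

    def __post_init__(self):
        ts = _as_float_array(self.timestamps, "timestamps")
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if pos.shape[0] != ts.size:
            raise ValueError("timestamps and positions must have equal length")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions contain non-finite values")
        if ts.size >= 2:
            dt = np.diff(ts)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must be uniformly spaced")
        if self.arena_radius <= 0 or self.px_per_cm <= 0:
            raise ValueError("arena_radius and px_per_cm must be positive")
        r = np.hypot(pos[:, 0] - self.arena_center[0],
                     pos[:, 1] - self.arena_center[1])
        if pos.shape[0] and r.max() > self.arena_radius * (1 + 1e-6):
            warnings.warn(
                "positions extend beyond the arena radius; check tracking",
                stacklevel=2,
            )
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "positions", pos)

    @property
    def fps(self) -> float:
        if self.timestamps.size < 2:
            raise ValueError("need >= 2 samples to define a frame rate")
        return 1.0 / float(self.timestamps[1] - self.timestamps[0])

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)

    def radii(self) -> np.ndarray:
        """Radial distance of every sample from the arena center (cm)."""
        return np.hypot(self.positions[:, 0] - self.arena_center[0],
                        self.positions[:, 1] - self.arena_center[1])


#: Length of one dystonia-scoring block (10 min).
SCORE_BLOCK_S = 600.0


@dataclass(frozen=True)
class BehaviorScoreSeries:
    """Ordinal dystonia scores (0-4) per 10-min block, one row per rater."""

    block_scores: np.ndarray  # shape (n_raters, n_blocks)
    rater_ids: tuple

    def __post_init__(self):
        scores = np.asarray(self.block_scores)
        if scores.ndim != 2:
            raise ValueError("block_scores must be 2-D (raters x blocks)")
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(scores == np.floor(scores)):
                raise ValueError("scores must be integers")
            scores = scores.astype(int)
        if scores.size and (scores.min() < 0 or scores.max() > 4):
            raise ValueError("scores must lie in {0,1,2,3,4}")
        if scores.shape[0] != len(self.rater_ids):
            raise ValueError("one row of scores per rater required")
        object.__setattr__(self, "block_scores", scores)
        object.__setattr__(self, "rater_ids", tuple(self.rater_ids))

    @property
    def n_blocks(self) -> int:
        return int(self.block_scores.shape[1])
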