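"""Evoked-response quantification around optogenetic stimulation onsets.

The core of the pipeline: peristimulus time histograms (10 ms bins over a
300 ms baseline and the stimulation span), the 4xSD responsiveness
criterion, the evoked rate change ("acceleration of discharge"), the
region-specific 10 ms afferent-volley rate, mean firing rate, interspike-
interval variability, the 6 Hz slow/fast-spiking classification, and the
early/late stimulation-half stability check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import defaults as d
from .types import SpikeTrain, StimProtocol


@dataclass(frozen=True)
class Psth:
    """Event-summed peristimulus histogram.

    ``bin_edges`` are relative to stimulation onset and span
    ``[-baseline, analysis_end)``; ``counts`` are integer totals over all
    events; rates are ``counts / (n_events * bin_width)`` in Hz.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_events: int
    bin_width: float
    n_baseline_bins: int

    @property
    def rates(self) -> np.ndarray:
        return self.counts / (self.n_events * self.bin_width)

    @property
    def baseline_rates(self) -> np.ndarray:
        return self.rates[: self.n_baseline_bins]

    @property
    def stim_rates(self) -> np.ndarray:
        return self.rates[self.n_baseline_bins:]


@dataclass(frozen=True)
class ResponseSummary:
    unit_id: str
    region: str
    responsive: bool
    delta_rate: float
    volley_rate_delta: float
    baseline_rate: float
    baseline_sd: float
    mean_rate: float
    cv_isi: float


@dataclass(frozen=True)
class UnitClass:
    label: str  # "slow_spiking" or "fast_spiking"
    mean_rate: float


def compute_psth(train: SpikeTrain, protocol: StimProtocol,
                 bin_width: float = d.BIN_WIDTH_S,
                 baseline: float = d.BASELINE_S,
                 analysis_end: float | None = None) -> Psth:
    """Event-summed PSTH with half-open bins ``[edge_i, edge_{i+1})``.

    ``analysis_end`` defaults to the pulse duration, so for the 100 ms
    probing protocol the histogram has 30 baseline and 10 stimulation
    bins.  Windows that are not integer multiples of the bin width are
    truncated with a warning.
    """
    if protocol.n_pulses < 1:
        raise ValueError("need at least one stimulation event")
    if analysis_end is None:
        analysis_end = protocol.pulse_duration
    n_base = int(np.floor(baseline / bin_width + 1e-9))
    n_stim = int(np.floor(analysis_end / bin_width + 1e-9))
    if abs(n_base * bin_width - baseline) > 1e-9 * max(1.0, baseline) or \
            abs(n_stim * bin_width - analysis_end) > 1e-9 * max(1.0, analysis_end):
        warnings.warn(
            "bin_width does not divide the analysis windows evenly; "
            "edges truncated",
            stacklevel=2,
        )
    if n_base < 1 or n_stim < 1:
        raise ValueError("windows shorter than one bin")
    edges = np.arange(-n_base, n_stim + 1) * bin_width
    counts = np.zeros(n_base + n_stim, dtype=int)
    spikes = train.spike_times
    for onset in protocol.onsets:
        lo = np.searchsorted(spikes, onset + edges[0], side="left")
        hi = np.searchsorted(spikes, onset + edges[-1], side="left")
        rel = spikes[lo:hi] - onset
        idx = np.searchsorted(edges, rel, side="right") - 1
        # spikes exactly on the left-most edge belong to bin 0; anything
        # outside [edges[0], edges[-1]) was already excluded above
        valid = (idx >= 0) & (idx < counts.size) & (rel >= edges[0]) \
            & (rel < edges[-1])
        np.add.at(counts, idx[valid], 1)
    return Psth(edges, counts, protocol.n_pulses, bin_width, n_base)


def evoked_delta_rate(psth: Psth) -> float:
    """Mean stimulation-window rate minus mean baseline rate (Hz)."""
    if psth.n_baseline_bins == 0 or psth.stim_rates.size == 0:
        raise ValueError("PSTH must have baseline and stimulation bins")
    return float(psth.stim_rates.mean() - psth.baseline_rates.mean())


def is_responsive(psth: Psth, k: float = d.RESPONSIVE_K) -> bool:
    """True when at least one stimulation bin rises more than ``k`` times
    the baseline-bin SD above the baseline mean.

    With a degenerate zero SD the criterion falls back to any
    stimulation bin exceeding the baseline mean.
    """
    base = psth.baseline_rates
    if base.size < 2:
        raise ValueError("need >= 2 baseline bins")
    mu = base.mean()
    sd = base.std(ddof=1)
    excess = psth.stim_rates - mu
    if sd == 0:
        return bool(np.any(excess > 0))
    return bool(np.max(excess) > k * sd)


def volley_delta_rate(train: SpikeTrain, protocol: StimProtocol,
                      region: str, baseline: float = d.BASELINE_S,
                      windows: dict | None = None) -> float:
    """Rate in the region's direct-response window minus baseline rate.

    Windows (relative to light onset): 0-10 ms in the DN, 4-14 ms in the
    thalamus, 7-17 ms in the cortex (and, by default, the striatum).
    """
    windows = d.VOLLEY_WINDOWS_S if windows is None else windows
    if region not in windows:
        raise ValueError(f"no volley window defined for region {region!r}")
    w0, w1 = windows[region]
    spikes = train.spike_times
    n_win = 0
    n_base = 0
    for onset in protocol.onsets:
        n_win += (np.searchsorted(spikes, onset + w1, side="left")
                  - np.searchsorted(spikes, onset + w0, side="left"))
        n_base += (np.searchsorted(spikes, onset, side="left")
                   - np.searchsorted(spikes, onset - baseline, side="left"))
    n_events = protocol.n_pulses
    rate_win = n_win / (n_events * (w1 - w0))
    rate_base = n_base / (n_events * baseline)
    return float(rate_win - rate_base)


def mean_firing_rate(train: SpikeTrain) -> float:
    """Spike count over the recording duration (Hz)."""
    return train.n_spikes / train.duration


def cv_isi(train: SpikeTrain) -> float:
    """Coefficient of variation of the interspike intervals.

    0 for perfectly regular firing, near 1 for Poisson firing.  NaN when
    fewer than three spikes (fewer than two intervals) are available.
    """
    if train.n_spikes < 3:
        return float("nan")
    isis = np.diff(train.spike_times)
    return float(np.std(isis, ddof=1) / np.mean(isis))


def classify_unit(mean_rate: float,
                  threshold: float = d.FAST_SPIKING_THRESHOLD_HZ) -> UnitClass:
    """Slow/fast-spiking split of striatal units at 6 Hz (ties are fast)."""
    label = "fast_spiking" if mean_rate >= threshold else "slow_spiking"
    return UnitClass(label, float(mean_rate))


def early_late_responses(train: SpikeTrain, protocol: StimProtocol,
                         **psth_kwargs) -> tuple[float, float]:
    """Evoked rate change over the first ceil(n/2) events vs the rest.

    A stability check: a stationary response gives matching halves.
    """
    n = protocol.n_pulses
    if n < 2:
        raise ValueError("need >= 2 events to split early/late")
    half = int(np.ceil(n / 2))
    early = StimProtocol(protocol.onsets[:half], protocol.pulse_duration,
                         protocol.kind)
    late = StimProtocol(protocol.onsets[half:], protocol.pulse_duration,
                        protocol.kind)
    return (evoked_delta_rate(compute_psth(train, early, **psth_kwargs)),
            evoked_delta_rate(compute_psth(train, late, **psth_kwargs)))


def summarize_response(train: SpikeTrain, protocol: StimProtocol,
                       region: str | None = None,
                       k: float = d.RESPONSIVE_K,
                       **psth_kwargs) -> ResponseSummary:
    """Full per-unit response summary used by the analyze stage."""
    region = train.region if region is None else region
    psth = compute_psth(train, protocol, **psth_kwargs)
    base = psth.baseline_rates
    return ResponseSummary(
        unit_id=train.unit_id,
        region=region,
        responsive=is_responsive(psth, k=k),
        delta_rate=evoked_delta_rate(psth),
        volley_rate_delta=volley_delta_rate(train, protocol, region),
        baseline_rate=float(base.mean()),
        baseline_sd=float(base.std(ddof=1)),
        mean_rate=mean_firing_rate(train),
        cv_isi=cv_isi(train),
    )
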