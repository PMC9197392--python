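"""Footprint gait metrics.

The five classical footprint parameters plus stride length and hind-base
width, computed from ordered, side-labeled hind-paw print coordinates:

step length
    net displacement from first to last print divided by the number of
    steps (prints minus one).
sigma
    standard deviation of the pooled consecutive right-right and
    left-left step distances (population SD by default).
gait width
    mean perpendicular distance of each print to the line connecting its
    opposite-side preceding and succeeding prints.
alternation coefficient
    mean of |0.5 - d(R,L)/d(R,R)| over left prints bracketed by
    consecutive right prints, distances measured along the travel axis.
linearity
    for right prints, the angle of each subsequent print relative to a
    line perpendicular to the travel direction through the first right
    print; the mean absolute change of that angle between consecutive
    right steps, in degrees.

The travel direction is estimated as the principal axis of all prints,
oriented along the first-to-last displacement; every metric is therefore
invariant under rigid rotation and translation of the print set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import FootprintSequence


@dataclass(frozen=True)
class GaitMetrics:
    step_length: float
    sigma: float
    gait_width: float
    alternation_coefficient: float
    linearity: float
    stride_length: float
    hind_base_width: float


def travel_axis(fp: FootprintSequence) -> np.ndarray:
    """Unit vector of the travel direction (principal axis of all prints,
    oriented by the net first-to-last displacement)."""
    pts = fp.points
    if fp.n_prints < 2:
        raise ValueError("need >= 2 prints to define a travel direction")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    u = vecs[:, -1]  # eigenvector of the largest eigenvalue
    net = pts[-1] - pts[0]
    if net @ u < 0:
        u = -u
    return u


def step_length(fp: FootprintSequence) -> float:
    """Net displacement first-to-last print over the number of steps."""
    if fp.n_prints < 2:
        raise ValueError("need >= 2 prints")
    net = fp.points[-1] - fp.points[0]
    return float(np.hypot(*net) / (fp.n_prints - 1))


def _same_side_distances(fp: FootprintSequence) -> np.ndarray:
    """Euclidean distances between consecutive same-side prints,
    concatenated over both sides in temporal order (R-R first)."""
    out = []
    for side in ("R", "L"):
        pts = fp.points[fp.sides == side]
        if len(pts) >= 2:
            out.append(np.hypot(*(np.diff(pts, axis=0).T)))
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def sigma(fp: FootprintSequence, ddof: int = 0) -> float:
    """SD of pooled consecutive same-side step distances.

    Population SD (``ddof=0``) by default; pass ``ddof=1`` for the
    sample convention.
    """
    dists = _same_side_distances(fp)
    if dists.size < 2:
        raise ValueError("need >= 2 same-side step intervals")
    return float(np.std(dists, ddof=ddof))


def gait_width(fp: FootprintSequence) -> float:
    """Mean perpendicular distance of each print to the line through its
    opposite-side preceding and succeeding prints."""
    sides = fp.sides
    pts = fp.points
    dists = []
    for i in range(fp.n_prints):
        opp = np.flatnonzero(sides != sides[i])
        before = opp[opp < i]
        after = opp[opp > i]
        if before.size == 0 or after.size == 0:
            continue
        a = pts[before[-1]]
        b = pts[after[0]]
        ab = b - a
        norm = np.hypot(*ab)
        if norm == 0:
            dists.append(float(np.hypot(*(pts[i] - a))))
        else:
            cross = ab[0] * (pts[i][1] - a[1]) - ab[1] * (pts[i][0] - a[0])
            dists.append(abs(cross) / norm)
    if not dists:
        raise ValueError("no print has opposite-side neighbors on both sides")
    return float(np.mean(dists))


def alternation_coefficient(fp: FootprintSequence) -> float:
    """Mean |0.5 - d(R,L)/d(R,R)| over left prints bracketed by
    consecutive right prints; distances are projections onto the travel
    axis so a left print midway between its flanking rights scores 0."""
    u = travel_axis(fp)
    sides = fp.sides
    pts = fp.points
    ratios = []
    right_idx = np.flatnonzero(sides == "R")
    for j0, j1 in zip(right_idx[:-1], right_idx[1:]):
        lefts = [i for i in range(j0 + 1, j1) if sides[i] == "L"]
        for i in lefts:
            d_rr = (pts[j1] - pts[j0]) @ u
            if d_rr == 0:
                continue
            d_rl = (pts[i] - pts[j0]) @ u
            ratios.append(abs(0.5 - d_rl / d_rr))
    if not ratios:
        raise ValueError("no left-right pair bracketed by an R-R interval")
    return float(np.mean(ratios))


def linearity(fp: FootprintSequence) -> float:
    """Mean absolute change in angle between consecutive right-right steps.

    Angles are measured between the line perpendicular to the travel
    direction through the first right print and each subsequent right
    print; a straight walk scores 0 degrees.
    """
    u = travel_axis(fp)
    v = np.array([-u[1], u[0]])
    pts = fp.points[fp.sides == "R"]
    if len(pts) < 3:
        raise ValueError("need >= 3 right prints")
    rel = pts[1:] - pts[0]
    angles = np.degrees(np.arctan2(rel @ u, rel @ v))
    return float(np.mean(np.abs(np.diff(angles))))


def stride_and_base(fp: FootprintSequence) -> tuple[float, float]:
    """(stride length, hind-base width).

    Stride = mean consecutive same-side distance; hind base = mean
    Euclidean distance between temporally adjacent opposite-side prints.
    """
    strides = _same_side_distances(fp)
    if strides.size == 0:
        raise ValueError("need >= 2 prints on at least one side")
    adj = np.flatnonzero(fp.sides[:-1] != fp.sides[1:])
    if adj.size == 0:
        raise ValueError("no adjacent opposite-side print pairs")
    diffs = fp.points[adj + 1] - fp.points[adj]
    base = float(np.mean(np.hypot(diffs[:, 0], diffs[:, 1])))
    return float(np.mean(strides)), base


def compute_gait_metrics(fp: FootprintSequence, ddof: int = 0) -> GaitMetrics:
    """All seven metrics for one trial."""
    if fp.n_prints < 3:
        raise ValueError("need >= 3 prints for gait metrics")
    stride, base = stride_and_base(fp)
    return GaitMetrics(
        step_length=step_length(fp),
        sigma=sigma(fp, ddof=ddof),
        gait_width=gait_width(fp),
        alternation_coefficient=alternation_coefficient(fp),
        linearity=linearity(fp),
        stride_length=stride,
        hind_base_width=base,
    )


def average_trials(metrics: list[GaitMetrics]) -> GaitMetrics:
    """Per-animal average across trials (three or more recommended)."""
    if not metrics:
        raise ValueError("no trials to average")
    fields = GaitMetrics.__dataclass_fields__
    return GaitMetrics(**{
        f: float(np.mean([getattr(m, f) for m in metrics])) for f in fields
    })
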