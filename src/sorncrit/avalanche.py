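"""Neuronal avalanches from a thresholded population-activity trace.

The SORN has no separation of time scales (activity rarely dies out,
there is no pause between events), so avalanches are defined against a
constant background threshold ``theta`` rather than by silent bins: an
avalanche starts when a(t) crosses above theta; its duration T is the
number of *subsequent* steps the activity remains above threshold, so
the whole excursion spans T + 1 steps, and its size
S = sum_{t0..t0+T} (a(t) - theta) is the exceedance summed over the
excursion.  A single-step excursion has T = 0 and S >= 1.

Conventions:

* thresholds are rounded half-up to an integer (a(t) is integer);
* equality is not exceedance (a(t) = theta does not extend a run;
  "silent" background means a(t) - theta <= 0);
* excursions in progress at the first or last step of the trace are
  censored (their T and S would be undefined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Avalanche",
    "AvalancheSet",
    "half_mean_threshold",
    "percentile_threshold",
    "detect_avalanches",
    "alternative_size",
    "alternative_sizes",
]


def _round_half_up(value: float) -> int:
    """Deterministic rounding: 2.5 -> 3 (no banker's rounding)."""
    return int(np.floor(value + 0.5))


@dataclass(frozen=True)
class Avalanche:
    """One avalanche: start step, duration, summed exceedance.

    ``duration`` counts the steps after onset during which activity
    stays above threshold; the excursion spans ``duration + 1`` steps,
    so the integer exceedance satisfies ``size >= duration + 1``.
    """

    t0: int
    duration: int
    size: int

    def __post_init__(self) -> None:
        if self.duration < 0 or self.size < self.duration + 1 or self.t0 < 0:
            raise ValueError(
                f"inconsistent avalanche (t0={self.t0}, T={self.duration}, "
                f"S={self.size}): need T >= 0, S >= T + 1, t0 >= 0"
            )


@dataclass
class AvalancheSet:
    """Avalanches of one trace, stored columnar for fast fitting.

    ``t0``, ``durations`` and ``sizes`` are aligned integer arrays,
    sorted by start step; avalanches never overlap.
    """

    t0: np.ndarray
    durations: np.ndarray
    sizes: np.ndarray
    theta: int
    trace_length: int
    alt_sizes: np.ndarray | None = field(default=None)

    def __len__(self) -> int:
        return len(self.t0)

    def __getitem__(self, i: int) -> Avalanche:
        return Avalanche(int(self.t0[i]), int(self.durations[i]), int(self.sizes[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @classmethod
    def concatenate(cls, sets: "list[AvalancheSet]") -> "AvalancheSet":
        """Pool avalanches from independent runs (t0 left run-local)."""
        if not sets:
            raise ValueError("nothing to concatenate")
        thetas = {s.theta for s in sets}
        if len(thetas) > 1:
            raise ValueError(f"mixed thresholds {sorted(thetas)} cannot be pooled")
        alt = None
        if all(s.alt_sizes is not None for s in sets):
            alt = np.concatenate([s.alt_sizes for s in sets])
        return cls(
            t0=np.concatenate([s.t0 for s in sets]),
            durations=np.concatenate([s.durations for s in sets]),
            sizes=np.concatenate([s.sizes for s in sets]),
            theta=sets[0].theta,
            trace_length=sum(s.trace_length for s in sets),
            alt_sizes=alt,
        )


def half_mean_threshold(activity: np.ndarray) -> int:
    """theta = round(mean activity / 2), rounded half-up.

    With the network at its target rate mu_ip the mean activity is
    mu_ip * N_E, so the default network (N_E=200) yields theta = 10.
    """
    activity = np.asarray(activity)
    if activity.size == 0:
        raise ValueError("empty activity trace")
    return _round_half_up(float(activity.mean()) / 2.0)


def percentile_threshold(activity: np.ndarray, pct: float) -> int:
    """theta at the pct-th percentile of the activity distribution."""
    if not 0.0 < pct < 100.0:
        raise ValueError("pct must lie strictly between 0 and 100")
    activity = np.asarray(activity)
    if activity.size == 0:
        raise ValueError("empty activity trace")
    return _round_half_up(float(np.percentile(activity, pct)))


def detect_avalanches(activity: np.ndarray, theta: int) -> AvalancheSet:
    """Extract all complete avalanches of a trace at threshold theta.

    Maximal runs with a(t) > theta become avalanches: the duration T is
    the number of steps the activity *remains* above threshold after
    the crossing step (run length minus one), and
    S = sum(a(t) - theta) over the whole run.  Runs touching either end
    of the trace are censored.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    a = np.asarray(activity, dtype=np.int64)
    above = a > theta
    edges = np.diff(np.concatenate(([False], above, [False])).astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)          # exclusive
    keep = (starts > 0) & (ends < a.size)       # censor boundary runs
    starts, ends = starts[keep], ends[keep]
    csum = np.concatenate(([0], np.cumsum(a - theta)))
    return AvalancheSet(
        t0=starts,
        durations=ends - starts - 1,
        sizes=csum[ends] - csum[starts],
        theta=int(theta),
        trace_length=a.size,
    )


def alternative_size(activity: np.ndarray, avalanche: Avalanche) -> int:
    """Size without threshold subtraction: S' = sum a(t) over the excursion."""
    a = np.asarray(activity, dtype=np.int64)
    lo, hi = avalanche.t0, avalanche.t0 + avalanche.duration + 1
    if lo < 0 or hi > a.size:
        raise ValueError("avalanche exceeds trace bounds")
    return int(a[lo:hi].sum())


def alternative_sizes(activity: np.ndarray, avset: AvalancheSet) -> np.ndarray:
    """Vectorized S' for every avalanche of a set; also cached on the set."""
    a = np.asarray(activity, dtype=np.int64)
    if a.size != avset.trace_length:
        raise ValueError("trace length does not match the avalanche set")
    csum = np.concatenate(([0], np.cumsum(a)))
    out = csum[avset.t0 + avset.durations + 1] - csum[avset.t0]
    avset.alt_sizes = out
    return out
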