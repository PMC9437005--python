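"""Telegraph statistics of center-of-mass traces along the pore axis.

A diffusing protein's z(t) trace shows long dwells on one side of the pore
punctuated by rapid translocations.  Two event definitions are extracted
against the pore-volume boundaries at z = ±boundary (default ±200 Å):

* **first passage** — from the moment the protein first enters the pore
  volume (crossing one boundary inward, after the last completed passage)
  to the moment it exits on the *opposite* side.  Includes any meandering
  back out of the entrance side in between.
* **crossing** — from the exit on one side back to the last prior moment
  the trace crossed the boundary on the *other* side.  Excludes the
  entrance-side meandering, so every crossing is contained in exactly one
  first-passage event and is never longer.

Boundary-crossing instants are located by linear interpolation between
samples, so durations are exact for piecewise-linear traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraceSeries",
    "PassageEvent",
    "detect_first_passages",
    "detect_crossings",
    "crossing_time_histogram",
]


@dataclass
class TraceSeries:
    """Uniformly sampled 1D center-of-mass trace."""

    t: np.ndarray  # us, strictly increasing
    z: np.ndarray  # A
    probe_id: str = ""
    confinement_radius: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.z = np.asarray(self.z, float)
        if self.t.shape != self.z.shape:
            raise ValueError("t and z must have the same shape")
        if len(self.t) < 2 or not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing with >= 2 samples")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite samples")


@dataclass
class PassageEvent:
    kind: str          # "first_passage" | "crossing"
    t_enter: float     # us
    t_exit: float      # us
    direction: int     # +1: entered from below, exited above; -1 converse
    duration: float    # us

    def __post_init__(self):
        if self.t_exit <= self.t_enter:
            raise ValueError("t_exit must exceed t_enter")


def _boundary_crossings(t, z, level):
    """Interpolated times and directions (+1 upward) of crossings of z = level."""
    s = z - level
    out = []
    for i in range(len(t) - 1):
        a, b = s[i], s[i + 1]
        if (a < 0 <= b) or (a <= 0 < b):
            tc = t[i] + (0.0 - a) / (b - a) * (t[i + 1] - t[i]) if b != a else t[i]
            out.append((tc, +1))
        elif (a > 0 >= b) or (a >= 0 > b):
            tc = t[i] + (0.0 - a) / (b - a) * (t[i + 1] - t[i]) if b != a else t[i]
            out.append((tc, -1))
    # a sample sitting exactly on the boundary yields the same crossing twice
    dedup = []
    for ev in out:
        if not dedup or ev != dedup[-1]:
            dedup.append(ev)
    return dedup


def _all_crossings(trace: TraceSeries, boundary: float):
    """Merged crossing list: (time, which boundary (+1 top / -1 bottom),
    direction of motion (+1 upward))."""
    ev = [(tc, +1, d) for tc, d in _boundary_crossings(trace.t, trace.z, boundary)]
    ev += [(tc, -1, d) for tc, d in _boundary_crossings(trace.t, trace.z, -boundary)]
    ev.sort()
    return ev


def detect_first_passages(trace: TraceSeries, boundary: float = 200.0):
    """First-passage events and their mean (MFPT) ± standard error.

    Returns ``(events, mfpt, sem)``; with no completed passage the list is
    empty and mfpt/sem are ``nan``.
    """
    crossings = _all_crossings(trace, boundary)
    z0 = trace.z[0]
    if z0 >= boundary:
        side = +1
    elif z0 <= -boundary:
        side = -1
    else:
        side = 0  # starts inside: wait until it reaches a compartment
    pending = None  # (entry_side, t_first_entry)
    events = []
    for tc, which, direction in crossings:
        inward = (which == +1 and direction == -1) or (which == -1 and direction == +1)
        if inward:
            if side == which and pending is None:
                pending = (which, tc)
            elif side == 0 and pending is None:
                # trace began inside; first inward crossing after it left
                pending = (which, tc)
        else:  # outward crossing of boundary `which`
            if pending is not None and pending[0] == -which:
                t0 = pending[1]
                events.append(PassageEvent(
                    kind="first_passage", t_enter=t0, t_exit=tc,
                    direction=+1 if which == +1 else -1, duration=tc - t0,
                ))
                pending = None
            side = which
    if events:
        durs = np.array([e.duration for e in events])
        mfpt = float(durs.mean())
        sem = float(durs.std(ddof=1) / np.sqrt(len(durs))) if len(durs) > 1 else 0.0
    else:
        mfpt = sem = float("nan")
    return events, mfpt, sem


def detect_crossings(trace: TraceSeries, boundary: float = 200.0):
    """Crossing events (exit minus last prior opposite-boundary crossing).

    Returns ``(events, mean, sem)``.  Each crossing corresponds to one
    completed first passage; its duration is never longer.
    """
    fp_events, _, _ = detect_first_passages(trace, boundary)
    crossings = _all_crossings(trace, boundary)
    events = []
    for fp in fp_events:
        entry_boundary = -fp.direction  # entered through the opposite boundary
        prior = [tc for tc, which, _ in crossings
                 if which == entry_boundary and fp.t_enter <= tc < fp.t_exit]
        t_start = max(prior) if prior else fp.t_enter
        events.append(PassageEvent(
            kind="crossing", t_enter=t_start, t_exit=fp.t_exit,
            direction=fp.direction, duration=fp.t_exit - t_start,
        ))
    if events:
        durs = np.array([e.duration for e in events])
        mean = float(durs.mean())
        sem = float(durs.std(ddof=1) / np.sqrt(len(durs))) if len(durs) > 1 else 0.0
    else:
        mean = sem = float("nan")
    return events, mean, sem


def crossing_time_histogram(durations, n_bins: int = 15, t_range=(0.0, 30.0)):
    """Normalized crossing-time histogram (evenly spaced bins, density=True).

    Returns (bin_centers, density)."""
    counts, edges = np.histogram(np.asarray(durations, float), bins=n_bins,
                                 range=t_range, density=True)
    return 0.5 * (edges[:-1] + edges[1:]), counts
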