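"""Per-assay behavioral statistics from worm event logs.

A lawn-avoidance assay is reduced to an ordered event log per worm.  Each
worm is a three-state machine:

    on_lawn --exit--> off_lawn --contact--> at_edge --entry--> on_lawn

``exit`` is the worm completely leaving contact with the bacterial lawn,
``contact`` its first subsequent touch of the lawn edge, and ``entry`` full
re-entry onto the lawn.  The delay between contact and entry is the latency
to re-entry; stalled worms can hold the at_edge state for tens of minutes
after pathogen exposure.

All internal times are seconds; hours/minutes appear only at the interface
(grid steps in minutes, windows and curves in hours), matching how the
assays are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EVENT_KINDS = ("exit", "contact", "entry")
CONDITIONS = ("plusATR", "minusATR", "naive", "exposed")

# state -> (legal next event, state after it)
_TRANSITIONS = {
    "on_lawn": ("exit", "off_lawn"),
    "off_lawn": ("contact", "at_edge"),
    "at_edge": ("entry", "on_lawn"),
}


@dataclass(frozen=True)
class WormEventLog:
    """Ordered contact/entry/exit events for one worm over one assay."""

    worm_id: str
    line_id: str
    condition: str
    events: tuple  # of (time_s, kind)
    duration_s: float
    initial_state: str = "on_lawn"

    def __post_init__(self):
        object.__setattr__(
            self, "events", tuple((float(t), str(k)) for t, k in self.events)
        )
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.initial_state not in ("on_lawn", "off_lawn"):
            raise ValueError(f"unknown initial state {self.initial_state!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        state = self.initial_state
        prev_t = -np.inf
        for t, kind in self.events:
            if kind not in EVENT_KINDS:
                raise ValueError(f"worm {self.worm_id}: unknown event kind {kind!r}")
            if not t > prev_t:
                raise ValueError(
                    f"worm {self.worm_id}: event times not strictly increasing at t={t}"
                )
            if t > self.duration_s:
                raise ValueError(
                    f"worm {self.worm_id}: event at t={t} beyond assay end"
                )
            expected, nxt = _TRANSITIONS[state]
            if kind != expected:
                raise ValueError(
                    f"worm {self.worm_id}: illegal event {kind!r} at t={t} "
                    f"(state {state}, expected {expected!r})"
                )
            state, prev_t = nxt, t

    def state_at(self, time_s: float) -> str:
        """State of the worm just after all events with time <= time_s."""
        state = self.initial_state
        for t, _kind in self.events:
            if t > time_s:
                break
            state = _TRANSITIONS[state][1]
        return state

    def event_times(self, kind: str) -> np.ndarray:
        return np.array([t for t, k in self.events if k == kind], dtype=float)


@dataclass(frozen=True)
class OccupancyCurve:
    """Fraction of worms on the lawn on a regular time grid (hours)."""

    times: np.ndarray  # hours, strictly increasing
    fraction_on: np.ndarray  # in [0, 1]
    n_worms: int

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        frac = np.asarray(self.fraction_on, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fraction_on", frac)
        if times.shape != frac.shape or times.ndim != 1:
            raise ValueError("times and fraction_on must be matching 1-D arrays")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("occupancy grid must be strictly increasing")
        if np.any(frac < 0) or np.any(frac > 1):
            raise ValueError("occupancy fractions must lie in [0, 1]")


@dataclass(frozen=True)
class RateEstimate:
    """Event rate in events per worm per hour over a scoring window."""

    value: float
    window: tuple  # (start_h, end_h)
    n_events: int
    n_worms: int
    sem: float

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("rate must be non-negative")


@dataclass(frozen=True)
class LatencySummary:
    """Latency-to-re-entry sample with explicit right-censoring.

    ``latencies_min`` holds one completed contact->entry delay per record
    (per event, or per worm mean, depending on ``aggregate``).  Contacts
    with no entry before assay end are counted in ``n_censored`` and are
    excluded from the mean, mirroring scoring that aggregates only worms
    that exited and re-entered within the recorded window.
    """

    latencies_min: np.ndarray
    n_censored: int
    aggregate: str
    mean_min: float = field(init=False)
    sem_min: float = field(init=False)

    def __post_init__(self):
        lat = np.asarray(self.latencies_min, dtype=float)
        object.__setattr__(self, "latencies_min", lat)
        mean = float(np.mean(lat)) if lat.size else float("nan")
        sem = float(np.std(lat, ddof=1) / np.sqrt(lat.size)) if lat.size > 1 else float("nan")
        object.__setattr__(self, "mean_min", mean)
        object.__setattr__(self, "sem_min", sem)

    @property
    def n(self) -> int:
        return int(self.latencies_min.size)


def _check_logs(logs) -> list:
    logs = list(logs)
    if not logs:
        raise ValueError("empty set of event logs")
    durations = {log.duration_s for log in logs}
    if len(durations) > 1:
        raise ValueError(f"logs have inconsistent durations: {sorted(durations)}")
    return logs


def compute_occupancy(logs, grid_step_min: float = 3.0,
                      edge_counts_as_on: bool = False) -> OccupancyCurve:
    """Fraction of worms on-lawn at each point of a regular grid.

    The default 3-minute grid matches full-assay imaging at one frame per
    three minutes.  A worm stalled at the lawn edge (between contact and
    entry) counts as off-lawn unless ``edge_counts_as_on`` is set.
    """
    logs = _check_logs(logs)
    if grid_step_min <= 0:
        raise ValueError("grid_step_min must be positive")
    duration_s = logs[0].duration_s
    step_s = grid_step_min * 60.0
    grid_s = np.arange(0.0, duration_s + 0.5 * step_s, step_s)
    grid_s[-1] = min(grid_s[-1], duration_s)
    on_states = {"on_lawn"} | ({"at_edge"} if edge_counts_as_on else set())

    counts = np.zeros(len(grid_s))
    for log in logs:
        # walk events once per worm instead of calling state_at per grid point
        state = log.initial_state
        ev = iter(log.events)
        nxt = next(ev, None)
        for gi, t in enumerate(grid_s):
            while nxt is not None and nxt[0] <= t:
                state = _TRANSITIONS[state][1]
                nxt = next(ev, None)
            if state in on_states:
                counts[gi] += 1
    return OccupancyCurve(
        times=grid_s / 3600.0, fraction_on=counts / len(logs), n_worms=len(logs)
    )


def event_rate_constant(logs, kind: str, window: tuple,
                        bin_min: float = 1.0) -> RateEstimate:
    """Rate constant (events per worm per hour) over a scoring window.

    Events are scored in ``bin_min``-minute intervals with at most one
    event per worm per interval, mirroring movie scoring at 1-minute
    resolution.  The rate divides the deduplicated count by
    (number of worms) x (window length in hours); all assayed worms enter
    the denominator regardless of their current state.
    """
    logs = _check_logs(logs)
    if kind not in ("exit", "entry"):
        raise ValueError(f"kind must be 'exit' or 'entry', got {kind!r}")
    start_h, end_h = window
    duration_h = logs[0].duration_s / 3600.0
    if not (0 <= start_h < end_h <= duration_h + 1e-9):
        raise ValueError(f"window {window} outside assay duration {duration_h} h")
    bin_s = bin_min * 60.0

    per_worm = np.zeros(len(logs))
    for wi, log in enumerate(logs):
        times = log.event_times(kind)
        times = times[(times >= start_h * 3600.0) & (times < end_h * 3600.0)]
        per_worm[wi] = len(np.unique(np.floor(times / bin_s).astype(np.int64)))
    hours = end_h - start_h
    rates = per_worm / hours
    value = float(rates.mean())
    sem = float(rates.std(ddof=1) / np.sqrt(len(logs))) if len(logs) > 1 else float("nan")
    return RateEstimate(value=value, window=(start_h, end_h),
                        n_events=int(per_worm.sum()), n_worms=len(logs), sem=sem)


def latency_to_reentry(logs, aggregate: str = "per_event",
                       window: tuple | None = None) -> LatencySummary:
    """Latency between first lawn contact and full re-entry, in minutes.

    Parameters
    ----------
    aggregate : {'per_event', 'per_worm_mean'}
        'per_event' pools every completed contact->entry pair; with
        'per_worm_mean' each worm contributes the mean of its own
        completed latencies.
    window : (start_h, end_h), optional
        Restrict to contacts occurring in this exposure-time window.
    """
    logs = _check_logs(logs)
    if aggregate not in ("per_event", "per_worm_mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    per_worm: list[np.ndarray] = []
    n_censored = 0
    for log in logs:
        contact_t = None
        completed = []
        for t, k in log.events:
            if k == "contact":
                contact_t = t
            elif k == "entry" and contact_t is not None:
                if window is None or (window[0] * 3600.0 <= contact_t < window[1] * 3600.0):
                    completed.append((t - contact_t) / 60.0)
                contact_t = None
        if contact_t is not None:  # contact with no entry before assay end
            if window is None or (window[0] * 3600.0 <= contact_t < window[1] * 3600.0):
                n_censored += 1
        if completed:
            per_worm.append(np.asarray(completed))

    if aggregate == "per_event":
        sample = np.concatenate(per_worm) if per_worm else np.array([])
    else:
        sample = np.array([w.mean() for w in per_worm])
    return LatencySummary(latencies_min=sample, n_censored=n_censored,
                          aggregate=aggregate)


def time_to_half_occupancy(curve: OccupancyCurve) -> float | None:
    """First time (hours) the occupancy curve falls to 0.5.

    Linearly interpolates between grid points; returns ``None`` (censored)
    if the curve never reaches 0.5.  The curve must start above 0.5.
    """
    frac = curve.fraction_on
    if frac[0] <= 0.5:
        raise ValueError("occupancy curve must start above 0.5")
    below = np.nonzero(frac <= 0.5)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    t0, t1 = curve.times[i - 1], curve.times[i]
    f0, f1 = frac[i - 1], frac[i]
    if f1 == f0:
        return float(t1)
    return float(t0 + (f0 - 0.5) * (t1 - t0) / (f0 - f1))
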