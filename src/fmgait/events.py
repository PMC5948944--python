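"""Supervisory correction of predicted gait-phase transitions.

Sample-wise classification yields a label stream whose raw transitions may
skip phases or jump backwards.  A small state machine repairs these so
that the output strictly follows the gait cycle 1→2→3→4→1:

* a transition to the expected next phase is accepted — but when the
  stream merely flickers between the accepted phase and its successor in
  bursts shorter than half the phases' average durations, the side the
  stream eventually settles on wins and the opposing blips are dropped;
* any other questionable transition opens a *recovery period* that lasts until the
  stream returns to the currently accepted phase or reaches its valid
  successor.  Short periods (relative to the average duration of the
  interrupted phase) are discarded as classifier blips; very long periods
  (relative to the average cycle) are promoted to a full synthesized
  cycle; intermediate periods are relabeled as the single expected
  successor phase.

Phase and cycle duration averages come from the training reference
events, per walking speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EventList, LabelTrack, PHASES


class EstimationError(ValueError):
    pass


@dataclass
class RuleConfig:
    """Duration statistics and thresholds driving the supervisory rules.

    ``short_fraction`` (default 0.5): a recovery period shorter than this
    fraction of the interrupted phase's average duration is discarded.
    ``long_multiple`` (default 1.0): a period longer than this multiple of
    the average cycle duration is treated as a full missed cycle.
    """

    avg_phase_duration: np.ndarray   # seconds, indexed by phase-1
    avg_cycle_duration: float
    short_fraction: float = 0.5
    long_multiple: float = 1.0

    def __post_init__(self) -> None:
        self.avg_phase_duration = np.asarray(self.avg_phase_duration, float)
        if self.avg_phase_duration.shape != (4,):
            raise ValueError("avg_phase_duration must hold 4 values")
        if np.any(self.avg_phase_duration <= 0) or self.avg_cycle_duration <= 0:
            raise ValueError("durations must be positive")
        if not (0 < self.short_fraction < 1):
            raise ValueError("short_fraction must lie in (0, 1)")

    def phase_duration(self, phase: int) -> float:
        return float(self.avg_phase_duration[phase - 1])


def raw_transitions(labels: LabelTrack) -> EventList:
    """Run-length boundaries of a label stream: one event at the first
    sample and one wherever the label differs from its predecessor."""
    if len(labels) == 0:
        raise ValueError("raw_transitions requires a non-empty label track")
    y, t = labels.labels, labels.timestamps
    idx = np.flatnonzero(np.r_[True, y[1:] != y[:-1]])
    return EventList(t[idx], y[idx])


def estimate_durations(reference: EventList, short_fraction: float = 0.5,
                       long_multiple: float = 1.0) -> RuleConfig:
    """Average per-phase and cycle durations from complete reference cycles.

    A complete cycle is a phase-1 event followed by phases 2, 3, 4 and a
    terminating next phase-1 event.  At least two complete cycles are
    required.
    """
    times, phases = reference.times, reference.phases
    starts = np.flatnonzero(phases == 1)
    per_phase = [[] for _ in PHASES]
    cycles = []
    for s in starts:
        if s + 4 >= len(reference):
            continue
        if not np.array_equal(phases[s:s + 5], [1, 2, 3, 4, 1]):
            continue
        seg = times[s:s + 5]
        for k in range(4):
            per_phase[k].append(seg[k + 1] - seg[k])
        cycles.append(seg[4] - seg[0])
    if len(cycles) < 2:
        raise EstimationError(
            f"need at least 2 complete cycles, found {len(cycles)}")
    return RuleConfig(np.array([np.mean(d) for d in per_phase]),
                      float(np.mean(cycles)),
                      short_fraction=short_fraction,
                      long_multiple=long_multiple)


def _synthesize_cycle(period, t_open: float, t_close: float,
                      start_phase: int) -> list[tuple[float, int]]:
    """Lay one full cycle over [t_open, t_close).

    Starts of phases found inside the period (greedily, in cyclic order)
    are kept; each missed phase splits the phase preceding it at the
    temporal midpoint of its span.
    """
    seq = [(start_phase - 1 + k) % 4 + 1 for k in range(4)]
    starts: list[float | None] = [t_open, None, None, None]
    prev_t = t_open
    for k in range(1, 4):
        for tj, pj in period:
            if tj > prev_t and pj == seq[k]:
                starts[k] = tj
                prev_t = tj
                break
    for k in range(1, 4):
        if starts[k] is None:
            nxt = next((s for s in starts[k + 1:] if s is not None), t_close)
            starts[k] = (starts[k - 1] + nxt) / 2.0
    return list(zip(starts, seq))


def apply_rules(raw: EventList, cfg: RuleConfig) -> EventList:
    """Correct a raw transition list so phases follow 1→2→3→4→1.

    The first event is accepted unconditionally.  A trailing recovery
    period that never closes before the stream ends cannot be judged and
    is discarded.
    """
    if len(raw) == 0:
        return EventList.from_pairs([])
    events = list(raw)
    accepted: list[tuple[float, int]] = [events[0]]
    i = 1
    while i < len(events):
        t, p = events[i]
        at, ap = accepted[-1]
        succ = ap % 4 + 1
        if p == ap:                      # not a transition; drop
            i += 1
            continue
        if p == succ:
            # flicker arbitration: the classifier can oscillate between
            # the accepted phase and its successor in sub-threshold
            # bursts around a boundary; side with whichever of the two
            # the stream settles into (first run at least short_fraction
            # of that phase's average duration, or a third phase)
            j = i
            settle = None
            while j < len(events):
                ph = events[j][1]
                if ph not in (p, ap):
                    settle = ph
                    break
                dur = ((events[j + 1][0] - events[j][0])
                       if j + 1 < len(events) else float("inf"))
                if dur >= cfg.short_fraction * cfg.phase_duration(ph):
                    settle = ph
                    break
                j += 1
            if settle == ap:
                i = j + 1        # premature blips of the successor: drop
                continue
            accepted.append((t, p))
            i = j if j > i else i + 1
            continue
        # recovery period opens at the questionable transition
        t_open = t
        close = None
        for j in range(i + 1, len(events)):
            if events[j][1] in (succ, ap):
                close = j
                break
        if close is None:
            break
        t_close, p_close = events[close]
        duration = t_close - t_open
        if duration < cfg.short_fraction * cfg.phase_duration(ap):
            # blip: the accepted phase continued; keep the closing
            # transition only if it moves the cycle forward
            if p_close == succ:
                accepted.append((t_close, p_close))
            i = close + 1
        elif duration > cfg.long_multiple * cfg.avg_cycle_duration:
            accepted.extend(_synthesize_cycle(events[i:close], t_open,
                                              t_close, succ))
            i = close                     # closing event re-enters the machine
        else:
            accepted.append((t_open, succ))
            i = close
    return EventList.from_pairs(accepted)


def save_rule_config(cfg: RuleConfig, path) -> None:
    from pathlib import Path
    lines = [f"phase{p}_duration_s = {cfg.phase_duration(p)}" for p in PHASES]
    lines += [f"cycle_duration_s = {cfg.avg_cycle_duration}",
              f"short_fraction = {cfg.short_fraction}",
              f"long_multiple = {cfg.long_multiple}"]
    Path(path).write_text("\n".join(lines) + "\n")


def load_rule_config(path) -> RuleConfig:
    from pathlib import Path
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            k, _, v = line.partition("=")
            kv[k.strip()] = float(v)
    return RuleConfig(
        np.array([kv[f"phase{p}_duration_s"] for p in PHASES]),
        kv["cycle_duration_s"],
        short_fraction=kv.get("short_fraction", 0.5),
        long_multiple=kv.get("long_multiple", 1.0))


def events_to_labels(events: EventList, timestamps) -> LabelTrack:
    """Convenience re-export of io.labels_from_events."""
    from .io import labels_from_events
    return labels_from_events(events, timestamps)
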