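"""Resolved pulse-program event tables.

A :class:`PulseProgram` is the fully resolved, timed list of channel events
of one experiment -- what a spectrometer would execute -- used for
inspection (``overtone-sim dump-sequence``) and for the rotor-
synchronization invariants of the recoupling blocks.  The simulation
engines build their propagators from the same parameters; the program is
the human-readable contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import RSymmetry, SimSettings, r_phase_list

__all__ = ["ChannelEvent", "PulseProgram", "build_program"]


@dataclass(frozen=True)
class ChannelEvent:
    """One constant-RF event on one channel (times in seconds, phase rad)."""

    channel: str            # "14N-overtone" | "1H" | (delay: channel "-")
    start: float
    duration: float
    amplitude_hz: float     # nutation amplitude; 0 for delays
    phase: float
    kind: str               # "pulse" | "r-element" | "delay" | "acquire"

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class PulseProgram:
    """Ordered channel events plus the per-scan phase-cycle table."""

    events: list[ChannelEvent]
    phase_cycle: list[dict] = field(default_factory=lambda: [
        {"scan": 0, "excitation_phase": 0.0, "receiver": +1}])

    def validate(self) -> None:
        """Events must not overlap within a channel."""
        by_channel: dict[str, list[ChannelEvent]] = {}
        for ev in self.events:
            by_channel.setdefault(ev.channel, []).append(ev)
        for ch, evs in by_channel.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end - 1e-12:
                    raise ValueError(f"overlapping events on channel {ch}: "
                                     f"{a} / {b}")

    def duration(self) -> float:
        return max((ev.end for ev in self.events), default=0.0)

    def table(self) -> str:
        lines = [f"{'channel':14s} {'start/us':>10s} {'dur/us':>9s} "
                 f"{'amp/kHz':>8s} {'phase/deg':>9s}  kind"]
        for ev in sorted(self.events, key=lambda e: (e.start, e.channel)):
            lines.append(f"{ev.channel:14s} {ev.start * 1e6:10.2f} "
                         f"{ev.duration * 1e6:9.2f} "
                         f"{ev.amplitude_hz / 1e3:8.2f} "
                         f"{np.degrees(ev.phase):9.1f}  {ev.kind}")
        if len(self.phase_cycle) > 1:
            lines.append("phase cycle: " + "; ".join(
                f"scan {c['scan']}: excitation "
                f"{np.degrees(c['excitation_phase']):.0f} deg, receiver "
                f"{'+' if c['receiver'] > 0 else '-'}"
                for c in self.phase_cycle))
        return "\n".join(lines)


def _r_block_events(sym: RSymmetry, n_cycles: int, block_phase: float,
                    start: float, rotor_period: float,
                    amplitude_hz: float | None) -> list[ChannelEvent]:
    n_el = sym.big_n * n_cycles
    t_el = sym.element_duration(rotor_period)
    if amplitude_hz is None:
        amplitude_hz = 1.0 / (2 * t_el)
    phases = r_phase_list(sym, n_el, block_phase)
    return [ChannelEvent("1H", start + e * t_el, t_el, amplitude_hz,
                         float(phases[e]), "r-element")
            for e in range(n_el)]


def build_program(sequence: str, settings: SimSettings,
                  **params) -> PulseProgram:
    """Resolve a named experiment into its event table.

    ``sequence`` is one of ``direct``, ``echo`` or ``presto``; parameters
    follow the corresponding simulation functions (seconds).
    """
    nut = settings.rf_nutation_hz
    rotor = 1.0 / settings.mas_hz
    t = 0.0
    events: list[ChannelEvent] = []
    cycle = [{"scan": 0, "excitation_phase": 0.0, "receiver": +1}]

    if sequence == "direct":
        wd = params["pulse_width"]
        events.append(ChannelEvent("14N-overtone", t, wd, nut, 0.0, "pulse"))
        t += wd
    elif sequence in ("echo", "presto"):
        if sequence == "presto":
            sym: RSymmetry = params["sym"]
            n_cycles = int(round(params["tau_exc"]
                                 / sym.cycle_duration(rotor)))
            if abs(n_cycles * sym.cycle_duration(rotor)
                   - params["tau_exc"]) > 1e-3 * params["tau_exc"]:
                raise ValueError("tau_exc is not rotor-synchronized")
            events += _r_block_events(sym, n_cycles, 0.0, t, rotor,
                                      params.get("h_nutation_hz"))
            t = events[-1].end
            cycle = [{"scan": 0, "excitation_phase": 0.0, "receiver": +1},
                     {"scan": 1, "excitation_phase": np.pi, "receiver": -1}]
        events.append(ChannelEvent("14N-overtone", t, params["t90"], nut,
                                   0.0, "pulse"))
        t += params["t90"]
        t += params.get("tau1", 0.0)
        events.append(ChannelEvent("14N-overtone", t, params["t180"], nut,
                                   0.0, "pulse"))
        t += params["t180"]
        if sequence == "presto":
            events += _r_block_events(sym, n_cycles, np.pi / 2, t, rotor,
                                      params.get("h_nutation_hz"))
            t = events[-1].end
        t += params.get("tau2", 0.0)
    else:
        raise ValueError(f"unknown sequence {sequence!r}")

    events.append(ChannelEvent("14N-overtone", t, 0.0, 0.0, 0.0, "acquire"))
    prog = PulseProgram(events=events, phase_cycle=cycle)
    prog.validate()
    return prog
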