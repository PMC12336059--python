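"""Breathing-challenge protocols: ordered blocks of room air and hypercapnia.

A :class:`Protocol` describes the timing of a gas-inhalation experiment as an
ordered sequence of ``(condition, duration)`` blocks, together with the MRI
sampling parameters (TR, number of dynamics) and the capnograph sampling rate.
The default protocols mirror a typical interleaved 5% CO2 block design: a
short initial room-air phase, two hypercapnic blocks, and recovery room-air
phases, sampled by a 200-dynamic BOLD scan at TR = 1.5 s, and a three-scan
phase-contrast session (one room-air minute followed by two hypercapnic
minutes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

ROOM_AIR = "room_air"
HYPERCAPNIA = "hypercapnia"
_CONDITIONS = (ROOM_AIR, HYPERCAPNIA)


@dataclass(frozen=True)
class Protocol:
    """Block design of a gas challenge plus acquisition timing.

    Parameters
    ----------
    blocks
        Ordered ``(condition, duration_s)`` pairs; condition is ``"room_air"``
        or ``"hypercapnia"``; durations are positive seconds.
    tr
        Repetition time of the accompanying MRI scan in seconds (``None`` for
        capnograph-only protocols).
    n_dynamics
        Number of MRI time points.
    capno_rate
        Capnograph sampling rate in Hz.
    """

    blocks: tuple[tuple[str, float], ...]
    tr: float | None = None
    n_dynamics: int | None = None
    capno_rate: float = 20.0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ParameterError("protocol needs at least one block")
        for cond, dur in self.blocks:
            if cond not in _CONDITIONS:
                raise ParameterError(f"unknown condition {cond!r}")
            if not dur > 0:
                raise ParameterError("block durations must be > 0")
        if self.capno_rate <= 0:
            raise ParameterError("capno_rate must be > 0")
        if self.tr is not None:
            if self.tr <= 0:
                raise ParameterError("tr must be > 0")
            if self.n_dynamics is None or self.n_dynamics < 1:
                raise ParameterError("n_dynamics required when tr is set")
            if self.total_duration < self.tr * self.n_dynamics - 1e-9:
                raise ParameterError(
                    "protocol blocks must cover the scan: "
                    f"{self.total_duration} s < {self.tr * self.n_dynamics} s"
                )

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.blocks))

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative block end times, shape ``(n_blocks,)``."""
        return np.cumsum([d for _, d in self.blocks])

    def condition_at(self, t):
        """Condition label(s) at time(s) ``t`` (clamped to the protocol)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.boundaries, t, side="right")
        idx = np.clip(idx, 0, len(self.blocks) - 1)
        labels = np.array([c for c, _ in self.blocks])
        out = labels[idx]
        return out if np.ndim(out) else str(out)

    def is_hypercapnic(self, t) -> np.ndarray:
        return np.asarray(self.condition_at(t)) == HYPERCAPNIA

    def frame_times(self) -> np.ndarray:
        """MRI frame acquisition times ``i * tr`` for ``i = 0..N-1``."""
        if self.tr is None or self.n_dynamics is None:
            raise ParameterError("protocol has no MRI timing")
        return np.arange(self.n_dynamics) * self.tr

    def hypercapnia_intervals(self) -> list[tuple[float, float]]:
        out, start = [], 0.0
        for cond, dur in self.blocks:
            if cond == HYPERCAPNIA:
                out.append((start, start + dur))
            start += dur
        return out


def bold_protocol(tr: float = 1.5, n_dynamics: int = 200) -> Protocol:
    """Interleaved hypercapnia block design for the BOLD-CVR scan.

    15 s room air, then two 55 s hypercapnic blocks separated by 75 s of room
    air; the final room-air phase is extended to 100 s so the blocks cover the
    full 300 s scan.
    """
    return Protocol(
        blocks=(
            (ROOM_AIR, 15.0),
            (HYPERCAPNIA, 55.0),
            (ROOM_AIR, 75.0),
            (HYPERCAPNIA, 55.0),
            (ROOM_AIR, 100.0),
        ),
        tr=tr,
        n_dynamics=n_dynamics,
    )


def pc_protocol() -> Protocol:
    """Phase-contrast session: 60 s room air then 120 s hypercapnia.

    Three back-to-back 1-minute flow scans are acquired; the first (room air)
    and third (steady-state hypercapnia) are used for CVR, the second falls in
    the physiological transient and is excluded.
    """
    return Protocol(blocks=((ROOM_AIR, 60.0), (HYPERCAPNIA, 120.0)))


#: Acquisition windows (start, end) in seconds of the three PC scans.
PC_SCAN_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 60.0), (60.0, 120.0), (120.0, 180.0))
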