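"""Simulated electro-pneumatic pressure control for the soft glove.

Each recognized motion maps to a preset gauge pressure PP (kilopascal):
with the glove worn on a hand, Extension/Rest/Spherical/Fist command
about -2 / 0 / 40 / 70 KPa; unloaded actuators (bench visualization)
need only -2 / 0 / 30 / 60 KPa.  The controller compares PP with the
current pressure CP each tick and picks one of four power modes:

* ``closed``  when |PP - CP| < x (the per-motion tolerance: 1 KPa for
  the low-pressure targets R and E, 5 KPa for S and F),
* ``supply``  when pressure must rise toward a positive target,
* ``release`` when pressure must fall toward a non-negative target, or
  rise from vacuum toward atmospheric (venting in either case),
* ``vacuum``  when pressure must fall below atmospheric.

The plant is modeled as a constant slew rate per mode, the simplest
model in which filling time grows with the target pressure; each tick
moves CP by rate x dt, capped at PP so the setpoint is never overshot.
A new motion command is consumed only once the previous target has been
reached (the system waits for each motion to complete).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ControlTimeoutError, InvalidConfigError
from .motions import MOTION_ORDER, Motion, as_motion

Mapping = Literal["worn", "unloaded"]
Mode = Literal["supply", "release", "vacuum", "closed"]

#: Preset pressures (KPa) with the glove worn on a hand.
WORN_PRESSURE: dict[Motion, float] = {
    Motion.EXTENSION: -2.0,
    Motion.REST: 0.0,
    Motion.SPHERICAL: 40.0,
    Motion.FIST: 70.0,
}

#: Preset pressures (KPa) for unloaded actuators (bench visualization).
UNLOADED_PRESSURE: dict[Motion, float] = {
    Motion.EXTENSION: -2.0,
    Motion.REST: 0.0,
    Motion.SPHERICAL: 30.0,
    Motion.FIST: 60.0,
}

#: Acceptable error x (KPa), keyed by the target motion.
DEFAULT_TOLERANCE: dict[Motion, float] = {
    Motion.EXTENSION: 1.0,
    Motion.REST: 1.0,
    Motion.SPHERICAL: 5.0,
    Motion.FIST: 5.0,
}


@dataclass(frozen=True)
class ControllerConfig:
    """Pressure mappings, tolerances and plant slew rates.

    Default rates give a 0 -> 70 KPa fill in about 2 s (supply
    35 KPa/s); release and vacuum rates are of the same order.  ``dt``
    is the control tick.
    """

    worn_pressure: dict[Motion, float] = field(
        default_factory=lambda: dict(WORN_PRESSURE)
    )
    unloaded_pressure: dict[Motion, float] = field(
        default_factory=lambda: dict(UNLOADED_PRESSURE)
    )
    tolerance: dict[Motion, float] = field(
        default_factory=lambda: dict(DEFAULT_TOLERANCE)
    )
    supply_rate: float = 35.0
    release_rate: float = 50.0
    vacuum_rate: float = 10.0
    dt: float = 0.02
    max_ticks_per_command: int = 100_000

    def __post_init__(self) -> None:
        if min(self.supply_rate, self.release_rate, self.vacuum_rate) <= 0:
            raise InvalidConfigError("slew rates must be > 0")
        if self.dt <= 0:
            raise InvalidConfigError("dt must be > 0")
        if any(v <= 0 for v in self.tolerance.values()):
            raise InvalidConfigError("tolerances must be > 0")
        for name in ("worn_pressure", "unloaded_pressure"):
            table = getattr(self, name)
            ordered = [table[m] for m in MOTION_ORDER]  # E, R, S, F
            if not all(a < b for a, b in zip(ordered, ordered[1:])):
                raise InvalidConfigError(
                    f"{name} must be strictly increasing over E < R < S < F"
                )

    def pressure_table(self, mapping: Mapping) -> dict[Motion, float]:
        if mapping == "worn":
            return self.worn_pressure
        if mapping == "unloaded":
            return self.unloaded_pressure
        raise InvalidConfigError(f"mapping must be 'worn' or 'unloaded'; got {mapping!r}")


def motion_to_pressure(
    m: Motion | str, cfg: ControllerConfig | None = None, mapping: Mapping = "worn"
) -> float:
    """Preset pressure (KPa) commanded by a motion under a mapping."""
    cfg = cfg or ControllerConfig()
    return cfg.pressure_table(mapping)[as_motion(m)]


def controller_step(
    cp: float, pp: float, x: float, cfg: ControllerConfig | None = None
) -> tuple[Mode, float]:
    """One control tick: pick the power mode and advance the pressure.

    Within tolerance the loop stays closed and CP is unchanged.
    Otherwise CP slews toward PP at the mode's rate, capped at PP.
    Raising pressure toward a positive target engages the supply pump;
    raising it from vacuum toward a non-positive target only vents
    (release).  Lowering pressure releases down to atmospheric targets
    and engages the vacuum pump for negative targets.
    """
    cfg = cfg or ControllerConfig()
    if abs(pp - cp) < x:
        return "closed", cp
    if pp > cp:
        mode: Mode = "supply" if pp > 0 else "release"
        rate = cfg.supply_rate if mode == "supply" else cfg.release_rate
        return mode, min(cp + rate * cfg.dt, pp)
    mode = "release" if pp >= 0 else "vacuum"
    rate = cfg.release_rate if mode == "release" else cfg.vacuum_rate
    return mode, max(cp - rate * cfg.dt, pp)


@dataclass
class PressureTrace:
    """Tick-by-tick record of the simulated plant."""

    times: np.ndarray
    pressure: np.ndarray
    mode: np.ndarray  # str per tick
    command: np.ndarray  # motion code per tick

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "pressure_kpa": self.pressure,
                "mode": self.mode,
                "command": self.command,
            }
        )

    def plateaus(self) -> list[tuple[Motion, float]]:
        """Final pressure reached for each consecutive command segment."""
        out: list[tuple[Motion, float]] = []
        for i in range(len(self.command)):
            last = i + 1 == len(self.command) or self.command[i + 1] != self.command[i]
            if last:
                out.append((Motion(self.command[i]), float(self.pressure[i])))
        return out


def simulate_commands(
    commands: Sequence[Motion | str],
    cfg: ControllerConfig | None = None,
    mapping: Mapping = "worn",
    initial_pressure: float = 0.0,
    settle_s: float = 0.2,
) -> PressureTrace:
    """Drive the simulated plant through a stream of motion commands.

    Each command is held until the plant reaches its preset pressure
    within tolerance, then kept closed for ``settle_s`` before the next
    command is consumed.  Raises :class:`ControlTimeoutError` if a
    target cannot be reached within the configured tick budget.
    """
    cfg = cfg or ControllerConfig()
    stream = [as_motion(c) for c in commands]
    if not stream:
        raise InvalidConfigError("command stream must be nonempty")
    table = cfg.pressure_table(mapping)
    settle_ticks = max(1, round(settle_s / cfg.dt))

    cp = float(initial_pressure)
    t = 0.0
    times, pressures, modes, cmds = [], [], [], []
    for cmd in stream:
        pp = table[cmd]
        x = cfg.tolerance[cmd]
        ticks = 0
        reached = False
        settled = 0
        while True:
            mode, cp = controller_step(cp, pp, x, cfg)
            times.append(t)
            pressures.append(cp)
            modes.append(mode)
            cmds.append(cmd.value)
            t += cfg.dt
            ticks += 1
            if mode == "closed":
                reached = True
                settled += 1
                if settled >= settle_ticks:
                    break
            elif ticks > cfg.max_ticks_per_command:
                raise ControlTimeoutError(
                    f"target {pp} KPa for motion {cmd.value} not reached within "
                    f"{cfg.max_ticks_per_command} ticks (rates too slow?)"
                )
        assert reached
    return PressureTrace(
        times=np.asarray(times),
        pressure=np.asarray(pressures),
        mode=np.asarray(modes),
        command=np.asarray(cmds),
    )


def ideal_pressure_track(
    labels: Sequence[Motion | str],
    cfg: ControllerConfig | None = None,
    mapping: Mapping = "worn",
) -> np.ndarray:
    """Instantaneous preset-pressure step function, without plant dynamics."""
    cfg = cfg or ControllerConfig()
    table = cfg.pressure_table(mapping)
    return np.asarray([table[as_motion(l)] for l in labels], dtype=float)
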