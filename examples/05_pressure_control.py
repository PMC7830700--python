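"""Simulate the pneumatic plant following a motion command sequence.

Each motion maps to a preset pressure (worn glove: E=-2, R=0, S=40,
F=70 KPa) and the controller supplies, releases or pulls vacuum until
the current pressure is within tolerance (1 KPa for E/R, 5 KPa for
S/F).  The printed plateaus show the plant settling at each commanded
pressure in order; fill time grows with the pressure jump.
"""

import numpy as np

from semglove import ControllerConfig, motion_to_pressure, simulate_commands

cfg = ControllerConfig()
commands = list("RSFSR")
trace = simulate_commands(commands, cfg, mapping="worn")

print(f"{len(trace.times)} ticks of {cfg.dt:g} s "
      f"({trace.times[-1] + cfg.dt:.2f} s simulated)")
for motion, pressure in trace.plateaus():
    target = motion_to_pressure(motion, cfg, "worn")
    print(f"  command {motion.value}: target {target:+5.1f} KPa, "
          f"settled at {pressure:+6.2f} KPa")
modes, counts = np.unique(trace.mode, return_counts=True)
print("tick count per mode:", dict(zip(modes.tolist(), counts.tolist())))
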