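"""Scan the band-pass down cut-off frequency for the best chemotaxis.

The down cut-off omega1 sets the controller 'memory' (adaptation time
~ 1/omega1).  Too-fast adaptation loses the running direction; too-slow
adaptation overshoots the crest.  The scan uses common random numbers
across grid points so differences reflect the parameter, not the seed.
(100 agents per grid point, 3 seed replicates, as in the
reference protocol.)
"""

import numpy as np

from taxisim import ControllerFilter, SimulationConfig, scan_parameters

base = SimulationConfig(
    controller=ControllerFilter(kind="band_pass", A=16.0, omega1=0.02,
                                omega2=5.0),
    n_bacteria=100, duration=1000.0, seed=1)

result = scan_parameters(base, {"omega1": [0.005, 0.01, 0.02, 0.05, 0.1]},
                         n_seeds=3)
print(result.to_frame().to_string(index=False,
                                  float_format=lambda v: f"{v:.4f}"))
best = result.grids[0][int(np.argmax(result.effects))]
print(f"\nbest down cut-off: omega1 = {best} /s "
      f"(adaptation time ~ {0.7 / best:.0f} s)")
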