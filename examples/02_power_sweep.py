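"""Sweep the LED drive power and find the ablation onset.

Each power runs 10 minutes on the coarse sweep grid.  The printed table
shows how the final maximum temperature and the 43/50 degC isotherm volumes
grow with power; the onset is the smallest power at which any tissue
crosses 50 degC (irreversible damage), i.e. the upper end of the safe
operating window.
"""

import ledtherm as lt

sweep = lt.run_power_sweep(
    "90deg", powers_mW=[100, 200, 300, 400, 500],
    duration=600.0, grid=lt.fast_skin_grid(),
    settings=lt.SolverSettings(dt=1.0, cg_rtol=1e-6),
)
print(sweep.table.round(2).to_string(index=False))
print(f"\nablation onset: {sweep.ablation_onset_mW:g} mW "
      "(first power with any tissue at or above 50 degC)")
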