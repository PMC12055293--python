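"""Forward-simulate shallow-water reflectance for contrasting conditions.

Builds the canonical 61-band grid, runs the semi-analytical simulator for
clear and turbid water over the default brown-coral bottom, and prints a
few reflectance values.  Expect the turbid case to be brighter in the
green (mineral backscatter) and the deep case to lose the bottom signal.
"""

import numpy as np

import reefsbi as rb

grid = rb.make_wavelength_grid(400, 700, 5)
sim = rb.ShallowWaterSimulator(grid)
print(f"grid: {len(grid)} bands from {grid.values[0]:.0f} to {grid.values[-1]:.0f} nm")

cases = {
    "clear, 3 m": rb.ParameterVector(0.2, 0.03, 0.3, 4.0, 3.0),
    "turbid, 3 m": rb.ParameterVector(0.2, 0.03, 8.0, 4.0, 3.0),
    "clear, 18 m": rb.ParameterVector(0.2, 0.03, 0.3, 4.0, 18.0),
}
bands = [440, 560, 665]
idx = [int(np.argmin(np.abs(grid.values - b))) for b in bands]

header = "".join(f"  Rrs({b} nm)" for b in bands)
print(f"{'case':<14}{header}")
for name, theta in cases.items():
    spec = sim(theta)
    vals = "".join(f"  {spec.values[i]:10.5f}" for i in idx)
    print(f"{name:<14}{vals}")

print(
    "\nValues are above-surface remote-sensing reflectance in sr^-1. "
    "Suspended minerals brighten the green band several-fold here; at 18 m "
    "the water column hides the bright red edge of the coral bottom and the "
    "spectrum relaxes toward the blue-green of optically deep water."
)
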