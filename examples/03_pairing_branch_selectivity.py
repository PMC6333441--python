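"""Pairing a driver input with a subthreshold bias on different branches.

A distal LOT "driver" input is scanned across intensities (number of
co-active synapses) while a constant subthreshold bias input (~3–4 mV at
the soma) is delivered to (a) the same branch, (b) a sister branch off the
same primary dendrite, or (c) a branch of a different primary dendrite.
A same-branch bias left-shifts the driver's input–output curve — it lowers
the NMDA-spike threshold — whereas sister/different-branch biases of equal
somatic size barely move it: individual apical branches act as separate
integrative subunits.
"""

from piriform.biophysics import ChannelSet
from piriform.engine import CompartmentalSystem
from piriform.morphology import discretize, generate_synthetic_morphology
from piriform.protocols import (
    StimulusSite,
    calibrate_bias_intensity,
    calibrate_unitary_input,
    pairing_experiment,
    standard_sites,
)

grid = discretize(generate_synthetic_morphology(seed=1))
system = CompartmentalSystem(grid=grid, channels=ChannelSet.passive())
sites = standard_sites(grid)

cal = calibrate_unitary_input(system, sites["driver"], trials=60, seed=1)
n_bias, bias_epsp = calibrate_bias_intensity(
    system, StimulusSite(sites["same"]), cal.scale, seed=1
)
print(f"Bias input: {n_bias} synapses, ~{bias_epsp:.1f} mV somatic EPSP\n")

driver = StimulusSite(sites["driver"])
for relation in ("same", "sister", "different"):
    res = pairing_experiment(
        system, driver, StimulusSite(sites[relation]), n_bias,
        scale=cal.scale, intensities=tuple(range(0, 15)), trials=4, seed=1,
    )
    print(
        f"{relation:9s} branch: threshold {res.theta_unpaired:.1f} -> "
        f"{res.theta_paired:.1f} synapses  "
        f"({res.reduction_pct:+.1f}% threshold reduction)"
    )

print(
    "\nA large same-branch reduction with small sister/different reductions "
    "reproduces the compartmentalized, sigmoid(I1 + I2) form of within-branch "
    "integration."
)
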