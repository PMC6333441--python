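"""Clustered versus dispersed synaptic drive under in-vivo-like background.

Twenty excitatory "odor" inputs (with forty inhibitory inputs and a
120-synapse background population) are placed either clustered on a single
distal branch or dispersed over the whole LOT-recipient zone, with
identical presynaptic trains in both arms.  Clustered drive reliably
ignites an NMDA spike and produces a much larger somatic EPSP; freezing the
NMDA voltage dependence (Ohmic control) abolishes the difference, showing
the preference for clustered input is entirely NMDA-spike-dependent.
"""

import numpy as np

from piriform.biophysics import ChannelSet
from piriform.engine import CompartmentalSystem
from piriform.morphology import discretize, generate_synthetic_morphology
from piriform.protocols import (
    calibrate_unitary_input,
    clustered_vs_dispersed,
    standard_sites,
)

grid = discretize(generate_synthetic_morphology(seed=1))
system = CompartmentalSystem(grid=grid, channels=ChannelSet.passive())
cal = calibrate_unitary_input(system, standard_sites(grid)["driver"], trials=60, seed=1)

for ohmic in (False, True):
    res = clustered_vs_dispersed(
        system, trials=10, seed=1, scale=cal.scale, ohmic=ohmic
    )
    label = "Ohmic NMDA " if ohmic else "regenerative"
    print(
        f"{label}: clustered {np.mean(res.peaks_clustered):5.1f} mV, "
        f"dispersed {np.mean(res.peaks_dispersed):5.1f} mV "
        f"(peak somatic EPSP above background, mean of {len(res.peaks_clustered)} trials)"
    )

print(
    "\nWith regenerative NMDA receptors the clustered arm is amplified far "
    "beyond the dispersed arm; with the voltage dependence frozen the two "
    "placements are nearly equivalent."
)
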