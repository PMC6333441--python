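"""Combination selectivity for glomerular input patterns.

Three glomeruli of six LOT inputs each innervate the model cell: A and B
target the same terminal apical dendrite, C a branch of a different primary
dendrite.  With odor-unselective inhibition and random background activity,
co-activation of A+B (same branch) crosses the local NMDA-spike threshold
and sums supralinearly, while A+C (different branches) stays near linear —
the cell responds to specific input combinations, a discontinuous receptive
field built from dendritic subunits.
"""

import numpy as np

from piriform.biophysics import ChannelSet
from piriform.engine import CompartmentalSystem
from piriform.morphology import discretize, generate_synthetic_morphology
from piriform.protocols import (
    calibrate_unitary_input,
    glomerular_combination,
    standard_sites,
)

grid = discretize(generate_synthetic_morphology(seed=1))
system = CompartmentalSystem(grid=grid, channels=ChannelSet.passive())
cal = calibrate_unitary_input(system, standard_sites(grid)["driver"], trials=60, seed=1)

res = glomerular_combination(system, trials=10, seed=1, scale=cal.scale)
for pair, nl in res.nonlinearity.items():
    print(
        f"{pair}: pairing nonlinearity {nl.mean_ratio:.2f} "
        f"(n={len(nl.ratios)}, excluded {nl.n_excluded}); "
        f"background-subtracted peak {np.mean(res.peaks[pair]):.1f} mV"
    )

print(
    "\nA ratio of 1 is exact linear summation; AB >> AC means the cell "
    "amplifies the same-branch glomerular combination only."
)
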