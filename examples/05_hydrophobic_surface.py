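"""Hydrophobic vs polar water-exposed area of a pore cavity lining.

Builds two synthetic cavity walls — an all-hydrocarbon one and one whose
upper ring is oxygen — and measures the accessible area inside the pore
region.  A larger hydrophobic fraction of the cavity lining is what primes
a pore for dewetting; polar substitutions (as in channel-opening mutations)
cut it down.
"""

import numpy as np

from poregate import PoreRegion, pore_exposed_area, sasa
from poregate.core_io import AtomIndexSet, Structure


def cavity_wall(polar_top: bool):
    spec = []
    for iz, z in enumerate(np.arange(0.0, 8.1, 2.0)):
        el = "O" if (polar_top and iz in (0, 1)) else "C"
        for a in 2 * np.pi * np.arange(12) / 12:
            spec.append((el, 7 * np.cos(a), 7 * np.sin(a), z))
    n = len(spec)
    return Structure(np.arange(1, n + 1), [s[0] for s in spec],
                     [s[0] for s in spec], ["WAL"] * n, np.arange(1, n + 1),
                     ["A"] * n, np.array([s[1:] for s in spec]),
                     np.where(np.array([s[0] for s in spec]) == "O",
                              15.999, 12.011))


for name, polar in (("hydrophobic lining", False), ("polar-substituted", True)):
    s = cavity_wall(polar)
    region = PoreRegion(AtomIndexSet(np.arange(12)),
                        AtomIndexSet(np.arange(s.n_atoms - 12, s.n_atoms)),
                        lateral_radius=7.0)
    res = pore_exposed_area(s, region, seed=0)
    frac = res.hydrophobic_total / res.total
    print(f"{name}: pore-facing area {res.total:8.1f} A^2, "
          f"hydrophobic {res.hydrophobic_total:8.1f} A^2 ({100 * frac:5.1f}%)")

print("\n(the hydrophobic share of the cavity surface, not its absolute "
      "size, sets the dewetting tendency)")
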