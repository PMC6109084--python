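"""Boltzmann inversion of an equilibrium density and PMF stitching.

A single-ion umbrella PMF is only valid where multiple-occupancy effects
are absent (the dewetted pore segment); the bulk-connected side is covered
by Boltzmann inversion of an equilibrium density.  The two segments are
joined by a constant shift plus a linear crossfade over their overlap,
giving one continuous profile across the full axial range.
"""

import numpy as np

from poregate import DensityProfile, boltzmann_invert, stitch_pmf, wham
from poregate.toysim import double_well_truth, sample_umbrella_windows
from poregate.units import kT

KT = kT(298.0)
truth = double_well_truth(barrier_kT=5.0)
rng = np.random.default_rng(11)

# umbrella segment: windows over the "dewetted" region 6-20 A
windows = sample_umbrella_windows(truth, np.arange(6.0, 20.1, 2.0),
                                  spring=100.0, n_per_window=5000, seed=3)
pmf_umbrella = wham(windows, np.arange(6.0, 20.01, 0.2)).pmf

# equilibrium segment: exact Boltzmann samples of the truth on 18-30 A
lo, hi = 18.0, 30.0
zs, have = [], 0
log_max = -truth.energy(np.linspace(lo, hi, 2001)).min() / KT
while have < 200_000:
    cand = rng.uniform(lo, hi, 400_000)
    keep = cand[rng.random(len(cand))
                < np.exp(-truth.energy(cand) / KT - log_max)]
    zs.append(keep)
    have += len(keep)
samples = np.concatenate(zs)[:200_000]
edges = np.arange(18.0, 30.01, 0.2)
density = DensityProfile(edges, np.histogram(samples, bins=edges)[0].astype(float),
                         n_frames=1, species="cation")
pmf_equilibrium = boltzmann_invert(density, bulk_zrange=(28.0, 30.0))

stitched = stitch_pmf(pmf_umbrella, pmf_equilibrium, overlap_zrange=(18.0, 20.0))
u = truth.energy(stitched.z)
u -= u.min()
rmsd = np.sqrt(np.mean((stitched.G - u - np.mean(stitched.G - u)) ** 2))
n_blend = int(np.sum(stitched.provenance == "blend"))

print(f"umbrella segment: {len(pmf_umbrella.z)} bins on [6, 20] A")
print(f"equilibrium segment: {len(pmf_equilibrium.z)} bins on [18, 30] A "
      f"({len(samples)} samples)")
print(f"stitched profile: {len(stitched.z)} bins on "
      f"[{stitched.z.min():.0f}, {stitched.z.max():.0f}] A, "
      f"{n_blend} crossfaded bins in the overlap")
print(f"RMSD vs the known potential: {rmsd / KT:.3f} kT")
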