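"""Build a synthetic Mn-O coordination cluster and analyse its geometry.

Generates a four-coordinate Mn centre with the published bond-length
statistics (ideal 2.08 Å, spread 0.05 Å), then reports the Gaussian-smoothed
coordination number — close to 4 when all ligands sit near the ideal shell —
and the screened effective charge of the metal centre.
"""

import numpy as np

from mncat.geometry import bond_angle, coordination_number, effective_charge
from mncat.synthetic import ClusterSpec, gen_mn_cluster

ideal, ideal_model = gen_mn_cluster(ClusterSpec(length_spread=0.0))
print(f"ideal cluster (spread 0):   N_coord = "
      f"{coordination_number(ideal, ideal_model):.3f}")

system, model = gen_mn_cluster(ClusterSpec(seed=42))
pos = system.positions
lengths = np.linalg.norm(pos[1:] - pos[0], axis=1)
print("noisy Mn-O bond lengths (Å):", np.round(lengths, 3))
print(f"noisy cluster N_coord:      {coordination_number(system, model):.3f}")
print(f"effective Mn charge:        {effective_charge(system, model):.4f}")
print(f"O-Mn-O angle (1,2):         {bond_angle(pos[1], pos[0], pos[2]):.2f} deg")
print()
print("All four ligands exactly on the 2.08 Å shell count as 4.0.  With the")
print("realistic 0.05 Å bond-length spread each ligand is Gaussian-discounted")
print("(expected factor 1/sqrt(2) when spread equals the smoothing width), so")
print("the smoothed count drops below the integer ligand number.  The")
print("effective charge is the screened Coulomb sum of the O partial charges")
print("(-0.40 e each) at the Mn centre.")
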