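"""Lipid order and bilayer thickness fields, and their coupling.

The order parameter chi is the folded angle between the membrane normal and
each tail's linker-to-terminal vector: 0 = fully ordered (raft-like), pi/2 =
lying flat.  Thickness is the gap between the leaflets' first-linker beads.
Both are averaged on a 0.175 nm grid over the non-flipping lipids.
"""

import numpy as np

import protomem as pm
from protomem.fields import order_field, sm_order_enrichment, thickness_map, \
    thickness_order_correlation

params = pm.GeneratorParams(patch_nm=20.0, n_proteins=4, n_frames=150, seed=7)
topology, frame0 = pm.build_system(params)
traj, _ = pm.simulate(topology, frame0, params)

ofld = order_field(traj, topology)
tfld = thickness_map(traj, topology)
chi_mean = ofld.value_sum.sum() / ofld.count.sum()
print(f"mean lipid order chi = {chi_mean:.3f} rad "
      "(smaller = more ordered tails)")
print(f"mean bilayer thickness = {np.nanmean(tfld.mean()):.2f} nm")

_, r = thickness_order_correlation(ofld, tfld)
print(f"per-bin thickness-order Pearson r = {r:.3f} "
      "(negative: ordered regions are thicker, as hydrophobic matching demands)")

enrich = sm_order_enrichment(traj, topology)
print("\nprobability of finding each lipid class in an ordered region "
      "(chi below the global mean):")
print(enrich.round(3))
print("sphingomyelin above 50% reflects its planted raft-like coupling; "
      "other classes sit near 50/50.")

ofld.save_text("scratch_order_field.txt")
tfld.save_text("scratch_thickness_field.txt")
print("\nwrote scratch_order_field.txt, scratch_thickness_field.txt")
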