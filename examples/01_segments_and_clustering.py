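"""Harvest dihedral segments from a backbone and cluster a population.

Builds an ideal-geometry helical chain, extracts sliding 9-residue windows
of (phi, psi) angles, then recovers three planted conformational clusters
with the single-pass procedure at the 30-degree threshold.
"""

import numpy as np

import crossprofiler as cp

# a 30-residue alpha-helix: every residue at (phi, psi) = (-60, -45)
chain = cp.backbone_from_dihedrals(np.full(30, -60.0), np.full(30, -45.0), "A" * 30)
segments = cp.extract_segments(chain, L=9)
print(f"helical chain: {len(segments)} overlapping 9-residue segments "
      f"(windows touching the chain termini are dropped)")

# a population with three planted conformations, 3 deg angular noise
spec = cp.FixtureSpec(seed=1, k_clusters=3, members_per_cluster=50,
                      angular_noise_deg=3.0)
population, true_labels = cp.generate_segment_population(spec)
clusters = cp.single_pass_cluster(population, cp.ClusteringConfig(d_th=30.0))
print(f"planted population: {len(population)} segments -> "
      f"{len(clusters)} clusters of sizes {[c.size for c in clusters]}")
medoid = clusters[0].medoid_index
print(f"cluster 1 medoid is segment {medoid} "
      f"(the member closest to all of its co-members)")
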