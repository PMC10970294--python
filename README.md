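# ringscape

Conformational-landscape analysis of per-particle atomic models of
ring-shaped protein complexes.

Cryo-EM methods that fit an atomic model to every particle image turn a
data set into an ensemble of Cα structures — one conformer per particle.
For partially symmetric complexes such as the AAA+ ATPase p97 (a C6
double ring of D1/D2 ATPase domains with six flexible N-terminal domains),
that ensemble is the only place where the continuous motion of the
flexible domains survives: discrete classification averages it away.
`ringscape` implements the downstream analysis of such ensembles:

- **Rigid-body superposition** with domain masks (Kabsch, proper rotations
  only), including alignment on the rigid D1+D2 core so the moving
  N-domains stay measurable, and canonicalization of the six-fold ring
  register.
- **Landscape embedding** (PCA or UMAP, 10-D by default) with free-energy
  surfaces by Boltzmann inversion, ΔG/k_BT = −ln(n/n₀), cluster-average
  structures, and per-residue RMSF.
- **Robust major/minor cluster partition** that recovers rare
  subpopulations (e.g. a split-washer open-ring state) even when the
  unresolved ring register smears them over symmetry-related directions.
- **Monomer hinge-angle analysis**: the hexamers are split into monomers,
  core-aligned, and the swing of each N-domain about its hinge is measured
  and discretized into K equal-count regions.
- **Ring-state combinatorics**: per-monomer states are mapped back onto
  their hexamer slots and counted up to cyclic rotation (necklace
  canonicalization; 3 states on a six-ring give exactly 130 classes), with
  adjacency statistics that quantify coordination between neighbouring
  domains.
- **A procedural toy hexamer and a seeded ensemble generator** (uniform
  ±30° swings about a 75° up-offset, optional ring coupling, 2% planted
  split-ring subpopulation, coordinate noise, random pose and register),
  plus elastic-network normal modes, so the whole pipeline is testable by
  parameter recovery without any experimental download.

## Worked example

```python
import numpy as np
from ringscape import (EnsembleSpec, align_ensemble, build_template, embed,
                       split_monomers)
from ringscape.ensemble_sim import sample_ensemble
from ringscape.landscape import free_energy_surface, two_cluster_partition
from ringscape.ring_states import (adjacency_stats, discretize_equal_count,
                                   map_to_hexamers, measure_hinge_angles,
                                   state_histogram)
from ringscape.superpose import core_mask

template = build_template()                      # 540-atom C6 toy hexamer
spec = EnsembleSpec(n_particles=5000, seed=1)    # default study conditions
ensemble, truth = sample_ensemble(spec, template)

aligned = align_ensemble(ensemble, template.coords, core_mask(template))
embedding = embed(aligned, method="pca", n_dimensions=10)
surface = free_energy_surface(embedding, n_bins=60)
partition = two_cluster_partition(embedding)
print(f"clusters: {partition['n_clusters']}, "
      f"minor fraction: {100*partition['minor_fraction']:.2f}%")

monomers, table = split_monomers(ensemble)
angles = measure_hinge_angles(monomers, template.monomers[0])
print(f"swing range: {np.ptp(angles):.1f} deg "
      f"({angles.min():.1f} to {angles.max():.1f})")

labels, boundaries = discretize_equal_count(angles, 3)
print(f"tertile boundaries: {boundaries.round(2)} deg")
states = map_to_hexamers(labels, table)
print(f"ring states observed: {len(state_histogram(states))} of 130")
adj = adjacency_stats(states)
print(f"hexamers with >=5 equal N-domain states: {100*adj['ge5_equal'].mean():.1f}%")
```

Output:

```
clusters: 2, minor fraction: 1.86%
swing range: 60.9 deg (-30.5 to 30.4)
tertile boundaries: [-10.15   9.86] deg
ring states observed: 130 of 130
hexamers with >=5 equal N-domain states: 5.2%
```

Reading it: the landscape partition finds the planted 2% open-ring
subpopulation; the N-domains swing over a ~60° range about the up
position; splitting the swing distribution into equal tertiles puts the
boundaries at ±10°; all 130 cyclically distinct hexamer states occur; and
with independent domains, ~5.3% of hexamers (the combinatorial baseline
39/729) have five or more N-domains in the same state — coordinated
ensembles (`neighbor_coupling > 0`) push this figure up.

The same pipeline runs from the shell:

```sh
ringscape simulate --config run.yaml --seed 1 --out run/
ringscape analyze  --ensemble run/ --method pca --dims 10
ringscape states   --ensemble run/ --k 3 --axis component1
ringscape report   --run run/
```

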