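# radcurve

Sliding semi-landmark geometric morphometrics and curvature metrics for
inferring forearm posture and active pronation ability from radius
morphology.

## The problem

In sprawling tetrapods (crocodylians, most squamates, monotremes) the radius
lies parallel to the ulna, its shaft is straight, and the radial head is
flattened against the ulnar articular surface.  In parasagittal taxa with
mammalian-style pronation the radius crosses the ulna — the shaft is curved
and the radial head is rounded so it can rotate in place.  Both signals can
be read from isolated bones, which makes them usable for extinct taxa such
as the secondarily quadrupedal dinosaur clades, where forelimb posture is
contested.  `radcurve` implements the complete quantitative toolkit:

* **Outline shape** — 21-point radial-head outlines (1 fixed landmark + 20
  sliding semi-landmarks) in TPS files; generalized Procrustes analysis in
  partial superimposition (centroid size fixed at 1) with semi-landmarks slid
  along their tangents by the minimum thin-plate-spline bending energy
  criterion; relative warp analysis (PCA of partial warp scores) with
  broken-stick axis assessment and axis-extreme shape reconstruction.
* **Group inference** — Goodall's F on partial Procrustes distances,

      F = [d²(x̄₁, x̄₂)/(1/n₁ + 1/n₂)] / [(ΣΣ d²(xᵢ, x̄g))/(n₁ + n₂ − 2)],

  tested by label permutation (exhaustive for small samples), run pairwise
  over all groups under a shared Bonferroni threshold (0.05/#pairs).
* **Angle of curvature** — the three-point angle between the radial-head
  plane and the shaft's long axis; 90° marks a straight radius that cannot
  cross the ulna.  Groups are compared with a tie-corrected Kruskal–Wallis
  test plus mean-rank multiple comparisons.
* **Phylogenetic signal** — Blomberg's K (K ≈ 1 under Brownian motion) per
  ordination axis, with tip-permutation p-values, on trees read from
  newick/NEXUS.
* **Synthetic data** — seeded generators for grouped outlines with a
  controlled Procrustes offset between group means, per-group angle
  distributions, and Brownian traits on pure-birth trees, so the entire
  pipeline runs and is testable without any external data.

The Procrustes/warp machinery is exposed as sklearn-style estimators
(`GeneralizedProcrustesAnalysis`, `RelativeWarps` with `fit`/`transform` and
trailing-underscore attributes) that compose with sklearn pipelines;
module-level functions (`gpa`, `relative_warps`, ...) wrap them.

## Worked example

```python
import radcurve as rc
from radcurve.tps_io import stack_configurations

model = rc.OutlineModel(delta=0.08, noise_sd=0.02, n_per_group=20, seed=42,
                        group_names=["sprawled", "parasagittal"])
records, table = rc.generate_outlines(model)
X = stack_configurations(records)

res = rc.gpa(X, slide=True)
rw = rc.RelativeWarps().fit(res.aligned, consensus=res.consensus)
battery = rc.pairwise_shape_tests(X, table["group"].to_numpy(),
                                  n_permutations=999, seed=0)
```

printing the fitted summaries gives:

```
GPA converged in 13 iterations; mean distance to consensus = 0.1277
RW1: 21.32% of variance (broken stick 11.13%)
RW2: 18.35% of variance (broken stick 8.49%)
RW3: 10.65% of variance (broken stick 7.18%)
Goodall's F = 5.39, permutation p = 0.001 (Bonferroni alpha = 0.05)
recovered group offset = 0.0773
angle of curvature = 96.9 deg -> curved
```

The two simulated groups differ by a partial Procrustes distance of 0.08
between their mean shapes; the bias-corrected estimate recovers 0.077, the
first relative warp exceeds its broken-stick expectation, and the permutation
test rejects equality of mean shapes at p = 0.001.  The angle line shows the
three-point metric on one digitized triple: 96.9° departs from the 90°
straight-radius expectation, so the shaft is classified as curved.

A full run (superimposition → warps → pairwise battery → angle tests →
optional phylogenetic signal → tables, SVG ordination plot with group convex
hulls, and a JSON run manifest) is driven by a config file:

```sh
radcurve simulate --tps sim.tps --groups groups.csv --seed 3
radcurve run --config analysis.yaml
```

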