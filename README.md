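# morphocloud

Rotation-invariant point-cloud representation learning for 3D multi-piece
intracellular structures.

## The problem

Many intracellular structures are not one blob: DNA replication foci are
hundreds of puncta whose spatial pattern tracks the cell cycle; nucleoli
are a handful of pieces whose individual shapes matter. Classical
shape descriptors (spherical harmonics, texture features) either require a
single continuous shape or are hard to interpret, and representations
learned by ordinary autoencoders depend on how the cell happened to be
oriented under the microscope. `morphocloud` addresses both problems by
encoding single-cell images as point clouds — intensity-weighted XYZ
points for punctate structures, surface points plus a signed distance
field (SDF) for polymorphic ones — and learning representations with a
3D rotation-equivariant vector-neuron autoencoder.

The encoder's latent is a stack of C vectors in R³ that transforms as
V → V·Rᵀ when the input rotates by R. The per-channel norms ‖V_c‖ are
therefore rotation-invariant features, and Gram–Schmidt on two designated
channels recovers the rotation matrix used to reorient canonical
reconstructions:

    input x  ──VN-DGCNN──►  V ∈ R^{C×3}
    invariant representation:  r_c = ‖V_c‖
    orientation:               R̂ = GS(V_0, V_1)
    reconstruction:            decode(r) · R̂   (folding, EMD loss)
                               or SDF(flatten(V) ⊕ query)  (implicit, MSE)

A built-in packing simulator (six spatial rules — random, radial, surface,
planar 0°/45°/90° — inside deformed-ellipsoid nuclei) and a multi-piece
blob generator supply synthetic data, so the entire pipeline runs and is
tested without downloading any dataset. Benchmark metrics (reconstruction,
evolution energy, compactness via Levina–Bickel intrinsic dimension,
classification/regression heads, rotation-invariance error) and
latent-space analyses (PCA walks, archetypal analysis, nuclear-volume
bins, LDA axes, mAP with permutation q-values) complete the toolkit.
See `docs/methods.md` for the model and all numerical choices.

## Worked example

Recover the six packing rules without supervision:

```python
from morphocloud import benchmarks, metrics

result = benchmarks.rule_archetype_recovery(
    seed=1, n_shapes_per_rule=50, epochs=6
)
print("rules recovered:", result.n_rules_recovered, "/", result.n_rules)
print("archetype majorities:", result.majority_rules)
print("per-epoch EMD loss:", [round(x, 4) for x in result.training_log])
acc = metrics.classification_score(result.representations, result.labels)
print("rule classification accuracy: %.2f +/- %.2f" % acc)
```

Output from this exact call:

```
rules recovered: 6 / 6
archetype majorities: ['random', 'surface', 'radial', 'planar90', 'planar0', 'planar45']
per-epoch EMD loss: [0.0944, 0.0511, 0.0464, 0.0419, 0.0386, 0.0388]
rule classification accuracy: 0.84 +/- 0.03
```

It generates 300 packings (6 rules × 50 shared nuclei, 256 points each),
trains the rotation-invariant autoencoder (bottleneck 64, sphere-template
folding decoder, earth mover's distance loss) for six epochs, and fits six
archetypes to the invariant representations. Each archetype's top-weight
members have a distinct majority rule — the six generative rules are
rediscovered unsupervised — and a linear classifier reads the rule from
the representation with 84% cross-validated accuracy (chance is 17%).

The same components are available from the shell:

```bash
morphocloud simulate pack --n-shapes 254 --n-points 256 --seed 1 --out data/
morphocloud train --data data/manifest.csv --seed 1 --out model.zip
morphocloud embed --checkpoint model.zip --data data/manifest.csv --out emb.npz
morphocloud analyze archetypes --embeddings emb.npz --n-archetypes 6 --out arch.npz
```

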