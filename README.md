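# scatlas

Hierarchical cell-type annotation and downstream analysis machinery for
large single-cell / single-nucleus RNA-seq atlases of brain tissue — for
computational biologists assembling many public datasets into one
consistently labeled resource.

Atlas building runs into the same problems regardless of tissue: raw
count matrices arrive in inconsistent layouts with inconsistently curated
metadata; quality control must not discard cells that already carry
trusted published labels; cell types live in a hierarchy (broad classes,
then subtypes) that flat classifiers ignore; labels from several
independent annotation tools must be reconciled; rare populations (such
as neural progenitors in adult hippocampus) need marker-module evidence
rather than cluster labels; and differential expression across regions
must respect donor-level batch structure. `scatlas` implements each of
these steps as a small, seeded, testable module, plus a synthetic-atlas
generator that reproduces the statistical structure they assume.

## The models at the core

**Annotation.** A semi-supervised variational autoencoder over a panel of
marker-derived feature genes: an encoder maps log-normalized counts x̃ to
a Gaussian posterior q(z|x) over a 50-dimensional latent space, a decoder
returns per-gene proportions ρ(z) so counts are negative binomial with
mean l·ρ(z)_g (l the cell's library size) and per-gene inverse dispersion
θ_g, and a linear-softmax head on z predicts cell types. Training
maximizes the ELBO

    Σ_c [ Σ_g log NB(x_cg | l_c·ρ(z)_g, θ_g) − KL(q(z|x_c) ‖ N(0, I)) ]

unsupervised for 5 epochs, then fine-tunes with an added λ·cross-entropy
term (λ = 50) on labeled cells, early-stopping on validation accuracy
over a stratified 5:1 split. Two such models are stacked: one over broad
classes, then one per class over its subtypes. Implemented in pure NumPy
with hand-written gradients; bitwise reproducible given a seed.

**Consensus.** Per cell, the label called by the most annotation methods
wins only if it exceeds half the methods that voted; otherwise the cell
is `unannotated`.

**Module scoring.** The NPC gene-module score counts module genes
(TOP2A, HMGB2, PBK, UBE2C, RRM2, CDCA3, CCNA2, TPX) detected with ≥1
UMI; score ≥3 defines a putative NPC.

**Differential expression.** Counts are aggregated per sample
(pseudobulk) and modeled per gene as NB GLM with log link,
normalization-factor offset and covariates-then-group design
(`~donor_ID+group`, or `~donor_age+donor_sex+group` when donor is
confounded with the contrast); the group effect is tested by a
likelihood-ratio χ² test with Cox–Reid-estimated, shrunk dispersions and
BH correction.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from scatlas import (
    SynthConfig, simulate_atlas, apply_qc,
    train_hierarchy, predict_hierarchy, evaluate_confusion,
)
from scatlas.latent import LatentModelConfig

cfg = SynthConfig(seed=0)            # 10 classes x 3 subtypes, 3,000 genes
ds, truth = simulate_atlas(cfg)      # 6,000 cells
annot = train_hierarchy(ds, cfg.tree, LatentModelConfig(seed=0))

val = annot.level1_model.validation_indices    # held-out 1/6 of the labeled cells
pred = predict_hierarchy(annot, ds.subset_cells(val))
_, per_type, mean_acc = evaluate_confusion(truth.level1[val], pred["level1"])
acc2 = (pred["level2"].to_numpy() == truth.level2[val]).mean()
print(f"level-1: min per-type {per_type.min():.3f}, macro {mean_acc:.3f}")
print(f"level-2: overall {acc2:.3f}")
```

Output:

```
level-1: min per-type 0.970, macro 0.992
level-2: overall 0.992
```

Meaning: on held-out cells of the well-separated benchmark atlas, the
worst-recovered broad class is recalled at 97%, the macro average over
the 10 classes is 99.2%, and subtype labels are recovered at 99.2% —
comfortably above the 93% / 98% / 83% floors the package treats as its
accuracy contract for this benchmark.

The same pipeline is scriptable from a shell:

```bash
scatlas simulate --seed 0 --out sim/
scatlas qc --data sim/ --out qc/
scatlas train --data sim/ --tree tree.json --labels labels.tsv --out model/
scatlas annotate --data sim/ --model-dir model/ --out ann/
scatlas de --data cohort/ --group-field region --design auto --out de/
```

## Layout

- `src/scatlas/io.py` — data model, MTX triplet IO, metadata validation,
  age normalization, ortholog merging
- `src/scatlas/qc.py` — count/doublet/mito filters, simulated-doublet scorer
- `src/scatlas/features.py` — Wilcoxon markers, feature panels, HVGs
- `src/scatlas/latent.py` — the NB-VAE classifier and logistic label transfer
- `src/scatlas/hierarchy.py` — two-level annotator, consensus vote, confusion
- `src/scatlas/scoring.py` — gene-module scores, silhouette evaluation
- `src/scatlas/pseudobulk.py` — pseudobulk NB-GLM LRT differential expression
- `src/scatlas/synth.py` — seeded synthetic atlas and DE cohort generators
- `src/scatlas/cli.py` — `scatlas` command-line entry points
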