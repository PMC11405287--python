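"""Seeded synthetic-atlas generator.

Emulates the statistical structure the rest of the toolkit assumes:
hierarchically organized cell types with disjoint marker-gene blocks,
negative-binomial counts with log-normal library sizes and per-sample
batch factors, doublets formed by summing random cell pairs, mitochondrial
genes with controlled per-cell fractions, an optional rare proliferative
population co-expressing a marker module, and two-group cohorts with known
per-gene effects for differential-expression benchmarking.

Counts for a cell of type t in sample s are drawn

    x_cg ~ NB(mean = l_c * p_{g,t} * b_{g,s}, dispersion)

where p_{.,t} is a proportion vector in which the markers of t's class and
of t itself are elevated ``marker_fold_change``-fold, l_c is a log-normal
library size and b a log-normal gene-by-sample batch factor. Because every
type elevates the same number of genes, the in-type/out-of-type mean ratio
of a marker equals the fold change exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import MISSING, METADATA_FIELDS, AnnotatedDataset, CountMatrix, LabelTree

DEFAULT_NPC_MODULE = (
    "TOP2A", "HMGB2", "PBK", "UBE2C", "RRM2", "CDCA3", "CCNA2", "TPX",
)


def default_tree(n_classes: int = 10, n_subtypes: int = 3) -> LabelTree:
    """Balanced label hierarchy C01..Cxx each with subtypes C..S1..."""
    return LabelTree(
        {
            f"C{i + 1:02d}": [f"C{i + 1:02d}S{j + 1}" for j in range(n_subtypes)]
            for i in range(n_classes)
        }
    )


@dataclass
class SynthConfig:
    """Parameters of the synthetic atlas.

    Defaults are the toolkit's standard benchmark atlas: 10 classes × 3
    subtypes, 3,000 genes, 20 markers per class and per subtype elevated
    8-fold, 200 cells per subtype spread over 6 samples.
    """

    tree: LabelTree = field(default_factory=default_tree)
    n_cells_per_subtype: int = 200
    n_genes: int = 3000
    markers_per_type: int = 20
    marker_fold_change: float = 8.0
    baseline_mean_counts: float = 2000.0  # mean library size
    library_sigma: float = 0.25  # log-normal sd of library sizes
    nb_dispersion: float = 0.3
    n_samples: int = 6
    batch_effect_sd: float = 0.1
    doublet_rate: float = 0.0
    mito_gene_count: int = 0
    mito_fraction_range: tuple[float, float] = (0.01, 0.05)
    npc_module_genes: tuple[str, ...] = ()
    npc_population: str | None = None  # subtype name that expresses the module
    npc_fold_change: float = 20.0
    publish_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.doublet_rate <= 1):
            raise ValueError("doublet_rate must lie in [0, 1]")
        if self.marker_fold_change <= 0:
            raise ValueError("marker_fold_change must be positive")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        n_types = len(self.tree.class_names) + sum(
            len(s) for s in self.tree.classes.values()
        )
        need = n_types * self.markers_per_type + len(self.npc_module_genes)
        if need > self.n_genes:
            raise ValueError(
                f"{self.n_genes} genes cannot host {need} marker genes"
            )


@dataclass
class GroundTruth:
    """Everything needed to evaluate module outputs without re-deriving
    hidden state."""

    level1: np.ndarray
    level2: np.ndarray
    is_doublet: np.ndarray
    sample: np.ndarray
    class_markers: dict[str, list[str]]
    subtype_markers: dict[str, list[str]]
    mito_genes: list[str]
    mito_fraction: np.ndarray
    npc_module_genes: list[str]
    library_size: np.ndarray


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson draw with Var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_atlas(cfg: SynthConfig) -> tuple[AnnotatedDataset, GroundTruth]:
    """Draw one synthetic atlas; bitwise reproducible for a given seed."""
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree
    classes = tree.class_names
    subtypes = [(c, s) for c in classes for s in tree.subtypes(c)]

    n_mito = cfg.mito_gene_count
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes - n_mito - len(cfg.npc_module_genes))]
    gene_ids += list(cfg.npc_module_genes)
    mito_genes = [f"MT-{i + 1}" for i in range(n_mito)]
    gene_ids += mito_genes
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_genes = len(gene_ids)
    non_mito = np.arange(n_genes - n_mito)
    npc_idx = np.arange(
        len(non_mito) - len(cfg.npc_module_genes), len(non_mito)
    )

    # disjoint marker blocks: first the class blocks, then the subtype blocks
    class_markers: dict[str, list[str]] = {}
    subtype_markers: dict[str, list[str]] = {}
    cursor = 0
    for c in classes:
        class_markers[c] = list(gene_ids[cursor : cursor + cfg.markers_per_type])
        cursor += cfg.markers_per_type
    for _, s in subtypes:
        subtype_markers[s] = list(gene_ids[cursor : cursor + cfg.markers_per_type])
        cursor += cfg.markers_per_type

    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # per-sample batch factors on non-mito genes
    batch = np.exp(
        rng.normal(0.0, cfg.batch_effect_sd, size=(cfg.n_samples, len(non_mito)))
    )

    blocks: list[sp.csr_matrix] = []
    lvl1: list[str] = []
    lvl2: list[str] = []
    samples: list[int] = []
    libs: list[np.ndarray] = []
    fracs: list[np.ndarray] = []

    for c, s in subtypes:
        n = cfg.n_cells_per_subtype
        rel = np.ones(len(non_mito))
        rel[[gene_pos[g] for g in class_markers[c]]] *= cfg.marker_fold_change
        rel[[gene_pos[g] for g in subtype_markers[s]]] *= cfg.marker_fold_change
        if cfg.npc_population == s and len(npc_idx):
            rel[npc_idx] *= cfg.npc_fold_change
        p = rel / rel.sum()

        lib = cfg.baseline_mean_counts * np.exp(
            rng.normal(0.0, cfg.library_sigma, size=n)
        )
        samp = rng.integers(0, cfg.n_samples, size=n)
        if n_mito:
            f = rng.uniform(*cfg.mito_fraction_range, size=n)
        else:
            f = np.zeros(n)

        mean = (lib * (1.0 - f))[:, None] * p[None, :] * batch[samp]
        counts = _nb_sample(rng, mean, cfg.nb_dispersion)
        if n_mito:
            mito_mean = (lib * f)[:, None] * np.full(n_mito, 1.0 / n_mito)[None, :]
            mito_counts = _nb_sample(rng, mito_mean, cfg.nb_dispersion)
            counts = np.hstack([counts, mito_counts])
        blocks.append(sp.csr_matrix(counts))
        lvl1 += [c] * n
        lvl2 += [s] * n
        samples.append(samp)
        libs.append(lib)
        fracs.append(f)

    counts = sp.vstack(blocks, format="csr")
    level1 = np.asarray(lvl1, dtype=object)
    level2 = np.asarray(lvl2, dtype=object)
    sample = np.concatenate(samples)
    lib = np.concatenate(libs)
    frac = np.concatenate(fracs)
    n_singlets = counts.shape[0]

    # doublets: sums of two distinct random singlets
    n_doublets = int(round(cfg.doublet_rate * n_singlets))
    if n_doublets:
        i = rng.integers(0, n_singlets, size=n_doublets)
        j = rng.integers(0, n_singlets, size=n_doublets)
        j = np.where(j == i, (j + 1) % n_singlets, j)
        dbl = sp.csr_matrix(counts[i].toarray() + counts[j].toarray())
        counts = sp.vstack([counts, dbl], format="csr")
        level1 = np.concatenate([level1, np.full(n_doublets, "doublet", object)])
        level2 = np.concatenate([level2, np.full(n_doublets, "doublet", object)])
        sample = np.concatenate([sample, sample[i]])
        lib = np.concatenate([lib, lib[i] + lib[j]])
        frac = np.concatenate([frac, (frac[i] + frac[j]) / 2])

    n_cells = counts.shape[0]
    is_doublet = np.zeros(n_cells, dtype=bool)
    is_doublet[n_singlets:] = True

    cell_ids = np.asarray([f"cell{i + 1:06d}" for i in range(n_cells)], dtype=object)
    md = pd.DataFrame({f: [MISSING] * n_cells for f in METADATA_FIELDS})
    md["cell_ID"] = cell_ids.astype(str)
    md["sample_ID"] = [f"S{k + 1:02d}" for k in sample]
    md["donor_ID"] = [f"D{k + 1:02d}" for k in sample]
    md["donor_sex"] = ["female" if k % 2 else "male" for k in sample]
    md["donor_age"] = [str(30 + 3 * k) for k in sample]
    md["region"] = "hippocampus"
    md["if_patient"] = "healthy"
    md["seq_method"] = "10x"
    if cfg.publish_labels:
        md["original_name"] = level1.astype(str)
        md["original_name2"] = level2.astype(str)

    ds = AnnotatedDataset(
        CountMatrix(counts, cell_ids, gene_ids),
        md,
        level1=level1.copy(),
        level2=level2.copy(),
    )
    truth = GroundTruth(
        level1=level1,
        level2=level2,
        is_doublet=is_doublet,
        sample=md["sample_ID"].to_numpy(object),
        class_markers=class_markers,
        subtype_markers=subtype_markers,
        mito_genes=mito_genes,
        mito_fraction=frac,
        npc_module_genes=list(cfg.npc_module_genes),
        library_size=lib,
    )
    return ds, truth


@dataclass
class DECohortConfig:
    """Two-group cohort with known per-gene effects for DE benchmarking."""

    n_genes: int = 500
    n_samples_per_group: int = 10
    n_cells_per_sample: int = 50
    baseline_mean_counts: float = 2000.0
    nb_dispersion: float = 0.1
    effect_genes: tuple[str, ...] = ()
    effect_log2fc: float = 0.0
    donors_confounded: bool = True  # each donor contributes to one group only
    seed: int = 0


def simulate_de_cohort(cfg: DECohortConfig) -> tuple[AnnotatedDataset, dict]:
    """Simulate a two-group cohort of single cells ready for pseudobulking.

    Group "g2" multiplies ``effect_genes`` by 2**effect_log2fc. When
    ``donors_confounded`` each donor belongs to exactly one group (the
    layout that forces demographic covariates in the design); otherwise
    every donor contributes one sample to each group.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = np.asarray([f"G{i + 1:05d}" for i in range(cfg.n_genes)], dtype=object)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    effect_idx = np.asarray([gene_pos[g] for g in cfg.effect_genes], dtype=int)

    base_rel = rng.lognormal(0.0, 0.5, size=cfg.n_genes)
    n_samples = 2 * cfg.n_samples_per_group

    blocks, sample_ids, donor_ids, groups, sexes, ages = [], [], [], [], [], []
    for s in range(n_samples):
        grp = "g1" if s < cfg.n_samples_per_group else "g2"
        if cfg.donors_confounded:
            donor = f"D{s + 1:02d}"
        else:
            donor = f"D{(s % cfg.n_samples_per_group) + 1:02d}"
        rel = base_rel.copy()
        if grp == "g2" and len(effect_idx):
            rel[effect_idx] *= 2.0 ** cfg.effect_log2fc
        p = rel / rel.sum()
        lib = cfg.baseline_mean_counts * np.exp(
            rng.normal(0.0, 0.2, size=cfg.n_cells_per_sample)
        )
        mean = lib[:, None] * p[None, :]
        counts = _nb_sample(rng, mean, cfg.nb_dispersion)
        blocks.append(sp.csr_matrix(counts))
        sample_ids += [f"S{s + 1:02d}"] * cfg.n_cells_per_sample
        donor_ids += [donor] * cfg.n_cells_per_sample
        groups += [grp] * cfg.n_cells_per_sample
        sexes += ["female" if s % 2 else "male"] * cfg.n_cells_per_sample
        ages += [str(int(rng.integers(25, 80)))] * cfg.n_cells_per_sample

    counts = sp.vstack(blocks, format="csr")
    n_cells = counts.shape[0]
    cell_ids = np.asarray([f"cell{i + 1:06d}" for i in range(n_cells)], dtype=object)
    md = pd.DataFrame({f: [MISSING] * n_cells for f in METADATA_FIELDS})
    md["cell_ID"] = cell_ids.astype(str)
    md["sample_ID"] = sample_ids
    md["donor_ID"] = donor_ids
    md["donor_sex"] = sexes
    md["donor_age"] = ages
    md["group"] = groups
    ds = AnnotatedDataset(CountMatrix(counts, cell_ids, gene_ids), md)
    truth = {
        "effect_genes": list(cfg.effect_genes),
        "effect_log2fc": cfg.effect_log2fc,
        "group_of_sample": {
            f"S{s + 1:02d}": ("g1" if s < cfg.n_samples_per_group else "g2")
            for s in range(n_samples)
        },
    }
    return ds, truth
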