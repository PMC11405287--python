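"""Gene-module scoring for putative proliferative progenitors, and
silhouette-based evaluation of covariate mixing in a latent embedding.

The NPC gene-module score of a cell is the number of module marker genes
detected with at least one UMI; cells with a score of at least 3 (default)
are called putative NPCs. The default module is the conserved cross-species
NPC marker set TOP2A, HMGB2, PBK, UBE2C, RRM2, CDCA3, CCNA2 and TPX; the
last entry is kept verbatim as published, with an optional alias mapping
TPX to TPX2 for panels that use the systematic symbol.

The silhouette evaluation asks, within each cell type, how separable a
nuisance covariate (sequencing method, sex, donor status...) is in the
embedding: coefficients near 0 mean the covariate is well mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import AnnotatedDataset

logger = logging.getLogger(__name__)

DEFAULT_NPC_GENES = (
    "TOP2A", "HMGB2", "PBK", "UBE2C", "RRM2", "CDCA3", "CCNA2", "TPX",
)
NPC_SCORE_THRESHOLD = 3


@dataclass(frozen=True)
class GeneModule:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene module must be nonempty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene module contains duplicates")

    def with_alias(self, alias: dict[str, str]) -> "GeneModule":
        return GeneModule(self.name, tuple(alias.get(g, g) for g in self.genes))


def default_npc_module(tpx_alias: bool = False) -> GeneModule:
    """The conserved NPC marker module; ``tpx_alias=True`` maps TPX→TPX2."""
    mod = GeneModule("NPC", DEFAULT_NPC_GENES)
    return mod.with_alias({"TPX": "TPX2"}) if tpx_alias else mod


@dataclass
class ModuleScoreResult:
    scores: np.ndarray  # integer per-cell score in [0, module size]
    putative: np.ndarray  # boolean flags, score >= threshold
    threshold: int


def npc_module_score(ds: AnnotatedDataset, module: GeneModule) -> np.ndarray:
    """Number of module genes detected (count >= 1) per cell."""
    pos = {g: i for i, g in enumerate(ds.gene_ids)}
    idx = [pos[g] for g in module.genes if g in pos]
    absent = len(module.genes) - len(idx)
    if absent:
        logger.warning(
            "%d of %d module genes absent from the matrix; they score 0",
            absent, len(module.genes),
        )
    if not idx:
        return np.zeros(ds.n_cells, dtype=int)
    detected = ds.counts[:, idx] > 0
    return np.asarray(detected.sum(axis=1)).ravel().astype(int)


def classify_putative_npc(
    scores: np.ndarray, threshold: int = NPC_SCORE_THRESHOLD
) -> np.ndarray:
    """Putative-NPC flag: module score >= threshold."""
    return np.asarray(scores, dtype=int) >= threshold


def score_npc(
    ds: AnnotatedDataset,
    module: GeneModule | None = None,
    threshold: int = NPC_SCORE_THRESHOLD,
) -> ModuleScoreResult:
    module = module or default_npc_module()
    scores = npc_module_score(ds, module)
    return ModuleScoreResult(scores, classify_putative_npc(scores, threshold), threshold)


def module_fraction_by_type(
    ds: AnnotatedDataset, labels, module: GeneModule
) -> pd.DataFrame:
    """Fraction of cells of each type expressing each module gene
    (count >= 1); types × genes, values in [0, 1]."""
    labels = np.asarray(labels).astype(str)
    if len(labels) != ds.n_cells:
        raise ValueError("labels not aligned to cells")
    pos = {g: i for i, g in enumerate(ds.gene_ids)}
    types = sorted(set(labels))
    out = pd.DataFrame(0.0, index=types, columns=list(module.genes))
    for t in types:
        mask = labels == t
        if not mask.any():
            raise ValueError(f"empty type {t!r}")
        sub = ds.counts[np.flatnonzero(mask)]
        for g in module.genes:
            if g in pos:
                out.loc[t, g] = float((sub[:, pos[g]] > 0).mean())
    return out


def score_distribution(
    scores: np.ndarray, reference_subset: np.ndarray | None = None,
    threshold: int = NPC_SCORE_THRESHOLD,
) -> pd.Series:
    """Relative percentage of cells at each score value.

    Percentages are taken relative to ``reference_subset`` (a boolean mask;
    default: the putative cells, score >= threshold), so with the default
    denominator the percentages over scores >= threshold sum to 100.
    """
    scores = np.asarray(scores, dtype=int)
    if reference_subset is None:
        reference_subset = scores >= threshold
    denom = int(np.asarray(reference_subset, dtype=bool).sum())
    if denom == 0:
        raise ValueError("reference subset is empty")
    values, counts = np.unique(scores, return_counts=True)
    return pd.Series(100.0 * counts / denom, index=values, name="percent")


def silhouette_covariate(
    latent: np.ndarray, cell_type_labels, covariate_labels
) -> pd.Series:
    """Per-cell-type mean silhouette coefficient of a covariate grouping.

    Within each cell type: for each cell, a is its mean Euclidean distance
    to other cells of its covariate group (excluding itself) and b the
    smallest mean distance to any other group; the coefficient is
    (b − a)/max(a, b). Cells in singleton groups get coefficient 0. A type
    with a single covariate group has no defined score and is reported as
    NaN.
    """
    latent = np.asarray(latent, dtype=float)
    types = np.asarray(cell_type_labels).astype(str)
    cov = np.asarray(covariate_labels).astype(str)
    if not (len(types) == len(cov) == latent.shape[0]):
        raise ValueError("labels not aligned to embedding rows")

    result = {}
    for t in sorted(set(types)):
        mask = types == t
        x = latent[mask]
        groups = cov[mask]
        uniq = sorted(set(groups))
        if len(uniq) < 2:
            result[t] = np.nan
            continue
        dist = cdist(x, x)
        coeffs = np.zeros(len(x))
        for i in range(len(x)):
            own = groups == groups[i]
            n_own = own.sum()
            if n_own < 2:
                coeffs[i] = 0.0  # singleton group convention
                continue
            a = dist[i, own].sum() / (n_own - 1)  # exclude self (distance 0)
            b = min(
                dist[i, groups == g].mean() for g in uniq if g != groups[i]
            )
            denom = max(a, b)
            coeffs[i] = 0.0 if denom == 0 else (b - a) / denom
        result[t] = float(coeffs.mean())
    return pd.Series(result, name="silhouette")
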