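"""Per-cell quality control.

Filter rules: unlabeled cells must have at least 200 total counts, a
doublet score of at most 0.3 and a mitochondrial fraction of at most 10%;
cells that already carry a published cell-type label are retained without
filtering — unless that label is "doublet", in which case they are removed.
All threshold comparisons are strict on the removal side ("fewer than 200",
">0.3", "greater than 10%"), so a cell sitting exactly on a threshold is
retained.

The doublet scorer simulates synthetic doublets by summing the raw counts
of random cell pairs, embeds observed and simulated cells jointly by PCA of
log-normalized expression, and scores each observed cell by the
ratio-corrected fraction of simulated doublets among its k nearest
neighbours — the standard simulated-doublet kNN construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import AnnotatedDataset, MISSING

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_counts: int = 200
    max_doublet_score: float = 0.3
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_counts < 0:
            raise ValueError("min_counts must be nonnegative")
        for name in ("max_doublet_score", "max_mito_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-criterion pass/fail flags and removal counts.

    ``removed + retained + skipped == n_cells`` always holds; skipped cells
    are those exempted by a published label.
    """

    flags: pd.DataFrame  # columns: pass_counts, pass_doublet, pass_mito, skipped, retained
    n_cells: int
    removed_low_counts: int
    removed_doublet_score: int
    removed_mito: int
    removed_published_doublet: int
    n_skipped: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return self.n_cells - self.n_retained

    @property
    def n_retained_unlabeled(self) -> int:
        """Retained cells that actually went through the filters."""
        return self.n_retained - self.n_skipped

    def to_json_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "n_skipped_published": self.n_skipped,
            "removed_low_counts": self.removed_low_counts,
            "removed_doublet_score": self.removed_doublet_score,
            "removed_mito": self.removed_mito,
            "removed_published_doublet": self.removed_published_doublet,
        }


def default_mito_predicate(gene_id: str) -> bool:
    return str(gene_id).upper().startswith("MT-")


def mito_fraction(
    ds: AnnotatedDataset,
    mito_gene_predicate: Callable[[str], bool] = default_mito_predicate,
) -> np.ndarray:
    """Fraction of each cell's counts coming from mitochondrial genes.

    Cells with zero total counts get fraction 0 (they fail the count filter
    anyway); a warning is logged for them.
    """
    mito_mask = np.fromiter(
        (bool(mito_gene_predicate(g)) for g in ds.gene_ids),
        dtype=bool,
        count=ds.n_genes,
    )
    total = np.asarray(ds.counts.sum(axis=1)).ravel().astype(float)
    mito = np.asarray(ds.counts[:, mito_mask].sum(axis=1)).ravel().astype(float)
    zero = total == 0
    if zero.any():
        logger.warning("%d cells have zero total counts", int(zero.sum()))
    frac = np.zeros(ds.n_cells)
    np.divide(mito, total, out=frac, where=~zero)
    return frac


def _lognorm(counts: sp.spmatrix, target_sum: float = 1e4) -> np.ndarray:
    total = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    total[total == 0] = 1.0
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, float)
    return np.log1p(dense * (target_sum / total)[:, None])


def doublet_score(
    ds: AnnotatedDataset,
    n_sim: int | None = None,
    n_pcs: int = 30,
    k: int | None = None,
    seed: int = 0,
    return_simulated: bool = False,
):
    """Simulated-doublet kNN score per observed cell, in [0, 1].

    ``n_sim`` defaults to the number of cells; ``k`` defaults to
    round(0.5 * sqrt(n_obs + n_sim)). The raw kNN fraction f of simulated
    neighbours is corrected for the simulation ratio r = n_sim/n_cells via
    f / (f + r*(1-f)), so the score estimates the doublet posterior at the
    nominal doublet prior. With ``return_simulated`` the scores of the
    simulated doublets themselves are returned as a second array.
    """
    n = ds.n_cells
    if n_sim is None:
        n_sim = n
    rng = np.random.default_rng(seed)
    if n_sim == 0:
        out = np.zeros(n)
        return (out, np.zeros(0)) if return_simulated else out

    i = rng.integers(0, n, size=n_sim)
    j = rng.integers(0, n, size=n_sim)
    j = np.where(j == i, (j + 1) % n, j)
    counts = ds.counts
    sim = counts[i].toarray() + counts[j].toarray()
    joint = sp.vstack([counts, sp.csr_matrix(sim)], format="csr")

    if k is None:
        k = max(1, int(round(0.5 * np.sqrt(joint.shape[0]))))
    if joint.shape[0] < 2 * k:
        raise ValueError(f"need at least {2 * k} cells for k={k} neighbours")

    x = _lognorm(joint)
    x -= x.mean(axis=0)
    n_comp = min(n_pcs, x.shape[1], joint.shape[0] - 1)
    z = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed).fit_transform(x)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    _, idx = nn.kneighbors(z)
    idx = idx[:, 1:]  # drop self
    f = (idx >= n).mean(axis=1)
    r = n_sim / n
    score = f / (f + r * (1.0 - f))
    if return_simulated:
        return score[:n], score[n:]
    return score[:n]


def apply_qc(
    ds: AnnotatedDataset,
    th: QCThresholds | None = None,
    published_label_field: str = "original_name",
    compute_doublets: bool = True,
    doublet_seed: int = 0,
) -> tuple[AnnotatedDataset, QCReport]:
    """Apply the atlas QC rules and return the filtered dataset + report.

    Cells whose ``published_label_field`` holds a label other than "N/A"
    skip filtering entirely ("doublet" labels are removed instead).
    Unlabeled cells pass iff total counts >= min_counts, doublet score <=
    max_doublet_score and mito fraction <= max_mito_fraction.
    """
    th = th or QCThresholds()
    n = ds.n_cells

    published = np.full(n, MISSING, dtype=object)
    if published_label_field in ds.metadata.columns:
        published = ds.metadata[published_label_field].astype(str).to_numpy(object)
    has_label = published != MISSING
    is_pub_doublet = has_label & (
        np.char.lower(published.astype(str)) == "doublet"
    )
    skipped = has_label & ~is_pub_doublet

    total = np.asarray(ds.counts.sum(axis=1)).ravel()
    scores = ds.doublet_score
    if scores is None:
        if compute_doublets:
            scores = doublet_score(ds, seed=doublet_seed)
        else:
            raise ValueError(
                "doublet scores absent and scorer disabled; provide "
                "ds.doublet_score or enable compute_doublets"
            )
    scores = np.asarray(scores, dtype=float)
    mito = mito_fraction(ds)

    pass_counts = total >= th.min_counts
    pass_doublet = scores <= th.max_doublet_score
    pass_mito = mito <= th.max_mito_fraction

    retained = skipped | (~is_pub_doublet & pass_counts & pass_doublet & pass_mito)

    unlabeled = ~has_label
    flags = pd.DataFrame(
        {
            "cell_ID": ds.cell_ids.astype(str),
            "total_counts": total,
            "doublet_score": scores,
            "mito_fraction": mito,
            "pass_counts": pass_counts,
            "pass_doublet": pass_doublet,
            "pass_mito": pass_mito,
            "skipped": skipped,
            "retained": retained,
        }
    )
    report = QCReport(
        flags=flags,
        n_cells=n,
        removed_low_counts=int((unlabeled & ~pass_counts).sum()),
        removed_doublet_score=int((unlabeled & ~pass_doublet).sum()),
        removed_mito=int((unlabeled & ~pass_mito).sum()),
        removed_published_doublet=int(is_pub_doublet.sum()),
        n_skipped=int(skipped.sum()),
        n_retained=int(retained.sum()),
    )
    out = ds.subset_cells(retained)
    if out.doublet_score is None:
        out.doublet_score = scores[retained]
    return out, report
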