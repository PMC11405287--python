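"""Marker statistics and feature-panel construction.

Markers are ranked per group by a one-vs-rest two-sided Wilcoxon rank-sum
test on log1p library-normalized expression (per-cell scaling to 10,000
counts), with Benjamini–Hochberg adjustment within each group. Feature
panels take the top ``n_per_type`` genes of every group under the fully
deterministic key (q ascending, |log2FC| descending, gene ID ascending)
and union them; a reference panel built this way is what the hierarchical
annotator trains on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import AnnotatedDataset

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9
NORM_TARGET = 1e4


@dataclass
class FeaturePanel:
    """Ordered, de-duplicated gene list with per-gene provenance."""

    genes: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.genes) + "\n")

    @classmethod
    def load(cls, path) -> "FeaturePanel":
        with open(path) as fh:
            genes = [line.strip() for line in fh if line.strip()]
        return cls(genes)


def normalized_expression(ds: AnnotatedDataset, log: bool = True) -> np.ndarray:
    """Per-cell scaling to NORM_TARGET counts, optionally log1p."""
    total = np.asarray(ds.counts.sum(axis=1)).ravel().astype(float)
    total[total == 0] = 1.0
    x = ds.counts.toarray() * (NORM_TARGET / total)[:, None]
    return np.log1p(x) if log else x


def rank_markers_wilcoxon(ds: AnnotatedDataset, group_field) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table.

    ``group_field`` may be a metadata column name or a per-cell label array.
    Returns one row per (group, gene) with columns group, gene, log2FC,
    p_value, q_value, frac_in, frac_out. log2FC is computed on normalized
    (non-log) expression means with a small epsilon, q by BH within group.
    """
    if isinstance(group_field, str):
        labels = ds.metadata[group_field].to_numpy(object)
    else:
        labels = np.asarray(group_field, dtype=object)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")

    norm = normalized_expression(ds, log=False)
    logx = np.log1p(norm)
    detected = ds.counts.toarray() > 0

    rows = []
    for g in groups:
        mask = labels == g
        x_in, x_out = logx[mask], logx[~mask]
        res = mannwhitneyu(
            x_in, x_out, alternative="two-sided", method="auto", axis=0
        )
        p = np.atleast_1d(res.pvalue)
        mean_in = norm[mask].mean(axis=0)
        mean_out = norm[~mask].mean(axis=0)
        lfc = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))
        q = multipletests(p, method="fdr_bh")[1]
        rows.append(
            pd.DataFrame(
                {
                    "group": g,
                    "gene": ds.gene_ids,
                    "log2FC": lfc,
                    "p_value": p,
                    "q_value": q,
                    "frac_in": detected[mask].mean(axis=0),
                    "frac_out": detected[~mask].mean(axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def select_feature_genes(mt: pd.DataFrame, n_per_type: int = 200) -> FeaturePanel:
    """Union of each group's top ``n_per_type`` marker genes.

    Ranking key within a group: q ascending, then |log2FC| descending, then
    gene ID ascending. Groups with fewer than ``n_per_type`` genes
    contribute all of theirs (with a logged warning). Order of the panel
    follows first occurrence over groups in sorted group order.
    """
    if mt.empty:
        raise ValueError("marker table is empty")
    genes: list[str] = []
    seen: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for g, sub in mt.groupby("group", sort=True):
        sub = sub.assign(_abslfc=sub["log2FC"].abs())
        sub = sub.sort_values(
            ["q_value", "_abslfc", "gene"], ascending=[True, False, True],
            kind="mergesort",
        )
        if len(sub) < n_per_type:
            logger.warning(
                "group %r has only %d genes (< %d requested)", g, len(sub), n_per_type
            )
        top = sub["gene"].head(n_per_type).tolist()
        for gene in top:
            provenance.setdefault(gene, []).append(str(g))
            if gene not in seen:
                seen.add(gene)
                genes.append(gene)
    return FeaturePanel(genes, provenance)


def select_hvg(ds: AnnotatedDataset, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes by binned normalized dispersion.

    Dispersion = var/mean of log1p-normalized expression, z-scored within
    20 equal-frequency mean bins; ties broken by gene ID so the selection
    is deterministic and invariant to cell order.
    """
    if n > ds.n_genes:
        raise ValueError(f"requested {n} HVGs from {ds.n_genes} genes")
    x = np.sort(normalized_expression(ds, log=True), axis=0)
    # summing in sorted order makes the moments (and hence the selection)
    # bitwise invariant to cell order
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)

    df = pd.DataFrame({"gene": ds.gene_ids.astype(str), "mean": mean, "disp": disp})
    try:
        df["bin"] = pd.qcut(df["mean"], q=n_bins, duplicates="drop", labels=False)
    except ValueError:
        df["bin"] = 0
    df["bin"] = df["bin"].fillna(0)

    def zscore(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return s * 0.0
        return (s - s.mean()) / sd

    df["norm_disp"] = df.groupby("bin")["disp"].transform(zscore)
    df = df.sort_values(["norm_disp", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].head(n).tolist()
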