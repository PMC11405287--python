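"""Pseudobulk aggregation and negative-binomial GLM differential expression.

Single-cell counts are summed within each sample ("pseudobulk"), turning
the per-cell dropout-ridden matrix into a small sample-level count matrix
on which classic count GLMs are valid. Each gene is then modeled as

    y_sg ~ NB(mu_sg, alpha_g),   log mu_sg = x_s' beta_g + log N_s

with N_s the sample library size as offset, and the group effect tested by
a likelihood-ratio test of the full design against the design without the
group term. Covariates follow the atlas convention: donor identity absorbs
batch effects (~donor_ID + group) unless donors are confounded (collinear)
with the biological grouping, in which case donor age and sex stand in
(~donor_age + donor_sex + group); "auto" mode detects the confounding.

Per-gene dispersions alpha_g are maximum Cox–Reid adjusted-profile-
likelihood estimates, shrunk toward the common all-gene dispersion by a
fixed 0.25/0.75 weighted average — a deliberately simple stand-in for full
empirical-Bayes dispersion moderation. GLMs are fit by iteratively
reweighted least squares (relative tolerance 1e-8, at most 100 iterations);
genes that fail to converge are flagged, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import AnnotatedDataset

logger = logging.getLogger(__name__)

_SAMPLE_COVARIATES = ("donor_ID", "donor_age", "donor_sex")
_ALPHA_MIN, _ALPHA_MAX = 1e-8, 10.0


@dataclass
class PseudobulkMatrix:
    counts: np.ndarray  # samples × genes, integer
    sample_ids: list[str]
    gene_ids: np.ndarray
    covariates: pd.DataFrame  # indexed like sample_ids; includes group, n_cells

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1).astype(float)

    def size_factors(self, method: str = "median_ratio") -> np.ndarray:
        """Per-sample normalization factors for the GLM offset.

        "median_ratio" is the median-of-ratios estimator computed on genes
        with a positive geometric mean — robust to composition shifts when
        a minority of genes change; "library" is the plain library size.
        Falls back to library sizes when fewer than 10 genes are usable.
        """
        lib = self.library_sizes
        if method == "library":
            return lib
        if method != "median_ratio":
            raise ValueError(f"unknown normalization {method!r}")
        with np.errstate(divide="ignore"):
            logc = np.log(self.counts.astype(float))
        finite = np.isfinite(logc).all(axis=0)
        if finite.sum() < 10:
            logger.warning("too few all-positive genes; using library sizes")
            return lib
        ref = logc[:, finite].mean(axis=0)  # log geometric mean per gene
        sf = np.exp(np.median(logc[:, finite] - ref[None, :], axis=1))
        # scale so factors average to the mean library size (units of counts)
        return sf * lib.mean() / sf.mean()


def aggregate_pseudobulk(
    ds: AnnotatedDataset,
    sample_field: str = "sample_ID",
    group_field: str = "group",
    population_filter: np.ndarray | None = None,
    min_cells: int = 10,
) -> PseudobulkMatrix:
    """Sum raw counts per sample over the selected cell population.

    Samples contributing fewer than ``min_cells`` cells are dropped with a
    warning. Sample-level covariates (donor_ID, donor_age, donor_sex and
    the group) are carried over from the cell metadata and must be constant
    within each sample.
    """
    md = ds.metadata
    for f in (sample_field, group_field):
        if f not in md.columns:
            raise ValueError(f"metadata lacks field {f!r}")
    if population_filter is None:
        keep = np.ones(ds.n_cells, dtype=bool)
    else:
        keep = np.asarray(population_filter, dtype=bool)
    samples = md[sample_field].astype(str).to_numpy()

    rows, ids, covs = [], [], []
    for s in sorted(set(samples[keep])):
        mask = keep & (samples == s)
        n = int(mask.sum())
        if n < min_cells:
            logger.warning("sample %r dropped: %d < %d cells", s, n, min_cells)
            continue
        sub = md.loc[mask]
        cov = {"n_cells": n}
        for f in _SAMPLE_COVARIATES + (group_field,):
            if f not in md.columns:
                continue
            vals = sub[f].astype(str).unique()
            if len(vals) > 1:
                raise ValueError(
                    f"covariate {f!r} varies within sample {s!r}: {sorted(vals)}"
                )
            cov[f] = vals[0]
        rows.append(np.asarray(ds.counts[np.flatnonzero(mask)].sum(axis=0)).ravel())
        ids.append(s)
        covs.append(cov)
    if not rows:
        raise ValueError("no samples survive the min_cells filter")
    covariates = pd.DataFrame(covs, index=ids)
    covariates = covariates.rename(columns={group_field: "group"})
    return PseudobulkMatrix(
        np.vstack(rows).astype(np.int64), ids, ds.gene_ids.copy(), covariates
    )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class DEDesign:
    X_full: np.ndarray
    X_reduced: np.ndarray
    full_terms: list[str]
    reduced_terms: list[str]
    colnames_full: list[str]
    group_col: int  # index of the tested group coefficient in X_full
    df: int
    confounded: bool


def _dummies(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(values.astype(str).unique())
    cols = []
    names = []
    for lev in levels[1:]:  # drop first level as reference
        cols.append((values.astype(str) == lev).to_numpy(float))
        names.append(f"{prefix}[{lev}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(values), 0)), names


def build_design(pb: PseudobulkMatrix, mode: str = "auto") -> DEDesign:
    """Construct full/reduced model matrices with the group term last.

    mode "donor_covariate" gives ~donor_ID + group, "demographic_covariate"
    gives ~donor_age + donor_sex + group, and "auto" detects whether donor
    is confounded with group (every donor in a single group level) and
    picks accordingly.
    """
    cov = pb.covariates
    groups = cov["group"].astype(str)
    if groups.nunique() < 2:
        raise ValueError("group must have at least two levels")

    donor_group = cov.groupby("donor_ID")["group"].nunique()
    confounded = bool((donor_group == 1).all())
    if mode == "auto":
        mode = "demographic_covariate" if confounded else "donor_covariate"
    if mode not in ("donor_covariate", "demographic_covariate"):
        raise ValueError(f"unknown design mode {mode!r}")

    intercept = np.ones((pb.n_samples, 1))
    if mode == "donor_covariate":
        Xc, names_c = _dummies(cov["donor_ID"], "donor_ID")
        terms = ["donor_ID", "group"]
    else:
        age = pd.to_numeric(cov["donor_age"], errors="coerce")
        if age.isna().any():
            raise ValueError("donor_age is not numeric for all samples")
        sex, names_s = _dummies(cov["donor_sex"], "donor_sex")
        Xc = np.column_stack([age.to_numpy(float), sex])
        names_c = ["donor_age"] + names_s
        terms = ["donor_age", "donor_sex", "group"]

    Xg, names_g = _dummies(groups, "group")
    X_reduced = np.hstack([intercept, Xc])
    X_full = np.hstack([X_reduced, Xg])
    colnames = ["intercept"] + names_c + names_g

    r_full = np.linalg.matrix_rank(X_full)
    r_red = np.linalg.matrix_rank(X_reduced)
    if r_full < X_full.shape[1]:
        raise ValueError(
            "full design matrix is singular (covariates collinear with group?)"
        )
    return DEDesign(
        X_full=X_full,
        X_reduced=X_reduced,
        full_terms=terms,
        reduced_terms=terms[:-1],
        colnames_full=colnames,
        group_col=X_full.shape[1] - 1,
        df=int(r_full - r_red),
        confounded=confounded,
    )


# ---------------------------------------------------------------------------
# NB GLM by IRLS
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    mu = np.maximum(mu, 1e-10)
    if alpha < 1e-12:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _fit_nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float,
    offset: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Fit one NB GLM with log link and fixed dispersion by IRLS.

    Returns (beta, mu, loglik, converged).
    """
    # start from a flat model matching the mean rate
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    ll_old = -np.inf
    converged = False
    mu = np.exp(X @ beta + offset)
    for _ in range(max_iter):
        mu = np.clip(mu, 1e-10, 1e12)
        w = mu / (1.0 + alpha * mu)
        z = (X @ beta) + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        beta = beta_new
        mu = np.exp(np.clip(X @ beta + offset, -30, 30))
        ll = _nb_loglik(y, mu, alpha)
        if np.abs(ll - ll_old) <= tol * (np.abs(ll) + 0.1):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return beta, mu, _nb_loglik(y, mu, alpha), converged


def _cox_reid_apl(y, X, alpha, offset) -> float:
    """Cox–Reid adjusted profile log-likelihood of alpha for one gene."""
    beta, mu, ll, _ = _fit_nb_irls(y, X, alpha, offset)
    w = mu / (1.0 + alpha * mu)
    info = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll - 0.5 * logdet


def estimate_dispersions(
    counts: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    shrink_weight: float = 0.25,
) -> tuple[np.ndarray, float]:
    """Tagwise + common Cox–Reid APL dispersion estimates with linear
    shrinkage: alpha_g <- w*tagwise + (1-w)*common."""
    n_genes = counts.shape[1]
    log_bounds = (np.log(_ALPHA_MIN), np.log(_ALPHA_MAX))

    def tagwise(y) -> float:
        res = minimize_scalar(
            lambda la: -_cox_reid_apl(y, X, np.exp(la), offset),
            bounds=log_bounds, method="bounded",
            options={"xatol": 1e-3},
        )
        return float(np.exp(res.x))

    alphas = np.array([tagwise(counts[:, g].astype(float)) for g in range(n_genes)])

    def common_obj(la: float) -> float:
        a = np.exp(la)
        return -sum(
            _cox_reid_apl(counts[:, g].astype(float), X, a, offset)
            for g in range(n_genes)
        )

    res = minimize_scalar(
        common_obj, bounds=log_bounds, method="bounded", options={"xatol": 1e-3}
    )
    common = float(np.exp(res.x))
    shrunk = shrink_weight * alphas + (1.0 - shrink_weight) * common
    return shrunk, common


@dataclass
class DEResult:
    """Per-gene differential-expression table plus fit metadata."""

    table: pd.DataFrame  # gene, log2FC, LR, p_value, q_value, converged, tested
    design: DEDesign
    common_dispersion: float
    dispersions: np.ndarray = field(repr=False, default=None)

    def significant(self, q_max: float = 0.05, min_abs_lfc: float = 0.5) -> list[str]:
        return significant_degs(self, q_max, min_abs_lfc)


def fit_nb_glm_lrt(
    pb: PseudobulkMatrix,
    design: DEDesign,
    min_total_counts: int = 10,
    shrink_weight: float = 0.25,
    normalization: str = "median_ratio",
) -> DEResult:
    """NB GLM likelihood-ratio test of the group effect for every gene.

    Genes with fewer than ``min_total_counts`` summed counts are reported
    untested (NaN statistics) and excluded from the BH correction. LR is
    2(l_full − l_reduced), p the chi-square upper tail on
    rank(full) − rank(reduced) degrees of freedom, log2FC the group
    coefficient divided by ln 2. The offset is the log of the per-sample
    normalization factor (median-of-ratios by default, plain library size
    with ``normalization="library"``).
    """
    X_full, X_red = design.X_full, design.X_reduced
    if pb.n_samples < X_full.shape[1] + 1:
        raise ValueError("fewer samples than model parameters + 1")
    offset = np.log(pb.size_factors(normalization))
    tested = pb.counts.sum(axis=0) >= min_total_counts

    idx = np.flatnonzero(tested)
    counts_t = pb.counts[:, idx]
    alphas, common = estimate_dispersions(counts_t, X_full, offset, shrink_weight)

    n_genes = pb.counts.shape[1]
    lr = np.full(n_genes, np.nan)
    lfc = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)
    conv = np.zeros(n_genes, dtype=bool)

    for k, g in enumerate(idx):
        y = pb.counts[:, g].astype(float)
        a = alphas[k]
        beta_f, _, ll_f, conv_f = _fit_nb_irls(y, X_full, a, offset)
        _, _, ll_r, conv_r = _fit_nb_irls(y, X_red, a, offset)
        lr[g] = max(2.0 * (ll_f - ll_r), 0.0)
        lfc[g] = beta_f[design.group_col] / np.log(2.0)
        pvals[g] = chi2.sf(lr[g], df=design.df)
        conv[g] = conv_f and conv_r

    qvals = np.full(n_genes, np.nan)
    if tested.any():
        qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    disp_full = np.full(n_genes, np.nan)
    disp_full[tested] = alphas
    table = pd.DataFrame(
        {
            "gene": pb.gene_ids.astype(str),
            "log2FC": lfc,
            "LR": lr,
            "p_value": pvals,
            "q_value": qvals,
            "converged": conv,
            "tested": tested,
        }
    )
    return DEResult(table, design, common, disp_full)


def significant_degs(
    res: DEResult, q_max: float = 0.05, min_abs_lfc: float = 0.5
) -> list[str]:
    """Genes with q < q_max and |log2FC| > min_abs_lfc (both strict)."""
    t = res.table
    mask = (t["q_value"] < q_max) & (t["log2FC"].abs() > min_abs_lfc)
    return t.loc[mask.fillna(False), "gene"].tolist()
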