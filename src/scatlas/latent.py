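"""Semi-supervised latent-variable classifier with NB likelihood.

The model is a compact variational autoencoder for raw counts on a fixed
feature panel: an MLP encoder maps log-normalized counts to a D-dimensional
Gaussian posterior, a decoder maps latent draws to per-gene proportions via
a softmax head, and counts are modeled as negative binomial with the cell's
observed panel library size as an exact mean offset and a free per-gene
inverse dispersion. A linear-softmax classifier head on the latent space
provides cell-type probabilities.

Training follows a two-phase schedule: first a purely unsupervised phase
maximizing the evidence lower bound (ELBO), then a semi-supervised phase
minimizing −ELBO + λ·cross-entropy on labeled cells, with a stratified
5:1 train:validation split, early stopping on validation classification
accuracy (best state restored) and learning-rate reduction on training-loss
plateau. All arithmetic is plain NumPy with hand-written gradients and an
Adam optimizer, so a fitted model is bitwise reproducible from its seed.

Also provided: latent-space label transfer by multinomial logistic
regression, the standard recipe for carrying reference annotations onto
query cells through a shared batch-corrected embedding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln, softmax
from sklearn.linear_model import LogisticRegression

from .features import FeaturePanel
from .io import AnnotatedDataset

logger = logging.getLogger(__name__)

_EPS = 1e-10
_NORM_TARGET = 1e4


def nb_log_likelihood(x, mean, theta):
    """Elementwise negative-binomial log pmf with mean/inverse-dispersion
    parameterization (Var = mean + mean^2/theta). As theta → ∞ this
    approaches the Poisson log pmf."""
    x = np.asarray(x, dtype=float)
    mean = np.maximum(np.asarray(mean, dtype=float), _EPS)
    theta = np.asarray(theta, dtype=float)
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * np.log(theta / (theta + mean))
        + x * np.log(mean / (theta + mean))
    )


@dataclass
class LatentModelConfig:
    latent_dim: int = 50
    n_layers: int = 2
    hidden_dim: int = 128
    classification_weight: float = 50.0
    learning_rate: float = 1e-3
    unsup_epochs: int = 5
    max_epochs: int = 60
    early_stop_patience: int = 5
    early_stop_threshold: float = 0.001
    plateau_patience: int = 8
    plateau_factor: float = 0.1
    min_learning_rate: float = 1e-6
    batch_size: int = 128
    kl_weight: float = 1.0
    split_ratio: tuple[int, int] = (5, 1)
    use_batch_covariate: str = "auto"  # "auto" | "on" | "off"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ValueError("patience values must be >= 1")
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau_factor must lie in (0, 1)")


def _relu(x):
    return np.maximum(x, 0.0)


def _one_hot(labels: np.ndarray, vocab: list) -> np.ndarray:
    pos = {v: i for i, v in enumerate(vocab)}
    out = np.zeros((len(labels), len(vocab)))
    for r, v in enumerate(labels):
        out[r, pos[v]] = 1.0
    return out


class LatentClassifier:
    """Semi-supervised NB-VAE classifier over a fixed gene panel.

    Construct with a config, then :meth:`fit` on a labeled reference;
    :meth:`encode` and :meth:`classify` apply the trained model. A fitted
    instance carries the parameters, the gene panel, the label vocabulary
    and the training history, and persists to a directory.
    """

    def __init__(self, config: LatentModelConfig | None = None):
        self.config = config or LatentModelConfig()
        self.panel: FeaturePanel | None = None
        self.labels_vocab: list[str] | None = None
        self.batch_vocab: list[str] | None = None
        self.params: dict[str, np.ndarray] | None = None
        self.history: dict[str, list[float]] = {}
        self.best_val_accuracy: float | None = None
        self._val_idx: np.ndarray | None = None

    @property
    def validation_indices(self) -> np.ndarray:
        """Row indices (into the training dataset) of the held-out
        validation split chosen during :meth:`fit`."""
        if self._val_idx is None:
            raise RuntimeError("model is not trained")
        return self._val_idx

    # ------------------------------------------------------------------
    # parameter plumbing
    # ------------------------------------------------------------------
    def _init_params(self, n_in: int, n_genes: int, n_classes: int,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        D, H, L = cfg.latent_dim, cfg.hidden_dim, cfg.n_layers
        n_batch = len(self.batch_vocab) if self.batch_vocab else 0

        def glorot(fan_in, fan_out):
            s = np.sqrt(2.0 / (fan_in + fan_out))
            return rng.normal(0.0, s, size=(fan_in, fan_out))

        p: dict[str, np.ndarray] = {}
        d = n_in + n_batch
        for l in range(L):
            p[f"enc_W{l}"] = glorot(d, H)
            p[f"enc_b{l}"] = np.zeros(H)
            d = H
        p["enc_Wmu"] = glorot(d, D)
        p["enc_bmu"] = np.zeros(D)
        p["enc_Wlv"] = glorot(d, D)
        p["enc_blv"] = np.zeros(D)
        d = D + n_batch
        for l in range(L):
            p[f"dec_W{l}"] = glorot(d, H)
            p[f"dec_b{l}"] = np.zeros(H)
            d = H
        p["dec_Ws"] = glorot(d, n_genes)
        p["dec_bs"] = np.zeros(n_genes)
        p["log_theta"] = np.zeros(n_genes)
        p["cls_W"] = glorot(D, n_classes)
        p["cls_b"] = np.zeros(n_classes)
        return p

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------
    def _loss_and_grads(
        self,
        X: np.ndarray,
        lib: np.ndarray,
        bat: np.ndarray | None,
        y: np.ndarray | None,
        labeled: np.ndarray | None,
        eps: np.ndarray,
        lam: float,
    ) -> tuple[float, dict[str, np.ndarray], dict[str, float]]:
        """One minibatch of −ELBO (+ λ·CE) and its parameter gradients.

        X: raw panel counts (B×G); lib: per-cell panel library size;
        bat: optional batch one-hot; y: label one-hot; labeled: bool mask;
        eps: reparameterization noise (B×D), pass zeros for a
        deterministic evaluation.
        """
        p = self.params
        cfg = self.config
        B = X.shape[0]
        L = cfg.n_layers

        xin = np.log1p(X * (_NORM_TARGET / lib)[:, None])
        if bat is not None:
            xin = np.hstack([xin, bat])

        # encoder
        acts = [xin]
        a = xin
        for l in range(L):
            h = a @ p[f"enc_W{l}"] + p[f"enc_b{l}"]
            a = _relu(h)
            acts.append(a)
        mu = a @ p["enc_Wmu"] + p["enc_bmu"]
        lv_pre = a @ p["enc_Wlv"] + p["enc_blv"]
        lv = np.clip(lv_pre, -10.0, 10.0)
        z = mu + np.exp(0.5 * lv) * eps

        # decoder
        din = z if bat is None else np.hstack([z, bat])
        dacts = [din]
        a = din
        for l in range(L):
            h = a @ p[f"dec_W{l}"] + p[f"dec_b{l}"]
            a = _relu(h)
            dacts.append(a)
        s = a @ p["dec_Ws"] + p["dec_bs"]
        s -= s.max(axis=1, keepdims=True)
        rho = softmax(s, axis=1)
        m = lib[:, None] * rho + _EPS
        theta = np.exp(p["log_theta"])[None, :]

        ll = nb_log_likelihood(X, m, theta)
        recon = -ll.sum(axis=1).mean()
        kl = 0.5 * (mu ** 2 + np.exp(lv) - lv - 1.0).sum(axis=1).mean()
        loss = recon + cfg.kl_weight * kl

        # classifier
        n_lab = int(labeled.sum()) if labeled is not None else 0
        ce = 0.0
        if lam > 0 and n_lab > 0:
            logits = z @ p["cls_W"] + p["cls_b"]
            logits -= logits.max(axis=1, keepdims=True)
            probs = softmax(logits, axis=1)
            ce = -(
                (y[labeled] * np.log(probs[labeled] + _EPS)).sum(axis=1).mean()
            )
            loss += lam * ce

        # ---------------- backward ----------------
        g: dict[str, np.ndarray] = {}
        # NB reconstruction wrt mean
        g_m = -(X / m - (X + theta) / (theta + m)) / B
        t = g_m * m
        g_s = t - rho * t.sum(axis=1, keepdims=True)
        # inverse dispersion
        dll_dtheta = (
            digamma(X + theta)
            - digamma(theta)
            + np.log(theta / (theta + m))
            + (m - X) / (theta + m)
        )
        g["log_theta"] = (-dll_dtheta / B * theta).sum(axis=0)

        # decoder backward
        g["dec_Ws"] = dacts[-1].T @ g_s
        g["dec_bs"] = g_s.sum(axis=0)
        ga = g_s @ p["dec_Ws"].T
        for l in range(L - 1, -1, -1):
            ga = ga * (dacts[l + 1] > 0)
            g[f"dec_W{l}"] = dacts[l].T @ ga
            g[f"dec_b{l}"] = ga.sum(axis=0)
            ga = ga @ p[f"dec_W{l}"].T
        g_z = ga[:, : cfg.latent_dim]

        # classifier backward
        if lam > 0 and n_lab > 0:
            g_logits = np.zeros_like(probs)
            g_logits[labeled] = lam * (probs[labeled] - y[labeled]) / n_lab
            g["cls_W"] = z.T @ g_logits
            g["cls_b"] = g_logits.sum(axis=0)
            g_z = g_z + g_logits @ p["cls_W"].T
        else:
            g["cls_W"] = np.zeros_like(p["cls_W"])
            g["cls_b"] = np.zeros_like(p["cls_b"])

        # KL + reparameterization
        g_mu = g_z + cfg.kl_weight * mu / B
        g_lv = g_z * 0.5 * np.exp(0.5 * lv) * eps + cfg.kl_weight * 0.5 * (
            np.exp(lv) - 1.0
        ) / B
        g_lv = g_lv * (np.abs(lv_pre) < 10.0)  # clip is flat outside the band

        # encoder backward
        a_last = acts[-1]
        g["enc_Wmu"] = a_last.T @ g_mu
        g["enc_bmu"] = g_mu.sum(axis=0)
        g["enc_Wlv"] = a_last.T @ g_lv
        g["enc_blv"] = g_lv.sum(axis=0)
        ga = g_mu @ p["enc_Wmu"].T + g_lv @ p["enc_Wlv"].T
        for l in range(L - 1, -1, -1):
            ga = ga * (acts[l + 1] > 0)
            g[f"enc_W{l}"] = acts[l].T @ ga
            g[f"enc_b{l}"] = ga.sum(axis=0)
            ga = ga @ p[f"enc_W{l}"].T

        metrics = {"recon": float(recon), "kl": float(kl), "ce": float(ce)}
        return float(loss), g, metrics

    # ------------------------------------------------------------------
    # data preparation
    # ------------------------------------------------------------------
    def _panel_counts(self, ds: AnnotatedDataset) -> np.ndarray:
        genes = self.panel.genes
        pos = {g: i for i, g in enumerate(ds.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            logger.warning(
                "%d of %d panel genes absent from dataset; zero-filled",
                len(missing), len(genes),
            )
        X = np.zeros((ds.n_cells, len(genes)))
        present = [(j, pos[g]) for j, g in enumerate(genes) if g in pos]
        if present:
            cols = [c for _, c in present]
            tgt = [j for j, _ in present]
            X[:, tgt] = ds.counts[:, cols].toarray()
        return X

    def _batch_onehot(self, ds: AnnotatedDataset) -> np.ndarray | None:
        if not self.batch_vocab:
            return None
        if "sample_ID" not in ds.metadata.columns:
            return np.zeros((ds.n_cells, len(self.batch_vocab)))
        samples = ds.metadata["sample_ID"].astype(str).to_numpy()
        pos = {b: i for i, b in enumerate(self.batch_vocab)}
        out = np.zeros((ds.n_cells, len(self.batch_vocab)))
        for r, b in enumerate(samples):
            if b in pos:
                out[r, pos[b]] = 1.0
        return out

    @staticmethod
    def _library(X: np.ndarray) -> np.ndarray:
        lib = X.sum(axis=1)
        lib[lib == 0] = 1.0
        return lib

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------
    def fit(
        self,
        ref: AnnotatedDataset,
        labels: np.ndarray | Sequence[str],
        panel: FeaturePanel,
    ) -> "LatentClassifier":
        """Two-phase training on a labeled reference dataset.

        ``labels`` may contain None/"N/A" for unlabeled cells; those cells
        still contribute to the unsupervised ELBO.
        """
        cfg = self.config
        labels = np.asarray(labels, dtype=object)
        lab_mask = np.array([l is not None and str(l) != "N/A" for l in labels])
        vocab = sorted({str(l) for l in labels[lab_mask]})
        if len(vocab) < 2:
            raise ValueError("need at least two label classes to train a classifier")
        self.labels_vocab = vocab
        self.panel = panel

        use_batch = cfg.use_batch_covariate
        samples = (
            ref.metadata["sample_ID"].astype(str).to_numpy()
            if "sample_ID" in ref.metadata.columns
            else np.array(["s0"] * ref.n_cells)
        )
        if use_batch == "on" or (use_batch == "auto" and len(set(samples)) > 1):
            self.batch_vocab = sorted(set(samples))
        else:
            self.batch_vocab = None

        X = self._panel_counts(ref)
        lib = self._library(X)
        bat = self._batch_onehot(ref)
        y = np.zeros((ref.n_cells, len(vocab)))
        pos = {v: i for i, v in enumerate(vocab)}
        for r in np.flatnonzero(lab_mask):
            y[r, pos[str(labels[r])]] = 1.0

        rng = np.random.default_rng(cfg.seed)
        self.params = self._init_params(X.shape[1], X.shape[1], len(vocab), rng)

        # stratified train:val split of labeled cells
        train_frac = cfg.split_ratio[0] / sum(cfg.split_ratio)
        val_idx: list[int] = []
        train_lab_idx: list[int] = []
        for v in vocab:
            idx = np.flatnonzero(lab_mask & (labels.astype(str) == v))
            idx = idx[rng.permutation(len(idx))]
            n_val = max(1, int(round(len(idx) * (1 - train_frac))))
            val_idx += idx[:n_val].tolist()
            train_lab_idx += idx[n_val:].tolist()
        val_idx = np.asarray(sorted(val_idx))
        self._val_idx = val_idx
        val_labels = labels[val_idx].astype(str)

        train_mask = np.ones(ref.n_cells, dtype=bool)
        train_mask[val_idx] = False
        train_idx = np.flatnonzero(train_mask)
        labeled_train = lab_mask & train_mask

        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_t = 0
        lr = cfg.learning_rate

        def step(batch_idx: np.ndarray, lam: float) -> float:
            nonlocal adam_t
            eps = rng.standard_normal((len(batch_idx), cfg.latent_dim))
            labeled = lab_mask[batch_idx] & train_mask[batch_idx]
            loss, grads, _ = self._loss_and_grads(
                X[batch_idx], lib[batch_idx],
                None if bat is None else bat[batch_idx],
                y[batch_idx], labeled, eps, lam,
            )
            adam_t += 1
            b1, b2, eps_adam = 0.9, 0.999, 1e-8
            for k, gk in grads.items():
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * gk
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * gk ** 2
                mhat = adam_m[k] / (1 - b1 ** adam_t)
                vhat = adam_v[k] / (1 - b2 ** adam_t)
                self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps_adam)
            self.params["log_theta"] = np.clip(self.params["log_theta"], -6.0, 10.0)
            return loss

        def full_elbo() -> float:
            total = 0.0
            for start in range(0, ref.n_cells, 1024):
                sl = slice(start, min(start + 1024, ref.n_cells))
                nb = ref.n_cells
                loss, _, met = self._loss_and_grads(
                    X[sl], lib[sl], None if bat is None else bat[sl],
                    None, None,
                    np.zeros((sl.stop - sl.start, cfg.latent_dim)), 0.0,
                )
                total += (met["recon"] + cfg.kl_weight * met["kl"]) * (sl.stop - sl.start)
            return -total / ref.n_cells

        def epoch_pass(idx_pool: np.ndarray, lam: float) -> float:
            order = idx_pool[rng.permutation(len(idx_pool))]
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                losses.append(step(order[start : start + cfg.batch_size], lam))
            return float(np.mean(losses))

        history = {"elbo_unsup": [], "train_loss": [], "val_accuracy": []}

        # phase 1: unsupervised ELBO on the training split
        for _ in range(cfg.unsup_epochs):
            epoch_pass(train_idx, 0.0)
            history["elbo_unsup"].append(full_elbo())

        # phase 2: semi-supervised fine-tuning with early stopping
        def val_accuracy() -> float:
            pred, _ = self._classify_arrays(X[val_idx], lib[val_idx],
                                            None if bat is None else bat[val_idx])
            return float((pred == val_labels).mean())

        best_acc = -np.inf
        best_params = None
        best_loss = np.inf
        wait = 0
        plateau_wait = 0
        for _ in range(cfg.max_epochs):
            train_loss = epoch_pass(train_idx, cfg.classification_weight)
            acc = val_accuracy()
            history["train_loss"].append(train_loss)
            history["val_accuracy"].append(acc)
            if acc > best_acc + cfg.early_stop_threshold:
                best_acc = acc
                best_params = {k: v.copy() for k, v in self.params.items()}
                wait = 0
            else:
                wait += 1
            if train_loss < best_loss - 1e-12:
                best_loss = train_loss
                plateau_wait = 0
            else:
                plateau_wait += 1
                if plateau_wait >= cfg.plateau_patience:
                    lr = max(lr * cfg.plateau_factor, cfg.min_learning_rate)
                    plateau_wait = 0
            if wait >= cfg.early_stop_patience:
                break
        if best_params is not None:
            self.params = best_params
        self.best_val_accuracy = float(best_acc) if np.isfinite(best_acc) else None
        self.history = history
        return self

    # ------------------------------------------------------------------
    # inference
    # ------------------------------------------------------------------
    def _encode_arrays(self, X: np.ndarray, lib: np.ndarray,
                       bat: np.ndarray | None) -> np.ndarray:
        p = self.params
        L = self.config.n_layers
        xin = np.log1p(X * (_NORM_TARGET / lib)[:, None])
        if self.batch_vocab:
            if bat is None:
                bat = np.zeros((X.shape[0], len(self.batch_vocab)))
            xin = np.hstack([xin, bat])
        a = xin
        for l in range(L):
            a = _relu(a @ p[f"enc_W{l}"] + p[f"enc_b{l}"])
        return a @ p["enc_Wmu"] + p["enc_bmu"]

    def _classify_arrays(self, X, lib, bat) -> tuple[np.ndarray, np.ndarray]:
        z = self._encode_arrays(X, lib, bat)
        logits = z @ self.params["cls_W"] + self.params["cls_b"]
        probs = softmax(logits - logits.max(axis=1, keepdims=True), axis=1)
        pred = np.asarray(self.labels_vocab, dtype=object)[probs.argmax(axis=1)]
        return pred.astype(str), probs

    def encode(self, ds: AnnotatedDataset) -> np.ndarray:
        """Posterior-mean latent embedding (cells × latent_dim)."""
        if self.params is None:
            raise RuntimeError("model is not trained")
        X = self._panel_counts(ds)
        return self._encode_arrays(X, self._library(X), self._batch_onehot(ds))

    def classify(self, ds: AnnotatedDataset) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell argmax label and the full probability matrix."""
        if self.params is None:
            raise RuntimeError("model is not trained")
        X = self._panel_counts(ds)
        return self._classify_arrays(X, self._library(X), self._batch_onehot(ds))

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)
        np.savez(d / "params.npz", **self.params)
        self.panel.save(d / "panel.txt")
        with open(d / "vocab.json", "w") as fh:
            json.dump(
                {"labels": self.labels_vocab, "batches": self.batch_vocab}, fh
            )

    @classmethod
    def load(cls, directory: str | Path) -> "LatentClassifier":
        d = Path(directory)
        with open(d / "config.json") as fh:
            cfg_dict = json.load(fh)
        cfg_dict["split_ratio"] = tuple(cfg_dict["split_ratio"])
        model = cls(LatentModelConfig(**cfg_dict))
        with np.load(d / "params.npz") as npz:
            model.params = {k: npz[k] for k in npz.files}
        model.panel = FeaturePanel.load(d / "panel.txt")
        with open(d / "vocab.json") as fh:
            vocab = json.load(fh)
        model.labels_vocab = vocab["labels"]
        model.batch_vocab = vocab["batches"]
        return model


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_latent_model(
    ref: AnnotatedDataset,
    labels,
    panel: FeaturePanel,
    cfg: LatentModelConfig | None = None,
) -> LatentClassifier:
    return LatentClassifier(cfg).fit(ref, labels, panel)


def encode(model: LatentClassifier, ds: AnnotatedDataset) -> np.ndarray:
    return model.encode(ds)


def classify(model: LatentClassifier, ds: AnnotatedDataset):
    return model.classify(ds)


@dataclass
class HyperparamGrid:
    latent_dims: tuple[int, ...] = tuple(range(10, 101, 10))
    n_layers: tuple[int, ...] = tuple(range(1, 11))
    seeds: tuple[int, ...] = tuple(range(10))

    def __post_init__(self) -> None:
        if not (self.latent_dims and self.n_layers and self.seeds):
            raise ValueError("grid axes must be nonempty")


def hyperparameter_search(
    ref: AnnotatedDataset,
    labels,
    panel: FeaturePanel,
    grid: HyperparamGrid,
    base_cfg: LatentModelConfig | None = None,
) -> LatentClassifier:
    """Train one model per grid point, return the best by validation
    accuracy (ties: smaller latent_dim, then fewer layers, then smaller
    seed). Failing grid points are logged and skipped."""
    base = asdict(base_cfg or LatentModelConfig())
    best = None
    best_key = None
    for D, L, s in product(
        sorted(grid.latent_dims), sorted(grid.n_layers), sorted(grid.seeds)
    ):
        cfg_dict = dict(base, latent_dim=D, n_layers=L, seed=s)
        cfg_dict["split_ratio"] = tuple(cfg_dict["split_ratio"])
        try:
            model = fit_latent_model(ref, labels, panel, LatentModelConfig(**cfg_dict))
        except Exception as exc:  # noqa: BLE001 - grid points fail independently
            logger.warning("grid point (D=%d, L=%d, seed=%d) failed: %s", D, L, s, exc)
            continue
        key = (-model.best_val_accuracy, D, L, s)
        if best_key is None or key < best_key:
            best, best_key = model, key
    if best is None:
        raise RuntimeError("all hyperparameter grid points failed")
    return best


def logistic_transfer(
    ref_latent: np.ndarray,
    ref_labels,
    query_latent: np.ndarray,
    l2_strength: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent-space label transfer via multinomial logistic regression.

    Fits a penalized softmax-linear model on the reference embedding and
    applies it to the query embedding; returns (labels, probabilities)
    with probability columns in ``clf.classes_`` order.
    """
    ref_latent = np.asarray(ref_latent, dtype=float)
    query_latent = np.asarray(query_latent, dtype=float)
    if ref_latent.shape[1] != query_latent.shape[1]:
        raise ValueError("reference and query embeddings differ in dimension")
    ref_labels = np.asarray(ref_labels).astype(str)
    if len(set(ref_labels)) < 2:
        raise ValueError("need at least two reference classes")
    clf = LogisticRegression(
        C=1.0 / l2_strength, max_iter=2000, solver="lbfgs"
    ).fit(ref_latent, ref_labels)
    probs = clf.predict_proba(query_latent)
    return clf.classes_[probs.argmax(axis=1)], probs
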