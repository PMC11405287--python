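"""Two-level hierarchical annotation, consensus voting, and evaluation.

A hierarchical annotator holds one latent classifier over the broad cell
classes (level 1) and, for each class with enough labeled subtype
structure, a second classifier over that class's subtypes (level 2).
Prediction routes every cell through the level-1 model and then through
exactly one level-2 model; classes without a level-2 model pass their
level-1 label through.

Consensus voting combines label calls from several independent annotation
methods: a cell keeps the most frequent label only when it is supported by
more than half of the methods that voted on that cell, and is labeled
"unannotated" otherwise. Missing or failed method outputs count as
non-votes (the per-cell method count shrinks accordingly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeaturePanel, rank_markers_wilcoxon, select_feature_genes
from .io import AnnotatedDataset, LabelTree
from .latent import LatentClassifier, LatentModelConfig

logger = logging.getLogger(__name__)

UNANNOTATED = LabelTree.UNANNOTATED
#: Vote-table entries treated as abstentions.
NON_VOTES = ("", "N/A", "nan", "None")


@dataclass
class HierarchicalAnnotator:
    level1_model: LatentClassifier
    level2_models: dict[str, LatentClassifier] = field(default_factory=dict)
    tree: LabelTree | None = None
    min_cells_per_subtype: int = 20

    def __post_init__(self) -> None:
        if self.tree is not None:
            for cls, model in self.level2_models.items():
                extra = set(model.labels_vocab) - set(self.tree.subtypes(cls))
                if extra:
                    raise ValueError(
                        f"level-2 model for {cls!r} predicts labels outside "
                        f"its subtree: {sorted(extra)}"
                    )

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.level1_model.save(d / "level1")
        for cls, model in self.level2_models.items():
            model.save(d / "level2" / cls)
        if self.tree is not None:
            self.tree.to_json(d / "tree.json")

    @classmethod
    def load(cls, directory) -> "HierarchicalAnnotator":
        from pathlib import Path

        d = Path(directory)
        lvl1 = LatentClassifier.load(d / "level1")
        lvl2 = {}
        if (d / "level2").exists():
            for sub in sorted((d / "level2").iterdir()):
                lvl2[sub.name] = LatentClassifier.load(sub)
        tree = LabelTree.from_json(d / "tree.json") if (d / "tree.json").exists() else None
        return cls(lvl1, lvl2, tree)


def train_hierarchy(
    ref: AnnotatedDataset,
    tree: LabelTree,
    cfg: LatentModelConfig | None = None,
    n_per_type: int = 200,
    min_cells_per_subtype: int = 20,
) -> HierarchicalAnnotator:
    """Train the level-1 model and one level-2 model per eligible class.

    The reference must carry consistent level-1/level-2 labels. Each model
    gets its own Wilcoxon-derived feature panel (``n_per_type`` genes per
    label). A class gets a level-2 model only if it has at least two
    subtypes each with at least ``min_cells_per_subtype`` labeled cells.
    """
    cfg = cfg or LatentModelConfig()
    if ref.level1 is None or ref.level2 is None:
        raise ValueError("reference must be labeled at both levels")
    lvl1 = np.asarray(ref.level1, dtype=object).astype(str)
    lvl2 = np.asarray(ref.level2, dtype=object).astype(str)
    for c, s in zip(lvl1, lvl2):
        if c not in tree.classes:
            raise ValueError(f"level-1 label {c!r} not in tree")
        if s != c and s not in tree.subtypes(c):
            raise ValueError(f"subtype {s!r} not a subtype of class {c!r}")

    markers1 = rank_markers_wilcoxon(ref, lvl1)
    panel1 = select_feature_genes(markers1, n_per_type)
    model1 = LatentClassifier(cfg).fit(ref, lvl1, panel1)

    level2_models: dict[str, LatentClassifier] = {}
    for cls in tree.class_names:
        mask = lvl1 == cls
        if not mask.any():
            continue
        subs, counts = np.unique(lvl2[mask], return_counts=True)
        if len(subs) < 2:
            logger.info("class %r has a single subtype; level-2 passes through", cls)
            continue
        if counts.min() < min_cells_per_subtype:
            logger.warning(
                "class %r skipped at level 2: smallest subtype has %d < %d cells",
                cls, int(counts.min()), min_cells_per_subtype,
            )
            continue
        sub_ds = ref.subset_cells(mask)
        markers2 = rank_markers_wilcoxon(sub_ds, lvl2[mask])
        panel2 = select_feature_genes(markers2, n_per_type)
        level2_models[cls] = LatentClassifier(cfg).fit(sub_ds, lvl2[mask], panel2)

    return HierarchicalAnnotator(model1, level2_models, tree, min_cells_per_subtype)


def predict_hierarchy(
    annot: HierarchicalAnnotator, ds: AnnotatedDataset
) -> pd.DataFrame:
    """Predict (level1, level2) labels for every cell.

    Cells are routed to exactly one level-2 model — the one of their
    predicted class — or keep their level-1 label where no level-2 model
    exists.
    """
    lvl1_pred, _ = annot.level1_model.classify(ds)
    lvl2_pred = lvl1_pred.astype(object).copy()
    for cls, model in annot.level2_models.items():
        mask = lvl1_pred == cls
        if not mask.any():
            continue
        sub_pred, _ = model.classify(ds.subset_cells(mask))
        lvl2_pred[np.flatnonzero(mask)] = sub_pred
    return pd.DataFrame(
        {
            "cell_ID": ds.cell_ids.astype(str),
            "level1": lvl1_pred.astype(str),
            "level2": lvl2_pred.astype(str),
        }
    )


def consensus_vote(vt: pd.DataFrame) -> np.ndarray:
    """Per-cell majority-vote consensus over annotation methods.

    ``vt`` is a cells × methods table of label strings (an optional
    ``cell_ID`` column is ignored). For each cell, the most frequent label
    wins if its count exceeds half the number of methods that voted on
    that cell; otherwise the cell is "unannotated". A label exceeding m/2
    is necessarily unique, so no tie-break is needed.
    """
    cols = [c for c in vt.columns if c != "cell_ID"]
    if not cols:
        raise ValueError("vote table has no method columns")
    votes = vt[cols].astype(str).to_numpy(object)
    out = np.empty(len(vt), dtype=object)
    n_abstain = 0
    for r in range(len(vt)):
        row = [v for v in votes[r] if v not in NON_VOTES]
        if len(row) < len(cols):
            n_abstain += 1
        if not row:
            out[r] = UNANNOTATED
            continue
        vals, counts = np.unique(np.asarray(row, dtype=object), return_counts=True)
        best = counts.argmax()
        out[r] = vals[best] if counts[best] > len(row) / 2 else UNANNOTATED
    if n_abstain:
        logger.info(
            "%d cells had missing method outputs; per-cell method counts reduced",
            n_abstain,
        )
    return out


def evaluate_confusion(
    true_labels, pred_labels
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Row-normalized confusion matrix, per-type accuracy, macro accuracy.

    Rows are the reported (true) labels, columns the predictions; each row
    with at least one cell sums to 1. Per-type accuracy is the diagonal
    entry for types present in both axes; mean accuracy is the unweighted
    (macro) mean over true types.
    """
    t = np.asarray(true_labels).astype(str)
    p = np.asarray(pred_labels).astype(str)
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    rows = sorted(set(t))
    cols = sorted(set(t) | set(p))
    mat = pd.DataFrame(0.0, index=rows, columns=cols)
    for ti, pi in zip(t, p):
        mat.loc[ti, pi] += 1
    norm = mat.div(mat.sum(axis=1), axis=0)
    per_type = pd.Series(
        {r: (norm.loc[r, r] if r in norm.columns else 0.0) for r in rows}
    )
    return norm, per_type, float(per_type.mean())
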