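"""Data model and standard-format IO for atlas-style single-cell datasets.

The unit of exchange throughout the package is :class:`AnnotatedDataset`: a
sparse raw cell×gene count matrix plus a curated per-cell metadata table,
optionally carrying hierarchical labels, a latent embedding and doublet
scores. Counts are read and written as Matrix Market coordinate triplets
(``matrix.mtx`` + ``barcodes.tsv`` + ``genes.tsv``), the lingua franca of
droplet-based pipelines. Metadata follows a fixed curated schema in which
missing values are the literal string ``"N/A"``.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Curated per-cell metadata fields. Missing values are encoded as "N/A".
METADATA_FIELDS = (
    "cell_ID",
    "sample_ID",
    "donor_ID",
    "donor_sex",
    "donor_age",
    "donor_status",
    "sample_status",
    "if_patient",
    "original_name",
    "original_name2",
    "region",
    "subregion",
    "treatment",
    "ethnicity",
    "seq_method",
    "reference",
)

#: Controlled vocabularies for categorical metadata fields.
METADATA_VOCAB: Mapping[str, tuple[str, ...]] = {
    "if_patient": ("healthy", "patient", "N/A"),
}

MISSING = "N/A"


class AtlasIOError(ValueError):
    """Raised on malformed on-disk inputs or invalid in-memory containers."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse nonnegative-integer cell×gene count matrix with axis IDs."""

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise AtlasIOError(
                f"{len(self.cell_ids)} cell IDs for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise AtlasIOError(
                f"{len(self.gene_ids)} gene IDs for {g} matrix columns"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise AtlasIOError(f"duplicate {name} IDs")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise AtlasIOError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise AtlasIOError("non-integer counts")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class AgeRecord:
    """Canonical donor age: a nonnegative value plus its unit.

    Adults use years, donors under one year use months, fetal samples use
    gestational weeks (GW) and organoids use culture days.
    """

    value: float
    unit: str  # gestational_week | month | year | culture_day

    _UNITS = ("gestational_week", "month", "year", "culture_day")

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise AtlasIOError(f"unknown age unit {self.unit!r}")
        if self.value < 0:
            raise AtlasIOError("age value must be nonnegative")
        if self.unit == "month" and self.value >= 12:
            raise AtlasIOError("ages of 12 months or more are recorded in years")


@dataclass
class LabelTree:
    """Two-level cell-type hierarchy: classes and their subtypes.

    The reserved sink label ``"unannotated"`` never appears as a class or
    subtype name; it is what consensus voting emits when no majority exists.
    """

    classes: dict[str, list[str]]

    UNANNOTATED = "unannotated"

    def __post_init__(self) -> None:
        all_subtypes: list[str] = []
        for cls, subs in self.classes.items():
            if cls == self.UNANNOTATED:
                raise AtlasIOError("'unannotated' is a reserved label")
            if len(set(subs)) != len(subs):
                raise AtlasIOError(f"duplicate subtypes in class {cls!r}")
            all_subtypes.extend(subs)
        if len(set(all_subtypes)) != len(all_subtypes):
            raise AtlasIOError("subtype names must be unique across classes")

    @property
    def class_names(self) -> list[str]:
        return list(self.classes)

    def subtypes(self, cls: str) -> list[str]:
        return list(self.classes[cls])

    def class_of(self, subtype: str) -> str:
        for cls, subs in self.classes.items():
            if subtype in subs:
                return cls
        raise KeyError(subtype)

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelTree":
        with open(path) as fh:
            obj = json.load(fh)
        return cls({c["name"]: list(c["subtypes"]) for c in obj["classes"]})

    def to_json(self, path: str | Path) -> None:
        obj = {
            "classes": [
                {"name": c, "subtypes": subs} for c, subs in self.classes.items()
            ]
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


@dataclass
class AnnotatedDataset:
    """A count matrix, its metadata and optional annotation layers."""

    matrix: CountMatrix
    metadata: pd.DataFrame
    level1: np.ndarray | None = None
    level2: np.ndarray | None = None
    embedding: np.ndarray | None = None
    doublet_score: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.matrix.n_cells
        if len(self.metadata) != n:
            raise AtlasIOError("metadata rows must match cell count")
        if "cell_ID" in self.metadata.columns:
            md_ids = self.metadata["cell_ID"].to_numpy()
            if not np.array_equal(md_ids.astype(str), self.matrix.cell_ids.astype(str)):
                raise AtlasIOError("metadata cell_ID does not align with matrix cells")
        for name in ("level1", "level2", "doublet_score"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != n:
                    raise AtlasIOError(f"{name} not aligned to cells")
                setattr(self, name, arr)
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            if self.embedding.ndim != 2 or self.embedding.shape[0] != n:
                raise AtlasIOError("embedding must be cells × D")

    # -- convenience -------------------------------------------------------
    @property
    def counts(self) -> sp.csr_matrix:
        return self.matrix.counts

    @property
    def cell_ids(self) -> np.ndarray:
        return self.matrix.cell_ids

    @property
    def gene_ids(self) -> np.ndarray:
        return self.matrix.gene_ids

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    @property
    def n_genes(self) -> int:
        return self.matrix.n_genes

    def subset_cells(self, mask: np.ndarray) -> "AnnotatedDataset":
        """Return a new dataset restricted to cells where ``mask`` is True
        (or to the given integer positions)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        cm = CountMatrix(
            self.counts[idx], self.cell_ids[idx], self.gene_ids.copy()
        )
        pick = lambda a: None if a is None else np.asarray(a)[idx]
        return AnnotatedDataset(
            cm,
            self.metadata.iloc[idx].reset_index(drop=True),
            level1=pick(self.level1),
            level2=pick(self.level2),
            embedding=None if self.embedding is None else self.embedding[idx],
            doublet_score=pick(self.doublet_score),
        )

    def subset_genes(self, genes: Sequence[str]) -> "AnnotatedDataset":
        order = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([order[g] for g in genes], dtype=int)
        cm = CountMatrix(self.counts[:, idx], self.cell_ids.copy(), np.asarray(genes, dtype=object))
        return replace(self, matrix=cm)

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (convenience, lossless for
        counts/metadata/labels/embedding)."""
        import anndata as ad

        obs = self.metadata.copy()
        obs.index = pd.Index(self.cell_ids.astype(str), name="cell_ID")
        adata = ad.AnnData(X=self.counts.copy(), obs=obs)
        adata.var_names = self.gene_ids.astype(str)
        if self.level1 is not None:
            adata.obs["level1"] = self.level1
        if self.level2 is not None:
            adata.obs["level2"] = self.level2
        if self.doublet_score is not None:
            adata.obs["doublet_score"] = self.doublet_score
        if self.embedding is not None:
            adata.obsm["X_latent"] = self.embedding
        return adata


# ---------------------------------------------------------------------------
# Matrix Market triplet IO
# ---------------------------------------------------------------------------


def _read_id_column(path: str | Path) -> np.ndarray:
    try:
        ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].to_numpy(object)
    except pd.errors.EmptyDataError:
        ids = np.empty(0, dtype=object)
    return ids


def read_count_triplet(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    genes_path: str | Path,
) -> CountMatrix:
    """Read a 10x-style MTX triplet into a cells×genes :class:`CountMatrix`.

    Both on-disk orientations (cells×genes and genes×cells) occur in the
    wild; the orientation is resolved by matching the matrix dimensions
    against the barcode and gene file lengths. A square matrix whose two ID
    files have equal length is ambiguous and defaults to rows=cells with a
    logged warning.
    """
    mat = scipy.io.mmread(str(mtx_path))
    mat = sp.coo_matrix(mat)
    barcodes = _read_id_column(barcodes_path)
    genes = _read_id_column(genes_path)
    n_rows, n_cols = mat.shape
    nb, ng = len(barcodes), len(genes)

    if (n_rows, n_cols) == (nb, ng) and (n_rows, n_cols) == (ng, nb):
        logger.warning(
            "square matrix with equally many barcodes and genes: "
            "assuming rows are cells"
        )
        cells_by_genes = mat
    elif (n_rows, n_cols) == (nb, ng):
        cells_by_genes = mat
    elif (n_rows, n_cols) == (ng, nb):
        cells_by_genes = mat.T
    else:
        raise AtlasIOError(
            f"matrix shape {mat.shape} matches neither "
            f"(barcodes={nb}, genes={ng}) nor its transpose"
        )
    return CountMatrix(sp.csr_matrix(cells_by_genes), barcodes, genes)


def write_count_triplet(cm: CountMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write ``matrix.mtx`` + ``barcodes.tsv`` + ``genes.tsv`` so that
    :func:`read_count_triplet` is an exact inverse."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "genes": out / "genes.tsv",
    }
    scipy.io.mmwrite(
        str(paths["mtx"]), sp.coo_matrix(cm.counts), field="integer"
    )
    pd.Series(cm.cell_ids).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    pd.Series(cm.gene_ids).to_csv(paths["genes"], sep="\t", index=False, header=False)
    return paths


def read_dataset(directory: str | Path) -> AnnotatedDataset:
    """Read an MTX triplet plus optional ``metadata.tsv`` from a directory."""
    d = Path(directory)
    cm = read_count_triplet(d / "matrix.mtx", d / "barcodes.tsv", d / "genes.tsv")
    md_path = d / "metadata.tsv"
    if md_path.exists():
        md = read_metadata(md_path)
    else:
        md = pd.DataFrame({"cell_ID": cm.cell_ids.astype(str)})
    return AnnotatedDataset(cm, md)


def write_dataset(ds: AnnotatedDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    write_count_triplet(ds.matrix, out)
    write_metadata(ds.metadata, out / "metadata.tsv")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return md


def write_metadata(md: pd.DataFrame, path: str | Path) -> None:
    md.fillna(MISSING).to_csv(path, sep="\t", index=False)


@dataclass
class ValidationReport:
    """Outcome of metadata validation; empty ``errors`` means it passed."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_metadata(
    md: pd.DataFrame,
    schema: Sequence[str] = METADATA_FIELDS,
    vocab: Mapping[str, tuple[str, ...]] = METADATA_VOCAB,
) -> ValidationReport:
    """Check a metadata table against the curated field schema.

    Report-only: lists missing fields, out-of-vocabulary values and
    duplicated cell IDs instead of raising.
    """
    report = ValidationReport()
    if "cell_ID" not in md.columns:
        report.errors.append("missing field: cell_ID")
        return report
    for fld in schema:
        if fld not in md.columns:
            report.errors.append(f"missing field: {fld}")
    dup = md["cell_ID"][md["cell_ID"].duplicated()].unique()
    for d in dup:
        report.errors.append(f"duplicated cell_ID: {d}")
    for fld, allowed in vocab.items():
        if fld not in md.columns:
            continue
        bad = sorted(set(md[fld].astype(str)) - set(allowed))
        for value in bad:
            report.errors.append(
                f"out-of-vocabulary value in {fld}: {value!r}"
            )
    return report


# ---------------------------------------------------------------------------
# Age normalization
# ---------------------------------------------------------------------------

_AGE_PATTERNS = (
    # (regex, unit); value captured in group 1
    (re.compile(r"^(\d+(?:\.\d+)?)\s*GW$", re.I), "gestational_week"),
    (re.compile(r"^GW\s*(\d+(?:\.\d+)?)$", re.I), "gestational_week"),
    (re.compile(r"^(\d+(?:\.\d+)?)\s*months?$", re.I), "month"),
    (re.compile(r"^(\d+(?:\.\d+)?)\s*(?:years?|y)$", re.I), "year"),
    (re.compile(r"^D\s*(\d+(?:\.\d+)?)$", re.I), "culture_day"),
    (re.compile(r"^(\d+(?:\.\d+)?)\s*(?:culture\s*days?|days?)$", re.I), "culture_day"),
)

_DEFAULT_UNIT = {
    "adult": "year",
    "tumor": "year",
    "fetal": "gestational_week",
    "organoid": "culture_day",
}


def normalize_age(raw_age: str, sample_type: str) -> AgeRecord | None:
    """Parse a raw age string into a canonical :class:`AgeRecord`.

    Grammar: ``"6 GW"``, ``"3 months"``, ``"47"`` (unit implied by the
    sample type), ``"D60"``, or ``"N/A"`` (returns None). Bare numbers in
    adult/tumor samples under 1 are still years; the months convention
    applies only when the unit is written out. Unparseable strings raise,
    naming the token.
    """
    if sample_type not in _DEFAULT_UNIT:
        raise AtlasIOError(f"unknown sample type {sample_type!r}")
    tok = str(raw_age).strip()
    if tok == MISSING or tok == "":
        return None
    for pattern, unit in _AGE_PATTERNS:
        m = pattern.match(tok)
        if m:
            return AgeRecord(float(m.group(1)), unit)
    if re.match(r"^\d+(?:\.\d+)?$", tok):
        return AgeRecord(float(tok), _DEFAULT_UNIT[sample_type])
    raise AtlasIOError(f"unparseable age token: {tok!r}")


# ---------------------------------------------------------------------------
# Cross-species ortholog merge
# ---------------------------------------------------------------------------


def merge_orthologs(
    ds_a: AnnotatedDataset,
    ds_b: AnnotatedDataset,
    ortholog_table: pd.DataFrame,
    source_names: tuple[str, str] = ("a", "b"),
) -> AnnotatedDataset:
    """Combine two datasets on shared one-to-one orthologous genes.

    ``ortholog_table`` has two columns mapping gene IDs of ``ds_a`` to gene
    IDs of ``ds_b``. Rows participating in one-to-many or many-to-one
    relationships are dropped before joining (ambiguous orthology), and the
    result is restricted to pairs present in both datasets, with B's genes
    renamed into A's namespace. Cells are concatenated and a ``species``
    column records the source. Gene matching is case-sensitive and exact.
    """
    tab = ortholog_table.iloc[:, :2].astype(str)
    tab.columns = ["a", "b"]
    # keep 1:1 rows only
    tab = tab[~tab["a"].duplicated(keep=False) & ~tab["b"].duplicated(keep=False)]
    n_dropped = len(ortholog_table) - len(tab)
    if n_dropped:
        logger.info("dropped %d non-1:1 ortholog rows", n_dropped)

    genes_a = set(ds_a.gene_ids)
    genes_b = set(ds_b.gene_ids)
    tab = tab[tab["a"].isin(genes_a) & tab["b"].isin(genes_b)]
    if tab.empty:
        raise AtlasIOError("no shared 1:1 orthologs between the datasets")
    shared_a = [g for g in ds_a.gene_ids if g in set(tab["a"])]
    b_for_a = dict(zip(tab["a"], tab["b"]))
    shared_b = [b_for_a[g] for g in shared_a]

    sub_a = ds_a.subset_genes(shared_a)
    sub_b = ds_b.subset_genes(shared_b)

    counts = sp.vstack([sub_a.counts, sub_b.counts], format="csr")
    cell_ids = np.concatenate(
        [
            np.char.add(f"{source_names[0]}:", sub_a.cell_ids.astype(str)),
            np.char.add(f"{source_names[1]}:", sub_b.cell_ids.astype(str)),
        ]
    ).astype(object)
    md_a = sub_a.metadata.copy()
    md_b = sub_b.metadata.copy()
    md_a["species"] = source_names[0]
    md_b["species"] = source_names[1]
    md = pd.concat([md_a, md_b], ignore_index=True).fillna(MISSING)
    if "cell_ID" in md.columns:
        md["cell_ID"] = cell_ids.astype(str)

    cm = CountMatrix(counts, cell_ids, np.asarray(shared_a, dtype=object))

    def cat(x, y, n_a, n_b):
        if x is None and y is None:
            return None
        x = np.asarray(x, dtype=object) if x is not None else np.full(n_a, None, object)
        y = np.asarray(y, dtype=object) if y is not None else np.full(n_b, None, object)
        return np.concatenate([x, y])

    return AnnotatedDataset(
        cm,
        md,
        level1=cat(ds_a.level1, ds_b.level1, sub_a.n_cells, sub_b.n_cells),
        level2=cat(ds_a.level2, ds_b.level2, sub_a.n_cells, sub_b.n_cells),
    )
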