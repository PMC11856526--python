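"""Shared data model and I/O for annotation tables, bulk matrices and sparse
single-cell counts.

Three input families are supported, all plain text:

* **Gene annotation tables** (TSV): one row per gene carrying the regional
  expression categories, per-tissue normalized expression (NX), per-cancer
  FPKM, ranked subcellular localization and a blood mass-spectrometry
  detection flag — the fields the shortlisting filter chain consumes.
  Column headers are mapped through an extensible alias table so exports
  from the Human Protein Atlas load without editing.
* **Bulk expression matrices** (TSV): samples x genes, first column the
  sample id, a ``group`` column labelling each sample ``case`` or
  ``control``.
* **Single-cell count matrices**: MatrixMarket coordinate MTX plus
  row-aligned ``cells.tsv`` / ``genes.tsv`` sidecars.

Writers emit exactly the dialects the readers accept, so round-trips are
lossless.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CATEGORIES",
    "CellMatrix",
    "ExpressionDataset",
    "FormatError",
    "GeneAnnotation",
    "ValidationError",
    "normalize_category",
    "read_annotation_table",
    "read_bulk_dataset",
    "read_cell_matrix",
    "write_annotation_table",
    "write_bulk_dataset",
    "write_cell_matrix",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


#: The regional-distribution vocabulary used by both the brain and the
#: whole-body tissue annotation. Anything that does not normalize to one of
#: the first five becomes ``unknown`` (which the brain filter excludes).
CATEGORIES = frozenset(
    {
        "detected_in_all",
        "detected_in_many",
        "detected_in_some",
        "detected_in_single",
        "not_detected",
        "unknown",
    }
)


def normalize_category(raw: object) -> str:
    """Map a free-text distribution category onto the canonical vocabulary.

    Matching is case-insensitive after trimming; both ``"Detected in all"``
    (atlas style) and ``"detected_in_all"`` (canonical) are accepted.
    Unmatched or missing values map to ``"unknown"``.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    key = re.sub(r"[\s\-]+", "_", str(raw).strip().lower())
    return key if key in CATEGORIES else "unknown"


@dataclass
class GeneAnnotation:
    """Per-gene annotations driving the shortlisting filter chain.

    Parameters
    ----------
    gene_symbol
        Unique gene identifier within a table.
    brain_distribution, tissue_distribution
        Regional-distribution categories (see :data:`CATEGORIES`).
    tissue_nx
        Tissue name -> consensus normalized expression (NX, unitless, >= 0).
    cancer_fpkm
        Cancer type -> FPKM (>= 0).
    subcellular
        ``(location, confidence)`` pairs ordered by non-increasing
        confidence; an empty list means "no annotation".
    blood_detected
        Whether the encoded protein was detected in blood by mass
        spectrometry.
    """

    gene_symbol: str
    brain_distribution: str = "unknown"
    tissue_distribution: str = "unknown"
    tissue_nx: dict[str, float] = field(default_factory=dict)
    cancer_fpkm: dict[str, float] = field(default_factory=dict)
    subcellular: list[tuple[str, float]] = field(default_factory=list)
    blood_detected: bool = False

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")
        self.brain_distribution = normalize_category(self.brain_distribution)
        self.tissue_distribution = normalize_category(self.tissue_distribution)
        for name, value in {**self.tissue_nx, **self.cancer_fpkm}.items():
            if value < 0:
                raise ValidationError(
                    f"negative expression value {value!r} for {name!r} "
                    f"in gene {self.gene_symbol!r}"
                )
        # canonical order: descending confidence, location name as tie-break
        self.subcellular = sorted(self.subcellular, key=lambda lc: (-lc[1], lc[0]))


@dataclass
class ExpressionDataset:
    """A bulk samples x genes expression matrix with case/control labels."""

    dataset_id: str
    modality: str  # "transcript" | "protein"
    values: pd.DataFrame  # index: sample ids, columns: gene symbols
    sample_groups: dict[str, str]  # sample -> "case" | "control"

    def __post_init__(self) -> None:
        if self.modality not in ("transcript", "protein"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate gene columns: {dupes}")
        missing = [s for s in self.values.index if s not in self.sample_groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        bad = {g for g in self.sample_groups.values()} - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if not any(self.sample_groups[s] == "case" for s in self.values.index):
            raise ValidationError("dataset has no case samples")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, group: str) -> pd.DataFrame:
        keep = [s for s in self.values.index if self.sample_groups[s] == group]
        return self.values.loc[keep]


@dataclass
class CellMatrix:
    """Sparse single-cell counts with group labels and mitochondrial flags.

    ``counts`` is cells x genes (CSR, non-negative integers); ``normalized``
    is populated by :func:`surfrank.sc_correlation.log_normalize` and has
    the same shape.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    cell_groups: dict[str, str]  # cell -> "case" | "control"
    mito_flags: np.ndarray  # boolean, per gene
    normalized: np.ndarray | None = None  # dense cells x genes, optional

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"sidecar lengths ({len(self.cell_ids)} cells, "
                f"{len(self.gene_ids)} genes) do not match matrix shape "
                f"{self.counts.shape}"
            )
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.mito_flags.shape != (n_genes,):
            raise ValidationError("mito_flags must be defined for every gene")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if self.counts.nnz and not np.allclose(
            self.counts.data, np.round(self.counts.data)
        ):
            raise ValidationError("counts must be integral")
        missing = [c for c in self.cell_ids if c not in self.cell_groups]
        if missing:
            raise ValidationError(f"cells without group label: {missing[:5]}")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValidationError("normalized matrix shape must equal counts shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.cell_groups[c] == group for c in self.cell_ids])

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

#: Canonical column names and the atlas-style headers they absorb. Patterned
#: columns (per-tissue NX, per-cancer FPKM) are handled by regexes below.
DEFAULT_HEADER_ALIASES: dict[str, str] = {
    "gene": "gene",
    "gene_symbol": "gene",
    "rna brain regional distribution": "brain_distribution",
    "brain_distribution": "brain_distribution",
    "rna tissue distribution": "tissue_distribution",
    "tissue_distribution": "tissue_distribution",
    "subcellular location": "subcellular",
    "subcellular": "subcellular",
    "blood_detected": "blood_detected",
    "detected in blood by mass spectrometry": "blood_detected",
}

_NX_PATTERNS = (
    re.compile(r"^tissue rna - (?P<key>.+) \[nx\]$"),
    re.compile(r"^nx_(?P<key>.+)$"),
)
_FPKM_PATTERNS = (
    re.compile(r"^rna cancer specific fpkm - (?P<key>.+)$"),
    re.compile(r"^fpkm_(?P<key>.+)$"),
)

_REQUIRED_COLUMNS = (
    "gene",
    "brain_distribution",
    "tissue_distribution",
    "subcellular",
    "blood_detected",
)

_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}
_FALSE_STRINGS = {"false", "0", "no", "n", "f", ""}


def _canonical_header(raw: str, aliases: Mapping[str, str]) -> tuple[str, str | None]:
    """Return (kind, key) where kind is a canonical column name, 'nx',
    'fpkm', or 'ignored'."""
    low = raw.strip().lower()
    if low in aliases:
        return aliases[low], None
    for pat in _NX_PATTERNS:
        m = pat.match(low)
        if m:
            return "nx", m.group("key").strip()
    for pat in _FPKM_PATTERNS:
        m = pat.match(low)
        if m:
            return "fpkm", m.group("key").strip()
    return "ignored", None


def _parse_bool(raw: object, column: str) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return False
    s = str(raw).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise FormatError(f"cannot parse boolean {raw!r} in column {column!r}")


def _parse_subcellular(raw: object) -> list[tuple[str, float]]:
    """Parse ``"plasma membrane:5;cytosol:3"`` into ordered pairs."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    text = str(raw).strip()
    if not text:
        return []
    out: list[tuple[str, float]] = []
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise FormatError(f"subcellular entry {item!r} lacks ':confidence'")
        loc, conf = item.rsplit(":", 1)
        out.append((loc.strip(), float(conf)))
    return out


def read_annotation_table(
    path: str | Path,
    extra_aliases: Mapping[str, str] | None = None,
) -> list[GeneAnnotation]:
    """Read a TSV gene annotation table into :class:`GeneAnnotation` records.

    Headers are resolved through :data:`DEFAULT_HEADER_ALIASES` plus
    ``extra_aliases`` (lower-cased header -> canonical name), so real atlas
    exports load unmodified. Unrecognized columns are ignored with a
    warning; unparseable categories become ``"unknown"``. Every data row
    yields exactly one record — nothing is dropped silently.

    Raises
    ------
    FormatError
        If a required column is missing (the error names it).
    ValidationError
        On duplicate gene symbols.
    """
    aliases = dict(DEFAULT_HEADER_ALIASES)
    if extra_aliases:
        aliases.update({k.strip().lower(): v for k, v in extra_aliases.items()})

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    plan: list[tuple[str, str, str | None]] = []  # (raw, kind, key)
    seen = set()
    for raw in df.columns:
        kind, key = _canonical_header(raw, aliases)
        if kind == "ignored":
            warnings.warn(f"ignoring unrecognized column {raw!r}", stacklevel=2)
        plan.append((raw, kind, key))
        seen.add(kind)
    missing = [c for c in _REQUIRED_COLUMNS if c not in seen]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    records: list[GeneAnnotation] = []
    symbols: set[str] = set()
    for _, row in df.iterrows():
        fields: dict[str, object] = {"tissue_nx": {}, "cancer_fpkm": {}}
        for raw, kind, key in plan:
            value = row[raw]
            if kind == "nx":
                if str(value).strip():
                    fields["tissue_nx"][key] = float(value)  # type: ignore[index]
            elif kind == "fpkm":
                if str(value).strip():
                    fields["cancer_fpkm"][key] = float(value)  # type: ignore[index]
            elif kind == "subcellular":
                fields["subcellular"] = _parse_subcellular(value)
            elif kind == "blood_detected":
                fields["blood_detected"] = _parse_bool(value, raw)
            elif kind == "gene":
                fields["gene_symbol"] = str(value).strip()
            elif kind != "ignored":
                fields[kind] = value
        rec = GeneAnnotation(**fields)  # type: ignore[arg-type]
        if rec.gene_symbol in symbols:
            raise ValidationError(f"duplicate gene symbol {rec.gene_symbol!r}")
        symbols.add(rec.gene_symbol)
        records.append(rec)
    return records


def write_annotation_table(
    records: Sequence[GeneAnnotation], path: str | Path
) -> None:
    """Write records as a canonical-dialect TSV readable by
    :func:`read_annotation_table`."""
    tissues = sorted({t for r in records for t in r.tissue_nx})
    cancers = sorted({c for r in records for c in r.cancer_fpkm})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "gene": r.gene_symbol,
            "brain_distribution": r.brain_distribution,
            "tissue_distribution": r.tissue_distribution,
        }
        for t in tissues:
            row[f"nx_{t}"] = r.tissue_nx.get(t, "")
        for c in cancers:
            row[f"fpkm_{c}"] = r.cancer_fpkm.get(c, "")
        row["subcellular"] = ";".join(
            f"{loc}:{conf!r}" for loc, conf in r.subcellular
        )
        row["blood_detected"] = str(r.blood_detected).lower()
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bulk expression matrices
# ---------------------------------------------------------------------------


def read_bulk_dataset(
    path: str | Path,
    dataset_id: str | None = None,
    modality: str = "transcript",
) -> ExpressionDataset:
    """Read a TSV bulk matrix: first column sample id, a ``group`` column,
    remaining columns genes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in df.columns:
        raise FormatError("missing required column(s): group")
    groups = {str(s): str(g) for s, g in df["group"].items()}
    values = df.drop(columns=["group"]).astype(float)
    values.index = values.index.astype(str)
    return ExpressionDataset(
        dataset_id=dataset_id or Path(path).stem,
        modality=modality,
        values=values,
        sample_groups=groups,
    )


def write_bulk_dataset(ds: ExpressionDataset, path: str | Path) -> None:
    df = ds.values.copy()
    df.insert(0, "group", [ds.sample_groups[s] for s in df.index])
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Single-cell matrices
# ---------------------------------------------------------------------------


def read_cell_matrix(
    mtx_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
    mito_prefix: str = "MT-",
) -> CellMatrix:
    """Read a MatrixMarket counts matrix (cells x genes) with sidecar TSVs.

    ``cells.tsv`` needs columns ``cell`` and ``group``; ``genes.tsv`` needs
    ``gene`` and optionally ``mito`` (``true``/``false``). When the ``mito``
    column is absent, flags fall back to a gene-name prefix rule
    (``mito_prefix``, default ``"MT-"``) — the convention for human
    mitochondrial gene symbols.

    Raises
    ------
    FormatError
        On a dimension mismatch between the MTX header and the sidecars.
    """
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    for col, frame, name in (("cell", cells, "cells"), ("gene", genes, "genes")):
        if col not in frame.columns:
            raise FormatError(f"missing required column(s): {col} in {name} sidecar")
    if "group" not in cells.columns:
        raise FormatError("missing required column(s): group in cells sidecar")
    if counts.shape != (len(cells), len(genes)):
        raise FormatError(
            f"MTX shape {counts.shape} does not match sidecars "
            f"({len(cells)} cells, {len(genes)} genes)"
        )
    gene_ids = genes["gene"].tolist()
    if "mito" in genes.columns:
        mito = np.array([_parse_bool(v, "mito") for v in genes["mito"]])
    else:
        mito = np.array([g.upper().startswith(mito_prefix.upper()) for g in gene_ids])
    return CellMatrix(
        counts=counts,
        cell_ids=cells["cell"].tolist(),
        gene_ids=gene_ids,
        cell_groups=dict(zip(cells["cell"], cells["group"])),
        mito_flags=mito,
    )


def write_cell_matrix(
    m: CellMatrix,
    mtx_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
) -> None:
    """Write counts as integer coordinate MTX plus the two sidecar TSVs."""
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(m.counts), field="integer")
    pd.DataFrame(
        {"cell": m.cell_ids, "group": [m.cell_groups[c] for c in m.cell_ids]}
    ).to_csv(cells_path, sep="\t", index=False)
    pd.DataFrame(
        {"gene": m.gene_ids, "mito": [str(bool(f)).lower() for f in m.mito_flags]}
    ).to_csv(genes_path, sep="\t", index=False)
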