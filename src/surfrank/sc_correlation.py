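"""Single-cell QC, log-normalization and target-gene co-expression modules.

The workflow mirrors a standard droplet scRNA-seq preprocessing chain and
feeds ontology analysis downstream:

1. :func:`qc_filter` — a single fixed-order pass dropping (a) features
   present in too few cells, (b) cells with too few expressed features or
   zero total count, (c) cells whose mitochondrial-count percentage lies
   above a pooled percentile cutoff (apoptotic/stressed cells);
2. :func:`log_normalize` — per-cell library-size scaling to a fixed factor
   followed by ``log(1+x)``;
3. :func:`target_correlations` — Pearson correlation of every gene's
   normalized vector against a target gene, within one cell group, after
   excluding cells with zero raw target count;
4. :func:`resolve_modules` — threshold the case and control correlation
   maps and resolve genes above the cutoff in both groups to the group
   with the higher correlation, so the two modules are disjoint.

QC is deliberately single-pass: after cell removal a surviving feature is
not guaranteed to still be present in the minimum number of cells; the
contract is that each stage's rule held at the moment it ran.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from surfrank.annotation_io import CellMatrix, ValidationError

__all__ = [
    "CorrelationResult",
    "InsufficientDataError",
    "QCConfig",
    "log_normalize",
    "qc_filter",
    "resolve_modules",
    "target_correlations",
]


class InsufficientDataError(ValueError):
    """Too few cells remain for a meaningful computation."""


@dataclass
class QCConfig:
    """Quality-control and normalization parameters.

    ``min_cells_per_feature`` (default 200) and ``min_features_per_cell``
    (default 500) are the droplet-data defaults of the published screen;
    ``mito_percentile_cutoff`` (default 99) is the pooled percentile above
    which a cell's mitochondrial-count percentage marks it for removal;
    ``normalization_scale`` (default 10 000) is the per-cell library-size
    target.
    """

    min_cells_per_feature: int = 200
    min_features_per_cell: int = 500
    mito_percentile_cutoff: float = 99.0
    normalization_scale: float = 10_000.0

    def __post_init__(self) -> None:
        if self.min_cells_per_feature <= 0 or self.min_features_per_cell <= 0:
            raise ValidationError("QC thresholds must be positive")
        if not 0 < self.mito_percentile_cutoff <= 100:
            raise ValidationError("mito_percentile_cutoff must be in (0, 100]")
        if self.normalization_scale <= 0:
            raise ValidationError("normalization_scale must be positive")


@dataclass
class CorrelationResult:
    """Per-group correlation maps and the resolved disjoint modules."""

    target_gene: str
    r_case: dict[str, float]
    r_control: dict[str, float]
    n_cells_used: dict[str, int]
    cutoff: float
    module_case: set[str] = field(default_factory=set)
    module_control: set[str] = field(default_factory=set)


def qc_filter(m: CellMatrix, cfg: QCConfig | None = None) -> CellMatrix:
    """Apply the three QC stages once, in fixed order, and return a new
    :class:`~surfrank.annotation_io.CellMatrix`.

    Stage order: feature filter, cell filter, mitochondrial filter. The
    mitochondrial percentage is computed on the genes surviving stage 1,
    over all remaining cells pooled, and cells strictly above the
    ``mito_percentile_cutoff`` percentile are dropped. No iteration.

    Raises
    ------
    InsufficientDataError
        If any stage removes every remaining cell (the message names the
        stage).
    """
    cfg = cfg or QCConfig()
    counts = sp.csr_matrix(m.counts)

    # stage 1: features present (count > 0) in >= min_cells_per_feature cells
    cells_per_feature = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_feature >= cfg.min_cells_per_feature
    counts = counts[:, keep_genes]
    gene_ids = [g for g, k in zip(m.gene_ids, keep_genes) if k]
    mito_flags = m.mito_flags[keep_genes]

    # stage 2: cells with >= min_features_per_cell expressed features and
    # a positive total count
    features_per_cell = np.asarray((counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    keep_cells = (features_per_cell >= cfg.min_features_per_cell) & (totals > 0)
    if not keep_cells.any():
        raise InsufficientDataError(
            "all cells removed at the cell filter stage "
            "(min expressed features / zero total count)"
        )
    counts = counts[keep_cells]
    cell_ids = [c for c, k in zip(m.cell_ids, keep_cells) if k]

    # stage 3: mitochondrial percentage above the pooled percentile
    totals = np.asarray(counts.sum(axis=1)).ravel()
    mito_counts = np.asarray(counts[:, mito_flags].sum(axis=1)).ravel()
    mito_pct = 100.0 * mito_counts / totals
    cutoff = np.percentile(mito_pct, cfg.mito_percentile_cutoff)
    keep_cells = mito_pct <= cutoff
    if not keep_cells.any():
        raise InsufficientDataError(
            "all cells removed at the mitochondrial filter stage"
        )
    counts = counts[keep_cells]
    cell_ids = [c for c, k in zip(cell_ids, keep_cells) if k]

    return CellMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_groups={c: m.cell_groups[c] for c in cell_ids},
        mito_flags=mito_flags,
    )


def log_normalize(m: CellMatrix, cfg: QCConfig | None = None) -> CellMatrix:
    """Library-size log-normalization:
    ``normalized[c, g] = ln(1 + counts[c, g] * scale / total(c))``.

    Requires strictly positive per-cell totals, which QC guarantees.
    Returns the same matrix with ``normalized`` populated (dense).
    """
    cfg = cfg or QCConfig()
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise ValidationError(
            "log_normalize requires positive per-cell totals; run qc_filter first"
        )
    dense = m.counts.toarray().astype(float)
    m.normalized = np.log1p(dense * cfg.normalization_scale / totals[:, None])
    return m


def target_correlations(
    m: CellMatrix, target: str, group: str
) -> tuple[dict[str, float], int]:
    """Pearson correlation of each gene with the target within one group.

    Cells of the group with zero *raw* target count are excluded before
    correlating, so the statistic reflects co-variation where the target
    is actually expressed. Correlations use the log-normalized matrix.
    Genes with zero variance across the retained cells have undefined
    correlation and are omitted from the returned map; the target itself
    is also omitted.

    Returns
    -------
    (r_by_gene, n_cells_used)

    Raises
    ------
    InsufficientDataError
        With fewer than 3 eligible cells.
    """
    if m.normalized is None:
        raise ValidationError("normalized matrix missing; run log_normalize first")
    ti = m.gene_index(target)
    mask = m.group_mask(group)
    raw_target = np.asarray(m.counts[:, ti].todense()).ravel()
    mask = mask & (raw_target > 0)
    n_used = int(mask.sum())
    if n_used < 3:
        raise InsufficientDataError(
            f"only {n_used} {group!r} cells with nonzero {target!r} count"
        )
    x = m.normalized[mask]
    t = x[:, ti]
    t_centered = t - t.mean()
    t_ss = float(t_centered @ t_centered)
    if t_ss == 0:
        raise InsufficientDataError(
            f"target {target!r} has zero variance in eligible {group!r} cells"
        )
    centered = x - x.mean(axis=0)
    ss = (centered**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered.T @ t_centered) / np.sqrt(ss * t_ss)
    out: dict[str, float] = {}
    for j, g in enumerate(m.gene_ids):
        if j == ti or ss[j] == 0:
            continue
        out[g] = float(r[j])
    return out, n_used


def resolve_modules(
    r_case: dict[str, float],
    r_control: dict[str, float],
    cutoff: float = 0.6,
    strict: bool = False,
) -> tuple[set[str], set[str]]:
    """Threshold the two correlation maps into disjoint gene modules.

    A gene joins the case module iff its case correlation clears the
    cutoff and either its control correlation does not, or the case value
    is strictly higher; symmetrically for control. A gene above the cutoff
    in both groups therefore goes to the group where it correlates more
    strongly; an exact tie above the cutoff is assigned to neither, with a
    warning. ``strict`` switches the cutoff comparison from ``>=`` to
    ``>``.
    """
    clears = (lambda r: r > cutoff) if strict else (lambda r: r >= cutoff)
    module_case: set[str] = set()
    module_control: set[str] = set()
    for g in set(r_case) | set(r_control):
        rc = r_case.get(g, float("-inf"))
        rn = r_control.get(g, float("-inf"))
        in_case, in_control = clears(rc), clears(rn)
        if in_case and in_control and rc == rn:
            warnings.warn(
                f"gene {g!r} ties at r={rc:.3f} in both groups; "
                "assigned to neither module",
                stacklevel=2,
            )
            continue
        if in_case and (not in_control or rc > rn):
            module_case.add(g)
        elif in_control and (not in_case or rn > rc):
            module_control.add(g)
    return module_case, module_control


def correlation_modules(
    m: CellMatrix,
    target: str,
    cutoff: float = 0.6,
    strict: bool = False,
) -> CorrelationResult:
    """Convenience wrapper: correlations in both groups plus resolved
    modules, on an already-normalized matrix."""
    r_case, n_case = target_correlations(m, target, "case")
    r_control, n_control = target_correlations(m, target, "control")
    module_case, module_control = resolve_modules(r_case, r_control, cutoff, strict)
    return CorrelationResult(
        target_gene=target,
        r_case=r_case,
        r_control=r_control,
        n_cells_used={"case": n_case, "control": n_control},
        cutoff=cutoff,
        module_case=module_case,
        module_control=module_control,
    )
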