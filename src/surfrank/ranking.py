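"""Multi-dataset rank-score aggregation for shortlisted target genes.

Within each expression dataset the candidate genes are ranked by their
median expression in case samples; the gene ranked ``k``-th from the bottom
receives rank score ``RS = k * rs_step`` (default step 0.1, so eight genes
span 0.1–0.8, the highest median scoring 0.8). Tied medians share the mean
of their tied ranks' scores, which conserves the RS sum and keeps results
independent of input order.

Each dataset's scores are normalized by that dataset's maximum, giving
normalized scores NS in (0, 1] with top gene exactly 1. Transcript-dataset
NS are averaged into ``x̄_T``, protein-dataset NS into ``x̄_P``, and the
final prioritization statistic is the dataset-count-weighted mean

    x̄_TP = (m·x̄_T + n·x̄_P) / (m + n)

with ``m`` transcript and ``n`` protein datasets. Ordering uses unrounded
values; reported values are rounded half-away-from-zero at a configurable
number of decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from surfrank.annotation_io import ExpressionDataset, ValidationError

__all__ = [
    "RankingConfig",
    "RankTable",
    "aggregate_scores",
    "assign_rank_scores",
    "median_expression",
    "normalize_scores",
    "rank_targets",
    "round_half_away_from_zero",
]


def round_half_away_from_zero(x: float, decimals: int = 3) -> float:
    """Round with ties going away from zero (0.5625 -> 0.563), unlike
    numpy's banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RankingConfig:
    """Parameters of the rank-aggregation statistic.

    ``rs_step`` is the per-rank score increment; ``rounding_decimals``
    controls display rounding only (internal arithmetic and the final order
    are unrounded).
    """

    rs_step: float = 0.1
    rounding_decimals: int = 3
    rounding_mode: str = "half_away_from_zero"

    def __post_init__(self) -> None:
        if self.rs_step <= 0:
            raise ValidationError("rs_step must be positive")
        if self.rounding_mode != "half_away_from_zero":
            raise ValidationError(f"unsupported rounding mode {self.rounding_mode!r}")


@dataclass
class RankTable:
    """Full result of one rank-aggregation run.

    All score maps hold unrounded values; use :meth:`to_frame` for the
    display-rounded table. ``final_order`` sorts genes by descending
    ``x̄_TP`` (ties broken alphabetically for determinism).
    """

    genes: list[str]
    medians: dict[str, dict[str, float]]  # dataset -> gene -> median
    rank_scores: dict[str, dict[str, float]]  # dataset -> gene -> RS
    max_rs: dict[str, float]  # dataset -> greatest RS
    normalized_scores: dict[str, dict[str, float]]  # dataset -> gene -> NS
    xbar_t: dict[str, float]
    xbar_p: dict[str, float]
    xbar_tp: dict[str, float]
    final_order: list[str]
    transcript_datasets: list[str] = field(default_factory=list)
    protein_datasets: list[str] = field(default_factory=list)
    missing_genes: dict[str, list[str]] = field(default_factory=dict)
    config: RankingConfig = field(default_factory=RankingConfig)

    @property
    def top_gene(self) -> str:
        return self.final_order[0]

    def to_frame(self) -> pd.DataFrame:
        """Tabulate RS/NS per dataset plus the aggregate scores, rounded
        per config, ordered by final rank."""
        nd = self.config.rounding_decimals
        rows = []
        for g in self.final_order:
            row: dict[str, float | str] = {"gene": g}
            for ds in self.transcript_datasets + self.protein_datasets:
                row[f"RS_{ds}"] = self.rank_scores[ds][g]
                row[f"NS_{ds}"] = round_half_away_from_zero(
                    self.normalized_scores[ds][g], nd
                )
            if self.transcript_datasets:
                row["xbar_T"] = round_half_away_from_zero(self.xbar_t[g], nd)
            if self.protein_datasets:
                row["xbar_P"] = round_half_away_from_zero(self.xbar_p[g], nd)
            row["xbar_TP"] = round_half_away_from_zero(self.xbar_tp[g], nd)
            rows.append(row)
        return pd.DataFrame(rows)


def median_expression(
    d: ExpressionDataset,
    genes: Sequence[str],
    group: str = "case",
) -> dict[str, float]:
    """Per-gene median expression over the samples of one group.

    Even sample counts use the mean of the two central order statistics.
    Genes absent from the dataset's platform are excluded from the result
    with a warning (they are reported via ``rank_targets``' missing-gene
    bookkeeping rather than raising, mirroring genes absent from an assay
    platform).
    """
    sub = d.group_values(group)
    if sub.empty:
        raise ValidationError(f"dataset {d.dataset_id!r} has no {group!r} samples")
    present = [g for g in genes if g in sub.columns]
    absent = [g for g in genes if g not in sub.columns]
    if absent:
        warnings.warn(
            f"gene(s) {absent} not present in dataset {d.dataset_id!r}; "
            "excluded from its ranking",
            stacklevel=2,
        )
    return {g: float(np.median(sub[g].to_numpy())) for g in present}


def assign_rank_scores(
    medians: Mapping[str, float], cfg: RankingConfig | None = None
) -> dict[str, float]:
    """Assign rank scores ``k * rs_step`` by ascending median.

    Rank 1 is the lowest median; tied medians receive the mean of their
    tied ranks' scores (so two genes tied for ranks 3 and 4 both get
    ``0.35`` at the default step).
    """
    cfg = cfg or RankingConfig()
    if not medians:
        raise ValidationError("assign_rank_scores requires at least one gene")
    genes = list(medians)
    ranks = rankdata([medians[g] for g in genes], method="average")
    return {g: float(r) * cfg.rs_step for g, r in zip(genes, ranks)}


def normalize_scores(rs: Mapping[str, float]) -> dict[str, float]:
    """Divide every rank score by the dataset's greatest, so the top gene
    scores exactly 1."""
    if not rs:
        raise ValidationError("normalize_scores requires a non-empty map")
    top = max(rs.values())
    if top <= 0:
        raise ValidationError("rank scores must be positive")
    return {g: v / top for g, v in rs.items()}


def _mean_over(
    datasets: Sequence[str], ns: Mapping[str, Mapping[str, float]], gene: str
) -> float:
    return float(np.mean([ns[ds][gene] for ds in datasets]))


def aggregate_scores(
    ns_by_dataset: Mapping[str, Mapping[str, float]],
    modality: Mapping[str, str],
    cfg: RankingConfig | None = None,
    medians: Mapping[str, Mapping[str, float]] | None = None,
    rank_scores: Mapping[str, Mapping[str, float]] | None = None,
    missing_genes: Mapping[str, Sequence[str]] | None = None,
) -> RankTable:
    """Combine per-dataset normalized scores into the weighted statistic.

    Genes not present in every dataset's NS map are dropped with a warning
    before aggregation. ``m`` (transcript) and ``n`` (protein) dataset
    counts come from ``modality``; with ``n = 0`` the statistic reduces to
    ``x̄_T`` (and symmetrically for ``m = 0``).
    """
    cfg = cfg or RankingConfig()
    if not ns_by_dataset:
        raise ValidationError("aggregate_scores requires at least one dataset")
    transcript = sorted(ds for ds, m in modality.items() if m == "transcript")
    protein = sorted(ds for ds, m in modality.items() if m == "protein")
    if set(ns_by_dataset) != set(transcript) | set(protein):
        raise ValidationError("modality must cover exactly the provided datasets")

    common = set.intersection(*(set(ns.keys()) for ns in ns_by_dataset.values()))
    union = set.union(*(set(ns.keys()) for ns in ns_by_dataset.values()))
    dropped = union - common
    if dropped:
        warnings.warn(
            f"gene(s) {sorted(dropped)} missing from some dataset; "
            "dropped before aggregation",
            stacklevel=2,
        )
    if not common:
        raise ValidationError("no gene is present in every dataset")
    genes = sorted(common)

    m, n = len(transcript), len(protein)
    xbar_t, xbar_p, xbar_tp = {}, {}, {}
    for g in genes:
        xt = _mean_over(transcript, ns_by_dataset, g) if m else 0.0
        xp = _mean_over(protein, ns_by_dataset, g) if n else 0.0
        xbar_t[g] = xt
        xbar_p[g] = xp
        xbar_tp[g] = (m * xt + n * xp) / (m + n)

    final_order = sorted(genes, key=lambda g: (-xbar_tp[g], g))
    ns_common = {
        ds: {g: ns[g] for g in genes} for ds, ns in ns_by_dataset.items()
    }
    rs = (
        {ds: dict(r) for ds, r in rank_scores.items()}
        if rank_scores
        else {ds: {} for ds in ns_by_dataset}
    )
    return RankTable(
        genes=genes,
        medians={ds: dict(v) for ds, v in (medians or {}).items()},
        rank_scores=rs,
        max_rs={ds: max(r.values()) if r else float("nan") for ds, r in rs.items()},
        normalized_scores=ns_common,
        xbar_t=xbar_t,
        xbar_p=xbar_p,
        xbar_tp=xbar_tp,
        final_order=final_order,
        transcript_datasets=transcript,
        protein_datasets=protein,
        missing_genes={ds: list(v) for ds, v in (missing_genes or {}).items()},
        config=cfg,
    )


def rank_targets(
    transcript: Sequence[ExpressionDataset],
    protein: Sequence[ExpressionDataset],
    genes: Sequence[str],
    cfg: RankingConfig | None = None,
) -> RankTable:
    """End-to-end rank aggregation: case-group medians per dataset ->
    rank scores -> normalized scores -> weighted aggregate table."""
    cfg = cfg or RankingConfig()
    if not genes:
        raise ValidationError("rank_targets requires a non-empty gene set")
    datasets = list(transcript) + list(protein)
    if not datasets:
        raise ValidationError("rank_targets requires at least one dataset")
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate dataset ids: {ids}")

    medians: dict[str, dict[str, float]] = {}
    rank_scores: dict[str, dict[str, float]] = {}
    ns_by_dataset: dict[str, dict[str, float]] = {}
    missing: dict[str, list[str]] = {}
    modality: dict[str, str] = {}
    for d in datasets:
        med = median_expression(d, genes, group="case")
        medians[d.dataset_id] = med
        missing[d.dataset_id] = [g for g in genes if g not in med]
        rs = assign_rank_scores(med, cfg)
        rank_scores[d.dataset_id] = rs
        ns_by_dataset[d.dataset_id] = normalize_scores(rs)
        modality[d.dataset_id] = d.modality
    return aggregate_scores(
        ns_by_dataset,
        modality,
        cfg,
        medians=medians,
        rank_scores=rank_scores,
        missing_genes=missing,
    )
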