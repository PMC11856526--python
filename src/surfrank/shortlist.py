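"""Sequential annotation filter chain for cell-surface target shortlisting.

Candidate genes pass through six per-gene predicates in a fixed order, each
motivated by an immunotherapy safety or efficacy concern:

1. **brain** — exclude genes detected in normal brain tissue (on-target,
   off-tumor neurotoxicity);
2. **lung** — exclude genes with lung NX above a threshold (pulmonary
   toxicity);
3. **tissue distribution** — exclude genes detected in all or many normal
   tissues (broad off-tumor expression);
4. **tumor expression** — keep genes with cancer FPKM above a threshold
   (the target must actually be high in the tumor);
5. **surface localization** — keep genes whose top-confidence subcellular
   site is uniquely the plasma membrane and not tied with an extracellular
   annotation (secreted proteins can decoy the therapeutic);
6. **blood** — exclude proteins detected in blood by mass spectrometry
   (shed antigen).

Each predicate is a pure function of one :class:`~surfrank.annotation_io.GeneAnnotation`,
so the final survivor set is the intersection of the per-predicate pass
sets and is invariant to stage order; only the audit trail (per-stage
survivor sets and first-failure reasons) depends on the order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

from surfrank.annotation_io import CATEGORIES, GeneAnnotation, ValidationError

__all__ = [
    "FilterConfig",
    "ShortlistAudit",
    "STAGE_NAMES",
    "passes_blood_filter",
    "passes_brain_filter",
    "passes_hcc_expression_filter",
    "passes_lung_filter",
    "passes_surface_filter",
    "passes_tissue_distribution_filter",
    "run_shortlist",
]

#: Default stage order of the filter chain.
STAGE_NAMES: tuple[str, ...] = (
    "brain",
    "lung",
    "tissue_distribution",
    "tumor_fpkm",
    "surface_localization",
    "blood",
)


@dataclass
class FilterConfig:
    """Thresholds and category sets for the filter chain.

    Defaults encode the published screen: only ``not_detected`` passes the
    brain stage; lung NX strictly above 1.5 excludes; ``detected_in_all`` /
    ``detected_in_many`` tissue distribution excludes; cancer FPKM must be
    strictly above 50; the top subcellular site must be uniquely
    ``plasma membrane`` with no ``extracellular`` tie; blood detection
    excludes.
    """

    brain_excluded_categories: frozenset[str] = frozenset(
        {
            "detected_in_all",
            "detected_in_many",
            "detected_in_some",
            "detected_in_single",
            "unknown",
        }
    )
    lung_nx_threshold: float = 1.5
    lung_tissue_key: str = "lung"
    tissue_excluded_categories: frozenset[str] = frozenset(
        {"detected_in_all", "detected_in_many"}
    )
    fpkm_threshold: float = 50.0
    cancer_key: str = "liver cancer"
    extracellular_label: str = "extracellular"
    pm_label: str = "plasma membrane"

    def __post_init__(self) -> None:
        self.brain_excluded_categories = frozenset(self.brain_excluded_categories)
        self.tissue_excluded_categories = frozenset(self.tissue_excluded_categories)
        if self.lung_nx_threshold < 0 or self.fpkm_threshold < 0:
            raise ValidationError("thresholds must be non-negative")
        for cats in (self.brain_excluded_categories, self.tissue_excluded_categories):
            unknown = cats - CATEGORIES
            if unknown:
                raise ValidationError(f"unknown categories: {sorted(unknown)}")


@dataclass
class ShortlistAudit:
    """Full audit trail of one filter-chain run.

    ``survivors_per_stage[i]`` is the set of genes still alive *after*
    stage ``stage_names[i]``; the chain is weakly decreasing. Every
    excluded gene appears exactly once in ``exclusion_reason`` with the
    first stage that rejected it.
    """

    stage_names: list[str] = field(default_factory=list)
    survivors_per_stage: list[set[str]] = field(default_factory=list)
    exclusion_reason: dict[str, tuple[str, str]] = field(default_factory=dict)
    input_genes: set[str] = field(default_factory=set)

    @property
    def survivors(self) -> set[str]:
        """The final survivor set."""
        return set(self.survivors_per_stage[-1]) if self.survivors_per_stage else set()

    @property
    def counts(self) -> list[int]:
        """Gene counts: input followed by survivors after each stage."""
        return [len(self.input_genes)] + [len(s) for s in self.survivors_per_stage]


def passes_brain_filter(g: GeneAnnotation, c: FilterConfig) -> bool:
    """True iff the gene's brain regional distribution is not excluded
    (under defaults, only ``not_detected`` passes)."""
    return g.brain_distribution not in c.brain_excluded_categories


def passes_lung_filter(g: GeneAnnotation, c: FilterConfig) -> bool:
    """True iff lung NX <= threshold ("above" excludes strictly).

    A gene with no lung entry is treated as NX 0 and passes — consensus
    atlas tables always carry lung, so absence marks a partial or synthetic
    table and we do not exclude on absent evidence. A warning is emitted.
    """
    if c.lung_tissue_key not in g.tissue_nx:
        warnings.warn(
            f"gene {g.gene_symbol!r} lacks NX for {c.lung_tissue_key!r}; "
            "treating as 0",
            stacklevel=2,
        )
        return True
    return g.tissue_nx[c.lung_tissue_key] <= c.lung_nx_threshold


def passes_tissue_distribution_filter(g: GeneAnnotation, c: FilterConfig) -> bool:
    """True iff the whole-body tissue distribution category is not excluded."""
    return g.tissue_distribution not in c.tissue_excluded_categories


def passes_hcc_expression_filter(g: GeneAnnotation, c: FilterConfig) -> bool:
    """True iff cancer FPKM is strictly above the threshold; a missing
    cancer entry counts as 0 (inclusion requires a value)."""
    return g.cancer_fpkm.get(c.cancer_key, 0.0) > c.fpkm_threshold


def passes_surface_filter(g: GeneAnnotation, c: FilterConfig) -> bool:
    """True iff the unique maximal-confidence subcellular site is the
    plasma membrane.

    Fails when the annotation list is empty, when any other location —
    extracellular in particular, which marks transient surface residence
    before secretion — ties the plasma membrane at the top confidence, or
    when the top site is not the plasma membrane at all.
    """
    if not g.subcellular:
        return False
    top_conf = g.subcellular[0][1]
    top_sites = [loc for loc, conf in g.subcellular if conf == top_conf]
    return top_sites == [c.pm_label]


def passes_blood_filter(g: GeneAnnotation) -> bool:
    """True iff the protein was not detected in blood by mass spectrometry."""
    return not g.blood_detected


_STAGE_PREDICATES: dict[str, Callable[[GeneAnnotation, FilterConfig], bool]] = {
    "brain": passes_brain_filter,
    "lung": passes_lung_filter,
    "tissue_distribution": passes_tissue_distribution_filter,
    "tumor_fpkm": passes_hcc_expression_filter,
    "surface_localization": passes_surface_filter,
    "blood": lambda g, c: passes_blood_filter(g),
}

_STAGE_REASONS: dict[str, str] = {
    "brain": "detected in brain or unknown brain status",
    "lung": "lung NX above threshold",
    "tissue_distribution": "detected in all/many tissues",
    "tumor_fpkm": "cancer FPKM not above threshold",
    "surface_localization": "plasma membrane not the unique top subcellular site",
    "blood": "detected in blood by mass spectrometry",
}


def run_shortlist(
    genes: Sequence[GeneAnnotation],
    c: FilterConfig | None = None,
    stage_order: Sequence[str] = STAGE_NAMES,
) -> ShortlistAudit:
    """Run the sequential filter chain and return its audit trail.

    Each stage evaluates its predicate on the genes surviving the previous
    stage; a rejected gene is recorded with that stage and a reason, and is
    never re-examined. ``stage_order`` may permute the stages — the final
    survivor set is unchanged (predicates are per-gene and independent),
    only the audit differs.

    Raises
    ------
    ValidationError
        On duplicate gene symbols or an unknown stage name.
    """
    c = c or FilterConfig()
    symbols = [g.gene_symbol for g in genes]
    if len(set(symbols)) != len(symbols):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValidationError(f"duplicate gene symbols: {dupes}")
    unknown = [s for s in stage_order if s not in _STAGE_PREDICATES]
    if unknown:
        raise ValidationError(f"unknown stage name(s): {unknown}")
    if not genes:
        warnings.warn("empty gene list: shortlist audit will be empty", stacklevel=2)

    audit = ShortlistAudit(input_genes=set(symbols))
    alive: list[GeneAnnotation] = list(genes)
    for stage in stage_order:
        predicate = _STAGE_PREDICATES[stage]
        survivors: list[GeneAnnotation] = []
        for g in alive:
            if predicate(g, c):
                survivors.append(g)
            else:
                audit.exclusion_reason[g.gene_symbol] = (stage, _STAGE_REASONS[stage])
        audit.stage_names.append(stage)
        audit.survivors_per_stage.append({g.gene_symbol for g in survivors})
        alive = survivors
    return audit
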