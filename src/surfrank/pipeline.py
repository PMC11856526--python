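"""End-to-end orchestration: shortlist -> rank -> correlate, with
provenance.

A single YAML config drives the run; its sections map one-to-one onto
:class:`~surfrank.shortlist.FilterConfig`,
:class:`~surfrank.ranking.RankingConfig`,
:class:`~surfrank.sc_correlation.QCConfig` and the synthetic generator
configs. All randomness flows from one root seed. The report captures the
config snapshot, seed and input checksums, sufficient to re-run the
deterministic stages bit-identically.

Config schema (version 1)::

    seed: 42
    out_dir: results
    annotations: annotations.tsv        # omit when synthetic
    synthetic:                          # optional: generate inputs first
      n_genes: 1000
    filter: {lung_nx_threshold: 1.5, ...}
    ranking: {rs_step: 0.1, ...}
    bulk:
      - {path: tcga.tsv, id: TCGA, modality: transcript}
      - {path: chcc.tsv, id: CHCC, modality: protein}
    single_cell:                        # optional stage
      mtx: counts.mtx
      cells: cells.tsv
      genes: genes.tsv
      target: TM4SF4
      cutoff: 0.6
      qc: {min_cells_per_feature: 200, ...}
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from surfrank import __version__
from surfrank.annotation_io import (
    read_annotation_table,
    read_bulk_dataset,
    read_cell_matrix,
    write_annotation_table,
    write_bulk_dataset,
    write_cell_matrix,
)
from surfrank.ranking import RankingConfig, RankTable, rank_targets
from surfrank.sc_correlation import (
    CorrelationResult,
    QCConfig,
    correlation_modules,
    log_normalize,
    qc_filter,
)
from surfrank.shortlist import FilterConfig, ShortlistAudit, run_shortlist
from surfrank.synthetic_data import (
    BulkConfig,
    SingleCellConfig,
    SyntheticConfig,
    make_planted_labels,
    simulate_annotations,
    simulate_bulk,
    simulate_single_cell,
)

__all__ = ["PipelineError", "PipelineReport", "run_pipeline"]

logger = logging.getLogger("surfrank")

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and implicated input."""


@dataclass
class PipelineReport:
    """Everything one pipeline run produced."""

    audit: ShortlistAudit
    rank_table: RankTable | None
    correlation: CorrelationResult | None
    provenance: dict[str, Any]

    @property
    def candidate_target(self) -> str | None:
        """The top-ranked surviving gene — the declared candidate."""
        return self.rank_table.top_gene if self.rank_table else None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str, path: Any, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {name!r} failed on input {path}: {exc}") from exc


def _materialize_synthetic(config: dict[str, Any], out_dir: Path) -> dict[str, Any]:
    """Generate synthetic inputs into ``out_dir`` and rewrite the config to
    point at the files, so the rest of the pipeline exercises the readers."""
    syn = config["synthetic"]
    seed = int(config.get("seed", 0))
    n_genes = int(syn.get("n_genes", 1000))
    n_all_pass = int(syn.get("n_all_pass", 8))
    labels = make_planted_labels(n_genes, seed, n_all_pass=n_all_pass)
    all_pass = sorted(g for g, vec in labels.items() if all(vec))
    bulk_specs = []
    for b in syn.get("bulk", []):
        b = dict(b)
        # default the planted median ordering to the all-pass survivors, so
        # the ranking stage sees exactly the genes the shortlist yields
        b.setdefault("target_median_order", all_pass)
        bulk_specs.append(BulkConfig(**b))
    scfg = SyntheticConfig(
        seed=seed,
        n_genes=n_genes,
        planted_pass_labels=labels,
        bulk=bulk_specs,
        sc=SingleCellConfig(**syn.get("sc", {})) if "sc" in syn else SingleCellConfig(),
    )
    out_dir.mkdir(parents=True, exist_ok=True)

    ann_path = out_dir / "annotations.tsv"
    write_annotation_table(simulate_annotations(scfg), ann_path)
    config = dict(config)
    config["annotations"] = str(ann_path)

    if scfg.bulk:
        entries = []
        for ds in simulate_bulk(scfg):
            p = out_dir / f"{ds.dataset_id}.tsv"
            write_bulk_dataset(ds, p)
            entries.append({"path": str(p), "id": ds.dataset_id,
                            "modality": ds.modality})
        config["bulk"] = entries

    if "sc" in syn:
        m = simulate_single_cell(scfg)
        paths = {k: out_dir / v for k, v in
                 (("mtx", "counts.mtx"), ("cells", "cells.tsv"),
                  ("genes", "genes.tsv"))}
        write_cell_matrix(m, paths["mtx"], paths["cells"], paths["genes"])
        sc_conf = dict(config.get("single_cell", {}))
        sc_conf.setdefault("target", scfg.sc.target_gene)
        sc_conf.update({k: str(v) for k, v in paths.items()})
        config["single_cell"] = sc_conf
    return config


def run_pipeline(config: str | Path | dict[str, Any]) -> PipelineReport:
    """Execute shortlist -> rank -> correlate per the config and write the
    TSV/JSON report into ``out_dir``.

    Synthetic mode (a ``synthetic`` section) first generates the inputs to
    disk and then consumes them through the ordinary readers, so the run
    is identical to one on user-supplied files. Any stage error aborts
    with the stage name and the input file implicated.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        config = yaml.safe_load(config_path.read_text())
        config.setdefault("out_dir", str(config_path.parent / "surfrank_out"))
    out_dir = Path(config.get("out_dir", "surfrank_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    if "synthetic" in config:
        config = _materialize_synthetic(config, out_dir / "inputs")

    checksums: dict[str, str] = {}

    # --- shortlist -------------------------------------------------------
    ann_path = Path(config["annotations"])
    checksums[str(ann_path)] = _sha256(ann_path)
    annotations = _stage("shortlist", ann_path, read_annotation_table, ann_path)
    fcfg = FilterConfig(**config.get("filter", {}))
    audit = _stage("shortlist", ann_path, run_shortlist, annotations, fcfg)
    survivors = sorted(audit.survivors)
    logger.info("shortlist: %s -> %s survivors", len(annotations), len(survivors))

    # --- rank ------------------------------------------------------------
    rank_table: RankTable | None = None
    if config.get("bulk") and survivors:
        transcript, protein = [], []
        for entry in config["bulk"]:
            p = Path(entry["path"])
            checksums[str(p)] = _sha256(p)
            ds = _stage("rank", p, read_bulk_dataset, p,
                        entry.get("id"), entry.get("modality", "transcript"))
            (transcript if ds.modality == "transcript" else protein).append(ds)
        rcfg = RankingConfig(**config.get("ranking", {}))
        rank_table = _stage("rank", [e["path"] for e in config["bulk"]],
                            rank_targets, transcript, protein, survivors, rcfg)
        logger.info("rank: top gene %s", rank_table.top_gene)

    # --- correlate -------------------------------------------------------
    correlation: CorrelationResult | None = None
    if "single_cell" in config:
        scc = config["single_cell"]
        paths = {k: Path(scc[k]) for k in ("mtx", "cells", "genes")}
        for p in paths.values():
            checksums[str(p)] = _sha256(p)
        matrix = _stage("correlate", paths["mtx"], read_cell_matrix,
                        paths["mtx"], paths["cells"], paths["genes"])
        qcfg = QCConfig(**scc.get("qc", {}))
        matrix = _stage("correlate", paths["mtx"], qc_filter, matrix, qcfg)
        matrix = log_normalize(matrix, qcfg)
        target = scc.get("target") or (rank_table.top_gene if rank_table else None)
        if target is None:
            raise PipelineError(
                "stage 'correlate' failed: no target gene configured or ranked"
            )
        correlation = _stage("correlate", paths["mtx"], correlation_modules,
                             matrix, target, float(scc.get("cutoff", 0.6)),
                             bool(scc.get("strict", False)))
        logger.info("correlate: %d case / %d control module genes",
                    len(correlation.module_case), len(correlation.module_control))

    provenance = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.get("seed"),
        "config": {k: v for k, v in config.items() if k != "out_dir"},
        "filter_config": asdict(fcfg)
        | {"brain_excluded_categories": sorted(fcfg.brain_excluded_categories),
           "tissue_excluded_categories": sorted(fcfg.tissue_excluded_categories)},
        "input_checksums": checksums,
    }
    report = PipelineReport(audit=audit, rank_table=rank_table,
                            correlation=correlation, provenance=provenance)
    _write_report(report, out_dir)
    return report


def _write_report(report: PipelineReport, out_dir: Path) -> None:
    audit = report.audit
    audit_rows = [
        {"gene": g, "stage": stage, "reason": reason}
        for g, (stage, reason) in sorted(audit.exclusion_reason.items())
    ] + [{"gene": g, "stage": "", "reason": "survivor"}
         for g in sorted(audit.survivors)]
    pd.DataFrame(audit_rows).to_csv(out_dir / "shortlist_audit.tsv",
                                    sep="\t", index=False)
    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "stage_names": audit.stage_names,
        "stage_counts": audit.counts,
        "survivors": sorted(audit.survivors),
        "candidate_target": report.candidate_target,
        "provenance": report.provenance,
    }
    if report.rank_table is not None:
        report.rank_table.to_frame().to_csv(out_dir / "rank_table.tsv",
                                            sep="\t", index=False)
        summary["final_order"] = report.rank_table.final_order
    if report.correlation is not None:
        corr = report.correlation
        genes = sorted(set(corr.r_case) | set(corr.r_control))
        rows = []
        for g in genes:
            module = ("case" if g in corr.module_case
                      else "control" if g in corr.module_control else "")
            rows.append({"gene": g,
                         "r_case": corr.r_case.get(g, float("nan")),
                         "r_control": corr.r_control.get(g, float("nan")),
                         "assigned_module": module})
        pd.DataFrame(rows).to_csv(out_dir / "correlation_modules.tsv",
                                  sep="\t", index=False)
        summary["correlation"] = {
            "target": corr.target_gene,
            "cutoff": corr.cutoff,
            "n_cells_used": corr.n_cells_used,
            "module_case": sorted(corr.module_case),
            "module_control": sorted(corr.module_control),
        }
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True) + "\n")
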