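"""Config-driven orchestration: simulate -> expression -> methylome ->
selection -> enrichment, with a run manifest.

A run either simulates its inputs (when the config carries a
``simulate:`` section) or reads them from disk, then writes every stage's
TSV plus a JSON selection report and a manifest recording the config
hash, package version and per-stage row counts. All randomness flows from
the single configured seed, so a rerun of the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__, enrichment, expression, integration, io_formats, methylome
from .expression import Thresholds
from .synthetic_data import SimulationConfig

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Either ``simulate`` is set (inputs are generated under
    ``outdir/inputs``) or the five input paths are. ``seed`` overrides the
    simulation seed so CLI ``--seed`` has one obvious hook.
    """

    outdir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: SimulationConfig | None = None
    fasta: Path | None = None
    gff3: Path | None = None
    counts: Path | None = None
    sample_sheet: Path | None = None
    cytosine_reports: dict[str, Path] = field(default_factory=dict)
    term_map: Path | None = None
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulate", None)
        th = raw.pop("thresholds", None)
        reports = raw.pop("cytosine_reports", {}) or {}
        cfg = cls(
            outdir=Path(raw.pop("outdir", "methexpr_run")),
            thresholds=Thresholds(**th) if th else Thresholds(),
            simulate=SimulationConfig(**sim) if sim is not None else None,
            cytosine_reports={k: Path(v) for k, v in reports.items()},
            **{
                k: (Path(v) if k in ("fasta", "gff3", "counts", "sample_sheet", "term_map") and v else v)
                for k, v in raw.items()
            },
        )
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            required = {
                "fasta": self.fasta,
                "gff3": self.gff3,
                "counts": self.counts,
                "sample_sheet": self.sample_sheet,
            }
            for name, p in required.items():
                if p is None:
                    raise ValueError(f"run config: {name!r} is required without a simulate section")
                if not Path(p).exists():
                    raise FileNotFoundError(f"run config: {name} file not found: {p}")
            if not self.cytosine_reports:
                raise ValueError("run config: cytosine_reports required without a simulate section")
            for sample, p in self.cytosine_reports.items():
                if not Path(p).exists():
                    raise FileNotFoundError(
                        f"run config: cytosine report for {sample!r} not found: {p}"
                    )
        if self.term_map is not None and not Path(self.term_map).exists():
            raise FileNotFoundError(f"run config: term map not found: {self.term_map}")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every pipeline stage; returns the in-memory results.

    Writes expression.tsv, methylation.tsv, context_summary.tsv,
    top_expressed.tsv, demethylated.tsv, candidates.tsv,
    selection_report.json, optional enrichment tables, and manifest.json
    under ``config.outdir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        logger.info("simulating inputs (seed=%d)", sim.seed)
        from .synthetic_data import write_dataset

        data = write_dataset(sim, outdir / "inputs")
        genome, genes = data["genome"], data["genes"]
        sheet, counts = data["sheet"], data["counts"]
        wide = data["methylation"]
        reports = io_formats.split_cytosine_reports(wide, sheet.samples)
    else:
        genome = io_formats.read_fasta(config.fasta)
        genes = io_formats.read_gff3(config.gff3)
        sheet = io_formats.read_sample_sheet(config.sample_sheet)
        counts = io_formats.read_counts(config.counts, sheet)
        reports = {
            s: io_formats.read_cytosine_report(p) for s, p in config.cytosine_reports.items()
        }
        wide = io_formats.combine_cytosine_reports(reports)
    io_formats.validate_genes(genes, genome)
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    logger.info("differential expression over %d genes", len(counts.gene_ids))
    expr = expression.differential_expression(counts, genes, sheet, th)
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    expr_summary = expression.expression_summary(expr)

    logger.info("promoter methylation over %d cytosines", len(wide))
    meth = methylome.promoter_methylation(wide, genes, sheet, th, chrom_lengths)
    meth.to_csv(outdir / "methylation.tsv", sep="\t")
    meth_summary = methylome.methylation_summary(meth)
    ctx = methylome.context_summary(reports)
    ctx.to_csv(outdir / "context_summary.tsv", sep="\t")

    tf_flags = pd.Series({g.gene_id: g.is_tf for g in genes})
    top = integration.select_top_expressed(
        expr, th, n_tolerized=len(sheet.tolerized), tf_flags=tf_flags
    )
    top.to_csv(outdir / "top_expressed.tsv", sep="\t")
    demeth = integration.select_demethylated(meth, th)
    demeth.to_csv(outdir / "demethylated.tsv", sep="\t")
    candidates, report = integration.select_candidates(expr, meth, th)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t")
    (outdir / "selection_report.json").write_text(report.to_json())

    results = {
        "expression": expr,
        "methylation": meth,
        "context_summary": ctx,
        "top_expressed": top,
        "demethylated": demeth,
        "candidates": candidates,
        "selection_report": report,
        "expression_summary": expr_summary,
        "methylation_summary": meth_summary,
    }

    if config.term_map is not None:
        term_map = io_formats.read_term_map(config.term_map)
        detected = set(expr.index[expr["expr_class"] != "undetected"])
        up = set(expr.index[expr["expr_class"] == "up"])
        enr_up = enrichment.enrich(up, term_map, detected, th.alpha) if up else None
        if enr_up is not None:
            enr_up.to_csv(outdir / "enrichment_up.tsv", sep="\t", index=False)
            results["enrichment_up"] = enr_up
        covered = meth[meth["meth_class"] != "uncovered"]
        demeth_relaxed = set(covered.index[covered["fc_rate"] <= th.meth_fc_relaxed])
        if demeth_relaxed:
            enr_dm = enrichment.enrich(demeth_relaxed, term_map, set(covered.index), th.alpha)
            enr_dm.to_csv(outdir / "enrichment_demethylated.tsv", sep="\t", index=False)
            results["enrichment_demethylated"] = enr_dm

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "row_counts": {
            "genes": len(genes),
            "expression": len(expr),
            "methylation": len(meth),
            "top_expressed": len(top),
            "demethylated": len(demeth),
            "candidates_selected": int(candidates["selected"].sum()),
        },
        "expression_summary": expr_summary,
        "methylation_summary": meth_summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", outdir)
    return results
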