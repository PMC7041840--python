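"""Synthetic paired transcriptome + methylome data with known ground truth.

Emulates the statistical structure the analysis assumes for a 3-vs-3
control/tolerized T-cell study:

* replicate read counts per gene are negative binomial (overdispersed
  Poisson); spiked "up"/"down" genes have their tolerized mean scaled by
  ``expr_effect``;
* "candidate" genes carry the joint signal the integrative cascade looks
  for: expression up in tolerized samples — with an optional dropout
  pattern (zero control counts, giving the extreme fold changes and
  single-replicate CV = sqrt(3) signatures seen in deeply tolerized
  cells) — coupled with reduced promoter CpG methylation;
* every genomic cytosine (both strands) receives Poisson coverage and
  binomial methylated calls at a context-specific rate, ~0.75 for CpG and
  ~0.01 for CHG/CHH as in mammalian somatic cells; candidate genes'
  upstream-window CpGs are demethylated by ``demeth_effect`` in tolerized
  samples only.

One integer seed drives all stages through per-stage child generators, so
identical configurations produce identical datasets no matter which
stages are re-run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import CountMatrix, GeneModel, SampleSheet
from .methylome import genome_cytosines, promoter_window

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "generate_genome",
    "assign_labels",
    "simulate_counts",
    "simulate_methylation",
    "simulate_dataset",
    "write_dataset",
]

_NUCS = np.array(["A", "C", "G", "T"])


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for the generator.

    Defaults reflect the design the pipeline targets: three replicates per
    group, CpG methylation probability 0.75 with ~1% non-CpG methylation,
    and strong coupled expression-up / promoter-demethylation effects on
    the candidate genes (eight-fold expression, methylation probability
    scaled by 0.4).
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_length: int = 500_000
    n_genes: int = 20
    gene_length: int = 1_500
    gc_content: float = 0.42
    n_per_group: int = 3
    nb_mean: float = 100.0
    nb_dispersion: float = 10.0  # NB shape; variance = mu + mu^2 / dispersion
    n_up_spiked: int = 2
    n_down_spiked: int = 2
    n_candidate_spiked: int = 2
    expr_effect: float = 8.0
    dropout_pattern: bool = True
    single_replicate_fraction: float = 0.0
    cpg_meth_rate: float = 0.75
    chg_meth_rate: float = 0.01
    chh_meth_rate: float = 0.01
    coverage_mean: float = 10.0
    demeth_effect: float = 0.4
    tf_fraction: float = 0.1
    window_bp: int = 10_000

    def __post_init__(self) -> None:
        rates = {
            "cpg_meth_rate": self.cpg_meth_rate,
            "chg_meth_rate": self.chg_meth_rate,
            "chh_meth_rate": self.chh_meth_rate,
            "demeth_effect": self.demeth_effect,
            "gc_content": self.gc_content,
            "single_replicate_fraction": self.single_replicate_fraction,
            "tf_fraction": self.tf_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        for name in (
            "n_chrom",
            "chrom_length",
            "n_genes",
            "gene_length",
            "n_per_group",
            "window_bp",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("n_up_spiked", "n_down_spiked", "n_candidate_spiked"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_up_spiked + self.n_down_spiked + self.n_candidate_spiked > self.n_genes:
            raise ConfigError("spiked gene counts exceed n_genes")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0 or self.coverage_mean <= 0:
            raise ConfigError("nb_mean, nb_dispersion and coverage_mean must be positive")
        if self.expr_effect <= 0:
            raise ConfigError("expr_effect must be positive")

    @property
    def samples(self) -> SampleSheet:
        ctl = [f"control_{i + 1}" for i in range(self.n_per_group)]
        tol = [f"tolerized_{i + 1}" for i in range(self.n_per_group)]
        return SampleSheet(
            samples=tuple(ctl + tol),
            groups={**{s: "control" for s in ctl}, **{s: "tolerized" for s in tol}},
        )


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome with non-overlapping genes, each with a clear upstream flank.

    Genes are laid out in equal slots per chromosome; within its slot a
    gene is positioned so that the full ``window_bp`` upstream window fits
    inside the slot, which makes promoter windows pairwise disjoint and of
    exact length.
    """
    rng = _rng(config, 0)
    probs = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )
    genome = {
        f"chr{i + 1}": "".join(rng.choice(_NUCS, size=config.chrom_length, p=probs))
        for i in range(config.n_chrom)
    }

    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gid_width = max(4, len(str(config.n_genes)))
    k = 0
    for ci, n_here in enumerate(per_chrom):
        if n_here == 0:
            continue
        slot = config.chrom_length // n_here
        if slot < config.window_bp + config.gene_length + 1:
            raise ConfigError(
                f"chromosome length {config.chrom_length} too small to place {n_here} "
                f"genes with {config.window_bp} bp upstream windows "
                f"(need >= {n_here * (config.window_bp + config.gene_length + 1)})"
            )
        for j in range(n_here):
            k += 1
            strand = "+" if rng.random() < 0.5 else "-"
            slot_start = j * slot
            if strand == "+":
                start0 = slot_start + config.window_bp  # window fills [slot_start, start0)
                tss = start0
            else:
                start0 = slot_start
                tss = start0 + config.gene_length - 1
            genes.append(
                GeneModel(
                    gene_id=f"g{k:0{gid_width}d}",
                    chrom=f"chr{ci + 1}",
                    strand=strand,
                    tss=tss,
                    gene_length=config.gene_length,
                    is_tf=bool(rng.random() < config.tf_fraction),
                )
            )
    return genome, genes


# ---------------------------------------------------------------------------
# ground-truth labels
# ---------------------------------------------------------------------------


def assign_labels(genes: Sequence[GeneModel], config: SimulationConfig) -> pd.DataFrame:
    """Truth table: gene_id -> label in {null, up, down, candidate} plus the
    true expression fold and true promoter demethylation fold.

    Both the count and the methylation simulators call this with the same
    config, so the spiked-gene identities are consistent across stages.
    """
    rng = _rng(config, 1)
    ids = np.array([g.gene_id for g in genes])
    order = rng.permutation(len(ids))
    labels = np.full(len(ids), "null", dtype=object)
    i = 0
    for label, n in (
        ("up", config.n_up_spiked),
        ("down", config.n_down_spiked),
        ("candidate", config.n_candidate_spiked),
    ):
        labels[order[i : i + n]] = label
        i += n
    expr_fold = np.where(
        labels == "up",
        config.expr_effect,
        np.where(
            labels == "down",
            1.0 / config.expr_effect,
            np.where(labels == "candidate", config.expr_effect, 1.0),
        ),
    ).astype(float)
    demeth_fold = np.where(labels == "candidate", config.demeth_effect, 1.0).astype(float)
    return pd.DataFrame(
        {"gene_id": ids, "label": labels, "expr_fold": expr_fold, "demeth_fold": demeth_fold}
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _nb(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Replicate count matrix with spiked differential-expression effects."""
    rng = _rng(config, 2)
    truth = assign_labels(genes, config)
    sheet = config.samples
    labels = truth["label"].to_numpy()
    n_genes = len(genes)

    mu_ctl = np.full(n_genes, config.nb_mean)
    mu_tol = np.full(n_genes, config.nb_mean)
    mu_tol[labels == "up"] *= config.expr_effect
    mu_tol[labels == "down"] /= config.expr_effect
    mu_tol[labels == "candidate"] *= config.expr_effect

    counts = {}
    for s in sheet.control:
        col = _nb(rng, mu_ctl, config.nb_dispersion)
        if config.dropout_pattern:
            col[labels == "candidate"] = 0
        counts[s] = col
    tol_cols = {s: _nb(rng, mu_tol, config.nb_dispersion) for s in sheet.tolerized}

    cand_idx = np.flatnonzero(labels == "candidate")
    n_single = int(round(config.single_replicate_fraction * len(cand_idx)))
    single_idx = set(rng.choice(cand_idx, size=n_single, replace=False)) if n_single else set()
    for i in cand_idx:
        keep = rng.integers(config.n_per_group) if i in single_idx else None
        for j, s in enumerate(sheet.tolerized):
            if keep is not None and j != keep:
                tol_cols[s][i] = 0
            else:
                tol_cols[s][i] = max(1, tol_cols[s][i])  # detected by construction
    counts.update(tol_cols)

    df = pd.DataFrame(counts, index=[g.gene_id for g in genes]).astype("int64")
    df = df[list(sheet.samples)]
    df.index.name = "gene_id"
    return CountMatrix.from_counts(df), truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def simulate_methylation(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample methylation calls for every genomic cytosine.

    Returns the wide per-cytosine table (see
    :func:`methexpr.io_formats.combine_cytosine_reports` for the layout)
    plus the truth table. Coverage is Poisson(``coverage_mean``) per
    cytosine and sample; methylated calls are Binomial(coverage, rate)
    with the context rate, scaled by ``demeth_effect`` for candidate
    genes' upstream-window CpGs in tolerized samples.
    """
    rng = _rng(config, 3)
    truth = assign_labels(genes, config)
    sheet = config.samples
    cyt = genome_cytosines(genome)

    rate = np.select(
        [cyt["context"] == "CpG", cyt["context"] == "CHG", cyt["context"] == "CHH"],
        [config.cpg_meth_rate, config.chg_meth_rate, config.chh_meth_rate],
    )

    demeth_mask = np.zeros(len(cyt), dtype=bool)
    cand_ids = set(truth.index[truth["label"] == "candidate"])
    is_cpg = (cyt["context"] == "CpG").to_numpy()
    chrom_arr = cyt["chrom"].to_numpy()
    pos_arr = cyt["pos"].to_numpy()
    for gene in genes:
        if gene.gene_id not in cand_ids:
            continue
        start, end = promoter_window(gene, config.window_bp, len(genome[gene.chrom]))
        demeth_mask |= (chrom_arr == gene.chrom) & (pos_arr >= start) & (pos_arr < end) & is_cpg
    rate_tol = np.where(demeth_mask, rate * config.demeth_effect, rate)

    wide = cyt.copy()
    for s in sheet.samples:
        cov = rng.poisson(config.coverage_mean, size=len(cyt))
        r = rate_tol if sheet.groups[s] == "tolerized" else rate
        meth = rng.binomial(cov, r)
        wide[f"meth_{s}"] = meth
        wide[f"unmeth_{s}"] = cov - meth
    return wide, truth


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> dict:
    """Run all generator stages; returns genome, genes, sheet, counts,
    methylation (wide table) and the truth table in one dict."""
    genome, genes = generate_genome(config)
    counts, truth = simulate_counts(genes, config)
    meth, _ = simulate_methylation(genome, genes, config)
    return {
        "genome": genome,
        "genes": genes,
        "sheet": config.samples,
        "counts": counts,
        "methylation": meth,
        "truth": truth,
    }


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Simulate and write every input file the pipeline reads.

    Produces genome.fa, genes.gff3, counts.tsv, samples.tsv, one
    ``cytosine_<sample>.tsv`` per sample and truth.tsv under ``outdir``;
    returns the in-memory dataset as well.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(config)
    io_formats.write_fasta(data["genome"], outdir / "genome.fa")
    io_formats.write_gff3(data["genes"], outdir / "genes.gff3")
    io_formats.write_counts(data["counts"], outdir / "counts.tsv")
    io_formats.write_sample_sheet(data["sheet"], outdir / "samples.tsv")
    reports = io_formats.split_cytosine_reports(data["methylation"], data["sheet"].samples)
    for sample, df in reports.items():
        io_formats.write_cytosine_report(df, outdir / f"cytosine_{sample}.tsv")
    data["truth"].to_csv(outdir / "truth.tsv", sep="\t")
    return data
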