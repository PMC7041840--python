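"""Readers and writers for the external formats the pipeline touches.

Conventions fixed here once and for all:

* every internal coordinate is 0-based and intervals are half-open;
  GFF3 (1-based, inclusive) and cytosine reports (1-based positions)
  are converted at this boundary;
* genome sequences are uppercased and restricted to the {A, C, G, T, N}
  alphabet;
* cytosine reports carry methylated / unmethylated *call counts* per
  sample (Bismark cytosine-report style), never pre-computed rates.

All tabular formats are plain TSV with header rows, except the cytosine
report which is headerless like the Bismark original.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GeneModel",
    "SampleSheet",
    "CountMatrix",
    "GROUPS",
    "CONTEXTS",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_counts",
    "write_counts",
    "read_cytosine_report",
    "write_cytosine_report",
    "combine_cytosine_reports",
    "split_cytosine_reports",
    "read_term_map",
    "validate_genes",
]

GROUPS = ("control", "tolerized")
CONTEXTS = ("CpG", "CHG", "CHH")

_ALPHABET = frozenset("ACGTN")
_TRUTHY = frozenset({"1", "true", "yes"})


class FormatError(ValueError):
    """An input file violates the format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene.

    ``tss`` is the 0-based transcription start site: the first transcribed
    base (GFF3 ``start`` for '+' genes, ``end`` for '-' genes, converted).
    ``is_tf`` marks curated transcription-regulator genes; ``terms`` holds
    arbitrary annotation-term identifiers for enrichment analysis.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_length: int
    is_tf: bool = False
    terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.gene_length <= 0:
            raise FormatError(f"gene {self.gene_id!r}: gene_length must be > 0")
        if self.tss < 0:
            raise FormatError(f"gene {self.gene_id!r}: tss must be >= 0")


@dataclass(frozen=True)
class SampleSheet:
    """Ordered samples with their control / tolerized group labels."""

    samples: tuple[str, ...]
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("sample ids must be unique")
        for s in self.samples:
            g = self.groups.get(s)
            if g not in GROUPS:
                raise FormatError(f"sample {s!r}: group must be one of {GROUPS}, got {g!r}")
        for g in GROUPS:
            if not any(self.groups[s] == g for s in self.samples):
                raise FormatError(f"sample sheet has no {g!r} samples")

    def group_samples(self, group: str) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.groups[s] == group)

    @property
    def control(self) -> tuple[str, ...]:
        return self.group_samples("control")

    @property
    def tolerized(self) -> tuple[str, ...]:
        return self.group_samples("tolerized")


@dataclass
class CountMatrix:
    """Genes x samples raw read counts with per-sample library sizes.

    ``library_size`` defaults to the column sums but may be supplied
    externally (mapped-read totals), in which case it is what FPKM
    normalisation uses.
    """

    counts: pd.DataFrame  # index gene_id, columns sample ids, int64
    library_size: pd.Series  # index sample ids

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise FormatError("count matrix contains negative entries")
        self.library_size = self.library_size.reindex(counts.columns)
        if self.library_size.isna().any():
            missing = self.library_size.index[self.library_size.isna()].tolist()
            raise FormatError(f"library_size missing for samples {missing}")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CountMatrix":
        return cls(counts=counts, library_size=counts.sum(axis=0))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into {chrom: uppercase sequence}, order preserved."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path.name} line {lineno}: expected FASTA header '>', got {line[:30]!r}"
                    )
                break
        else:
            raise FormatError(f"{path.name}: empty FASTA file")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise FormatError(
                f"{path.name} record {rec.id!r}: invalid characters {sorted(bad)}"
            )
        if rec.id in genome:
            raise FormatError(f"{path.name}: duplicate record {rec.id!r}")
        genome[rec.id] = seq
    if not genome:
        raise FormatError(f"{path.name}: no FASTA records found")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path, side_annotations: str | Path | None = None) -> list[GeneModel]:
    """Read gene-type features from a GFF3 file into GeneModels.

    TSS conversion (to 0-based): '+' genes tss = start - 1, '-' genes
    tss = end - 1. The optional attribute keys ``is_tf`` and ``terms``
    (comma-separated) are honoured; a two-column side TSV
    ``gene_id<TAB>value`` may add terms, with the special value
    ``is_tf`` flagging transcription regulators.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except ValueError as exc:  # gffutils names the offending ID
        raise FormatError(f"{path.name}: {exc}") from exc

    side_tf: set[str] = set()
    side_terms: dict[str, set[str]] = {}
    if side_annotations is not None:
        ann = pd.read_csv(side_annotations, sep="\t", header=None, names=["gene_id", "value"])
        for gid, value in zip(ann["gene_id"], ann["value"]):
            if str(value) == "is_tf":
                side_tf.add(str(gid))
            else:
                side_terms.setdefault(str(gid), set()).add(str(value))

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.id
        if gid in seen:
            raise FormatError(f"{path.name}: duplicate gene id {gid!r}")
        seen.add(gid)
        if feat.strand not in ("+", "-"):
            raise FormatError(f"{path.name}: gene {gid!r} has no strand")
        if feat.end < feat.start:
            raise FormatError(f"{path.name}: gene {gid!r} has end < start")
        tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
        attrs = feat.attributes
        is_tf = gid in side_tf or (
            "is_tf" in attrs and str(attrs["is_tf"][0]).lower() in _TRUTHY
        )
        terms = set(attrs["terms"]) if "terms" in attrs else set()
        terms |= side_terms.get(gid, set())
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                tss=tss,
                gene_length=feat.end - feat.start + 1,
                is_tf=is_tf,
                terms=frozenset(terms),
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels back to GFF3 (gene features only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if g.strand == "+":
                start, end = g.tss + 1, g.tss + g.gene_length
            else:
                end, start = g.tss + 1, g.tss + 1 - (g.gene_length - 1)
            attrs = [f"ID={g.gene_id}"]
            if g.is_tf:
                attrs.append("is_tf=true")
            if g.terms:
                attrs.append("terms=" + ",".join(sorted(g.terms)))
            fh.write(
                f"{g.chrom}\t.\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t{';'.join(attrs)}\n"
            )


def validate_genes(genes: Sequence[GeneModel], genome: Mapping[str, str]) -> None:
    """Check every gene lies on a known chromosome with tss inside it."""
    for g in genes:
        if g.chrom not in genome:
            raise FormatError(f"gene {g.gene_id!r}: unknown chromosome {g.chrom!r}")
        if not 0 <= g.tss < len(genome[g.chrom]):
            raise FormatError(
                f"gene {g.gene_id!r}: tss {g.tss} outside chromosome "
                f"{g.chrom!r} (length {len(genome[g.chrom])})"
            )


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise FormatError(
            f"sample sheet must have columns 'sample_id' and 'group', got {list(df.columns)}"
        )
    return SampleSheet(
        samples=tuple(df["sample_id"]),
        groups=dict(zip(df["sample_id"], df["group"])),
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(sheet.samples), "group": [sheet.groups[s] for s in sheet.samples]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

_LIBSIZE_TAG = "#library_size"


def read_counts(path: str | Path, sheet: SampleSheet) -> CountMatrix:
    """Read a gene x sample count TSV.

    An optional first line ``#library_size<TAB>t1<TAB>t2...`` (aligned with
    the sample columns) supplies mapped-read totals; otherwise library sizes
    are the column sums.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    libsizes_raw: list[str] | None = None
    skip = 0
    if first.startswith(_LIBSIZE_TAG):
        libsizes_raw = first.rstrip("\n").split("\t")[1:]
        skip = 1
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    missing = [s for s in sheet.samples if s not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: sample column(s) missing from file: {missing}")
    extra = [c for c in df.columns if c not in sheet.samples]
    if extra:
        raise FormatError(f"{path.name}: column(s) not in sample sheet: {extra}")
    df = df[list(sheet.samples)]
    try:
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise FormatError(f"{path.name}: missing or non-finite counts present")
        if (values < 0).any():
            raise FormatError(f"{path.name}: negative counts present")
        if (values != np.floor(values)).any():
            raise FormatError(f"{path.name}: non-integer counts present")
    except (TypeError, ValueError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path.name}: non-numeric counts present") from exc
    counts = df.astype("int64")
    if libsizes_raw is not None:
        if len(libsizes_raw) != counts.shape[1]:
            raise FormatError(
                f"{path.name}: {_LIBSIZE_TAG} row has {len(libsizes_raw)} values "
                f"for {counts.shape[1]} sample columns"
            )
        library_size = pd.Series(
            [int(v) for v in libsizes_raw], index=counts.columns, name="library_size"
        )
    else:
        library_size = counts.sum(axis=0)
    return CountMatrix(counts=counts, library_size=library_size)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_LIBSIZE_TAG + "\t" + "\t".join(str(int(v)) for v in cm.library_size) + "\n")
        cm.counts.rename_axis("gene_id").to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

_CYT_COLS = ["chrom", "pos", "strand", "meth_count", "unmeth_count", "context"]


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read one sample's per-cytosine methylation calls.

    Headerless six-column TSV: chrom, 1-based position, strand,
    methylated call count, unmethylated call count, context. Positions are
    converted to 0-based. Zero-coverage rows (0, 0) are retained.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=_CYT_COLS,
        dtype={"chrom": str, "strand": str, "context": str},
    )
    bad_ctx = set(df["context"]) - set(CONTEXTS)
    if bad_ctx:
        raise FormatError(f"{path.name}: unknown context token(s) {sorted(bad_ctx)}")
    bad_strand = set(df["strand"]) - {"+", "-"}
    if bad_strand:
        raise FormatError(f"{path.name}: invalid strand token(s) {sorted(bad_strand)}")
    for col in ("pos", "meth_count", "unmeth_count"):
        vals = df[col].to_numpy()
        if not (vals == vals.astype("int64")).all() or (vals < 0).any():
            raise FormatError(f"{path.name}: column {col!r} must be non-negative integers")
        df[col] = df[col].astype("int64")
    if (df["pos"] < 1).any():
        raise FormatError(f"{path.name}: positions are 1-based, found value < 1")
    df["pos"] -= 1
    return df


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    out = df[_CYT_COLS].copy()
    out["pos"] += 1
    out.to_csv(path, sep="\t", header=False, index=False)


def combine_cytosine_reports(reports: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-sample reports into one wide table.

    Output columns: chrom, pos, strand, context, then meth_<sample> and
    unmeth_<sample> for every sample; cytosines absent from a sample get
    zero counts (uncovered).
    """
    if not reports:
        raise FormatError("no cytosine reports to combine")
    keys = ["chrom", "pos", "strand", "context"]
    wide: pd.DataFrame | None = None
    for sample, df in reports.items():
        part = df.rename(
            columns={"meth_count": f"meth_{sample}", "unmeth_count": f"unmeth_{sample}"}
        )
        wide = part if wide is None else wide.merge(part, on=keys, how="outer")
    assert wide is not None
    count_cols = [c for c in wide.columns if c not in keys]
    wide[count_cols] = wide[count_cols].fillna(0).astype("int64")
    return wide.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def split_cytosine_reports(wide: pd.DataFrame, samples: Iterable[str]) -> dict[str, pd.DataFrame]:
    """Inverse of :func:`combine_cytosine_reports` for writing per-sample files."""
    out: dict[str, pd.DataFrame] = {}
    for s in samples:
        out[s] = pd.DataFrame(
            {
                "chrom": wide["chrom"],
                "pos": wide["pos"],
                "strand": wide["strand"],
                "meth_count": wide[f"meth_{s}"],
                "unmeth_count": wide[f"unmeth_{s}"],
                "context": wide["context"],
            }
        )
    return out


# ---------------------------------------------------------------------------
# term maps (enrichment input)
# ---------------------------------------------------------------------------


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) -> {term_id: set of gene ids}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"], dtype=str)
    out: dict[str, set[str]] = {}
    for term, gid in zip(df["term_id"], df["gene_id"]):
        out.setdefault(term, set()).add(gid)
    return out
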