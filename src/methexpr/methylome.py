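"""Promoter methylation statistics from per-cytosine bisulfite calls.

The unit of analysis is the 10 kb window immediately upstream of each
gene's TSS (strand-aware, TSS base excluded, clipped at chromosome ends).
Methylated and total calls from every cytosine on *both* strands inside
the window are pooled across the replicates of each group; the group
methylation rate is pooled-M over pooled-T, and group differences are
scored by a two-sided Fisher's exact test on the pooled call counts.

Cytosine sequence contexts follow the standard bisulfite taxonomy: CpG
(next base downstream is G), CHG and CHH, with H = A, C or T, read 5'->3'
on the cytosine's own strand.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import Thresholds, fisher_exact_two_sided, largest_remainder_percentages
from .io_formats import CONTEXTS, GeneModel, SampleSheet

__all__ = [
    "classify_context",
    "genome_cytosines",
    "promoter_window",
    "promoter_methylation",
    "methylation_summary",
    "context_summary",
]

_H = frozenset("ACT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def classify_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """Sequence context of the cytosine at (chrom, pos, strand).

    The two bases downstream of the cytosine are read 5'->3' on the
    cytosine's strand (for '-', forward bases upstream in coordinates,
    complemented). Returns 'CpG', 'CHG', 'CHH' or 'undefined' when a
    needed base is N or off the chromosome end (CpG needs only the first
    downstream base; CHG/CHH need both).
    """
    seq = genome[chrom]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[pos]!r}, not C")
        down1 = seq[pos + 1] if pos + 1 < len(seq) else None
        down2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {seq[pos]!r} on forward, not G")
        down1 = seq[pos - 1].translate(_COMPLEMENT) if pos - 1 >= 0 else None
        down2 = seq[pos - 2].translate(_COMPLEMENT) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if down1 is None or down1 == "N":
        return "undefined"
    if down1 == "G":
        return "CpG"
    if down2 is None or down2 == "N":
        return "undefined"
    if down2 == "G":
        return "CHG"
    if down2 in _H:
        return "CHH"
    return "undefined"


def genome_cytosines(genome: Mapping[str, str]) -> pd.DataFrame:
    """Enumerate every cytosine on both strands with its context.

    Vectorised over whole chromosomes; agrees with :func:`classify_context`
    position by position. Cytosines with undefined context (N neighbours,
    chromosome edges) are excluded. Columns: chrom, pos, strand, context.
    """
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        n = len(arr)
        for strand, base in (("+", b"C"), ("-", b"G")):
            pos = np.flatnonzero(arr == base)
            if strand == "+":
                ok1 = pos + 1 < n
                d1 = np.where(ok1, arr[np.minimum(pos + 1, n - 1)], b"N")
                ok2 = pos + 2 < n
                d2 = np.where(ok2, arr[np.minimum(pos + 2, n - 1)], b"N")
            else:
                # downstream on '-' = upstream forward coordinates, complemented;
                # comparisons are done against the complement targets directly
                ok1 = pos - 1 >= 0
                d1f = np.where(ok1, arr[np.maximum(pos - 1, 0)], b"N")
                ok2 = pos - 2 >= 0
                d2f = np.where(ok2, arr[np.maximum(pos - 2, 0)], b"N")
                comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A", b"N": b"N"}
                d1 = np.select([d1f == k for k in comp], [comp[k] for k in comp], default=b"N")
                d2 = np.select([d2f == k for k in comp], [comp[k] for k in comp], default=b"N")
            is_h1 = (d1 == b"A") | (d1 == b"C") | (d1 == b"T")
            is_h2 = (d2 == b"A") | (d2 == b"C") | (d2 == b"T")
            context = np.select(
                [d1 == b"G", is_h1 & (d2 == b"G"), is_h1 & is_h2],
                ["CpG", "CHG", "CHH"],
                default="undefined",
            )
            keep = context != "undefined"
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos[keep],
                        "strand": strand,
                        "context": context[keep],
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def promoter_window(
    gene: GeneModel, window_bp: int = 10_000, chrom_length: int | None = None
) -> tuple[int, int]:
    """Half-open 0-based interval of the promoter window upstream of the TSS.

    '+' genes: [max(0, tss - window_bp), tss); '-' genes:
    [tss + 1, min(chrom_length, tss + 1 + window_bp)). The TSS base itself
    is excluded; windows are clipped at chromosome boundaries.
    """
    if gene.strand == "+":
        return max(0, gene.tss - window_bp), gene.tss
    end = gene.tss + 1 + window_bp
    if chrom_length is not None:
        end = min(chrom_length, end)
    return gene.tss + 1, end


def promoter_methylation(
    records: pd.DataFrame,
    genes: Sequence[GeneModel],
    sheet: SampleSheet,
    th: Thresholds | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene promoter-window methylation statistics.

    ``records`` is the wide per-cytosine table from
    :func:`methexpr.io_formats.combine_cytosine_reports`. For every gene,
    methylated (M) and total (T) calls are pooled over all window cytosines
    (both strands) and all replicates of each group. Outputs per gene:

    * r_ctl / r_tol — pooled methylation rates M/T,
    * fc_rate — r_tol / r_ctl,
    * fc_count — ratio of the group means of per-replicate methylated
      counts (so an exactly unchanged gene prints 1.000),
    * p_meth — two-sided Fisher's exact p on [[M_tol, U_tol], [M_ctl, U_ctl]],
    * meth_class — up (fc_rate >= 2), down (<= 0.5), unchanged, or
      uncovered when either group has zero calls in the window,
    * control_meth_count_sum — summed methylated calls over control
      replicates (selection criterion input).
    """
    th = th or Thresholds()
    ctl, tol = list(sheet.control), list(sheet.tolerized)
    meth_cols = {s: f"meth_{s}" for s in sheet.samples}
    unmeth_cols = {s: f"unmeth_{s}" for s in sheet.samples}
    for c in list(meth_cols.values()) + list(unmeth_cols.values()):
        if c not in records.columns:
            raise ValueError(f"records table lacks column {c!r}")

    # per-chromosome position-sorted views for fast window slicing
    by_chrom: dict[str, pd.DataFrame] = {
        chrom: part.sort_values("pos", ignore_index=True)
        for chrom, part in records.groupby("chrom", sort=False)
    }

    rows = []
    for gene in genes:
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        start, end = promoter_window(gene, th.window_bp, clen)
        part = by_chrom.get(gene.chrom)
        if part is None:
            sub = None
        else:
            pos = part["pos"].to_numpy()
            lo, hi = np.searchsorted(pos, (start, end))
            sub = part.iloc[lo:hi]
        meth_rep = {s: 0 for s in sheet.samples}
        unmeth_rep = {s: 0 for s in sheet.samples}
        if sub is not None and len(sub):
            for s in sheet.samples:
                meth_rep[s] = int(sub[meth_cols[s]].sum())
                unmeth_rep[s] = int(sub[unmeth_cols[s]].sum())
        m_ctl = sum(meth_rep[s] for s in ctl)
        u_ctl = sum(unmeth_rep[s] for s in ctl)
        m_tol = sum(meth_rep[s] for s in tol)
        u_tol = sum(unmeth_rep[s] for s in tol)
        t_ctl, t_tol = m_ctl + u_ctl, m_tol + u_tol

        uncovered = t_ctl == 0 or t_tol == 0
        r_ctl = m_ctl / t_ctl if t_ctl else np.nan
        r_tol = m_tol / t_tol if t_tol else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            fc_rate = np.float64(r_tol) / np.float64(r_ctl)
        mean_m_ctl = m_ctl / len(ctl)
        mean_m_tol = m_tol / len(tol)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc_count = np.float64(mean_m_tol) / np.float64(mean_m_ctl)
        if uncovered:
            p = np.nan
            meth_class = "uncovered"
        else:
            p = fisher_exact_two_sided([[m_tol, u_tol], [m_ctl, u_ctl]])
            if fc_rate >= 2.0:
                meth_class = "up"
            elif fc_rate <= 0.5:
                meth_class = "down"
            else:
                meth_class = "unchanged"
        rows.append(
            {
                "gene_id": gene.gene_id,
                "window_start": start,
                "window_end": end,
                "M_ctl": m_ctl,
                "T_ctl": t_ctl,
                "r_ctl": r_ctl,
                "M_tol": m_tol,
                "T_tol": t_tol,
                "r_tol": r_tol,
                "fc_rate": float(fc_rate),
                "fc_count": float(fc_count),
                "p_meth": p,
                "meth_class": meth_class,
                "control_meth_count_sum": m_ctl,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def methylation_summary(results: pd.DataFrame) -> dict:
    """Counts/percentages of up/down/unchanged genes among covered genes."""
    if results.empty:
        raise ValueError("no methylation results to summarise")
    covered = results[results["meth_class"] != "uncovered"]
    n = len(covered)
    n_up = int((covered["meth_class"] == "up").sum())
    n_down = int((covered["meth_class"] == "down").sum())
    n_unchanged = n - n_up - n_down
    pct_up, pct_down, pct_unch = largest_remainder_percentages([n_up, n_down, n_unchanged])
    return {
        "n_covered": n,
        "n_up": n_up,
        "n_down": n_down,
        "n_unchanged": n_unchanged,
        "pct_up": pct_up,
        "pct_down": pct_down,
        "pct_unchanged": pct_unch,
        "pct_altered": round(pct_up + pct_down, 2),
    }


def context_summary(reports: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-sample tally of methylated cytosines by context.

    A cytosine counts as methylated when it has at least one methylated
    call. Context percentages are relative to the sample's total number of
    methylated cytosines (NaN when that total is zero); ``cpg_rate`` is the
    pooled methylation rate over all CpG records.
    """
    rows = []
    for sample, df in reports.items():
        methylated = df[df["meth_count"] > 0]
        total = len(methylated)
        row: dict[str, object] = {"sample": sample, "total_methylated": total}
        for ctx in CONTEXTS:
            n_ctx = int((methylated["context"] == ctx).sum())
            row[f"pct_{ctx}"] = 100.0 * n_ctx / total if total else np.nan
        cpg = df[df["context"] == "CpG"]
        calls = int(cpg["meth_count"].sum() + cpg["unmeth_count"].sum())
        row["cpg_rate"] = float(cpg["meth_count"].sum()) / calls if calls else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
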