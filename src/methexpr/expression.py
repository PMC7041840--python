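"""FPKM quantification and differential-expression statistics.

Expression change between tolerized and control T cells is scored per gene
as the ratio of group-mean FPKM values, with significance from a two-sided
Fisher's exact test on the pooled raw counts (the gene's reads versus all
other reads, tolerized versus control). Genes are classed up-regulated at
fold change >= 2, down-regulated at <= 0.5 (inclusive thresholds).

A small pseudocount (``pseudo_fpkm``) is added to both group means before
the ratio so that genes undetected in controls get large-but-finite fold
changes instead of divisions by zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import CountMatrix, GeneModel, SampleSheet

__all__ = [
    "Thresholds",
    "compute_fpkm",
    "fisher_exact_two_sided",
    "fisher_exact_greater",
    "coefficient_of_variation",
    "differential_expression",
    "expression_summary",
    "largest_remainder_percentages",
]


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the whole pipeline.

    fc_up / fc_down — expression fold-change cutoffs (inclusive).
    alpha — raw-p significance level for both Fisher tests.
    meth_fc_relaxed — methylation-rate fold cutoff for the joint candidate
        cascade (<= 0.9); meth_fc_strict — cutoff for the demethylated-gene
        list (<= 0.5).
    count_fc_max — methylated-count fold must not exceed this ("decreased
        or remained unchanged", i.e. <= 1.0).
    min_control_meth_count — minimum summed methylated calls over the
        control replicates in the promoter window.
    window_bp — promoter window size upstream of the TSS.
    pseudo_fpkm — denominator floor for expression fold changes.
    """

    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    meth_fc_relaxed: float = 0.9
    meth_fc_strict: float = 0.5
    count_fc_max: float = 1.0
    min_control_meth_count: int = 3
    window_bp: int = 10_000
    pseudo_fpkm: float = 1e-6

    def __post_init__(self) -> None:
        if not self.fc_down < 1.0 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudo_fpkm <= 0:
            raise ValueError("pseudo_fpkm must be positive")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------


def compute_fpkm(counts: CountMatrix, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """FPKM matrix: count / ((gene_length / 1e3) * (library_size / 1e6))."""
    lengths = {g.gene_id: g.gene_length for g in genes}
    missing = [gid for gid in counts.gene_ids if gid not in lengths]
    if missing:
        raise ValueError(f"no gene model (length) for gene(s): {missing[:5]}")
    if (counts.library_size <= 0).any():
        bad = counts.library_size.index[counts.library_size <= 0].tolist()
        raise ValueError(f"non-positive library size for sample(s): {bad}")
    len_kb = np.array([lengths[g] for g in counts.gene_ids], dtype=float) / 1e3
    lib_m = counts.library_size.to_numpy(dtype=float) / 1e6
    fpkm = counts.counts.to_numpy(dtype=float) / (len_kb[:, None] * lib_m[None, :])
    return pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.sample_ids)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

_TIE_SLACK = np.log1p(1e-7)


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(np.asarray(n) - np.asarray(k) + 1)


def _validate_table(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any() or (arr != np.floor(arr)).any() or not np.isfinite(arr).all():
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in arr.ravel())
    if a + b + c + d == 0:
        raise ValueError("all-zero table: Fisher's exact test undefined")
    return a, b, c, d


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative integers.

    Sums the conditional hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's (ties compared with relative slack 1e-7).
    """
    a, b, c, d = _validate_table(table)
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    # log P(k) up to the constant -log C(n, c1), which cancels in the comparison
    logw = _log_comb(r1, k) + _log_comb(n - r1, c1 - k)
    log_obs = logw[a - lo]
    keep = logw <= log_obs + _TIE_SLACK
    logz = _log_comb(n, c1)
    p = float(np.exp(logw[keep] - logz).sum())
    return min(1.0, max(p, np.nextafter(0, 1)))


def fisher_exact_greater(table) -> float:
    """One-sided (over-representation) Fisher's exact p: P(X >= a)."""
    a, b, c, d = _validate_table(table)
    r1, c1, n = a + b, a + c, a + b + c + d
    hi = min(r1, c1)
    k = np.arange(a, hi + 1)
    logw = _log_comb(r1, k) + _log_comb(n - r1, c1 - k) - _log_comb(n, c1)
    return min(1.0, float(np.exp(logw).sum()))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def coefficient_of_variation(values: np.ndarray | Sequence[float]) -> float:
    """Sample CV (SD with n-1 denominator over the mean); NaN when mean is 0.

    For a gene detected in exactly one of three replicates, (x, 0, 0), this
    equals sqrt(3) ~ 1.732 regardless of x.
    """
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0 or v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / m)


def differential_expression(
    counts: CountMatrix,
    genes: Sequence[GeneModel],
    sheet: SampleSheet,
    th: Thresholds | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene expression statistics and up/down/unchanged classification.

    Returns a DataFrame indexed by gene_id with per-sample FPKM columns
    (``fpkm_<sample>``), group means, fold change, Fisher p on pooled
    counts, the CV over tolerized replicates, the number of tolerized
    replicates with nonzero FPKM, and ``expr_class``. Genes with zero
    counts in every sample are classed ``undetected`` and excluded from
    classification denominators downstream.

    With ``bh_adjust`` a Benjamini-Hochberg ``q_expr`` column is added
    (computed over detected genes); classification still uses raw p.
    """
    th = th or Thresholds()
    for grp in ("control", "tolerized"):
        if not sheet.group_samples(grp):
            raise ValueError(f"no samples in group {grp!r}")
    fpkm = compute_fpkm(counts, genes)
    ctl, tol = list(sheet.control), list(sheet.tolerized)

    mean_ctl = fpkm[ctl].mean(axis=1)
    mean_tol = fpkm[tol].mean(axis=1)
    fc = (mean_tol + th.pseudo_fpkm) / (mean_ctl + th.pseudo_fpkm)
    # classification uses the exact mean ratio (inf when control mean is 0)
    # so the inclusive >= / <= thresholds are not perturbed by the pseudocount
    ratio = np.divide(
        mean_tol.to_numpy(),
        mean_ctl.to_numpy(),
        out=np.full(len(fpkm), np.inf),
        where=mean_ctl.to_numpy() > 0,
    )

    gene_tol = counts.counts[tol].sum(axis=1).to_numpy()
    gene_ctl = counts.counts[ctl].sum(axis=1).to_numpy()
    tot_tol = int(gene_tol.sum())
    tot_ctl = int(gene_ctl.sum())
    detected = (gene_tol + gene_ctl) > 0
    pvals = np.full(len(fpkm), np.nan)
    for i, (gt, gc) in enumerate(zip(gene_tol, gene_ctl)):
        if detected[i]:
            pvals[i] = fisher_exact_two_sided(
                [[int(gt), tot_tol - int(gt)], [int(gc), tot_ctl - int(gc)]]
            )

    tol_fpkm = fpkm[tol].to_numpy()
    cv = np.array([coefficient_of_variation(row) for row in tol_fpkm])
    n_det_tol = (tol_fpkm > 0).sum(axis=1)

    expr_class = np.where(
        ~detected,
        "undetected",
        np.where(ratio >= th.fc_up, "up", np.where(ratio <= th.fc_down, "down", "unchanged")),
    )

    out = fpkm.add_prefix("fpkm_")
    out["mean_fpkm_control"] = mean_ctl
    out["mean_fpkm_tolerized"] = mean_tol
    out["fc_expr"] = fc
    out["p_expr"] = pvals
    out["cv"] = cv
    out["n_detected_tolerized"] = n_det_tol
    out["expr_class"] = expr_class
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        q = np.full(len(out), np.nan)
        mask = detected & np.isfinite(pvals)
        if mask.any():
            q[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
        out["q_expr"] = q
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


def largest_remainder_percentages(counts: Sequence[int], decimals: int = 2) -> list[float]:
    """Percentages of ``counts`` over their total, apportioned to ``decimals``
    places so they sum exactly to 100 (largest-remainder method).

    Plain independent rounding can drift the printed parts away from the
    printed whole; apportionment keeps class percentages additive.
    """
    counts = list(counts)
    total = sum(counts)
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    unit = 10 ** decimals
    raw = [c / total * 100 * unit for c in counts]
    floors = [int(np.floor(r)) for r in raw]
    shortfall = 100 * unit - sum(floors)
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - floors[i], counts[i]), reverse=True
    )
    for i in remainders[:shortfall]:
        floors[i] += 1
    return [f / unit for f in floors]


def expression_summary(results: pd.DataFrame) -> dict:
    """Counts and percentages of up/down/unchanged genes among detected genes."""
    if results.empty:
        raise ValueError("no expression results to summarise")
    detected = results[results["expr_class"] != "undetected"]
    n = len(detected)
    n_up = int((detected["expr_class"] == "up").sum())
    n_down = int((detected["expr_class"] == "down").sum())
    n_unchanged = n - n_up - n_down
    pct_up, pct_down, pct_unch = largest_remainder_percentages([n_up, n_down, n_unchanged])
    return {
        "n_detected": n,
        "n_up": n_up,
        "n_down": n_down,
        "n_unchanged": n_unchanged,
        "pct_up": pct_up,
        "pct_down": pct_down,
        "pct_unchanged": pct_unch,
        "pct_changed": round(pct_up + pct_down, 2),
    }
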