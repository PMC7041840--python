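"""Multi-criteria candidate-gene selection.

Three selection rules operate on the expression and promoter-methylation
result tables:

* ``select_top_expressed`` — highlights among significantly up-regulated
  genes: the top-N by fold change, genes detected in every tolerized
  replicate, and curated transcription regulators;
* ``select_demethylated`` — promoter-demethylated genes: rate fold
  <= 0.5, significant by Fisher's exact test, methylated-count fold not
  increased, and at least 3 methylated calls summed over the control
  replicates;
* ``select_candidates`` — the joint cascade for putative epigenetically
  up-regulated master-regulator candidates: expression fold >= 2.0 and
  significant, promoter methylation-rate fold <= 0.9, methylated-count
  fold <= 1.0.

All thresholds are inclusive and live on
:class:`methexpr.expression.Thresholds`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import Thresholds

__all__ = [
    "SelectionReport",
    "select_top_expressed",
    "select_demethylated",
    "select_candidates",
    "intersect_up_lists",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    """Per-criterion attrition through a selection cascade."""

    n_input: int
    steps: list[tuple[str, int]] = field(default_factory=list)
    n_excluded_unjoined: int = 0
    n_excluded_uncovered: int = 0
    selected: list[str] = field(default_factory=list)

    def add_step(self, name: str, n_surviving: int) -> None:
        if self.steps and n_surviving > self.steps[-1][1]:
            raise ValueError("cascade attrition must be monotone non-increasing")
        self.steps.append((name, n_surviving))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _p_column(df: pd.DataFrame, raw: str, adjusted: bool) -> pd.Series:
    if adjusted:
        q = raw.replace("p_", "q_")
        if q not in df.columns:
            raise ValueError(f"adjusted selection requested but column {q!r} is absent")
        return df[q]
    return df[raw]


def select_top_expressed(
    expr_results: pd.DataFrame,
    th: Thresholds | None = None,
    top_n: int = 10,
    n_tolerized: int = 3,
    tf_flags: pd.Series | None = None,
    adjusted: bool = False,
) -> pd.DataFrame:
    """Flag highlights among significantly up-regulated genes.

    Restricted to genes with p < alpha; flag ``a`` marks the ``top_n`` by
    fold change (ties broken by descending fold then gene_id), ``b`` marks
    genes with nonzero FPKM in all ``n_tolerized`` replicates, ``c`` marks
    transcription regulators (``tf_flags``: gene_id -> bool). Returns the
    union of flagged genes, sorted by descending fold change.
    """
    th = th or Thresholds()
    p = _p_column(expr_results, "p_expr", adjusted)
    if "expr_class" in expr_results.columns:
        up = expr_results["expr_class"] == "up"
    else:
        up = expr_results["fc_expr"] >= th.fc_up
    sig = expr_results[(p < th.alpha) & up].copy()
    if len(sig) < top_n:
        warnings.warn(
            f"only {len(sig)} significant up-regulated genes for top_n={top_n}",
            stacklevel=2,
        )
    # stable two-pass sort: gene_id ascending breaks fold-change ties
    ranked = sig.sort_index().sort_values("fc_expr", ascending=False, kind="mergesort")
    top_ids = set(ranked.index[:top_n])
    sig["flag_a"] = sig.index.isin(top_ids)
    sig["flag_b"] = sig["n_detected_tolerized"] == n_tolerized
    if tf_flags is None:
        sig["flag_c"] = False
    else:
        sig["flag_c"] = tf_flags.reindex(sig.index, fill_value=False).astype(bool)
    out = sig[sig[["flag_a", "flag_b", "flag_c"]].any(axis=1)]
    return out.sort_values("fc_expr", ascending=False)


def select_demethylated(meth_results: pd.DataFrame, th: Thresholds | None = None,
                        adjusted: bool = False) -> pd.DataFrame:
    """Promoter-demethylated genes by the four-part rule (see module docs).

    Uncovered genes are skipped (logged), not errors.
    """
    th = th or Thresholds()
    covered = meth_results[meth_results["meth_class"] != "uncovered"]
    n_skipped = len(meth_results) - len(covered)
    if n_skipped:
        logger.info("select_demethylated: skipping %d uncovered gene(s)", n_skipped)
    p = _p_column(covered, "p_meth", adjusted)
    keep = (
        (covered["fc_rate"] <= th.meth_fc_strict)
        & (p < th.alpha)
        & (covered["fc_count"] <= th.count_fc_max)
        & (covered["control_meth_count_sum"] >= th.min_control_meth_count)
    )
    return covered[keep].sort_values("fc_rate")


def select_candidates(
    expr_results: pd.DataFrame,
    meth_results: pd.DataFrame,
    th: Thresholds | None = None,
    adjusted: bool = False,
) -> tuple[pd.DataFrame, SelectionReport]:
    """The joint expression-up + promoter-demethylation cascade.

    A gene is selected iff all four flags hold: ``expr_up``
    (fc_expr >= fc_up), ``expr_sig`` (p_expr < alpha),
    ``meth_rate_drop_relaxed`` (fc_rate <= meth_fc_relaxed) and
    ``count_not_increased`` (fc_count <= count_fc_max). Genes present in
    only one input table, or uncovered in methylation, are excluded and
    counted in the report.
    """
    th = th or Thresholds()
    report = SelectionReport(n_input=len(set(expr_results.index) | set(meth_results.index)))
    joined = expr_results.join(meth_results, how="inner", lsuffix="", rsuffix="_meth")
    report.n_excluded_unjoined = report.n_input - len(joined)
    covered = joined[joined["meth_class"] != "uncovered"].copy()
    report.n_excluded_uncovered = len(joined) - len(covered)

    p_expr = _p_column(covered, "p_expr", adjusted)
    covered["expr_up"] = covered["fc_expr"] >= th.fc_up
    covered["expr_sig"] = p_expr < th.alpha
    covered["meth_rate_drop_relaxed"] = covered["fc_rate"] <= th.meth_fc_relaxed
    covered["count_not_increased"] = covered["fc_count"] <= th.count_fc_max
    flags = ["expr_up", "expr_sig", "meth_rate_drop_relaxed", "count_not_increased"]
    covered["selected"] = covered[flags].all(axis=1)

    report.add_step("joined_covered", len(covered))
    surviving = covered
    for flag in flags:
        surviving = surviving[surviving[flag]]
        report.add_step(flag, len(surviving))
    report.selected = sorted(surviving.index)

    cols = ["fc_expr", "p_expr", "fc_rate", "fc_count", "p_meth",
            "control_meth_count_sum", *flags, "selected"]
    out = covered[cols].sort_values("fc_expr", ascending=False)
    return out, report


def intersect_up_lists(list_a: pd.Series, list_b: pd.Series) -> pd.DataFrame:
    """Inner-join two gene -> fold-change maps, sorted by the second fold
    change descending (cross-study comparison of up-regulated gene lists)."""
    df = pd.DataFrame({"fc_a": list_a}).join(pd.DataFrame({"fc_b": list_b}), how="inner")
    df.index.name = "gene_id"
    return df.sort_values("fc_b", ascending=False)
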