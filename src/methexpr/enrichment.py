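"""Gene-set over-representation analysis.

For each annotation term, the selected gene set is tested against a
background universe with a one-sided (over-representation) Fisher's exact
test, and the effect size is reported as fold enrichment
(k/n) / (K/N) — the term's frequency inside the set over its frequency in
the background. The plain hypergeometric tail is used, without the EASE
-1 correction some annotation servers apply.
"""

from __future__ import annotations

import warnings
from typing import Collection, Mapping

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["enrich"]


def enrich(
    gene_set: Collection[str],
    term_map: Mapping[str, Collection[str]],
    background: Collection[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every term for over-representation in ``gene_set``.

    Genes outside the background are dropped with a warning; term sets are
    intersected with the background. Terms with no gene of the set
    annotated (k = 0) are omitted. Columns: k (annotated in set), n (set
    size), K (annotated in background), N (background size),
    fold_enrichment, p_value, significant; sorted by p ascending.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    gene_set = set(gene_set)
    stray = gene_set - background
    if stray:
        warnings.warn(
            f"dropping {len(stray)} gene(s) absent from the background", stacklevel=2
        )
        gene_set &= background
    n, N = len(gene_set), len(background)
    rows = []
    for term, members in term_map.items():
        members = set(members) & background
        K = len(members)
        k = len(gene_set & members)
        if k == 0 or n == 0:
            continue
        fold = (k / n) / (K / N)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term, "k": k, "n": n, "K": K, "N": N,
             "fold_enrichment": fold, "p_value": p, "significant": p < alpha}
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "k", "n", "K", "N", "fold_enrichment", "p_value", "significant"],
    )
    return out.sort_values("p_value", kind="mergesort", ignore_index=True)
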