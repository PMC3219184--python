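"""Local over-representation analysis with the jackknifed Fisher tail (EASE).

For a study gene list against a background universe and a gene-set
collection, each term gets the one-sided hypergeometric tail
P(X >= k) (Fisher) and the EASE score — the same tail with one overlapping
gene removed, P(X >= max(k - 1, 0)) — a conservative variant that
deliberately kills single-gene overlaps. Over-representation only; the
background should be the measurable universe (by default, genes surviving
the expression presence filter), not the genome.
"""

from __future__ import annotations

from typing import Iterable, Set

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection

__all__ = ["ease_enrichment"]


def ease_enrichment(study: Iterable[str], background: Iterable[str],
                    sets: GeneSetCollection) -> pd.DataFrame:
    """Per-term Fisher and EASE tails, sorted by EASE score.

    ``study`` must be a subset of ``background``; symbols are case-folded.
    Columns: term, k (study hits), n (study size), K (background hits),
    N (background size), fisher_p, ease_p, ease_q (Benjamini–Hochberg over
    the EASE scores).
    """
    study_set: Set[str] = {str(g).upper() for g in study}
    bg: Set[str] = {str(g).upper() for g in background}
    stray = sorted(study_set - bg)
    if stray:
        raise ValueError(f"study gene(s) not in background: {stray}")
    n = len(study_set)
    N = len(bg)
    rows = []
    for term, members in sets.items():
        members_bg = members & bg
        K = len(members_bg)
        if K == 0:
            continue
        k = len(members_bg & study_set)
        fisher_p = float(hypergeom.sf(k - 1, N, K, n))
        ease_p = float(hypergeom.sf(max(k - 1, 0) - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N,
                     "fisher_p": fisher_p, "ease_p": ease_p})
    result = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N",
                                         "fisher_p", "ease_p"])
    if len(result):
        _, q, _, _ = multipletests(result["ease_p"], method="fdr_bh")
        result["ease_q"] = q
        result = (result.sort_values(["ease_p", "term"])
                  .reset_index(drop=True))
    else:
        result["ease_q"] = []
    return result
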