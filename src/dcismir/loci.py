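"""Genomic clustering of miRNA loci and within-cluster co-expression.

miRNA transcribed from the same genomic neighborhood (polycistronic or
closely spaced loci) tend to be co-expressed. Loci are chained by
single-linkage along each chromosome — consecutive intervals whose gap (end
of the upstream interval to start of the downstream one, 0 if they overlap)
is at most the threshold merge — and every within-cluster pair's Pearson
correlation of −ΔCt across all samples is reported, together with the
fraction of clustered miRNA whose within-cluster correlations are all
positive and the exception pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import CtMatrix, LocusTable
from .integrate import _pearson_with_p

logger = logging.getLogger("dcismir")

__all__ = ["LocusCluster", "cluster_loci", "cluster_coexpression"]


@dataclass
class LocusCluster:
    """Group of miRNA loci chained within a gap threshold on one chromosome."""

    members: List[str]
    chromosome: str
    span: int                       # bp from first start to last end
    member_gaps: List[int]          # consecutive inter-locus gaps
    pairwise: List[Tuple[str, str, int, float]] = field(default_factory=list)
    # (mirna_a, mirna_b, gap_bp, pearson_r) for all member pairs


def _gap(upstream_end: int, downstream_start: int) -> int:
    return max(0, downstream_start - upstream_end)


def cluster_loci(loci: LocusTable, max_gap: int,
                 mirnas: Optional[List[str]] = None
                 ) -> Tuple[List[LocusCluster], Dict[str, int]]:
    """Single-linkage chaining of loci with consecutive gaps <= ``max_gap``.

    Singletons are excluded from the cluster list but counted in the report.
    ``mirnas`` restricts to a query set; queried miRNA without a locus are
    excluded with a warning.
    """
    t = loci.table
    if mirnas is not None:
        missing = sorted(set(mirnas) - set(t["mirna_id"]))
        if missing:
            logger.warning("no locus for %d queried miRNA: %s", len(missing), missing)
        t = t[t["mirna_id"].isin(set(mirnas))]
    clusters: List[LocusCluster] = []
    n_singletons = 0
    for chrom, sub in t.groupby("chrom"):
        sub = sub.sort_values(["start", "end"])
        current: List[pd.Series] = []
        gaps: List[int] = []

        def flush():
            nonlocal n_singletons
            if len(current) >= 2:
                clusters.append(LocusCluster(
                    members=[r.mirna_id for r in current],
                    chromosome=chrom,
                    span=int(current[-1].end - current[0].start),
                    member_gaps=list(gaps)))
            elif current:
                n_singletons += 1

        for _, row in sub.iterrows():
            if current:
                g = _gap(int(current[-1].end), int(row.start))
                if g <= max_gap:
                    gaps.append(g)
                    current.append(row)
                    continue
                flush()
                gaps = []
            current = [row]
        flush()
    clusters.sort(key=lambda c: (c.chromosome, c.members))
    report = {"n_clusters": len(clusters),
              "n_clustered_mirna": sum(len(c.members) for c in clusters),
              "n_singletons": n_singletons}
    return clusters, report


def cluster_coexpression(clusters: List[LocusCluster], dct: CtMatrix,
                         loci: Optional[LocusTable] = None) -> Dict:
    """Within-cluster pairwise Pearson correlations of −ΔCt across all samples.

    A clustered miRNA counts as positively correlated when *all* of its
    within-cluster pairs have r > 0; pairs with r <= 0 are listed as
    exceptions. Members filtered out upstream are skipped with a note.
    """
    expr = -dct.values
    locus_pos = None
    if loci is not None:
        locus_pos = loci.table.set_index("mirna_id")[["start", "end"]]
    skipped: List[str] = []
    exceptions: List[Tuple[str, str, float]] = []
    positive_status: Dict[str, bool] = {}
    for cluster in clusters:
        present = [m for m in cluster.members if m in expr.index]
        skipped.extend(m for m in cluster.members if m not in expr.index)
        cluster.pairwise = []
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                r, _p, _n = _pearson_with_p(expr.loc[a].to_numpy(float),
                                            expr.loc[b].to_numpy(float))
                gap = 0
                if locus_pos is not None and a in locus_pos.index and b in locus_pos.index:
                    ae, bs = sorted([(locus_pos.at[a, "start"], locus_pos.at[a, "end"]),
                                     (locus_pos.at[b, "start"], locus_pos.at[b, "end"])])
                    gap = _gap(int(ae[1]), int(bs[0]))
                cluster.pairwise.append((a, b, gap, r))
                for m in (a, b):
                    ok = bool(r > 0)
                    positive_status[m] = positive_status.get(m, True) and ok
                if not (r > 0):
                    exceptions.append((a, b, r))
    n_clustered = len(positive_status)
    n_positive = sum(positive_status.values())
    return {
        "n_clustered_mirna": n_clustered,
        "n_positively_correlated": n_positive,
        "fraction_positive": (n_positive / n_clustered) if n_clustered else float("nan"),
        "exception_pairs": [(a, b, float(r)) for a, b, r in exceptions],
        "skipped_members": sorted(set(skipped)),
    }
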