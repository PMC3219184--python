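"""miRNA:mRNA target-pair integration.

Candidate pairs are the intersection of the prediction programs (support from
all loaded programs by default), restricted to miRNA significant in the
configured comparison and genes in the selected differentially expressed set
(expanding a gene to each of its selected probes). Each pair's expression
correlation is the Pearson r between the miRNA's −ΔCt (log2-abundance
orientation, so that larger means more abundant) and the probe's log2 value
across the pooled normal + lesion samples; the sign of r classifies the pair
as inverse (the canonical signature of miRNA-mediated mRNA destabilization)
or coordinate, with non-computable or exactly-zero correlations set aside as
undefined rather than forced into either side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .containers import (GROUP_LESION, GROUP_NORMAL, CtMatrix,
                         ExpressionMatrix, PredictionSet)
from .microarray import GeneDEResult
from .qpcr import MirnaDEResult

logger = logging.getLogger("dcismir")

__all__ = [
    "IntegrationResult",
    "intersect_predictions",
    "restrict_to_dysregulated",
    "correlate_pairs",
    "classify_pairs",
    "summarize_pairs",
    "run_integration",
]


def intersect_predictions(preds: PredictionSet,
                          cfg: Optional[PipelineConfig] = None,
                          min_support: Optional[int] = None) -> pd.DataFrame:
    """Pairs predicted by at least ``min_support`` programs (default: all loaded)."""
    n_programs = len(preds.programs)
    if n_programs < 2:
        raise ValueError("need predictions from at least 2 programs")
    if min_support is None:
        min_support = cfg.min_program_support if cfg is not None else None
    if min_support is None:
        min_support = n_programs
    if min_support > n_programs:
        raise ValueError(f"min_program_support={min_support} exceeds the "
                         f"{n_programs} loaded programs")
    support = preds.support_counts()
    return (support[support["support"] >= min_support]
            .reset_index(drop=True))


def restrict_to_dysregulated(pairs: pd.DataFrame, mirna_de: MirnaDEResult,
                             gene_de: GeneDEResult,
                             comparison: str = "DCIS-HN") -> pd.DataFrame:
    """Keep pairs whose miRNA is significant in ``comparison`` and whose gene
    is selected; expand each gene to all of its selected probes (one row per
    probe, as with multi-probe genes)."""
    sig_mirna = set(mirna_de.significant_in(comparison))
    sel = gene_de.table[gene_de.table["selected"]]
    if not sig_mirna or sel.empty:
        logger.warning("empty differential-expression set(s); no pairs retained")
    gene_probes = (sel.reset_index(names="probe_id")
                   .loc[:, ["probe_id", "gene_symbol", "fold_change"]]
                   .rename(columns={"fold_change": "gene_fold"}))
    kept = pairs[pairs["mirna_id"].isin(sig_mirna)]
    out = kept.merge(gene_probes, on="gene_symbol", how="inner")
    fold_col = f"fold_{comparison}"
    out["mirna_fold"] = mirna_de.table.loc[out["mirna_id"], fold_col].to_numpy()
    return out.reset_index(drop=True)


def _pearson_with_p(x: np.ndarray, y: np.ndarray):
    """Pearson r and two-sided p via the t transform; (nan, nan) when either
    vector is constant or fewer than 3 complete observations remain."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return np.nan, np.nan, n
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0.0:
        return np.nan, np.nan, n
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


def correlate_pairs(pairs: pd.DataFrame, mirna_dct: CtMatrix,
                    expr: ExpressionMatrix) -> pd.DataFrame:
    """Attach Pearson r / p per pair, across all normal + lesion samples.

    The miRNA enters as −ΔCt so that larger = more abundant (raw Ct would flip
    every sign); the gene as its log2 probe value. Pairs with a constant
    vector are flagged undefined, never silently zero.
    """
    samples = [s for s in mirna_dct.annotation.sample_ids
               if mirna_dct.annotation.table.loc[s, "group"]
               in (GROUP_NORMAL, GROUP_LESION) and s in expr.values.columns]
    if len(samples) < 3:
        raise ValueError("fewer than 3 shared normal/lesion samples")
    mirna_mat = -mirna_dct.values[samples]
    expr_mat = expr.values[samples]

    out = pairs.copy()
    rs, ps, ns = [], [], []
    for mirna, probe in zip(out["mirna_id"], out["probe_id"]):
        if mirna not in mirna_mat.index or probe not in expr_mat.index:
            rs.append(np.nan), ps.append(np.nan), ns.append(0)
            continue
        r, p, n = _pearson_with_p(mirna_mat.loc[mirna].to_numpy(float),
                                  expr_mat.loc[probe].to_numpy(float))
        rs.append(r), ps.append(p), ns.append(n)
    out["pearson_r"] = rs
    out["corr_p"] = ps
    out["n_obs"] = ns
    return out


def classify_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Sign-based partition into inverse (r < 0), coordinate (r > 0) and
    undefined (r not computable, or exactly 0 — tie rule)."""
    out = pairs.copy()
    r = out["pearson_r"]
    out["pair_class"] = np.where(r < 0, "inverse",
                                 np.where(r > 0, "coordinate", "undefined"))
    out.loc[r.isna(), "pair_class"] = "undefined"
    return out


def summarize_pairs(pairs: pd.DataFrame) -> Dict[str, dict]:
    """Per-class pair, unique-miRNA and unique-gene counts (classes partition
    the retained pairs, so the class counts sum to the total)."""
    summary: Dict[str, dict] = {"total_pairs": int(len(pairs))}
    for cls in ("inverse", "coordinate", "undefined"):
        sub = pairs[pairs["pair_class"] == cls]
        summary[cls] = {"pairs": int(len(sub)),
                        "unique_mirna": int(sub["mirna_id"].nunique()),
                        "unique_genes": int(sub["gene_symbol"].nunique())}
    return summary


@dataclass
class IntegrationResult:
    pairs: pd.DataFrame          # mirna, fold, probe, gene, gene fold, r, p, class
    candidate_pairs: pd.DataFrame
    summary: Dict[str, dict]


def run_integration(preds: PredictionSet, mirna_de: MirnaDEResult,
                    gene_de: GeneDEResult, expr: ExpressionMatrix,
                    cfg: PipelineConfig,
                    comparison: str = "DCIS-HN") -> IntegrationResult:
    """Intersect → restrict to dysregulated → correlate → classify."""
    candidates = intersect_predictions(preds, cfg)
    retained = restrict_to_dysregulated(candidates, mirna_de, gene_de, comparison)
    retained = correlate_pairs(retained, mirna_de.normalized, expr)
    retained = classify_pairs(retained)
    cols = ["mirna_id", "mirna_fold", "probe_id", "gene_symbol", "gene_fold",
            "support", "pearson_r", "corr_p", "n_obs", "pair_class"]
    retained = retained[cols]
    return IntegrationResult(pairs=retained, candidate_pairs=candidates,
                             summary=summarize_pairs(retained))
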