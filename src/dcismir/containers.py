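"""In-memory containers shared by every pipeline stage.

All downstream modules consume these types; no module re-parses files. The
matrices are thin wrappers around :class:`pandas.DataFrame` (features × samples)
that carry the sample annotation (group membership and patient pairing) along
with them and enforce the design invariants at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_POOL",
    "GROUP_NORMAL",
    "GROUP_LESION",
    "GROUPS",
    "SampleAnnotation",
    "CtMatrix",
    "ExpressionMatrix",
    "PredictionSet",
    "LocusTable",
    "GeneSetCollection",
]

# Canonical group labels: pooled reference (PRM), histologically normal
# epithelium (HN) and the paired lesion (DCIS). Generic aliases are accepted
# on input and mapped to these.
GROUP_POOL = "PRM"
GROUP_NORMAL = "HN"
GROUP_LESION = "DCIS"
GROUPS = (GROUP_POOL, GROUP_NORMAL, GROUP_LESION)

_GROUP_ALIASES = {
    "PRM": GROUP_POOL,
    "REFERENCE_POOL": GROUP_POOL,
    "POOL": GROUP_POOL,
    "HN": GROUP_NORMAL,
    "NORMAL": GROUP_NORMAL,
    "DCIS": GROUP_LESION,
    "LESION": GROUP_LESION,
}


def canonical_group(label: str) -> str:
    try:
        return _GROUP_ALIASES[str(label).strip().upper()]
    except KeyError:
        raise ValueError(f"unknown sample group label {label!r}; "
                         f"expected one of {sorted(set(_GROUP_ALIASES))}") from None


@dataclass
class SampleAnnotation:
    """Sample → group/patient metadata.

    ``table`` is indexed by sample id with columns ``group`` (PRM/HN/DCIS),
    ``patient_id`` (null for pool replicates) and ``replicate_index``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"group", "patient_id", "replicate_index"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in annotation: {dup}")
        t["group"] = [canonical_group(g) for g in t["group"]]
        t["patient_id"] = t["patient_id"].astype("object").where(t["patient_id"].notna(), None)
        t["replicate_index"] = t["replicate_index"].astype(int)
        if (t["replicate_index"] < 1).any():
            raise ValueError("replicate_index must be >= 1")
        pool = t[t["group"] == GROUP_POOL]
        if pool["patient_id"].notna().any():
            raise ValueError("pool replicates must have null patient_id")
        self._check_pairing(t)
        self.table = t

    @staticmethod
    def _check_pairing(t: pd.DataFrame) -> None:
        hn = t[(t["group"] == GROUP_NORMAL) & t["patient_id"].notna()]
        dcis = t[(t["group"] == GROUP_LESION) & t["patient_id"].notna()]
        if len(hn) == 0 and len(dcis) == 0:
            return
        for grp, frame in ((GROUP_NORMAL, hn), (GROUP_LESION, dcis)):
            counts = frame["patient_id"].value_counts()
            if (counts > 1).any():
                bad = counts[counts > 1].index.tolist()
                raise ValueError(f"patient(s) {bad} have multiple {grp} samples")
        if set(hn["patient_id"]) != set(dcis["patient_id"]):
            raise ValueError(
                "patient pairing broken: HN patients "
                f"{sorted(set(hn['patient_id']))} vs DCIS patients "
                f"{sorted(set(dcis['patient_id']))}")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.table.index)

    def samples_in_group(self, group: str) -> List[str]:
        group = canonical_group(group)
        return list(self.table.index[self.table["group"] == group])

    def paired_samples(self) -> pd.DataFrame:
        """One row per patient with the HN and DCIS sample ids, sorted by patient."""
        t = self.table
        hn = t[t["group"] == GROUP_NORMAL].reset_index(names="hn_sample")
        dc = t[t["group"] == GROUP_LESION].reset_index(names="dcis_sample")
        merged = hn.merge(dc, on="patient_id", suffixes=("_hn", "_dcis"))
        return (merged[["patient_id", "hn_sample", "dcis_sample"]]
                .sort_values("patient_id").reset_index(drop=True))

    def subset(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        """Restrict to a sample subset. Rows were validated at construction;
        pairing completeness is an invariant of the declared design, not of a
        matrix's column subset, so it is not re-checked here."""
        new = SampleAnnotation.__new__(SampleAnnotation)
        new.table = self.table.loc[list(sample_ids)].copy()
        return new


@dataclass
class CtMatrix:
    """qPCR threshold-cycle values, features × samples, with group metadata.

    ``values`` entries equal to ``ct_max`` are censored (undetected);
    ``censored`` marks them explicitly so the floor/exclude policies can be
    applied downstream. ``normalized`` is False for raw Ct, True after
    global-median rescaling (ΔCt).
    """

    values: pd.DataFrame
    annotation: SampleAnnotation
    ct_max: float = 40.0
    normalized: bool = False
    normalization_target: Optional[float] = None
    offsets: Optional[pd.Series] = None  # per-sample median shift applied
    latent: Optional[pd.DataFrame] = None  # simulator-only: latent log2 abundance
    censored_mask: Optional[pd.DataFrame] = None  # set on normalized matrices

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        unknown = [c for c in self.values.columns if c not in self.annotation.table.index]
        if unknown:
            raise ValueError(f"samples missing from annotation: {unknown}")
        self.values = self.values.astype(float)
        # keep annotation restricted + ordered to the matrix columns
        self.annotation = self.annotation.subset(list(self.values.columns))

    @property
    def censored(self) -> pd.DataFrame:
        """Undetected entries. On raw matrices this is values at the ceiling;
        normalized matrices carry the pre-normalization mask along."""
        if self.censored_mask is not None:
            return self.censored_mask.loc[self.values.index, self.values.columns]
        return self.values >= self.ct_max

    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.index)

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.annotation.samples_in_group(group)]

    def replace_values(self, values: pd.DataFrame, **kw) -> "CtMatrix":
        params = dict(ct_max=self.ct_max, normalized=self.normalized,
                      normalization_target=self.normalization_target,
                      offsets=self.offsets, latent=self.latent,
                      censored_mask=self.censored_mask)
        params.update(kw)
        return CtMatrix(values=values, annotation=self.annotation, **params)


@dataclass
class ExpressionMatrix:
    """Log2-scale probe-set expression, probes × samples, with probe→gene map.

    ``gene_map`` maps probe id → gene symbol (upper-cased; None when the probe
    has no annotation). ``present`` holds boolean presence calls with the same
    shape as ``values``.
    """

    values: pd.DataFrame
    annotation: SampleAnnotation
    gene_map: pd.Series
    present: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe ids: {dup}")
        unknown = [c for c in self.values.columns if c not in self.annotation.table.index]
        if unknown:
            raise ValueError(f"samples missing from annotation: {unknown}")
        self.values = self.values.astype(float)
        self.annotation = self.annotation.subset(list(self.values.columns))
        gm = self.gene_map.reindex(self.values.index)
        gm = gm.where(gm.notna(), None)
        self.gene_map = gm.map(lambda g: None if g is None else str(g).upper())
        if self.present is not None:
            self.present = self.present.reindex(index=self.values.index,
                                                columns=self.values.columns).fillna(False)

    @property
    def probe_ids(self) -> List[str]:
        return list(self.values.index)

    def presence_fraction(self) -> pd.Series:
        if self.present is None:
            raise ValueError("no presence calls available")
        return self.present.mean(axis=1)

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.annotation.samples_in_group(group)]

    def replace_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        present = None
        if self.present is not None:
            present = self.present.loc[values.index, values.columns]
        return ExpressionMatrix(values=values, annotation=self.annotation,
                                gene_map=self.gene_map.loc[values.index],
                                present=present)


@dataclass
class PredictionSet:
    """miRNA→gene predictions from one or more programs.

    ``table`` has one record per (program, mirna_id, gene_symbol); duplicate
    records within a program (e.g. two releases of the same database) are
    collapsed at load time so intersection semantics operate on program
    identity only.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"program", "mirna_id", "gene_symbol"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"prediction table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["gene_symbol"] = t["gene_symbol"].astype(str).str.upper()
        t = t.drop_duplicates(subset=["program", "mirna_id", "gene_symbol"])
        self.table = t.reset_index(drop=True)

    @property
    def programs(self) -> List[str]:
        return sorted(self.table["program"].unique())

    def support_counts(self) -> pd.DataFrame:
        """(mirna_id, gene_symbol, support): number of programs predicting the pair."""
        out = (self.table.groupby(["mirna_id", "gene_symbol"], as_index=False)
               .agg(support=("program", "nunique")))
        return out


@dataclass
class LocusTable:
    """Genomic loci of miRNA, keyed by miRNA id. 0-based half-open intervals."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "mirna_id", "strand"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"locus table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["start"] = t["start"].astype(int)
        t["end"] = t["end"].astype(int)
        bad = t[t["end"] <= t["start"]]
        if len(bad):
            raise ValueError(f"loci with end <= start: {bad['mirna_id'].tolist()}")
        if t["mirna_id"].duplicated().any():
            dup = t.loc[t["mirna_id"].duplicated(), "mirna_id"].tolist()
            raise ValueError(f"duplicate miRNA loci: {dup}")
        self.table = (t.sort_values(["chrom", "start", "end"])
                      .reset_index(drop=True))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics); symbols upper-cased, members deduplicated."""

    sets: Dict[str, frozenset]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, frozenset] = {}
        for name, members in self.sets.items():
            members = frozenset(str(m).upper() for m in members)
            if not members:
                continue
            clean[name] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()
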