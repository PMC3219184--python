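"""Readers and writers for the tabular formats the pipeline touches.

Dialects kept deliberately plain: tab-separated matrices (first column =
feature id), BED for genomic loci, GMT for gene sets, YAML/JSON for
configuration and provenance. Undetected-Ct sentinel cells ("Undetermined",
"Undet.", "N/A", blank) all map to the configured Ct ceiling, because TaqMan
export dialects vary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import (CtMatrix, ExpressionMatrix, GeneSetCollection,
                         LocusTable, PredictionSet, SampleAnnotation)

logger = logging.getLogger("dcismir")

__all__ = [
    "UNDETECTED_SENTINELS",
    "read_annotation",
    "read_ct_table",
    "write_ct_table",
    "read_probe_map",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_prediction_tables",
    "write_prediction_table",
    "read_bed_loci",
    "write_bed_loci",
    "read_gmt",
    "write_gmt",
    "write_provenance",
]

#: Cell contents treated as "undetected" in Ct tables (case-insensitive).
UNDETECTED_SENTINELS = {"undetermined", "undet", "undet.", "na", "n/a", ""}

PathLike = Union[str, Path]


def read_annotation(path: PathLike) -> SampleAnnotation:
    """Read a sample annotation table (TSV: sample_id, group, patient_id, replicate_index)."""
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    if "sample_id" not in t.columns:
        raise ValueError(f"{path}: annotation must have a 'sample_id' column")
    t = t.set_index("sample_id")
    if "replicate_index" not in t.columns:
        t["replicate_index"] = 1
    if "patient_id" not in t.columns:
        t["patient_id"] = None
    return SampleAnnotation(t)


def write_annotation(ann: SampleAnnotation, path: PathLike) -> None:
    ann.table.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


def read_ct_table(path: PathLike, annotation: Union[SampleAnnotation, PathLike],
                  ct_max: float = 40.0) -> CtMatrix:
    """Read a raw Ct matrix (TSV, first column feature id, one column per sample).

    Undetected sentinel cells are stored as ``ct_max``; values above ``ct_max``
    are clipped to it. Unknown sample columns and non-numeric cells are hard
    errors naming the offending column / cell.
    """
    if not isinstance(annotation, SampleAnnotation):
        annotation = read_annotation(annotation)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    feature_col = raw.columns[0]
    raw = raw.set_index(feature_col)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicated feature row(s): {dup}")
    unknown = [c for c in raw.columns if c not in annotation.table.index]
    if unknown:
        raise ValueError(f"{path}: sample column(s) {unknown} not in annotation")

    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for row, cell in raw[col].items():
            cell_str = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if cell_str.lower() in UNDETECTED_SENTINELS:
                values.at[row, col] = ct_max
                continue
            try:
                values.at[row, col] = float(cell_str)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell_str!r} at feature {row!r}, "
                    f"sample {col!r}") from None
    values = values.clip(upper=ct_max)
    return CtMatrix(values=values, annotation=annotation, ct_max=ct_max)


def write_ct_table(ct: CtMatrix, path: PathLike, feature_col: str = "mirna_id") -> None:
    ct.values.rename_axis(feature_col).reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_probe_map(path: PathLike) -> pd.Series:
    """Read probe→gene map (TSV: probe_id, gene_symbol). Many-to-one allowed."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"}.issubset(t.columns):
        raise ValueError(f"{path}: probe map needs columns probe_id, gene_symbol")
    if t["probe_id"].duplicated().any():
        dup = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"{path}: duplicate probe ids in map: {dup}")
    return t.set_index("probe_id")["gene_symbol"].str.upper()


def read_expression_matrix(path: PathLike,
                           probe_map: Union[pd.Series, PathLike],
                           annotation: Union[SampleAnnotation, PathLike],
                           log_scale: bool = True,
                           presence_path: Optional[PathLike] = None) -> ExpressionMatrix:
    """Read a probe-set expression matrix.

    ``log_scale=False`` declares linear intensities, which are log2-transformed
    on load (negative values are an error). Probes absent from the probe map
    are retained with a null gene symbol and a logged warning. An optional
    presence matrix (same shape; truthy = present, or MAS-style P/M/A calls)
    attaches detection calls.
    """
    if not isinstance(probe_map, pd.Series):
        probe_map = read_probe_map(probe_map)
    if not isinstance(annotation, SampleAnnotation):
        annotation = read_annotation(annotation)
    raw = pd.read_csv(path, sep="\t")
    raw = raw.set_index(raw.columns[0])
    values = raw.astype(float)
    if not log_scale:
        if (values < 0).any().any():
            raise ValueError(f"{path}: negative linear intensities")
        values = np.log2(values.clip(lower=np.finfo(float).tiny))
    unmapped = [p for p in values.index if p not in probe_map.index]
    if unmapped:
        logger.warning("%d probe(s) missing from probe map (null gene): %s%s",
                       len(unmapped), unmapped[:5], "..." if len(unmapped) > 5 else "")
    present = None
    if presence_path is not None:
        pres_raw = pd.read_csv(presence_path, sep="\t")
        pres_raw = pres_raw.set_index(pres_raw.columns[0])
        present = pres_raw.map(_presence_call)
    gene_map = probe_map.reindex(values.index)
    return ExpressionMatrix(values=values, annotation=annotation,
                            gene_map=gene_map, present=present)


def _presence_call(cell) -> bool:
    s = str(cell).strip().upper()
    if s in {"P", "TRUE", "1", "1.0"}:
        return True
    if s in {"A", "M", "FALSE", "0", "0.0"}:
        return False
    raise ValueError(f"unrecognized presence call {cell!r}")


def write_expression_matrix(expr: ExpressionMatrix, path: PathLike,
                            presence_path: Optional[PathLike] = None) -> None:
    expr.values.rename_axis("probe_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.6g")
    if presence_path is not None and expr.present is not None:
        expr.present.astype(int).rename_axis("probe_id").reset_index().to_csv(
            presence_path, sep="\t", index=False)


def write_probe_map(gene_map: pd.Series, path: PathLike) -> None:
    (gene_map.rename("gene_symbol").rename_axis("probe_id").reset_index()
     .to_csv(path, sep="\t", index=False))


def read_prediction_tables(paths: Sequence[PathLike],
                           programs: Optional[Sequence[str]] = None) -> PredictionSet:
    """Read one prediction table per file (TSV: mirna_id, gene_symbol[, score]).

    ``programs`` gives the program label per file; default is the file stem.
    Two files carrying the same program label (two releases of one database)
    are treated as one program: the union of their pairs counts as support 1.
    An empty table for a declared program is an error; malformed lines are
    reported with their line number.
    """
    if programs is None:
        programs = [Path(p).stem for p in paths]
    if len(programs) != len(paths):
        raise ValueError("programs must match paths one-to-one")
    records: List[dict] = []
    for program, path in zip(programs, paths):
        n_before = len(records)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 2:
                raise ValueError(f"{path}: line 1: expected >= 2 tab-separated columns")
            ncol = len(header)
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != ncol:
                    raise ValueError(
                        f"{path}: line {lineno}: expected {ncol} fields, got {len(fields)}")
                records.append({"program": program, "mirna_id": fields[0],
                                "gene_symbol": fields[1]})
        if len(records) == n_before:
            raise ValueError(f"{path}: empty prediction table for program {program!r}")
    return PredictionSet(pd.DataFrame(records))


def write_prediction_table(pairs: pd.DataFrame, path: PathLike) -> None:
    pairs[["mirna_id", "gene_symbol"]].to_csv(path, sep="\t", index=False)


def read_bed_loci(path: PathLike) -> LocusTable:
    """Read miRNA loci from BED (0-based half-open; name column = miRNA id)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 4 columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            rows.append({"chrom": chrom, "start": int(start), "end": int(end),
                         "mirna_id": name, "strand": strand})
    return LocusTable(pd.DataFrame(rows))


def write_bed_loci(loci: LocusTable, path: PathLike) -> None:
    t = loci.table
    with open(path, "w") as fh:
        for _, r in t.iterrows():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.mirna_id}\t0\t{r.strand}\n")


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read gene sets from GMT (set name, description, member genes)."""
    sets: Dict[str, frozenset] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: GMT needs name, description, members")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            if not members:
                logger.warning("%s: line %d: empty gene set %r dropped", path, lineno, name)
                continue
            sets[name] = frozenset(m.upper() for m in members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in sorted(collection.items()):
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def sha256_of(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path: PathLike, config: PipelineConfig, seed: int,
                     inputs: Optional[Dict[str, PathLike]] = None,
                     extra: Optional[dict] = None) -> None:
    """Write a machine-readable run-provenance record (config, seed, input digests)."""
    record = {
        "config": config.to_dict(),
        "seed": int(seed),
        "inputs": {name: {"path": str(p), "sha256": sha256_of(p)}
                   for name, p in (inputs or {}).items()},
    }
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
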