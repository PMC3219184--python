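"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design end to end: a pooled reference made
by equal-mass RNA pooling of ``n_pool_individuals`` healthy profiles and run
in ``n_pool_replicates`` technical replicates (so the pool's across-replicate
variance is purely technical and smaller than the across-patient biological
variance — the property the pooled-reference variance correction addresses);
eight patient-paired normal/lesion Ct profiles with planted log2 effects and
abundance-driven detection dropout at the Ct ceiling; patient-matched
lognormal probe-set expression with planted fold changes; negative
miRNA→target coupling so the integration stage has recoverable truth; and
prediction tables with per-program sensitivity and decoy rates.

Randomness discipline: one global seed; every stage draws from a substream
derived deterministically from (seed, stage name), so adding a stage never
perturbs earlier draws and fixed seeds give bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import (GROUP_LESION, GROUP_NORMAL, GROUP_POOL, CtMatrix,
                         ExpressionMatrix, GeneSetCollection, LocusTable,
                         PredictionSet, SampleAnnotation)

__all__ = [
    "SimulationDesign",
    "simulate_ct_dataset",
    "simulate_expression_dataset",
    "simulate_prediction_tables",
    "simulate_loci",
    "simulate_gene_sets",
    "simulate_bundle",
    "write_bundle",
    "null_design",
    "planted_design",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of the global seed (stable across platforms)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class SimulationDesign:
    """Parameters of one synthetic study.

    Defaults mirror the study design being emulated: a 365-assay miRNA panel,
    eight patient pairs, a nine-individual pooled reference run in triplicate.
    ``n_probesets`` defaults to a 2 000-probe array surrogate. Noise scales are
    on the log2 scale: biological spread across individuals 0.5, qPCR technical
    replication 0.1 cycles, patient random effect 0.3 and residual 0.25 for the
    expression arrays. Detection dropout follows a logistic curve in the latent
    Ct (midpoint 38 cycles, steepness 1.5 per cycle), reproducing the pattern
    of low-abundance assays hitting the Ct ceiling.
    """

    n_mirna: int = 365
    n_probesets: int = 2000
    n_patients: int = 8
    n_pool_individuals: int = 9
    n_pool_replicates: int = 3
    planted_mirna_effects: Dict[str, float] = field(default_factory=dict)
    planted_gene_effects: Dict[str, float] = field(default_factory=dict)
    coupling: List[Tuple[str, str, float]] = field(default_factory=list)
    mirna_sd_biological: float = 0.5
    mirna_sd_technical: float = 0.1
    gene_sd_patient: float = 0.3
    gene_sd_residual: float = 0.25
    dropout_midpoint: float = 38.0
    dropout_steepness: float = 1.5
    program_specs: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"pictar": (1.0, 0.1),
                                 "targetscan": (1.0, 0.1),
                                 "miranda": (1.0, 0.1)})
    ct_max: float = 40.0
    ct_at_unit_abundance: float = 40.0
    mirna_abundance_range: Tuple[float, float] = (2.0, 14.0)
    planted_abundance_min: float = 6.0
    gene_mean_range: Tuple[float, float] = (4.0, 10.0)
    gene_detect_threshold: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_probesets", "n_patients",
                     "n_pool_individuals", "n_pool_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mirna_sd_biological", "mirna_sd_technical",
                     "gene_sd_patient", "gene_sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        mirnas = set(self.mirna_ids)
        probes = set(self.probe_ids)
        for m in self.planted_mirna_effects:
            if m not in mirnas:
                raise ValueError(f"planted effect references unknown miRNA {m!r}")
        for p in self.planted_gene_effects:
            if p not in probes:
                raise ValueError(f"planted effect references unknown probe {p!r}")
        for m, p, _slope in self.coupling:
            if m not in mirnas:
                raise ValueError(f"coupling references unknown miRNA {m!r}")
            if p not in probes:
                raise ValueError(f"coupling references unknown probe {p!r}")

    @property
    def mirna_ids(self) -> List[str]:
        return [f"miR-sim-{i + 1:04d}" for i in range(self.n_mirna)]

    @property
    def probe_ids(self) -> List[str]:
        return [f"PS{i + 1:05d}_at" for i in range(self.n_probesets)]

    @property
    def gene_map(self) -> pd.Series:
        """Deterministic probe→gene map; every tenth probe shares the previous
        probe's gene, emulating multi-probe genes on real arrays."""
        probes = self.probe_ids
        genes = []
        gi = 0
        for i in range(len(probes)):
            if i % 10 == 9 and i > 0:
                genes.append(genes[-1])  # second probe for the same gene
            else:
                gi += 1
                genes.append(f"GENE{gi:05d}")
        return pd.Series(genes, index=probes, name="gene_symbol")

    @property
    def patient_ids(self) -> List[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_patients)]

    def annotation(self) -> SampleAnnotation:
        rows = []
        for r in range(self.n_pool_replicates):
            rows.append({"sample_id": f"PRM_r{r + 1}", "group": GROUP_POOL,
                         "patient_id": None, "replicate_index": r + 1})
        for p in self.patient_ids:
            rows.append({"sample_id": f"HN_{p}", "group": GROUP_NORMAL,
                         "patient_id": p, "replicate_index": 1})
            rows.append({"sample_id": f"DCIS_{p}", "group": GROUP_LESION,
                         "patient_id": p, "replicate_index": 1})
        return SampleAnnotation(pd.DataFrame(rows).set_index("sample_id"))


def simulate_ct_dataset(design: SimulationDesign) -> CtMatrix:
    """Simulate the qPCR Ct matrix (pool replicates + paired HN/DCIS samples).

    Latent per-individual log2 abundances carry the biological spread; the
    pool is the arithmetic mean of linear-scale abundances (equal RNA-mass
    pooling) and is shared by all its technical replicates; Ct is inverse to
    log2 abundance with additive technical noise; values are censored to the
    Ct ceiling with logistic probability in the latent Ct. The latent log2
    abundance per sample is attached for downstream coupling.
    """
    ann = design.annotation()
    mirnas = design.mirna_ids
    n_f = len(mirnas)
    lo, hi = design.mirna_abundance_range
    rng_mu = substream(design.rng_seed, "mirna_means")
    mu = rng_mu.uniform(lo, hi, size=n_f)
    # planted/coupled miRNA draw their means from the quantifiable range:
    # an effect planted below the detection limit measures the detector,
    # not the test, and real studies report fold changes only for assays
    # that survive the nonexpression filter
    special = set(design.planted_mirna_effects) | {m for m, _, _ in design.coupling}
    if special:
        idx = [i for i, m in enumerate(mirnas) if m in special]
        floor = max(lo, design.planted_abundance_min)
        mu[idx] = rng_mu.uniform(floor, max(hi, floor + 1.0), size=len(idx))

    rng_pool = substream(design.rng_seed, "pool")
    lam_ind = mu[:, None] + rng_pool.normal(0.0, design.mirna_sd_biological,
                                            size=(n_f, design.n_pool_individuals))
    lam_pool = np.log2(np.mean(np.exp2(lam_ind), axis=1))

    rng_pat = substream(design.rng_seed, "patients")
    lam_base = mu[:, None] + rng_pat.normal(0.0, design.mirna_sd_biological,
                                            size=(n_f, design.n_patients))
    effects = np.array([design.planted_mirna_effects.get(m, 0.0) for m in mirnas])
    lam_hn = lam_base
    lam_dcis = lam_base + effects[:, None]

    latent = {}
    for r in range(design.n_pool_replicates):
        latent[f"PRM_r{r + 1}"] = lam_pool
    for j, p in enumerate(design.patient_ids):
        latent[f"HN_{p}"] = lam_hn[:, j]
        latent[f"DCIS_{p}"] = lam_dcis[:, j]
    latent_df = pd.DataFrame(latent, index=mirnas)[ann.sample_ids]

    rng_tech = substream(design.rng_seed, "ct_technical")
    noise = rng_tech.normal(0.0, design.mirna_sd_technical, size=latent_df.shape)
    ct = design.ct_at_unit_abundance - latent_df.to_numpy() + noise

    rng_drop = substream(design.rng_seed, "dropout")
    if np.isfinite(design.dropout_midpoint) and design.dropout_steepness > 0:
        p_drop = expit(design.dropout_steepness * (ct - design.dropout_midpoint))
        censored = rng_drop.random(size=ct.shape) < p_drop
    else:
        censored = np.zeros(ct.shape, dtype=bool)
    censored |= ct >= design.ct_max
    ct = np.where(censored, design.ct_max, ct)

    values = pd.DataFrame(ct, index=mirnas, columns=latent_df.columns)
    return CtMatrix(values=values, annotation=ann, ct_max=design.ct_max,
                    latent=latent_df)


def simulate_expression_dataset(design: SimulationDesign,
                                ct: Optional[CtMatrix] = None) -> ExpressionMatrix:
    """Simulate the patient-paired probe-set expression matrix (log2 scale).

    log2 expression = probe mean + patient random intercept + planted group
    effect (lesion only) + Σ coupling-slope × centered latent miRNA level +
    residual; exponentiating gives lognormal linear intensities by
    construction. Presence calls derive from a fixed detection threshold.
    Probes that are planted or coupled draw their means from the detectable
    upper range so the truth is measurable.
    """
    if design.coupling and ct is None:
        raise ValueError("coupling requires the simulated Ct dataset (latent miRNA levels)")
    ann = design.annotation()
    paired = ann.paired_samples()
    samples = list(paired["hn_sample"]) + list(paired["dcis_sample"])
    probes = design.probe_ids
    n_probes = len(probes)

    lo, hi = design.gene_mean_range
    rng_means = substream(design.rng_seed, "gene_means")
    means = rng_means.uniform(lo, hi, size=n_probes)
    special = set(design.planted_gene_effects) | {p for _, p, _ in design.coupling}
    if special:
        idx = [i for i, p in enumerate(probes) if p in special]
        floor = design.gene_detect_threshold + 2.0
        means[idx] = rng_means.uniform(max(lo, floor), max(hi, floor + 1.0), size=len(idx))

    rng_pat = substream(design.rng_seed, "gene_patient_effects")
    pat_eff = rng_pat.normal(0.0, design.gene_sd_patient,
                             size=(n_probes, design.n_patients))
    pat_of_sample = np.array([list(paired["patient_id"]).index(pid)
                              for pid in list(paired["patient_id"]) * 2])
    is_lesion = np.array([0] * len(paired) + [1] * len(paired))

    effects = np.array([design.planted_gene_effects.get(p, 0.0) for p in probes])
    expr = (means[:, None]
            + pat_eff[:, pat_of_sample]
            + effects[:, None] * is_lesion[None, :])

    if design.coupling:
        latent = getattr(ct, "latent", None)
        probe_pos = {p: i for i, p in enumerate(probes)}
        for mirna, probe, slope in design.coupling:
            if latent is not None and mirna in latent.index:
                level = latent.loc[mirna, samples].to_numpy()
            else:
                # fall back to the measured orientation-corrected level
                level = (ct.ct_max - ct.values.loc[mirna, samples]).to_numpy()
            expr[probe_pos[probe]] += slope * (level - level.mean())

    rng_resid = substream(design.rng_seed, "gene_residual")
    expr = expr + rng_resid.normal(0.0, design.gene_sd_residual, size=expr.shape)

    values = pd.DataFrame(expr, index=probes, columns=samples)
    present = values > design.gene_detect_threshold
    return ExpressionMatrix(values=values, annotation=ann,
                            gene_map=design.gene_map, present=present)


def simulate_prediction_tables(design: SimulationDesign) -> PredictionSet:
    """Simulate per-program miRNA→gene prediction tables.

    Each truly coupled (miRNA, gene) pair is emitted by each program with that
    program's sensitivity; every uncoupled pair is emitted independently at the
    program's decoy rate, so the all-program intersection enriches for truth.
    """
    gene_map = design.gene_map
    genes = sorted(set(gene_map))
    mirnas = design.mirna_ids
    true_pairs = sorted({(m, gene_map[p]) for m, p, _ in design.coupling})
    true_set = set(true_pairs)
    n_m, n_g = len(mirnas), len(genes)
    rng = substream(design.rng_seed, "predictions")

    frames = []
    gene_arr = np.array(genes, dtype=object)
    mirna_arr = np.array(mirnas, dtype=object)
    for program in sorted(design.program_specs):
        sens, decoy_rate = design.program_specs[program]
        if true_pairs:
            emitted = rng.random(len(true_pairs)) < sens
            kept = [pair for pair, e in zip(true_pairs, emitted) if e]
            if kept:
                frames.append(pd.DataFrame(kept, columns=["mirna_id", "gene_symbol"])
                              .assign(program=program))
        if decoy_rate > 0:
            mask = rng.random((n_m, n_g)) < decoy_rate
            mi, gi = np.nonzero(mask)
            decoys = pd.DataFrame({"mirna_id": mirna_arr[mi],
                                   "gene_symbol": gene_arr[gi]})
            if true_set:
                is_true = pd.MultiIndex.from_frame(decoys).isin(
                    pd.MultiIndex.from_tuples(true_pairs))
                decoys = decoys[~is_true]
            frames.append(decoys.assign(program=program))
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["mirna_id", "gene_symbol", "program"]))
    return PredictionSet(table[["program", "mirna_id", "gene_symbol"]])


def simulate_loci(design: SimulationDesign,
                  clusters: Sequence[Tuple[Sequence[str], Sequence[int]]],
                  locus_length: int = 85,
                  inter_cluster_gap: int = 10_000_000) -> LocusTable:
    """Place miRNA loci on a synthetic chromosome with the requested gaps.

    ``clusters`` is a list of (members, gaps): gaps[i] separates member i from
    member i+1 (interval end to next interval start). A singleton is a
    one-member cluster with no gaps.
    """
    rows = []
    pos = 1_000_000
    known = set(design.mirna_ids)
    for members, gaps in clusters:
        members = list(members)
        if len(gaps) != max(len(members) - 1, 0):
            raise ValueError("need one gap per consecutive member pair")
        for m in members:
            if m not in known:
                raise ValueError(f"locus for unknown miRNA {m!r}")
        for i, m in enumerate(members):
            rows.append({"chrom": "chrSim1", "start": pos, "end": pos + locus_length,
                         "mirna_id": m, "strand": "+"})
            pos += locus_length + (gaps[i] if i < len(gaps) else 0)
        pos += inter_cluster_gap
    return LocusTable(pd.DataFrame(rows))


def simulate_gene_sets(design: SimulationDesign, n_sets: int = 20,
                       set_size: int = 50) -> GeneSetCollection:
    """Random gene sets over the simulated gene universe, plus one set holding
    every coupled target gene (a guaranteed-enriched term for testing)."""
    genes = sorted(set(design.gene_map))
    rng = substream(design.rng_seed, "gene_sets")
    sets: Dict[str, frozenset] = {}
    for i in range(n_sets):
        size = min(set_size, len(genes))
        sets[f"SIM_SET_{i + 1:03d}"] = frozenset(
            rng.choice(genes, size=size, replace=False))
    coupled = {design.gene_map[p] for _, p, _ in design.coupling}
    if coupled:
        pad = rng.choice([g for g in genes if g not in coupled],
                         size=min(10, len(genes) - len(coupled)), replace=False)
        sets["SIM_COUPLED_TARGETS"] = frozenset(coupled) | frozenset(pad)
    return GeneSetCollection(sets=sets)


def null_design(seed: int = 0, n_mirna: int = 365, n_probesets: int = 2000,
                **kw) -> SimulationDesign:
    """The no-effect study: nothing planted, default noise and design sizes."""
    return SimulationDesign(n_mirna=n_mirna, n_probesets=n_probesets,
                            rng_seed=seed, **kw)


def planted_design(seed: int = 0,
                   n_mirna: int = 365, n_probesets: int = 2000,
                   n_mirna_effects: int = 10, mirna_effect_log2: float = 2.0,
                   n_gene_effects: int = 50, gene_effect_log2: float = 1.0,
                   n_coupled_pairs: int = 20, coupling_slope: float = -0.8,
                   **kw) -> SimulationDesign:
    """The planted-truth study: alternating-sign miRNA effects of |log2 FC| =
    ``mirna_effect_log2``, independent gene effects, and negatively coupled
    miRNA:probe pairs distributed over the affected miRNA."""
    design = SimulationDesign(n_mirna=n_mirna, n_probesets=n_probesets,
                              rng_seed=seed, **kw)
    mirnas = design.mirna_ids
    probes = design.probe_ids
    if n_mirna_effects > n_mirna:
        raise ValueError("more miRNA effects than miRNA")
    if n_gene_effects + n_coupled_pairs > n_probesets:
        raise ValueError("more planted probes than probe sets")
    mirna_effects = {mirnas[i]: mirna_effect_log2 * (1 if i % 2 == 0 else -1)
                     for i in range(n_mirna_effects)}
    gene_effects = {probes[i]: gene_effect_log2 * (1 if i % 2 == 0 else -1)
                    for i in range(n_gene_effects)}
    # couple probes disjoint from the independently planted ones, cycling
    # through the affected miRNA; exclude second-probe positions (i % 10 == 9)
    # so each coupled probe owns its gene symbol
    coupled_probes = [p for i, p in enumerate(probes)
                      if i >= n_gene_effects and i % 10 != 9][:n_coupled_pairs]
    affected = list(mirna_effects)
    coupling = [(affected[i % len(affected)], p, coupling_slope)
                for i, p in enumerate(coupled_probes)]
    return SimulationDesign(n_mirna=n_mirna, n_probesets=n_probesets,
                            planted_mirna_effects=mirna_effects,
                            planted_gene_effects=gene_effects,
                            coupling=coupling, rng_seed=seed, **kw)


def simulate_bundle(design: SimulationDesign):
    """Simulate every input the pipeline consumes, as in-memory objects."""
    ct = simulate_ct_dataset(design)
    expr = simulate_expression_dataset(design, ct)
    preds = simulate_prediction_tables(design)
    # cluster two same-direction miRNA (co-located loci are co-transcribed,
    # hence co-expressed); everything else gets singleton loci
    effects = design.planted_mirna_effects
    up = sorted(m for m, e in effects.items() if e > 0)
    affected = up if len(up) >= 2 else sorted(effects) or design.mirna_ids[:4]
    clusters = [(affected[:2], [10_000])] if len(affected) >= 2 else []
    others = [m for m in design.mirna_ids[:30] if m not in affected[:2]]
    clusters += [([m], []) for m in others[:10]]
    loci = simulate_loci(design, clusters)
    gene_sets = simulate_gene_sets(design)
    truth = {
        "mirna_effects": dict(design.planted_mirna_effects),
        "gene_effects": dict(design.planted_gene_effects),
        "coupled_pairs": [list(c) for c in design.coupling],
    }
    return {"ct": ct, "expr": expr, "predictions": preds, "loci": loci,
            "gene_sets": gene_sets, "truth": truth}


def write_bundle(design: SimulationDesign, outdir) -> Dict[str, str]:
    """Write the full synthetic input bundle (TSV/BED/GMT + truth JSON)."""
    import json
    from pathlib import Path

    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(design)
    paths: Dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = str(outdir / name)
        return paths[name]

    dio.write_annotation(bundle["ct"].annotation, _p("annotation.tsv"))
    dio.write_ct_table(bundle["ct"], _p("ct.tsv"))
    dio.write_expression_matrix(bundle["expr"], _p("expression.tsv"),
                                presence_path=_p("presence.tsv"))
    dio.write_probe_map(bundle["expr"].gene_map, _p("probe_map.tsv"))
    for program in bundle["predictions"].programs:
        sub = bundle["predictions"].table.query("program == @program")
        dio.write_prediction_table(sub, _p(f"predictions_{program}.tsv"))
    dio.write_bed_loci(bundle["loci"], _p("loci.bed"))
    dio.write_gmt(bundle["gene_sets"], _p("gene_sets.gmt"))
    with open(_p("truth.json"), "w") as fh:
        json.dump(bundle["truth"], fh, indent=2)
    return paths
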