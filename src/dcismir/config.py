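"""Pipeline configuration.

All tunable thresholds of the analysis live in :class:`PipelineConfig` so that
every stage reads the same, validated set of constants: the undetected-Ct
ceiling, the global-median normalization target, the significance tiers, the
presence filter, the posterior fold-change screen, and the genomic clustering
gaps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Validated bag of pipeline constants.

    Parameters
    ----------
    ct_max
        Threshold-cycle ceiling; Ct equal to this value means "undetected"
        (cycles, default 40).
    normalization_target
        Per-sample median after global-median rescaling (ΔCt units, default 12).
    alpha_nominal
        Per-comparison significance level for the miRNA t-tests (default 0.005).
    alpha_bonferroni
        Fixed Bonferroni cut; ``None`` (default) derives ``family_alpha / m``
        from the number of features actually tested, which reproduces 0.00025
        when m = 200.
    family_alpha
        Family-wise level used for the derived Bonferroni cut (default 0.05).
    fdr_level
        Benjamini–Hochberg false-discovery-rate level (default 0.05).
    presence_min_frac
        Minimum fraction of samples a probe set must be present in (default 0.15).
    posterior_hi, posterior_lo
        Posterior fold-change screen cutoffs (defaults 0.975 / 0.025).
    fc_screen
        Fold-change threshold inside the posterior screen (default 1.5; 1 gives
        the symmetric "any change" screen).
    fc_threshold
        Fold-change threshold for final gene selection (default 1.5).
    mixed_model_alpha
        Significance level for the patient-matched mixed model (default 0.05).
    cluster_gap_bp, tight_gap_bp
        Genomic gap thresholds for locus clustering (defaults 50 000 / 13 000 bp).
    min_program_support
        Programs that must predict a pair; ``None`` means "all loaded programs".
    pool_size
        Number of individuals contributing to the pooled reference; used as the
        default variance-inflation factor κ for pool-involving t-tests (default 9).
    censored_policy
        How censored Ct values (at ``ct_max``) enter normalization and group
        means: ``"floor"`` keeps them at the detection floor, ``"exclude"``
        drops them.
    filter_precedence
        Nonexpression-filter clause combination: ``"pool_or_both"`` is
        A ∨ (B ∧ C) (undetected in pool, OR undetected in both lesion groups);
        ``"or_and"`` is the alternative (A ∨ B) ∧ C reading.
    paired_dcis_hn
        Use a paired t-test for the lesion-vs-adjacent-normal comparison
        (default True); False gives an unpaired Welch test for sensitivity
        analysis.
    """

    ct_max: float = 40.0
    normalization_target: float = 12.0
    alpha_nominal: float = 0.005
    alpha_bonferroni: Optional[float] = None
    family_alpha: float = 0.05
    fdr_level: float = 0.05
    presence_min_frac: float = 0.15
    posterior_hi: float = 0.975
    posterior_lo: float = 0.025
    fc_screen: float = 1.5
    fc_threshold: float = 1.5
    mixed_model_alpha: float = 0.05
    cluster_gap_bp: int = 50_000
    tight_gap_bp: int = 13_000
    min_program_support: Optional[int] = None
    pool_size: int = 9
    censored_policy: str = "floor"
    filter_precedence: str = "pool_or_both"
    paired_dcis_hn: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "alpha_nominal": self.alpha_nominal,
            "family_alpha": self.family_alpha,
            "fdr_level": self.fdr_level,
            "posterior_hi": self.posterior_hi,
            "posterior_lo": self.posterior_lo,
            "mixed_model_alpha": self.mixed_model_alpha,
        }
        if self.alpha_bonferroni is not None:
            probs["alpha_bonferroni"] = self.alpha_bonferroni
        for name, p in probs.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"{name} must lie in (0, 1); got {p!r}")
        if not (0.0 <= self.presence_min_frac <= 1.0):
            raise ValueError("presence_min_frac must lie in [0, 1]")
        if self.alpha_bonferroni is not None and self.alpha_bonferroni > self.alpha_nominal:
            raise ValueError("alpha_bonferroni must not exceed alpha_nominal")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")
        if self.fc_screen < 1.0:
            raise ValueError("fc_screen must be >= 1")
        if not (self.cluster_gap_bp >= self.tight_gap_bp > 0):
            raise ValueError("require cluster_gap_bp >= tight_gap_bp > 0")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.ct_max <= 0:
            raise ValueError("ct_max must be positive")
        if self.censored_policy not in ("floor", "exclude"):
            raise ValueError("censored_policy must be 'floor' or 'exclude'")
        if self.filter_precedence not in ("pool_or_both", "or_and"):
            raise ValueError("filter_precedence must be 'pool_or_both' or 'or_and'")

    def bonferroni_cut(self, n_tests: int) -> float:
        """Per-test Bonferroni cut: fixed override, else family_alpha / m."""
        if self.alpha_bonferroni is not None:
            return self.alpha_bonferroni
        if n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        return self.family_alpha / n_tests

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
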