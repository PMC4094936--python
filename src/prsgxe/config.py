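"""Simulation and run configuration.

The simulator emulates a two-cohort polygenic design: a large unrelated
discovery cohort with a continuous alcohol-problems phenotype, and a
twin-structured target cohort with a zero-inflated 0-30 alcohol-problems
sum score, two ordinal environment scales (parental knowledge, peer
deviance; 4-16, high = more risk), gene-environment correlation (rGE) and
a gene-by-environment interaction on the liability scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: the two environmental moderators carried through the whole pipeline
ENVIRONMENTS = ("parental_knowledge", "peer_deviance")

#: p-value thresholds of the default score series
DEFAULT_THRESHOLDS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)

#: integer range of both environment scales
ENV_SCALE = (4, 16)


def substream(seed: int, label: str) -> np.random.Generator:
    """Named, independent random substream derived from a single seed.

    Every stochastic stage draws from its own labelled stream so that
    changing one stage (e.g. adding permutations) never perturbs another.
    """
    tag = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def as_env_map(value, name: str) -> dict[str, float]:
    """Normalize a scalar or per-environment mapping to a full dict."""
    if isinstance(value, Mapping):
        unknown = set(value) - set(ENVIRONMENTS)
        if unknown:
            raise ValueError(f"{name}: unknown environment(s) {sorted(unknown)}")
        return {env: float(value.get(env, 0.0)) for env in ENVIRONMENTS}
    return {env: float(value) for env in ENVIRONMENTS}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-cohort study.

    Defaults mirror the structure of the motivating design: a ~4,300-person
    discovery cohort, ~580 twin pairs (46% MZ), additive heritability 0.34,
    environment main effects sized to yield environment-outcome correlations
    around 0.3, and small positive liability-scale rGE (0.05 / 0.08).
    The SNP panel (n_snps) is a scaled-down stand-in for a genome-wide
    panel; LD is block-wise with a first-order latent correlation.
    """

    n_discovery: int = 4304
    n_target_pairs: int = 581
    prop_mz: float = 0.456
    n_snps: int = 3000
    n_causal: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.6
    h2_additive: float = 0.34
    env_main_effects: Mapping[str, float] | float = field(
        default_factory=lambda: {"parental_knowledge": 0.30, "peer_deviance": 0.35}
    )
    rge_corr: Mapping[str, float] | float = field(
        default_factory=lambda: {"parental_knowledge": 0.05, "peer_deviance": 0.08}
    )
    gxe_coef: Mapping[str, float] | float = 0.3
    phenotype_max: int = 30
    seed: int = 0

    # secondary knobs of the data-generating model
    sex_effect: float = 0.2          # liability shift for sex=1, in SD units
    env_twin_corr: float = 0.4       # within-pair corr of the non-genetic env part
    zero_fraction: float = 0.8       # share of the target cohort scoring 0
    count_scale: float = 0.45        # liability SD units per alcohol-problem point
    env_locations: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "parental_knowledge": (6.6, 2.1),
            "peer_deviance": (7.9, 3.1),
        }
    )
    mcar_rate: float = 0.0           # optional missing-completely-at-random dosage mask

    def __post_init__(self) -> None:
        self.env_main_effects = as_env_map(self.env_main_effects, "env_main_effects")
        self.rge_corr = as_env_map(self.rge_corr, "rge_corr")
        self.gxe_coef = as_env_map(self.gxe_coef, "gxe_coef")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.prop_mz <= 1.0:
            raise ValueError(f"prop_mz must be in [0, 1], got {self.prop_mz}")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not 0.0 <= self.h2_additive <= 1.0:
            raise ValueError("h2_additive must be in [0, 1]")
        for env, r in self.rge_corr.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"rge_corr[{env}] must be in (-1, 1)")
            if self.h2_additive == 0.0 and r != 0.0:
                raise ValueError(
                    f"rge_corr[{env}]={r} is infeasible with h2_additive=0 "
                    "(no genetic liability to correlate with)"
                )
        main_var = sum(b * b for b in self.env_main_effects.values())
        if self.h2_additive + main_var > 1.0:
            raise ValueError(
                "h2_additive plus implied environment main-effect variance exceeds 1"
            )
        if not 0.0 < self.zero_fraction < 1.0:
            raise ValueError("zero_fraction must be in (0, 1)")
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValueError("mcar_rate must be in [0, 1)")

    def stream(self, label: str) -> np.random.Generator:
        """Random substream for a named stage of the simulation."""
        return substream(self.seed, label)
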