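"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required columns of a SNP metadata table
SNP_COLUMNS = ("snp_id", "effect_allele", "other_allele")

#: required columns of a summary-statistics table
SUMSTATS_COLUMNS = ("snp_id", "effect_allele", "other_allele",
                    "beta", "se", "t_stat", "p_value", "n_used")

#: columns of a target cohort table
COHORT_COLUMNS = ("individual_id", "family_id", "zygosity", "sex",
                  "alcohol_problems", "parental_knowledge", "peer_deviance")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele dosages plus SNP metadata.

    dosage holds effect-allele counts in [0, 2] (fractional values allowed,
    as for imputed data); NaN marks a missing genotype. ``families`` is
    present for twin-structured cohorts and maps each individual to a
    family and zygosity.
    """

    individual_ids: np.ndarray
    snps: pd.DataFrame
    dosage: np.ndarray
    families: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individual_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snps)} SNPs"
            )
        for col in SNP_COLUMNS:
            if col not in self.snps.columns:
                raise ValueError(f"snps table missing required column {col!r}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < -1e-9) | (self.dosage > 2 + 1e-9)
        if np.any(bad & ~np.isnan(self.dosage)):
            raise ValueError("dosages must lie in [0, 2] (or be NaN for missing)")
        if self.snps["snp_id"].duplicated().any():
            dups = self.snps["snp_id"][self.snps["snp_id"].duplicated()].tolist()
            raise ValueError(f"duplicated snp_id(s): {dups[:5]}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def snp_indices(self, snp_ids) -> np.ndarray:
        """Column indices of the requested SNPs, in the order given."""
        lookup = pd.Series(np.arange(self.n_snps), index=self.snps["snp_id"])
        missing = [s for s in snp_ids if s not in lookup.index]
        if missing:
            raise KeyError(f"SNP(s) not in genotype matrix: {missing[:5]}")
        return lookup.loc[list(snp_ids)].to_numpy()

    def subset_individuals(self, individual_ids) -> "GenotypeMatrix":
        lookup = pd.Series(np.arange(self.n_individuals), index=self.individual_ids)
        rows = lookup.loc[list(individual_ids)].to_numpy()
        fam = None
        if self.families is not None:
            fam = self.families[self.families["individual_id"].isin(set(individual_ids))]
            fam = fam.reset_index(drop=True)
        return GenotypeMatrix(
            individual_ids=self.individual_ids[rows],
            snps=self.snps.copy(),
            dosage=self.dosage[rows],
            families=fam,
        )


@dataclass
class SimulatedCohort:
    """A simulated cohort: the observable table plus the latent truth.

    ``table`` is what the analysis pipeline sees (phenotype, sex,
    environments, family structure). ``latent`` carries the unobservable
    quantities the generator used (genetic value, liability, continuous
    environment latents) for calibration and oracle checks only.
    """

    table: pd.DataFrame
    latent: pd.DataFrame
    achieved_rge: dict[str, float] = field(default_factory=dict)


@dataclass
class ScoreSet:
    """Per-individual polygenic scores at one discovery p-value threshold."""

    threshold: float
    scores: pd.Series                 # indexed by individual_id
    n_snps_in_threshold: int          # SNPs meeting the threshold in discovery
    n_snps_used: int                  # of those, usable in the target cohort

    def __post_init__(self) -> None:
        if self.n_snps_used > self.n_snps_in_threshold:
            raise ValueError("n_snps_used cannot exceed n_snps_in_threshold")

    @property
    def overlap_fraction(self) -> float:
        if self.n_snps_in_threshold == 0:
            return float("nan")
        return self.n_snps_used / self.n_snps_in_threshold


@dataclass
class ModerationResult:
    """Moderated-regression fit: outcome ~ sex + score + environment + score x environment.

    ``coefficients`` rows follow the fixed entry order (intercept, sex,
    score, environment, interaction); ``delta_r2`` holds the hierarchical
    R-squared increments for the same entry order (excluding the intercept).
    Means/SDs of the raw score and environment are stored so predicted
    values can be formed on the original scales.
    """

    environment: str
    coefficients: pd.DataFrame
    delta_r2: pd.Series
    total_r2: float
    n: int
    score_mean: float
    score_sd: float
    env_mean: float
    env_sd: float
    sex_mean: float
    resid_sd: float
    outcome: str = "alcohol_problems"

    @property
    def interaction(self) -> pd.Series:
        """Coefficient row for the score x environment term."""
        return self.coefficients.loc["score_x_environment"]


@dataclass
class EnrichmentResult:
    """Set-based permutation test of SNP-level G x E enrichment."""

    environment: str
    observed_stat: float
    r_exceed: int                 # permutations whose statistic strictly exceeds observed
    n_perm: int
    n_top_snps_discovery: int
    n_available_target: int
    n_after_pruning: int
    n_individuals: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_after_pruning <= self.n_available_target
                <= self.n_top_snps_discovery):
            raise ValueError("SNP counts must be nested: pruned <= available <= discovery")
        if not 0 <= self.r_exceed <= self.n_perm:
            raise ValueError("r_exceed must lie in [0, n_perm]")

    @property
    def empirical_p(self) -> float:
        """(R + 1) / (N + 1); bounded below by 1/(N+1), never zero."""
        return (self.r_exceed + 1) / (self.n_perm + 1)

    def to_dict(self) -> dict:
        return {
            "environment": self.environment,
            "n_top_snps_discovery": self.n_top_snps_discovery,
            "n_available_target": self.n_available_target,
            "n_after_pruning": self.n_after_pruning,
            "n_individuals": self.n_individuals,
            "observed_stat": self.observed_stat,
            "r_exceed": self.r_exceed,
            "n_perm": self.n_perm,
            "empirical_p": self.empirical_p,
        }
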