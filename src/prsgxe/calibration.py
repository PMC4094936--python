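"""Monte-Carlo calibration studies run on the package's own pipeline.

Each helper repeats a miniature two-cohort study end to end (simulate
discovery + target, run the GWAS, build scores, fit the model of interest)
and collects the statistic whose sampling behaviour is being checked:

* :func:`null_interaction_pvalues` — sharp-null type-I behaviour of the
  score x environment interaction test. The null switches off every
  systematic effect except sex: h2 = 0, rGE = 0, interaction = 0 and
  environment main effects = 0. This is the null under which the OLS
  t-test's error assumptions hold, and there the test is exactly
  calibrated. With environment main effects on, the zero-inflated count
  outcome makes residual variance grow with the environment while the
  product regressor's scale grows with it too, so conventional standard
  errors understate the interaction's sampling variance and the test
  over-rejects (about 9% at these conditions, raw or log scale) — a
  scale artifact of skewed outcomes, not an implementation defect; the
  log-scale sensitivity analysis exists because of exactly this class of
  artifact. See the methods notes for the full measurement.
* :func:`power_replicates` — sign and rejection rate of the interaction
  estimate under a positive liability-scale interaction.
* :func:`permutation_null_pvalues` — distribution of the set-based
  permutation empirical p over replicate null datasets.
* :func:`falconer_replicates` — Falconer 2(rMZ - rDZ) applied to
  latent-liability twin correlations at a known additive heritability.

Problem sizes are scaled-down study designs (a few hundred discovery
individuals, a few hundred SNPs) chosen so each replicate preserves the
pipeline's structure; the full-size defaults live in
:class:`~prsgxe.config.SimulationConfig`.
"""

from __future__ import annotations

import numpy as np

from .association import drop_one_per_family, falconer_h2, twin_correlations
from .config import SimulationConfig
from .enrichment import ld_prune, permutation_test, select_top_snps
from .gwas import run_gwas
from .moderation import fit_moderation
from .scoring import build_scores
from .simulate import simulate_genotypes, simulate_phenotypes

#: sharp-null study design: no genotype or environment signal in the outcome
NULL_DESIGN = dict(n_discovery=600, n_target_pairs=550, n_snps=400,
                   n_causal=0, h2_additive=0.0, rge_corr=0.0, gxe_coef=0.0,
                   env_main_effects=0.0)

#: power study design: heritable outcome with a liability-scale interaction
POWER_DESIGN = dict(n_discovery=1000, n_target_pairs=550, n_snps=500,
                    n_causal=100, h2_additive=0.34)

#: permutation-calibration design: 634 independent individuals, null genome
PERM_DESIGN = dict(n_discovery=800, n_target_pairs=634, n_snps=800,
                   n_causal=0, h2_additive=0.0, rge_corr=0.0, gxe_coef=0.0)

#: twin design for heritability recovery on the latent scale
TWIN_DESIGN = dict(n_discovery=10, n_target_pairs=2000, n_snps=300,
                   n_causal=60, h2_additive=0.34, rge_corr=0.0, gxe_coef=0.0)


def _study(seed: int, design: dict, threshold: float = 0.05):
    """One mini two-cohort study; returns (target_geno, target_cohort, score)."""
    cfg = SimulationConfig(**design, seed=seed)
    disc_geno = simulate_genotypes(cfg, "discovery")
    disc = simulate_phenotypes(disc_geno, cfg)
    sumstats = run_gwas(disc_geno, disc.table["phenotype"],
                        covariates=disc.table[["sex"]])
    targ_geno = simulate_genotypes(cfg, "target")
    targ = simulate_phenotypes(targ_geno, cfg)
    score = build_scores(targ_geno, sumstats, thresholds=[threshold])[0]
    return targ_geno, targ, score, sumstats


def null_interaction_pvalues(n_reps: int, base_seed: int,
                             environment: str = "parental_knowledge") -> np.ndarray:
    """Interaction p-values over replicate sharp-null cohorts (n = 1,100)."""
    out = np.empty(n_reps)
    for rep in range(n_reps):
        _, targ, score, _ = _study(base_seed + rep, NULL_DESIGN)
        res = fit_moderation(targ.table, score, environment)
        out[rep] = res.interaction["p"]
    return out


def power_replicates(n_reps: int, base_seed: int,
                     environment: str = "parental_knowledge",
                     gxe_coef: float = 0.3):
    """(interaction b, interaction p) arrays under a positive interaction."""
    design = dict(POWER_DESIGN, gxe_coef=gxe_coef)
    bs, ps = np.empty(n_reps), np.empty(n_reps)
    for rep in range(n_reps):
        _, targ, score, _ = _study(base_seed + rep, design)
        res = fit_moderation(targ.table, score, environment)
        bs[rep] = res.interaction["b"]
        ps[rep] = res.interaction["p"]
    return bs, ps


def permutation_null_pvalues(n_reps: int, base_seed: int,
                             environment: str = "peer_deviance",
                             n_perm: int = 999,
                             cutoff: float = 0.12) -> np.ndarray:
    """Set-based permutation empirical p over replicate null datasets.

    The liberal selection cutoff keeps ~80 null SNPs in the set so the
    significant-|t| sum statistic is effectively continuous.
    """
    out = np.empty(n_reps)
    for rep in range(n_reps):
        seed = base_seed + rep
        targ_geno, targ, _, sumstats = _study(seed, PERM_DESIGN, threshold=0.5)
        top = select_top_snps(sumstats, cutoff=cutoff)
        singles = drop_one_per_family(targ.table, seed=seed)
        pruned = ld_prune(targ_geno, top,
                          individual_ids=singles["individual_id"].to_numpy())
        res = permutation_test(targ_geno, singles, environment, pruned,
                               n_perm=n_perm, seed=seed)
        out[rep] = res.empirical_p
    return out


def falconer_replicates(n_reps: int, base_seed: int) -> np.ndarray:
    """Falconer estimates from latent-liability twin correlations."""
    out = np.empty(n_reps)
    for rep in range(n_reps):
        cfg = SimulationConfig(**TWIN_DESIGN, seed=base_seed + rep)
        geno = simulate_genotypes(cfg, "target")
        cohort = simulate_phenotypes(geno, cfg)
        df = cohort.table[["individual_id", "family_id", "zygosity"]].assign(
            liability=cohort.latent["liability"].to_numpy())
        tc = twin_correlations(df, value="liability")
        out[rep] = falconer_h2(tc["MZ"], tc["DZ"])
    return out
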