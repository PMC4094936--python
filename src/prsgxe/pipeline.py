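"""End-to-end orchestration: simulate -> gwas -> score -> assoc -> moderate -> enrich.

A run is driven by a nested configuration dict (typically loaded from
YAML); every stage writes its text outputs under the run directory and
contributes counts, seeds and file digests to a JSON run manifest so that
a run can be audited and replayed exactly.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (associate_scores, drop_one_per_family, falconer_h2,
                          rge_correlations, twin_correlations)
from .config import DEFAULT_THRESHOLDS, ENVIRONMENTS, SimulationConfig, substream
from .enrichment import ld_prune, permutation_test, select_top_snps
from .gwas import run_gwas
from .io import (write_cohort, write_genotypes, write_scores, write_sumstats)
from .moderation import fit_moderation, log_sensitivity, predicted_values
from .scoring import build_scores
from .simulate import simulate_genotypes, simulate_phenotypes

ALL_STAGES = ("simulate", "gwas", "score", "assoc", "moderate", "enrich")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulation": {},
    "scoring": {"thresholds": list(DEFAULT_THRESHOLDS), "mode": "avg"},
    "moderation": {"score_threshold": 0.05,
                   "environments": list(ENVIRONMENTS)},
    "enrichment": {"cutoff": 1e-4, "r2_max": 0.50, "alpha": 0.05,
                   "n_perm": 100_000, "environments": list(ENVIRONMENTS)},
    "stages": list(ALL_STAGES),
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def pipeline_run(config: dict | None, outdir, seed: int | None = None) -> dict:
    """Execute the requested stages and return the run manifest.

    ``seed`` overrides the config seed; per-stage seeds are derived from
    it through named substreams and recorded in the manifest.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    manifest: dict = {
        "package": "prsgxe",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg["seed"],
        "stage_seeds": {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stages": stages,
        "outputs": {},
        "counts": {},
    }

    def _record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _digest(path)}

    def _stage_seed(label: str) -> int:
        s = int(substream(cfg["seed"], label).integers(0, 2**31 - 1))
        manifest["stage_seeds"][label] = s
        return s

    sim_cfg = SimulationConfig(**cfg["simulation"], seed=_stage_seed("simulate"))
    state: dict = {}

    current_stage = None
    try:
        if "simulate" in stages:
            current_stage = "simulate"
            disc_geno = simulate_genotypes(sim_cfg, "discovery")
            disc = simulate_phenotypes(disc_geno, sim_cfg)
            targ_geno = simulate_genotypes(sim_cfg, "target")
            targ = simulate_phenotypes(targ_geno, sim_cfg)
            state.update(disc_geno=disc_geno, disc=disc,
                         targ_geno=targ_geno, targ=targ)
            write_genotypes(disc_geno, outdir / "discovery.raw",
                            outdir / "panel.bim")
            write_genotypes(targ_geno, outdir / "target.raw")
            write_cohort(disc.table, outdir / "discovery_cohort.csv")
            write_cohort(targ.table, outdir / "target_cohort.csv")
            for name in ("discovery.raw", "target.raw", "panel.bim",
                         "discovery_cohort.csv", "target_cohort.csv"):
                _record(name, outdir / name)
            manifest["counts"]["achieved_rge"] = targ.achieved_rge
            tc = twin_correlations(targ.table)
            manifest["counts"]["twin_correlations"] = tc
            manifest["counts"]["falconer_h2"] = falconer_h2(tc["MZ"], tc["DZ"])

        if "gwas" in stages:
            current_stage = "gwas"
            disc, disc_geno = state["disc"], state["disc_geno"]
            sumstats = run_gwas(disc_geno, disc.table["phenotype"],
                                covariates=disc.table[["sex"]])
            state["sumstats"] = sumstats
            write_sumstats(sumstats, outdir / "discovery_gwas.tsv")
            _record("discovery_gwas.tsv", outdir / "discovery_gwas.tsv")
            manifest["counts"]["gwas_snps"] = int(len(sumstats))

        if "score" in stages:
            current_stage = "score"
            sc = cfg["scoring"]
            scores = build_scores(state["targ_geno"], state["sumstats"],
                                  thresholds=sc["thresholds"], mode=sc["mode"])
            state["scores"] = scores
            table1 = []
            for ss in scores:
                name = f"scores_p{ss.threshold:g}.profile"
                write_scores(ss, outdir / name, state["targ"].table)
                _record(name, outdir / name)
                table1.append({"threshold": ss.threshold,
                               "n_snps_in_threshold": ss.n_snps_in_threshold,
                               "n_snps_used": ss.n_snps_used,
                               "overlap_fraction": ss.overlap_fraction})
            manifest["counts"]["score_thresholds"] = table1

        if "assoc" in stages:
            current_stage = "assoc"
            targ = state["targ"]
            assoc = associate_scores(state["scores"], targ.table)
            assoc.to_csv(outdir / "association.csv", index=False)
            _record("association.csv", outdir / "association.csv")
            manifest["counts"]["mean_variance_explained"] = (
                assoc.attrs["mean_variance_explained"])
            score05 = min(state["scores"], key=lambda s: s.threshold)
            rge = rge_correlations(score05, targ.table)
            rge.to_csv(outdir / "rge.csv", index=False)
            _record("rge.csv", outdir / "rge.csv")
            singles = drop_one_per_family(targ.table,
                                          seed=_stage_seed("drop_one_assoc"))
            assoc_ind = associate_scores(state["scores"], singles)
            assoc_ind.to_csv(outdir / "association_independent.csv", index=False)
            _record("association_independent.csv",
                    outdir / "association_independent.csv")
            state["assoc"] = assoc

        if "moderate" in stages:
            current_stage = "moderate"
            mc = cfg["moderation"]
            targ = state["targ"]
            score = next(s for s in state["scores"]
                         if s.threshold == mc["score_threshold"])
            mod_rows = []
            for env in mc["environments"]:
                res = fit_moderation(targ.table, score, env)
                logres = log_sensitivity(targ.table, score, env)
                tab = res.coefficients.assign(
                    delta_r2=[np.nan, *res.delta_r2.to_numpy()],
                    environment=env, n=res.n)
                mod_rows.append(tab.reset_index())
                pv = predicted_values(res)
                pv.to_csv(outdir / f"predicted_{env}.csv", index=False)
                _record(f"predicted_{env}.csv", outdir / f"predicted_{env}.csv")
                manifest["counts"][f"moderation_{env}"] = {
                    "interaction_b": float(res.interaction["b"]),
                    "interaction_p": float(res.interaction["p"]),
                    "interaction_delta_r2": float(res.delta_r2["score_x_environment"]),
                    "log_interaction_b": float(logres.interaction["b"]),
                    "log_interaction_p": float(logres.interaction["p"]),
                    "n": res.n,
                }
                state[f"moderation_{env}"] = res
            pd.concat(mod_rows).to_csv(outdir / "moderation.csv", index=False)
            _record("moderation.csv", outdir / "moderation.csv")

        if "enrich" in stages:
            current_stage = "enrich"
            ec = cfg["enrichment"]
            targ = state["targ"]
            top = select_top_snps(state["sumstats"], cutoff=ec["cutoff"])
            singles = drop_one_per_family(targ.table,
                                          seed=_stage_seed("drop_one_enrich"))
            available = [s for s in top
                         if s in set(state["targ_geno"].snps["snp_id"])]
            pruned = ld_prune(state["targ_geno"], available, r2_max=ec["r2_max"],
                              individual_ids=singles["individual_id"].to_numpy())
            results = {}
            for env in ec["environments"]:
                res = permutation_test(
                    state["targ_geno"], singles, env, pruned,
                    n_perm=ec["n_perm"], seed=_stage_seed(f"perm_{env}"),
                    alpha=ec["alpha"],
                    n_top_snps_discovery=len(top),
                    n_available_target=len(available))
                results[env] = res.to_dict()
            (outdir / "enrichment.json").write_text(
                json.dumps(results, indent=2))
            _record("enrichment.json", outdir / "enrichment.json")
            manifest["counts"]["enrichment"] = results
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current_stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
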