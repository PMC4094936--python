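"""Readers and writers for the text formats the pipeline touches.

Genotypes travel as the PLINK .raw dialect (header ``FID IID PAT MAT SEX
PHENOTYPE`` followed by one ``<snpid>_<effect allele>`` column per SNP,
dosages as decimals, ``NA`` for missing) with a 6-column .bim-like TSV
carrying the allele metadata. Summary statistics use the conventional
``SNP A1 A2 BETA SE T P N`` whitespace table; scores use the .profile
dialect ``FID IID CNT SCORE``; cohorts are plain CSV. Readers validate and
reject malformed input rather than coercing it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import COHORT_COLUMNS, GenotypeMatrix, ScoreSet

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_genotypes(genotypes: GenotypeMatrix, raw_path, bim_path=None) -> None:
    """Write a GenotypeMatrix as PLINK .raw plus an optional .bim-like TSV."""
    snps = genotypes.snps
    cols = [f"{s}_{a}" for s, a in zip(snps["snp_id"], snps["effect_allele"])]
    if genotypes.families is not None:
        fam = genotypes.families.set_index("individual_id")
        fids = fam.loc[list(genotypes.individual_ids), "family_id"].to_numpy()
    else:
        fids = genotypes.individual_ids
    df = pd.DataFrame(genotypes.dosage, columns=cols)
    meta = pd.DataFrame({
        "FID": fids,
        "IID": genotypes.individual_ids,
        "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9,
    })
    pd.concat([meta, df], axis=1).to_csv(raw_path, sep=" ", index=False,
                                         na_rep="NA", float_format="%.17g")
    if bim_path is not None:
        write_bim(snps, bim_path)


def write_bim(snps: pd.DataFrame, path) -> None:
    """6-column .bim-like TSV: chrom, snp_id, cm, pos, effect, other."""
    out = pd.DataFrame({
        "chrom": snps.get("chrom", pd.Series(1, index=snps.index)),
        "snp_id": snps["snp_id"],
        "cm": 0,
        "pos": snps.get("pos", pd.Series(range(1, len(snps) + 1), index=snps.index)),
        "effect_allele": snps["effect_allele"],
        "other_allele": snps["other_allele"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bim(path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "snp_id", "cm", "pos",
                             "effect_allele", "other_allele"])
    if bim["snp_id"].duplicated().any():
        raise ValueError("duplicated snp_id in bim file")
    return bim


def read_genotypes(path, dialect: str = "raw", bim_path=None) -> GenotypeMatrix:
    """Parse a genotype table; ``dialect`` is 'raw' (PLINK .raw) or 'csv'.

    Effect alleles come from the ``<snpid>_<allele>`` column suffixes;
    other alleles from the companion bim file when given, else 'N'.
    Dosages outside [0, 2] are rejected with the offending line number.
    """
    if dialect == "raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"],
                         float_precision="round_trip")
        if list(df.columns[:6]) != _RAW_META:
            raise ValueError(
                f"malformed .raw header: expected leading columns {_RAW_META}, "
                f"got {list(df.columns[:6])}")
        snp_cols = list(df.columns[6:])
        meta, data = df[_RAW_META], df[snp_cols]
    elif dialect == "csv":
        df = pd.read_csv(path, na_values=["NA"], float_precision="round_trip")
        if "IID" not in df.columns:
            raise ValueError("csv genotype dialect requires an IID column")
        snp_cols = [c for c in df.columns if c not in _RAW_META]
        meta, data = df[[c for c in _RAW_META if c in df.columns]], df[snp_cols]
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    ids, alleles = [], []
    for c in snp_cols:
        if "_" not in c:
            raise ValueError(f"genotype column {c!r} lacks an _<allele> suffix")
        snp, allele = c.rsplit("_", 1)
        ids.append(snp)
        alleles.append(allele)
    dosage = data.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (dosage < 0) | (dosage > 2)
    bad &= ~np.isnan(dosage)
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ValueError(
            f"dosage outside [0, 2] at data line {row + 2} of {path}")

    other = ["N"] * len(ids)
    if bim_path is not None:
        bim = read_bim(bim_path).set_index("snp_id")
        other = [str(bim.loc[s, "other_allele"]) if s in bim.index else "N"
                 for s in ids]
    snps = pd.DataFrame({"snp_id": ids, "effect_allele": alleles,
                         "other_allele": other})
    fam = None
    if "FID" in meta.columns and not (meta["FID"] == meta["IID"]).all():
        fam = pd.DataFrame({
            "individual_id": meta["IID"].astype(str),
            "family_id": meta["FID"].astype(str),
            "zygosity": "unknown",
        })
    return GenotypeMatrix(individual_ids=meta["IID"].astype(str).to_numpy(),
                          snps=snps, dosage=dosage, families=fam)


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    """SNP A1 A2 BETA SE T P N tab-separated summary statistics."""
    out = sumstats.rename(columns={
        "snp_id": "SNP", "effect_allele": "A1", "other_allele": "A2",
        "beta": "BETA", "se": "SE", "t_stat": "T", "p_value": "P",
        "n_used": "N",
    })
    out[["SNP", "A1", "A2", "BETA", "SE", "T", "P", "N"]].to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    required = ["SNP", "A1", "A2", "BETA", "SE", "P", "N"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"summary statistics missing required column {col!r}")
    if ((df["P"] <= 0) | (df["P"] > 1)).any():
        row = int(df.index[(df["P"] <= 0) | (df["P"] > 1)][0])
        raise ValueError(f"p-value outside (0, 1] at data row {row} "
                         "(score weights need finite -log10 p)")
    out = df.rename(columns={
        "SNP": "snp_id", "A1": "effect_allele", "A2": "other_allele",
        "BETA": "beta", "SE": "se", "T": "t_stat", "P": "p_value",
        "N": "n_used",
    })
    if "t_stat" not in out.columns:
        out["t_stat"] = out["beta"] / out["se"]
    for col in ("beta", "se", "t_stat", "p_value"):
        out[col] = out[col].astype(float)
    out["n_used"] = out["n_used"].astype(int)
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Target cohort CSV with phenotype, sex, environments, family structure."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort table missing required column {col!r}")
    if not df["alcohol_problems"].dropna().between(0, 30).all():
        raise ValueError("alcohol_problems outside [0, 30]")
    for env in ("parental_knowledge", "peer_deviance"):
        if not df[env].dropna().between(4, 16).all():
            raise ValueError(f"{env} outside [4, 16]")
    counts = df.groupby("family_id")["individual_id"].size()
    if (counts > 2).any():
        raise ValueError("family_id appearing more than twice")
    return df


def write_scores(score: ScoreSet, path, cohort: pd.DataFrame | None = None) -> None:
    """One .profile-style TSV per threshold: FID IID CNT SCORE."""
    ids = score.scores.index.to_numpy()
    if cohort is not None:
        fid = cohort.set_index("individual_id").loc[ids, "family_id"].to_numpy()
    else:
        fid = ids
    pd.DataFrame({
        "FID": fid,
        "IID": ids,
        "CNT": score.n_snps_used,
        "SCORE": score.scores.to_numpy(),
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores(path, threshold: float) -> ScoreSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("IID", "CNT", "SCORE"):
        if col not in df.columns:
            raise ValueError(f"profile file missing required column {col!r}")
    n = int(df["CNT"].iloc[0])
    return ScoreSet(threshold=threshold,
                    scores=pd.Series(df["SCORE"].to_numpy(),
                                     index=pd.Index(df["IID"].astype(str),
                                                    name="individual_id")),
                    n_snps_in_threshold=n, n_snps_used=n)
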