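"""Phenotype pre-adjustment, per-SNP association, and polygenic scores.

The pipeline mirrors the standard PRS workflow: residualize the trait on
covariates once, regress the residual on each SNP dosage separately
(intercept included), and score target individuals as the dosage-weighted
sum of estimated effects passing a p-value threshold.  Binary traits are
analysed by linear regression on the 0/1 scale, consistent with correlating
scores against the observed phenotype.  No clumping: the simulator emits
independent loci.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .simdata import MISSING, GenotypeMatrix, PhenotypeTable


class AssocError(ValueError):
    pass


@dataclasses.dataclass
class GwasResult:
    """Per-SNP effects: columns SNP, BETA, SE, P, N, MONO."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"SNP", "BETA", "SE", "P", "N"}
        if not need <= set(self.table.columns):
            raise AssocError(f"GWAS table lacks columns {sorted(need - set(self.table.columns))}")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "GwasResult":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype={"SNP": str}))


@dataclasses.dataclass
class PRSResult:
    """Per-individual polygenic scores: columns IID, SCORE, N_SNPS."""

    table: pd.DataFrame

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "PRSResult":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype={"IID": str}))

    @property
    def ids(self) -> np.ndarray:
        return self.table["IID"].to_numpy()

    def scores(self, ids=None) -> np.ndarray:
        s = self.table.set_index("IID")["SCORE"]
        if ids is None:
            return s.to_numpy(dtype=float)
        return s.loc[list(ids)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------


def adjust_phenotype(
    pheno: PhenotypeTable, covariate_names=()
) -> PhenotypeTable:
    """OLS-residualize the trait on an intercept plus the named covariates.

    Returns a new table whose TRAIT column holds the residuals (mean zero);
    simulation-truth columns are carried through.  Binary traits are
    residualized on the 0/1 scale.
    """
    covariate_names = list(covariate_names)
    missing = [c for c in covariate_names if c not in pheno.table.columns]
    if missing:
        raise AssocError(f"covariates not in phenotype table: {missing}")
    y = pheno.table["TRAIT"].to_numpy(dtype=float)
    if covariate_names:
        x = pheno.table[covariate_names].to_numpy(dtype=float)
        if np.isnan(x).any() or np.isnan(y).any():
            raise AssocError("missing values in trait or covariates")
        design = sm.add_constant(x, has_constant="add")
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # name offending columns by incremental rank
            bad, r = [], 1  # constant column has rank 1
            for k, name in enumerate(covariate_names):
                r_new = np.linalg.matrix_rank(design[:, : k + 2])
                if r_new == r:
                    bad.append(name)
                r = r_new
            raise AssocError(f"collinear covariate columns: {bad}")
        resid = sm.OLS(y, design).fit().resid
    else:
        resid = y - y.mean()
    tab = pheno.table.copy()
    tab["TRAIT"] = resid
    return PhenotypeTable(tab, trait_type="quantitative")


def run_gwas(genotypes: GenotypeMatrix, adjusted: PhenotypeTable) -> GwasResult:
    """Simple linear regression of the residualized trait on each dosage.

    Vectorized across SNPs; missing dosages are mean-imputed per SNP.
    Monomorphic SNPs are emitted with BETA=0, P=1 and MONO=True.
    """
    common = [i for i in genotypes.ids if i in set(adjusted.ids)]
    n = len(common)
    if n < 3:
        raise AssocError(f"need >= 3 overlapping individuals, have {n}")
    geno = genotypes.subset(ids=common)
    y = adjusted.trait(common)
    x = geno.dosages.astype(float)
    if (geno.dosages == MISSING).any():
        p = geno.allele_freqs()
        x = np.where(geno.dosages == MISSING, 2.0 * p, x)

    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    mono = sxx <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, 0.0, sxy / np.where(mono, 1.0, sxx))
        sse = np.maximum(syy - beta * sxy, 0.0)
        df = n - 2
        se = np.sqrt(sse / df / np.where(mono, np.nan, sxx))
        t = beta / se
        p_val = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    # p in (0, 1]: perfect fits get a tiny floor, undefined tests get 1
    p_val = np.where(np.isfinite(p_val), p_val, np.where(beta != 0.0, 0.0, 1.0))
    p_val = np.clip(p_val, np.finfo(float).tiny, 1.0)
    p_val[mono] = 1.0
    tab = pd.DataFrame(
        {
            "SNP": geno.snp_ids,
            "BETA": beta,
            "SE": se,
            "P": p_val,
            "N": n,
            "MONO": mono,
        }
    )
    return GwasResult(tab)


def score_prs(
    genotypes: GenotypeMatrix, gwas: GwasResult, p_threshold: float = 1.0
) -> PRSResult:
    """score_i = sum over SNPs with p <= threshold of dosage_ik * beta_k.

    Missing dosages contribute their expectation 2 p_k beta_k (target-sample
    allele frequency).  SNPs are matched by id; the default threshold 1.0
    keeps every SNP (whole-genome score).
    """
    eff = gwas.table.set_index("SNP")
    shared = [s for s in genotypes.snp_ids if s in eff.index]
    if not shared:
        raise AssocError("no SNPs shared between genotypes and GWAS results")
    eff = eff.loc[shared]
    keep = eff["P"].to_numpy() <= p_threshold
    if not keep.any():
        raise AssocError(
            f"no SNPs pass p <= {p_threshold} (min p = {eff['P'].min():.3g})"
        )
    used = [s for s, k in zip(shared, keep) if k]
    sub = genotypes.subset(snps=used)
    beta = eff.loc[used, "BETA"].to_numpy(dtype=float)
    x = sub.dosages.astype(float)
    if (sub.dosages == MISSING).any():
        p = sub.allele_freqs()
        x = np.where(sub.dosages == MISSING, 2.0 * p, x)
    score = x @ beta
    tab = pd.DataFrame(
        {"IID": genotypes.ids, "SCORE": score, "N_SNPS": len(used)}
    )
    return PRSResult(tab)
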