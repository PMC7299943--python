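"""Family-structured genotype/phenotype simulation.

Builds nuclear-family pedigrees (two or three generations), drops biallelic
genotypes through them locus by locus under Mendelian transmission (loci
independent, no LD), and draws phenotypes from the additive + shared-family
decomposition

    y_j = g_j + f_j + e_j,

where g is a polygenic additive value built from standardized causal dosages,
f is an environmental effect shared by all members of a family, and e is an
independent residual.  Phenotypes are generated on a unit-variance scale:
var(g) = h2 (rescaled exactly in-sample), var(f) = f2, var(e) = 1 - h2 - f2.
A binary mode thresholds the liability at the empirical (1 - prevalence)
quantile.

All randomness flows from a single master seed; each stage (founder allele
frequencies, gene dropping, phenotypes) uses an independent stream derived
from the master seed by a fixed stream offset, so identical configs give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd

#: sentinel for an unknown parent (PLINK .fam convention)
UNKNOWN = "0"

MISSING = -1  # missing dosage code inside GenotypeMatrix.dosages

# fixed per-stage stream offsets under the master seed
_STREAM_FREQS = 1
_STREAM_GENEDROP = 2
_STREAM_PHENO = 3


def stage_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for stage `stream` under master `seed`."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


class SimulationConfigError(ValueError):
    """A SimulationConfig field is out of range (message names the field)."""


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulator.

    Parameters
    ----------
    n_families
        Number of independent families.
    sibship_size
        Children per mating (applies to every mating in the pedigree).
    n_generations
        2 (founder couple + sibship) or 3 (each child mates an unrelated
        spouse and has `sibship_size` children, creating grandparent /
        avuncular second-degree and cousin third-degree pairs).
    n_snps
        Number of independent biallelic SNPs.
    maf_range
        (low, high) of the uniform distribution founder alternate-allele
        frequencies are drawn from.
    h2
        Narrow-sense heritability of the simulated trait (variance of g).
    f2
        Shared-family variance fraction (variance of f); h2 + f2 <= 1.
    prevalence
        If set, a binary trait is produced by thresholding the liability so
        that a fraction `prevalence` of individuals are cases.
    causal_fraction
        Fraction of SNPs carrying nonzero effects.
    seed
        Master seed; every stream derives from it.
    """

    n_families: int = 100
    sibship_size: int = 3
    n_generations: int = 2
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.1, 0.5)
    h2: float = 0.5
    f2: float = 0.0
    prevalence: float | None = None
    causal_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise SimulationConfigError("n_families must be >= 1")
        if self.sibship_size < 1:
            raise SimulationConfigError("sibship_size must be >= 1")
        if self.n_generations not in (2, 3):
            raise SimulationConfigError("n_generations must be 2 or 3")
        if self.n_snps < 1:
            raise SimulationConfigError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise SimulationConfigError("maf_range must satisfy 0 < low <= high < 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise SimulationConfigError("h2 must be in [0, 1]")
        if not 0.0 <= self.f2 < 1.0:
            raise SimulationConfigError("f2 must be in [0, 1)")
        if self.h2 + self.f2 > 1.0:
            raise SimulationConfigError("h2 + f2 must be <= 1")
        if self.prevalence is not None and not 0.0 < self.prevalence < 1.0:
            raise SimulationConfigError("prevalence must be in (0, 1)")
        if not 0.0 < self.causal_fraction <= 1.0:
            raise SimulationConfigError("causal_fraction must be in (0, 1]")


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, dangling parent, dup id)."""


@dataclasses.dataclass
class Pedigree:
    """Directed parent links; the basis of the A matrix and gene dropping.

    `table` columns: iid, sire, dam, sex, family_id, generation.  Parents are
    either the iid of another record or `UNKNOWN`.
    """

    table: pd.DataFrame

    COLUMNS = ("iid", "sire", "dam", "sex", "family_id", "generation")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.table["iid"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def parents(self) -> dict[str, tuple[str, str]]:
        return {
            r.iid: (r.sire, r.dam)
            for r in self.table.itertuples(index=False)
        }

    def founders(self) -> np.ndarray:
        mask = (self.table["sire"] == UNKNOWN) & (self.table["dam"] == UNKNOWN)
        return self.table.loc[mask, "iid"].to_numpy()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = self.table["iid"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise PedigreeError(f"duplicated individual ids: {dups}")
        known = set(ids)
        for col in ("sire", "dam"):
            bad = sorted(
                set(self.table[col]) - known - {UNKNOWN}
            )
            if bad:
                raise PedigreeError(f"unknown {col} ids: {bad}")
        # cycle check via topological sort of the parent graph
        graph = {
            r.iid: [p for p in (r.sire, r.dam) if p != UNKNOWN]
            for r in self.table.itertuples(index=False)
        }
        try:
            TopologicalSorter(graph).prepare()
        except CycleError as err:
            raise PedigreeError(f"pedigree contains a cycle: {err.args[1]}") from err

    def topological_order(self) -> list[str]:
        """Ids with every parent preceding its offspring (stable: generation,
        then original row order)."""
        self.validate()
        order = self.table.sort_values(
            "generation", kind="stable"
        )["iid"].tolist()
        return order

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype={c: str for c in ("iid", "sire", "dam", "sex", "family_id")}))


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele counts in {0, 1, 2}; -1 flags missing."""

    ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray  # (n, m) int8
    freqs: np.ndarray | None = None  # per-SNP alt-allele freq; None -> sample

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.snp_ids)} SNPs"
            )
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency (stored, else sample estimate
        over non-missing calls)."""
        if self.freqs is not None:
            return np.asarray(self.freqs, dtype=float)
        d = self.dosages
        obs = d != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(obs, d, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
        return p

    def subset(self, ids=None, snps=None) -> "GenotypeMatrix":
        rows = slice(None)
        cols = slice(None)
        out_ids, out_snps = self.ids, self.snp_ids
        if ids is not None:
            pos = {v: i for i, v in enumerate(self.ids)}
            missing = [i for i in ids if i not in pos]
            if missing:
                raise KeyError(f"ids not in genotype matrix: {missing[:5]}")
            rows = np.array([pos[i] for i in ids])
            out_ids = np.asarray(list(ids), dtype=object)
        if snps is not None:
            pos = {v: i for i, v in enumerate(self.snp_ids)}
            cols = np.array([pos[s] for s in snps])
            out_snps = np.asarray(list(snps), dtype=object)
        dos = self.dosages[rows][:, cols] if snps is not None else self.dosages[rows]
        freqs = None
        if self.freqs is not None:
            freqs = np.asarray(self.freqs)[cols] if snps is not None else self.freqs
        return GenotypeMatrix(out_ids, out_snps, dos, freqs)

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages: missing imputed to 2p, then
        (w - 2p) / sqrt(2 p (1 - p)).  Errors on monomorphic SNPs."""
        p = self.allele_freqs()
        mono = (p <= 0.0) | (p >= 1.0) | ~np.isfinite(p)
        if mono.any():
            bad = list(self.snp_ids[mono][:10])
            raise ValueError(
                f"cannot standardize monomorphic SNPs (p in {{0,1}}): {bad}"
            )
        x = self.dosages.astype(float)
        x = np.where(self.dosages == MISSING, 2.0 * p, x)
        return (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


@dataclasses.dataclass
class PhenotypeTable:
    """Trait values (plus simulation truth and covariates) keyed by id.

    `table` columns: IID, TRAIT, TRUE_G, TRUE_F, then any covariates.
    """

    table: pd.DataFrame
    trait_type: str = "quantitative"  # or "binary"
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for col in ("IID", "TRAIT"):
            if col not in self.table.columns:
                raise ValueError(f"phenotype table lacks column {col}")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError("trait_type must be quantitative or binary")
        if self.trait_type == "binary":
            vals = set(self.table["TRAIT"].unique().tolist())
            if not vals <= {0, 1}:
                raise ValueError("binary traits must contain only {0, 1}")
        self.table = self.table.reset_index(drop=True)

    @property
    def ids(self) -> np.ndarray:
        return self.table["IID"].to_numpy()

    def trait(self, ids=None) -> np.ndarray:
        if ids is None:
            return self.table["TRAIT"].to_numpy(dtype=float)
        s = self.table.set_index("IID")["TRAIT"]
        return s.loc[list(ids)].to_numpy(dtype=float)

    def column(self, name: str, ids=None) -> np.ndarray:
        s = self.table.set_index("IID")[name]
        if ids is None:
            return s.to_numpy(dtype=float)
        return s.loc[list(ids)].to_numpy(dtype=float)

    def subset(self, ids) -> "PhenotypeTable":
        sub = self.table.set_index("IID").loc[list(ids)].reset_index()
        return PhenotypeTable(sub, self.trait_type, self.covariate_names)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        cols = ["IID", "TRAIT", "TRUE_G", "TRUE_F", *self.covariate_names]
        cols = [c for c in cols if c in self.table.columns]
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table[cols].to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, trait_type: str = "quantitative") -> "PhenotypeTable":
        tab = pd.read_csv(path, sep="\t", comment="#", dtype={"IID": str})
        covars = tuple(
            c for c in tab.columns if c not in ("IID", "TRAIT", "TRUE_G", "TRUE_F")
        )
        return cls(tab, trait_type, covars)


# ---------------------------------------------------------------------------
# pedigree generation
# ---------------------------------------------------------------------------

def generate_pedigree(config: SimulationConfig) -> Pedigree:
    """Nuclear-family pedigree: founder couples plus descendants.

    With ``n_generations == 3`` every generation-1 child mates an unrelated
    spouse (a new founder) and has ``sibship_size`` children, so the output
    contains grandparent/avuncular (second-degree) and first-cousin
    (third-degree) pairs.  Fully deterministic.
    """
    rows: list[tuple] = []
    for fam in range(config.n_families):
        fid = f"FAM{fam:04d}"
        pa, ma = f"{fid}_G0M", f"{fid}_G0F"
        rows.append((pa, UNKNOWN, UNKNOWN, "M", fid, 0))
        rows.append((ma, UNKNOWN, UNKNOWN, "F", fid, 0))
        children = []
        for s in range(config.sibship_size):
            iid = f"{fid}_G1S{s}"
            sex = "M" if s % 2 == 0 else "F"
            rows.append((iid, pa, ma, sex, fid, 1))
            children.append((iid, sex))
        if config.n_generations == 3:
            for s, (child, sex) in enumerate(children):
                spouse = f"{fid}_G1S{s}SP"
                sp_sex = "F" if sex == "M" else "M"
                rows.append((spouse, UNKNOWN, UNKNOWN, sp_sex, fid, 1))
                sire, dam = (child, spouse) if sex == "M" else (spouse, child)
                for c in range(config.sibship_size):
                    iid = f"{fid}_G2S{s}C{c}"
                    rows.append(
                        (iid, sire, dam, "M" if c % 2 == 0 else "F", fid, 2)
                    )
    ped = Pedigree(pd.DataFrame(rows, columns=list(Pedigree.COLUMNS)))
    ped.validate()
    return ped


def unrelated_pedigree(n: int, prefix: str = "U") -> Pedigree:
    """Degenerate pedigree of `n` mutually unrelated founders, each its own
    family.  Used to build unrelated discovery/target pools."""
    rows = [
        (f"{prefix}{i:05d}", UNKNOWN, UNKNOWN, "M" if i % 2 == 0 else "F",
         f"{prefix}FAM{i:05d}", 0)
        for i in range(n)
    ]
    return Pedigree(pd.DataFrame(rows, columns=list(Pedigree.COLUMNS)))


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig, freqs: np.ndarray | None = None
) -> GenotypeMatrix:
    """Drop genotypes through the pedigree, locus by locus.

    Founders draw each of their two alleles as Bernoulli(p) with p uniform on
    ``config.maf_range`` per SNP; every non-founder receives one allele
    sampled uniformly from each parent's pair at each locus.  Loci are
    independent (no LD).
    """
    pedigree.validate()  # raises on cycles before any sampling
    m = config.n_snps
    rng_f = stage_rng(config.seed, _STREAM_FREQS)
    rng_d = stage_rng(config.seed, _STREAM_GENEDROP)
    if freqs is None:
        p = rng_f.uniform(config.maf_range[0], config.maf_range[1], size=m)
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (m,):
            raise ValueError("freqs length must equal config.n_snps")

    order = pedigree.topological_order()
    row_of = {iid: k for k, iid in enumerate(order)}
    parent_of = pedigree.parents()
    n = len(order)
    hap = np.empty((n, m, 2), dtype=np.int8)
    for iid in order:
        i = row_of[iid]
        sire, dam = parent_of[iid]
        for slot, par in enumerate((sire, dam)):
            if par == UNKNOWN:
                hap[i, :, slot] = rng_d.random(m) < p
            else:
                pick = rng_d.integers(0, 2, size=m)
                hap[i, :, slot] = hap[row_of[par], np.arange(m), pick]
    dosages = hap.sum(axis=2, dtype=np.int8)

    # emit rows in the pedigree's own id order
    ped_ids = pedigree.ids
    perm = np.array([row_of[i] for i in ped_ids])
    snp_ids = np.array([f"SNP{k + 1:06d}" for k in range(m)], dtype=object)
    return GenotypeMatrix(ped_ids.copy(), snp_ids, dosages[perm])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: SimulationConfig,
) -> PhenotypeTable:
    """Draw y = g + f + e on a unit-variance scale.

    g is a weighted sum of standardized causal dosages with N(0, h2/M_causal)
    effects, rescaled so its in-sample variance is exactly h2.  f is drawn
    once per family_id with variance f2; e is iid with variance 1 - h2 - f2.
    Binary mode thresholds the liability at the empirical (1 - prevalence)
    quantile.
    """
    if config.h2 + config.f2 > 1.0:
        raise SimulationConfigError("h2 + f2 must be <= 1")
    rng = stage_rng(config.seed, _STREAM_PHENO)
    n = genotypes.n_individuals
    m = genotypes.n_snps

    # additive genetic value
    if config.h2 > 0.0:
        m_causal = max(1, int(round(config.causal_fraction * m)))
        if m_causal < m:
            causal = np.sort(rng.choice(m, size=m_causal, replace=False))
        else:
            causal = np.arange(m)
        p = genotypes.allele_freqs()
        poly = (p > 0.0) & (p < 1.0)
        causal = causal[poly[causal]]  # monomorphic SNPs cannot carry signal
        w = genotypes.subset(snps=genotypes.snp_ids[causal]).standardized()
        beta = rng.normal(0.0, np.sqrt(config.h2 / len(causal)), size=len(causal))
        g = w @ beta
        sd = g.std()
        if sd > 0:
            g *= np.sqrt(config.h2) / sd  # exact in-sample var(g) = h2
    else:
        g = np.zeros(n)

    # shared-family effect
    fam = (
        pedigree.table.set_index("iid")["family_id"]
        .loc[list(genotypes.ids)]
        .to_numpy()
    )
    if config.f2 > 0.0:
        fams, inverse = np.unique(fam, return_inverse=True)
        fam_eff = rng.normal(0.0, np.sqrt(config.f2), size=len(fams))
        f = fam_eff[inverse]
    else:
        f = np.zeros(n)

    e = rng.normal(0.0, np.sqrt(max(0.0, 1.0 - config.h2 - config.f2)), size=n)
    liability = g + f + e

    if config.prevalence is not None:
        thr = np.quantile(liability, 1.0 - config.prevalence)
        trait = (liability > thr).astype(int)
        trait_type = "binary"
    else:
        trait = liability
        trait_type = "quantitative"

    tab = pd.DataFrame(
        {"IID": genotypes.ids, "TRAIT": trait, "TRUE_G": g, "TRUE_F": f}
    )
    return PhenotypeTable(tab, trait_type=trait_type)
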