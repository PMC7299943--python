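"""Relationship matrices (G, A, H) and pairwise kinship.

Three ways of writing down how related two individuals are:

* **G** — the genomic relationship matrix from observed SNPs, G = WW'/M with
  per-SNP standardized dosages (raw 0/1/2 coding available behind a flag);
* **A** — the pedigree numerator relationship matrix via the tabular method,
  a_ii = 1 + a_sd/2 and a_ij = (a_j,sire(i) + a_j,dam(i))/2;
* **H** — the single-step matrix merging pedigree relationships of
  ungenotyped individuals with genomic relationships of genotyped ones:

      H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21
      H12 = A12 A22^-1 G
      H22 = G

  (subscript 1 = ungenotyped, 2 = genotyped).

Pairwise kinship uses the robust within-sample estimator

    phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j)),

counting double-heterozygous and opposite-homozygous SNPs, with degrees of
relatedness assigned by the standard powers-of-two threshold table
(1/2^(d+3/2) boundaries).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg

from .simdata import MISSING, GenotypeMatrix, Pedigree, UNKNOWN

DEGREE_MZ = "MZ/dup"
DEGREE_UNRELATED = "unrelated"

#: upper kinship bound of each degree bin; bins are lower-exclusive /
#: upper-inclusive, so a tie at a boundary goes to the closer (higher) degree.
KINSHIP_THRESHOLDS = (
    (0.3536, DEGREE_MZ),       # phi > 0.3536
    (0.1768, "1"),             # (0.1768, 0.3536]
    (0.0884, "2"),             # (0.0884, 0.1768]
    (0.0442, "3"),             # (0.0442, 0.0884]
)


class RelmatError(ValueError):
    pass


@dataclasses.dataclass
class RelationshipMatrix:
    """Labelled symmetric relationship matrix of kind G, A, or H."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # {"G", "A", "H"}

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise RelmatError(
                f"matrix shape {self.values.shape} inconsistent with {n} ids"
            )
        if self.kind not in ("G", "A", "H"):
            raise RelmatError("kind must be G, A or H")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > 1e-10:
            raise RelmatError(f"matrix not symmetric (max asymmetry {asym:.3g})")
        self.values = (self.values + self.values.T) / 2.0

    def __len__(self) -> int:
        return len(self.ids)

    def _pos(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise RelmatError(f"ids not in {self.kind} matrix: {missing[:5]}")
        return np.array([lookup[i] for i in ids], dtype=int)

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        r = self._pos(row_ids)
        c = r if col_ids is None else self._pos(col_ids)
        return self.values[np.ix_(r, c)]

    def subset(self, ids) -> "RelationshipMatrix":
        return RelationshipMatrix(
            np.asarray(list(ids), dtype=object), self.submatrix(ids), self.kind
        )

    # -- persistence: lower triangle TSV + id list ----------------------
    def write_tsv(self, path, header_comment: str | None = None) -> None:
        """(id_i, id_j, value) lower triangle at 12 significant digits, plus
        a companion `<path>.ids` file preserving id order."""
        with open(f"{path}.ids", "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("\n".join(map(str, self.ids)) + "\n")
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# kind={self.kind}\n")
            fh.write("id_i\tid_j\tvalue\n")
            for i in range(len(self.ids)):
                for j in range(i + 1):
                    fh.write(
                        f"{self.ids[i]}\t{self.ids[j]}\t{self.values[i, j]:.12g}\n"
                    )

    @classmethod
    def read_tsv(cls, path) -> "RelationshipMatrix":
        with open(f"{path}.ids") as fh:
            ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        kind = "G"
        with open(path) as fh:
            for ln in fh:
                if ln.startswith("# kind="):
                    kind = ln.strip().split("=", 1)[1]
                if not ln.startswith("#"):
                    break
        tab = pd.read_csv(path, sep="\t", comment="#", dtype={"id_i": str, "id_j": str})
        pos = {v: i for i, v in enumerate(ids)}
        vals = np.zeros((len(ids), len(ids)))
        ii = tab["id_i"].map(pos).to_numpy()
        jj = tab["id_j"].map(pos).to_numpy()
        vals[ii, jj] = tab["value"].to_numpy()
        vals[jj, ii] = tab["value"].to_numpy()
        return cls(np.asarray(ids, dtype=object), vals, kind)


@dataclasses.dataclass(frozen=True)
class KinshipEstimate:
    id_i: str
    id_j: str
    phi: float
    degree: str


# ---------------------------------------------------------------------------
# G
# ---------------------------------------------------------------------------

def compute_grm(genotypes: GenotypeMatrix, standardize: bool = True) -> RelationshipMatrix:
    """Genomic relationship matrix G = WW'/M.

    Default W is per-SNP standardized (missing imputed to 2p); with
    ``standardize=False`` the raw 0/1/2 coding is used verbatim (missing
    imputed to 2p on the raw scale).
    """
    if standardize:
        w = genotypes.standardized()
    else:
        p = genotypes.allele_freqs()
        w = genotypes.dosages.astype(float)
        w = np.where(genotypes.dosages == MISSING, 2.0 * p, w)
    g = (w @ w.T) / genotypes.n_snps
    return RelationshipMatrix(genotypes.ids.copy(), g, "G")


# ---------------------------------------------------------------------------
# A
# ---------------------------------------------------------------------------

def compute_a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders get diagonal 1 and mutual relationship 0; each non-founder row
    is the half-sum of its parents' rows, and the diagonal carries half the
    parents' mutual relationship as inbreeding.
    """
    order = pedigree.topological_order()  # validates; raises on bad parents
    row_of = {iid: k for k, iid in enumerate(order)}
    parent_of = pedigree.parents()
    n = len(order)
    a = np.zeros((n, n))
    for k, iid in enumerate(order):
        sire, dam = parent_of[iid]
        si = row_of.get(sire) if sire != UNKNOWN else None
        di = row_of.get(dam) if dam != UNKNOWN else None
        if k:
            row = np.zeros(k)
            if si is not None:
                row += 0.5 * a[si, :k]
            if di is not None:
                row += 0.5 * a[di, :k]
            a[k, :k] = row
            a[:k, k] = row
        a[k, k] = 1.0 + (0.5 * a[si, di] if si is not None and di is not None else 0.0)
    # back to the pedigree's id order
    perm = np.array([row_of[i] for i in pedigree.ids])
    return RelationshipMatrix(pedigree.ids.copy(), a[np.ix_(perm, perm)], "A")


# ---------------------------------------------------------------------------
# H
# ---------------------------------------------------------------------------

def compute_h_matrix(
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    genotyped_ids,
    blend: float = 0.0,
) -> RelationshipMatrix:
    """Single-step H matrix over all pedigree ids.

    ``genotyped_ids`` must equal G's ids as a set; the H22 block is exactly G
    (or the blended G when ``blend > 0``).  ``blend=t`` replaces G by
    (1-t)*G + t*A22, the usual remedy when A22 or the joint system is
    ill-conditioned; it is opt-in and never applied silently.
    """
    gset = set(genotyped_ids)
    if set(G.ids) != gset:
        raise RelmatError("genotyped_ids must coincide with G.ids")
    if not gset <= set(A.ids):
        raise RelmatError("genotyped_ids must be a subset of A.ids")

    ung = [i for i in A.ids if i not in gset]
    gen = list(G.ids)  # keep G's own ordering for the 22 block
    a11 = A.submatrix(ung) if ung else np.zeros((0, 0))
    a12 = A.submatrix(ung, gen) if ung else np.zeros((0, len(gen)))
    a22 = A.submatrix(gen)
    gmat = G.values.copy()
    if blend:
        if not 0.0 < blend < 1.0:
            raise RelmatError("blend must be in (0, 1)")
        gmat = (1.0 - blend) * gmat + blend * a22

    if ung:
        try:
            c22 = scipy.linalg.cho_factor(a22)
        except np.linalg.LinAlgError as err:
            raise RelmatError(
                "A22 is singular; consider blending the genomic matrix "
                "(blend=0.01, i.e. G <- 0.99*G + 0.01*A22) or fixing "
                "duplicated pedigree records"
            ) from err
        x = scipy.linalg.cho_solve(c22, a12.T)  # A22^-1 A21
        h11 = a11 + x.T @ (gmat - a22) @ x
        h12 = x.T @ gmat
    else:
        h11 = a11
        h12 = a12

    ids = list(ung) + gen
    n = len(ids)
    h = np.empty((n, n))
    k = len(ung)
    h[:k, :k] = h11
    h[:k, k:] = h12
    h[k:, :k] = h12.T
    h[k:, k:] = gmat  # H22 == G exactly
    hm = RelationshipMatrix(np.asarray(ids, dtype=object), h, "H")
    return hm.subset(A.ids)  # emit in A's id order


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def classify_degree(phi: float) -> str:
    """Degree of relatedness from a kinship coefficient.

    Bins are lower-exclusive / upper-inclusive: phi = 0.0442 is still third
    degree, phi = 0.3536 is still first degree.
    """
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    for bound, label in KINSHIP_THRESHOLDS:
        if phi > bound:
            return label
    # a tie at the outermost boundary still counts as related (3rd degree)
    if phi >= KINSHIP_THRESHOLDS[-1][0]:
        return "3"
    return DEGREE_UNRELATED


def estimate_kinship(genotypes: GenotypeMatrix, id_i: str, id_j: str) -> KinshipEstimate:
    """Robust pairwise kinship from shared SNPs.

    phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j)) over SNPs where both
    individuals are non-missing; requires >= 100 such SNPs.
    """
    gi = genotypes.subset(ids=[id_i]).dosages[0]
    gj = genotypes.subset(ids=[id_j]).dosages[0]
    both = (gi != MISSING) & (gj != MISSING)
    if both.sum() < 100:
        raise RelmatError(
            f"only {both.sum()} SNPs non-missing in both {id_i} and {id_j}; "
            "need >= 100"
        )
    xi, xj = gi[both], gj[both]
    n_hh = int(np.sum((xi == 1) & (xj == 1)))
    n_opp = int(np.sum(((xi == 0) & (xj == 2)) | ((xi == 2) & (xj == 0))))
    n_het_i = int(np.sum(xi == 1))
    n_het_j = int(np.sum(xj == 1))
    denom = n_het_i + n_het_j
    if denom == 0:
        raise RelmatError(
            f"kinship undefined for ({id_i}, {id_j}): no heterozygous SNPs"
        )
    phi = (n_hh - 2.0 * n_opp) / denom
    return KinshipEstimate(id_i, id_j, phi, classify_degree(phi))


def pairwise_kinship(genotypes: GenotypeMatrix) -> np.ndarray:
    """All-pairs kinship matrix (same estimator as :func:`estimate_kinship`),
    vectorized; pairs with a zero denominator get NaN."""
    d = genotypes.dosages
    valid = (d != MISSING).astype(np.float32)
    het = (d == 1).astype(np.float32)
    hom0 = (d == 0).astype(np.float32)
    hom2 = (d == 2).astype(np.float32)
    n_hh = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    n_het_pair = het @ valid.T + valid @ het.T  # het_i and het_j on shared SNPs
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hh - 2.0 * n_opp) / n_het_pair
    phi[n_het_pair == 0] = np.nan
    return phi.astype(float)


def kinship_estimates(
    genotypes: GenotypeMatrix, min_phi: float = 0.0442
) -> list[KinshipEstimate]:
    """KinshipEstimate list for every pair with phi above ``min_phi``
    (default: anything at least third degree)."""
    phi = pairwise_kinship(genotypes)
    out = []
    ids = genotypes.ids
    iu, ju = np.triu_indices(len(ids), k=1)
    for i, j in zip(iu, ju):
        v = phi[i, j]
        if np.isfinite(v) and v > min_phi:
            out.append(KinshipEstimate(ids[i], ids[j], float(v), classify_degree(float(v))))
    return out
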