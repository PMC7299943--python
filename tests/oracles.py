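"""Independent oracles used by the test suite.

Each oracle reaches the checked quantity by a different route than the
implementation: IBD relationships by brute-force gene dropping instead of
the tabular recursion, BLUP by Henderson's mixed-model equations instead of
the kernel solve, GBLUP by the explicit SNP-ridge system instead of the
relationship-matrix system.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from kinpred.simdata import Pedigree, UNKNOWN


def ibd_relationship_oracle(
    pedigree: Pedigree, n_rep: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Additive-relationship matrix by Monte-Carlo gene dropping.

    Founders carry unique allele labels; one unlinked locus is dropped
    through the pedigree ``n_rep`` times.  The relationship is twice the
    kinship: a_ij = 2 * P(two randomly drawn homologous alleles are IBD),
    averaged over the four allele-pair combinations (this also yields
    a_ii = 1 + F on the diagonal).  Matrix is in the pedigree's id order.
    """
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order()
    row_of = {iid: k for k, iid in enumerate(order)}
    parent_of = pedigree.parents()
    n = len(order)
    alleles = np.empty((n_rep, n, 2), dtype=np.int32)
    label = 0
    for iid in order:
        i = row_of[iid]
        sire, dam = parent_of[iid]
        for slot, par in enumerate((sire, dam)):
            if par == UNKNOWN:
                alleles[:, i, slot] = label
                label += 1
            else:
                pick = rng.integers(0, 2, size=n_rep)
                alleles[:, i, slot] = alleles[np.arange(n_rep), row_of[par], pick]
    a = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            same = sum(
                np.mean(alleles[:, i, x] == alleles[:, j, y])
                for x in (0, 1)
                for y in (0, 1)
            )
            a[i, j] = a[j, i] = 2.0 * same / 4.0
    perm = np.array([row_of[i] for i in pedigree.ids])
    return a[np.ix_(perm, perm)]


def henderson_blup_oracle(
    K: np.ndarray, y: np.ndarray, n_disc: int, sigma_g2: float, sigma_e2: float
) -> np.ndarray:
    """BLUP of all individuals by a dense solve of Henderson's mixed-model
    equations; the first ``n_disc`` individuals carry the phenotypes ``y``.
    Requires K to be invertible."""
    n = K.shape[0]
    z = np.zeros((n_disc, n))
    z[:, :n_disc] = np.eye(n_disc)
    x = np.ones((n_disc, 1))
    kinv = np.linalg.inv(K)
    top = np.hstack([x.T @ x / sigma_e2, x.T @ z / sigma_e2])
    bot = np.hstack([z.T @ x / sigma_e2, z.T @ z / sigma_e2 + kinv / sigma_g2])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([x.T @ y / sigma_e2, z.T @ y / sigma_e2])
    sol = np.linalg.solve(lhs, rhs)
    return sol[1:]  # genetic values; sol[0] is the mean


def snp_ridge_predict(
    w_disc: np.ndarray,
    w_targ: np.ndarray,
    y: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
) -> np.ndarray:
    """Target predictions from explicit ridge regression on standardized
    SNPs with per-SNP prior variance sigma_g2/M (the SNP-BLUP dual of
    GBLUP with G = WW'/M).  Solves the M x M system."""
    n, m = w_disc.shape
    lam = sigma_e2 / (sigma_g2 / m)
    v = (sigma_g2 / m) * (w_disc @ w_disc.T) + sigma_e2 * np.eye(n)
    vi1 = scipy.linalg.solve(v, np.ones(n), assume_a="pos")
    mu = float(vi1 @ y) / float(vi1 @ np.ones(n))
    beta = scipy.linalg.solve(
        w_disc.T @ w_disc + lam * np.eye(m), w_disc.T @ (y - mu), assume_a="pos"
    )
    return w_targ @ beta


def union_find_components(pairs) -> list[frozenset]:
    """Connected components by union-find over (id_i, id_j) edges."""
    parent: dict = {}

    def find(a):
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for a in parent:
        groups.setdefault(find(a), set()).add(a)
    return [frozenset(g) for g in groups.values()]
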