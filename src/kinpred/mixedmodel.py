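"""REML variance components and BLUP prediction for any relationship matrix.

One linear mixed model serves three predictors: y = 1*mu + g + e with
g ~ N(0, K sigma_g2) is GBLUP when K is the genomic matrix, ABLUP when K is
the pedigree matrix, and HBLUP when K is the single-step H matrix.  The
two-component extension y = 1*mu + g + f + e adds a shared-family effect
(f ~ N(0, F sigma_f2) with F the 0/1 same-family indicator) and yields the
two heritabilities

    h2_narrow = sigma_g2 / (sigma_g2 + sigma_e2)
    h2_family = (sigma_g2 + sigma_f2) / (sigma_g2 + sigma_f2 + sigma_e2).

Single-component REML is exact: eigendecompose K once and run a bounded
one-dimensional search on the heritability, profiling out the total
variance.  The multi-component fit maximizes the REML log-likelihood with
its analytic gradient under non-negativity bounds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .relmat import RelationshipMatrix
from .simdata import PhenotypeTable


class MixedModelError(ValueError):
    pass


@dataclasses.dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_f2: float
    sigma_e2: float
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma_g2", "sigma_f2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise MixedModelError(f"{name} must be >= 0")

    @property
    def h2_narrow(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0

    @property
    def h2_family(self) -> float:
        tot = self.sigma_g2 + self.sigma_f2 + self.sigma_e2
        return (self.sigma_g2 + self.sigma_f2) / tot if tot > 0 else 0.0

    @classmethod
    def from_heritability(cls, h2: float, f2: float = 0.0) -> "VarianceComponents":
        """Truth-injection constructor on a unit-phenotypic-variance scale
        (isolates prediction error from estimation error)."""
        return cls(h2, f2, max(0.0, 1.0 - h2 - f2))

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("component\tvalue\n")
            fh.write(f"sigma_g2\t{self.sigma_g2:.10g}\n")
            fh.write(f"sigma_f2\t{self.sigma_f2:.10g}\n")
            fh.write(f"sigma_e2\t{self.sigma_e2:.10g}\n")
            fh.write(f"h2_narrow\t{self.h2_narrow:.10g}\n")
            fh.write(f"h2_family\t{self.h2_family:.10g}\n")
            fh.write(f"loglik\t{self.loglik:.10g}\n")
            fh.write(f"converged\t{int(self.converged)}\n")


@dataclasses.dataclass
class BlupResult:
    """Predicted total genetic values: columns IID, GHAT."""

    table: pd.DataFrame

    @property
    def ids(self) -> np.ndarray:
        return self.table["IID"].to_numpy()

    def ghat(self, ids=None) -> np.ndarray:
        s = self.table.set_index("IID")["GHAT"]
        if ids is None:
            return s.to_numpy(dtype=float)
        return s.loc[list(ids)].to_numpy(dtype=float)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# single-component REML (exact, eigendecomposition + bounded search)
# ---------------------------------------------------------------------------

def _aligned(K: RelationshipMatrix, y: PhenotypeTable):
    ids = [i for i in K.ids if i in set(y.ids)]
    return ids, K.submatrix(ids), y.trait(ids)


def reml_single(
    K: RelationshipMatrix, y: PhenotypeTable, min_n: int = 50
) -> VarianceComponents:
    """REML for y = 1*mu + g + e, g ~ N(0, K sigma_g2).

    Eigendecomposes K and profiles the total variance, leaving a
    one-dimensional bounded search on h2 = sigma_g2/(sigma_g2+sigma_e2).
    """
    ids, km, yv = _aligned(K, y)
    n = len(ids)
    if n < min_n:
        raise MixedModelError(f"need >= {min_n} phenotyped individuals, have {n}")
    if np.abs(km - np.eye(n)).max() < 1e-8:
        raise MixedModelError(
            "K is the identity: sigma_g2 and sigma_e2 are not identifiable"
        )
    w, u = scipy.linalg.eigh(km)
    if w.min() < -1e-8:
        raise MixedModelError(
            f"K is not positive semi-definite (min eigenvalue {w.min():.3g})"
        )
    w = np.maximum(w, 0.0)
    if np.ptp(w) < 1e-10:
        raise MixedModelError("K is a multiple of the identity: not identifiable")
    yt = u.T @ yv
    xt = u.T @ np.ones(n)

    def neg_restricted_ll(h2: float) -> float:
        d = h2 * w + (1.0 - h2)
        a = float(np.sum(xt * xt / d))
        b = float(np.sum(xt * yt / d))
        c = float(np.sum(yt * yt / d))
        ypy = max(c - b * b / a, 1e-300)
        s2 = ypy / (n - 1)
        return 0.5 * (
            (n - 1) * (np.log(s2) + 1.0) + float(np.sum(np.log(d))) + np.log(a)
        )

    res = scipy.optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, 1.0 - 1e-9), method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    d = h2 * w + (1.0 - h2)
    a = float(np.sum(xt * xt / d))
    b = float(np.sum(xt * yt / d))
    c = float(np.sum(yt * yt / d))
    s2 = max(c - b * b / a, 1e-300) / (n - 1)
    return VarianceComponents(
        sigma_g2=h2 * s2,
        sigma_f2=0.0,
        sigma_e2=(1.0 - h2) * s2,
        loglik=-float(res.fun),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# multi-component REML (bounded quasi-Newton with exact gradient)
# ---------------------------------------------------------------------------

def family_indicator(family_ids, ids=None) -> RelationshipMatrix:
    """0/1 same-family block matrix from a mapping id -> family label."""
    if ids is None:
        ids = list(family_ids.keys())
    fams = np.array([family_ids[i] for i in ids], dtype=object)
    mat = (fams[:, None] == fams[None, :]).astype(float)
    return RelationshipMatrix(np.asarray(ids, dtype=object), mat, "A")


def reml_two(
    K1: RelationshipMatrix,
    K2: RelationshipMatrix,
    y: PhenotypeTable,
    max_iter: int = 200,
) -> VarianceComponents:
    """REML for y = 1*mu + g + f + e over (sigma_g2, sigma_f2, sigma_e2).

    K1 is the genetic relationship matrix, K2 the same-family indicator.
    Starts from an equal split of the phenotypic variance; non-negativity is
    enforced by bounds.  Non-convergence within ``max_iter`` evaluations is
    flagged, returning the best point found.
    """
    ids, k1, yv = _aligned(K1, y)
    n = len(ids)
    if n < 50:
        raise MixedModelError(f"need >= 50 phenotyped individuals, have {n}")
    vary = float(np.var(yv, ddof=1))
    if vary <= 0:
        raise MixedModelError("phenotype has zero variance")
    k2 = K2.submatrix(ids)
    ones = np.ones(n)
    kernels = (k1, k2, np.eye(n))

    def nll_and_grad(sig: np.ndarray):
        v = sig[0] * k1 + sig[1] * k2 + sig[2] * np.eye(n)
        try:
            cf = scipy.linalg.cho_factor(v, lower=True)
        except np.linalg.LinAlgError:
            return 1e30, np.zeros(3)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        vi = scipy.linalg.cho_solve(cf, np.eye(n))
        vi1 = vi @ ones
        a = float(ones @ vi1)
        p = vi - np.outer(vi1, vi1) / a
        py = p @ yv
        nll = 0.5 * (logdet_v + np.log(a) + float(yv @ py))
        grad = np.array(
            [
                0.5 * (float(np.sum(p * k)) - float(py @ (k @ py)))
                for k in kernels
            ]
        )
        return nll, grad

    x0 = np.full(3, vary / 3.0)
    res = scipy.optimize.minimize(
        nll_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(1e-8, None)] * 3,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    sg, sf, se = np.maximum(res.x, 0.0)
    return VarianceComponents(
        sigma_g2=float(sg),
        sigma_f2=float(sf),
        sigma_e2=float(se),
        loglik=-float(res.fun),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# BLUP prediction
# ---------------------------------------------------------------------------

def blup_predict(
    K: RelationshipMatrix,
    y_discovery: PhenotypeTable,
    vc: VarianceComponents,
    target_ids,
    stabilize: float = 0.0,
) -> BlupResult:
    """BLUP of genetic values for the targets.

    ghat_t = K_td (K_dd + lambda I)^-1 (y_d - mu_hat) with
    lambda = sigma_e2/sigma_g2 and mu_hat the GLS mean — identical contract
    for G (GBLUP), A (ABLUP) and H (HBLUP).  ``stabilize`` adds an opt-in
    ridge to the diagonal when the system is reported singular.
    """
    target_ids = list(target_ids)
    disc_ids = [i for i in K.ids if i in set(y_discovery.ids)]
    missing = [t for t in target_ids if t not in set(K.ids)]
    if missing:
        raise MixedModelError(f"targets not spanned by K: {missing[:5]}")
    if not disc_ids:
        raise MixedModelError("no phenotyped individuals found in K")
    yv = y_discovery.trait(disc_ids)

    if vc.sigma_g2 <= 1e-12:  # infinite shrinkage
        tab = pd.DataFrame({"IID": target_ids, "GHAT": np.zeros(len(target_ids))})
        return BlupResult(tab)

    lam = vc.sigma_e2 / vc.sigma_g2
    kdd = K.submatrix(disc_ids)
    c = kdd + (lam + stabilize) * np.eye(len(disc_ids))
    try:
        cf = scipy.linalg.cho_factor(c)
    except np.linalg.LinAlgError as err:
        raise MixedModelError(
            "singular BLUP system; retry with stabilize=1e-8 (adds a ridge "
            "to the diagonal)"
        ) from err
    ci_y = scipy.linalg.cho_solve(cf, yv)
    ci_1 = scipy.linalg.cho_solve(cf, np.ones(len(disc_ids)))
    mu = float(np.ones(len(disc_ids)) @ ci_y) / float(np.ones(len(disc_ids)) @ ci_1)
    alpha = scipy.linalg.cho_solve(cf, yv - mu)
    ktd = K.submatrix(target_ids, disc_ids)
    ghat = ktd @ alpha
    return BlupResult(pd.DataFrame({"IID": target_ids, "GHAT": ghat}))
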