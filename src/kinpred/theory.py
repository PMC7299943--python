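"""Analytic layer: effective chromosome segments and theoretical accuracy.

The expected accuracy of a polygenic predictor — the correlation between the
score and the phenotype in an independent target sample — is

    r = h^2 / sqrt(h^2 + Me / N),

where h^2 is the heritability, N the number of phenotyped reference
individuals, and Me the effective number of chromosome segments.  Me is
estimated empirically as the inverse of the variance of genomic
relationships between the reference and target samples,

    Me = 1 / var(G_ij),  i in discovery, j in target.

Close relatives of a target inside the reference inflate that variance, so
adding them shrinks Me and raises the expected accuracy; the analytic
what-if operation appends the expected first/second/third-degree
relationship values (0.5 / 0.25 / 0.125) to a baseline relationship vector
and recomputes Me.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .relmat import RelationshipMatrix


class TheoryError(ValueError):
    pass


#: expected genomic relationship added by one relative of each degree
RELATIONSHIP_BY_DEGREE = {1: 0.5, 2: 0.25, 3: 0.125}


@dataclasses.dataclass(frozen=True)
class MeEstimate:
    """Effective number of chromosome segments (Me = 1/var when var > 0;
    math.inf is the distinguished all-relationships-equal signal)."""

    me: float
    n_pairs: int
    variance: float

    @property
    def infinite(self) -> bool:
        return math.isinf(self.me)

    @classmethod
    def from_relationships(cls, values) -> "MeEstimate":
        v = np.asarray(values, dtype=float).ravel()
        if v.size == 0:
            raise TheoryError("empty relationship vector")
        var = float(v.var())  # population variance, mean subtracted
        me = math.inf if var == 0.0 else 1.0 / var
        return cls(me=me, n_pairs=int(v.size), variance=var)


@dataclasses.dataclass(frozen=True)
class TheoryInputs:
    """Inputs of the accuracy formula; ``h2_kind`` records whether h2 is the
    narrow-sense or the family-based estimate."""

    h2: float
    me: float
    n: int
    h2_kind: str = "narrow"

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise TheoryError("h2 must be in [0, 1]")
        if self.me <= 0.0:
            raise TheoryError("me must be > 0")
        if self.n < 1:
            raise TheoryError("n must be >= 1")


def estimate_me(
    G: RelationshipMatrix, discovery_ids, target_ids
) -> MeEstimate:
    """Me from the discovery x target block of a relationship matrix."""
    disc, targ = list(discovery_ids), list(target_ids)
    if not disc or not targ:
        raise TheoryError("discovery and target sets must be non-empty")
    if set(disc) & set(targ):
        raise TheoryError("discovery and target sets must be disjoint")
    cross = G.submatrix(disc, targ)
    return MeEstimate.from_relationships(cross)


def theoretical_accuracy(inputs: TheoryInputs) -> float:
    """r = h^2 / sqrt(h^2 + Me/N) — the expected score-phenotype correlation."""
    if inputs.h2 == 0.0:
        return 0.0
    if math.isinf(inputs.me):
        return 0.0
    return inputs.h2 / math.sqrt(inputs.h2 + inputs.me / inputs.n)


def analytic_me_with_relatives(
    baseline, degree: int, k: int
) -> MeEstimate:
    """Me of a single target after adding ``k`` relatives of ``degree`` to
    its reference relationships: append k copies of the expected
    relationship (0.5/0.25/0.125) and recompute Me."""
    if degree not in RELATIONSHIP_BY_DEGREE:
        raise TheoryError("degree must be 1, 2 or 3")
    if k < 0:
        raise TheoryError("k must be >= 0")
    base = np.asarray(baseline, dtype=float).ravel()
    added = np.full(k, RELATIONSHIP_BY_DEGREE[degree])
    return MeEstimate.from_relationships(np.concatenate([base, added]))
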