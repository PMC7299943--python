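"""Empirical accuracy, cross-design fold changes, and decile risk analysis.

Accuracy is the Pearson correlation between a polygenic score (PRS or BLUP)
and the covariate-adjusted phenotype in targets.  Designs are compared by
the mean per-trait fold change with its 95% t-interval and a two-tailed
paired t-test.  Clinical utility of a binary-trait score is summarized by
prevalence and odds ratios in the cumulative upper tails above each decile
of the score distribution.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import scipy.stats

from .assoc import PRSResult
from .mixedmodel import BlupResult
from .simdata import PhenotypeTable


class EvalError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class AccuracyReport:
    """One design x one predictor: empirical and theoretical accuracies."""

    design: str
    r_empirical: float
    r_theory_narrow: float = math.nan
    r_theory_family: float = math.nan
    me: float = math.nan
    n_discovery: int = 0


@dataclasses.dataclass(frozen=True)
class FoldChangeSummary:
    mean_fold: float
    ci_low: float
    ci_high: float
    p_value: float          # paired t-test on differences acc_a - acc_b
    p_value_ratio: float    # t-test of per-trait folds against 1
    n_traits: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (
            self.ci_low <= self.mean_fold <= self.ci_high
        ):
            raise EvalError("confidence interval does not bracket the mean")


@dataclasses.dataclass
class DecileReport:
    """Cumulative upper-tail prevalence/odds ratio above each score decile.

    ``table`` columns: DECILE (1..9), N_TAIL, CASES, CONTROLS, PREVALENCE,
    ODDS_RATIO (inf flagged when the tail holds no controls).
    """

    table: pd.DataFrame
    population_odds: float

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# population_odds={self.population_odds:.10g}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------


def _score_vector(scores) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scores, PRSResult):
        return scores.ids, scores.scores()
    if isinstance(scores, BlupResult):
        return scores.ids, scores.ghat()
    raise EvalError("scores must be a PRSResult or BlupResult")


def empirical_accuracy(scores, adjusted: PhenotypeTable) -> float:
    """Pearson correlation between scores and adjusted phenotypes over the
    id intersection."""
    ids, vals = _score_vector(scores)
    common = [i for i in ids if i in set(adjusted.ids)]
    if len(common) < 3:
        raise EvalError(f"need >= 3 overlapping ids, have {len(common)}")
    lookup = dict(zip(ids, vals))
    x = np.array([lookup[i] for i in common], dtype=float)
    y = adjusted.trait(common)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise EvalError("correlation undefined: constant score or phenotype")
    return float(scipy.stats.pearsonr(x, y).statistic)


def fold_change_stats(acc_a, acc_b) -> FoldChangeSummary:
    """Mean per-trait fold change acc_a/acc_b with 95% t-interval, plus a
    two-tailed paired t-test on the differences acc_a - acc_b (and, for
    transparency, a t-test of the raw folds against 1)."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise EvalError("accuracy vectors must be equal-length 1-d with n >= 2")
    bad = np.where(b <= 0.0)[0]
    if bad.size:
        raise EvalError(
            f"non-positive denominator accuracy at trait indices {bad.tolist()}"
        )
    folds = a / b
    n = folds.size
    mean = float(folds.mean())
    sd = float(folds.std(ddof=1))
    degenerate = sd == 0.0 and float(np.std(a - b, ddof=1)) == 0.0
    if sd == 0.0:
        ci_low = ci_high = mean
    else:
        half = scipy.stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci_low, ci_high = mean - half, mean + half
    if degenerate:
        p_diff = p_ratio = math.nan
    else:
        with np.errstate(invalid="ignore"):
            p_diff = float(scipy.stats.ttest_rel(a, b).pvalue)
            p_ratio = (
                float(scipy.stats.ttest_1samp(folds, 1.0).pvalue)
                if sd > 0.0
                else math.nan
            )
    return FoldChangeSummary(
        mean_fold=mean,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_diff,
        p_value_ratio=p_ratio,
        n_traits=n,
        degenerate=degenerate,
    )


def decile_analysis(
    scores: PRSResult,
    status: PhenotypeTable,
    population_odds: float,
    seed: int = 0,
) -> DecileReport:
    """Prevalence and odds ratio in the tail above each score decile.

    Targets are ranked by score (ties broken by a seeded stable shuffle);
    for each decile threshold d in 1..9 the tail is the top (10-d)/10 of the
    distribution.  OR = (cases/controls in tail) / population_odds; a tail
    with no controls is flagged with an infinite OR.
    """
    if status.trait_type != "binary":
        raise EvalError("decile analysis needs a binary phenotype")
    if population_odds <= 0.0:
        raise EvalError("population_odds must be > 0")
    ids, vals = _score_vector(scores)
    common = [i for i in ids if i in set(status.ids)]
    n = len(common)
    if n < 10:
        raise EvalError(f"need >= 10 targets, have {n}")
    lookup = dict(zip(ids, vals))
    x = np.array([lookup[i] for i in common], dtype=float)
    y = status.trait(common).astype(int)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)          # seeded tie-break,
    order = perm[np.argsort(x[perm], kind="stable")]  # then stable by score
    y_sorted = y[order]

    rows = []
    for d in range(1, 10):
        cut = int(round(n * d / 10.0))
        tail = y_sorted[cut:]
        cases = int(tail.sum())
        controls = int(tail.size - cases)
        prevalence = cases / tail.size if tail.size else math.nan
        if cases == 0:
            odds_ratio = 0.0
        elif controls == 0:
            odds_ratio = math.inf
        else:
            odds_ratio = (cases / controls) / population_odds
        rows.append((d, int(tail.size), cases, controls, prevalence, odds_ratio))
    tab = pd.DataFrame(
        rows,
        columns=["DECILE", "N_TAIL", "CASES", "CONTROLS", "PREVALENCE", "ODDS_RATIO"],
    )
    return DecileReport(tab, population_odds)
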