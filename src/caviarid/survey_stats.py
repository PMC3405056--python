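"""Survey-level mislabeling statistics.

Point estimates are simple proportions over the testable lots (lots whose
DNA could not be extracted are excluded from the denominator).  Interval
estimates use the exact binomial (Clopper–Pearson) method; two surveys are
compared with Fisher's exact conditional test and a Newcombe score interval
for the difference of proportions.  "Mixed" lots (label-consistent and
inconsistent eggs in one tin) count as mislabeled in the headline rate and
are also reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import fisher_exact
from statsmodels.stats.proportion import (confint_proportions_2indep,
                                          proportion_confint)


@dataclass
class SurveySummary:
    """Counts and rate for one survey (or one stratum of it)."""

    n_lots: int                 # all lots seen, including extraction failures
    n_testable: int
    n_mislabeled: int           # headline count (mixed lots included)
    n_mixed: int
    n_unresolved: int
    rate_percent: float
    ci_low_percent: float
    ci_high_percent: float
    confidence: float = 0.95

    @classmethod
    def from_counts(cls, n_mislabeled: int, n_testable: int, *,
                    n_lots: int | None = None, n_mixed: int = 0,
                    n_unresolved: int = 0,
                    confidence: float = 0.95) -> "SurveySummary":
        if n_testable <= 0:
            raise ValueError("no testable lots")
        if not 0 <= n_mislabeled <= n_testable:
            raise ValueError("mislabeled count outside [0, n]")
        lo, hi = proportion_confint(n_mislabeled, n_testable,
                                    alpha=1 - confidence, method="beta")
        return cls(n_lots=n_lots if n_lots is not None else n_testable,
                   n_testable=n_testable, n_mislabeled=n_mislabeled,
                   n_mixed=n_mixed, n_unresolved=n_unresolved,
                   rate_percent=100.0 * n_mislabeled / n_testable,
                   ci_low_percent=100.0 * lo, ci_high_percent=100.0 * hi,
                   confidence=confidence)


def mislabeling_rate(results, confidence: float = 0.95) -> SurveySummary:
    """Survey summary over a list of :class:`~caviarid.workflow.LotResult`.

    The denominator is the lots with a usable extraction; the numerator is
    confirmed mislabeled lots plus mixed lots.
    """
    results = list(results)
    if not results:
        raise ValueError("no lot results")
    testable = [r for r in results if r.testable]
    if not testable:
        raise ValueError("no testable lots (all extractions failed)")
    n_mis = sum(r.is_mislabeled for r in testable)
    n_mixed = sum(r.verdict == "mixed" for r in testable)
    n_unres = sum(r.verdict == "unresolved" for r in testable)
    return SurveySummary.from_counts(
        n_mis, len(testable), n_lots=len(results), n_mixed=n_mixed,
        n_unresolved=n_unres, confidence=confidence)


def breakdown(results, key: str, confidence: float = 0.95) -> dict:
    """Per-stratum summaries by ``key`` ('channel' or 'year').

    Every result must carry the key; strata partition the lots, so stratum
    counts reconcile with the overall summary.
    """
    if key not in ("channel", "year"):
        raise ValueError(f"unsupported breakdown key {key!r}")
    strata: dict = {}
    for r in results:
        value = getattr(r, key)
        if value is None:
            raise ValueError(f"lot {r.lot_id} has no {key}")
        strata.setdefault(value, []).append(r)
    return {value: mislabeling_rate(rs, confidence=confidence)
            for value, rs in sorted(strata.items(), key=lambda kv: str(kv[0]))}


@dataclass
class PeriodComparison:
    """Two-survey comparison of mislabeling proportions.

    The p-value is Fisher's exact conditional test on the 2x2 table; the
    confidence interval for the difference in percent is the Newcombe
    score-interval method.
    """

    count_a: int
    n_a: int
    count_b: int
    n_b: int
    rate_a_percent: float = field(init=False)
    rate_b_percent: float = field(init=False)
    difference_percent: float = field(init=False)
    ci_low_percent: float = 0.0
    ci_high_percent: float = 0.0
    p_value: float = 1.0

    def __post_init__(self) -> None:
        self.rate_a_percent = 100.0 * self.count_a / self.n_a
        self.rate_b_percent = 100.0 * self.count_b / self.n_b
        self.difference_percent = self.rate_a_percent - self.rate_b_percent


def compare_periods(a: tuple[int, int], b: tuple[int, int],
                    confidence: float = 0.95) -> PeriodComparison:
    """Compare (mislabeled, tested) counts of two surveys.

    ``a`` and ``b`` are ``(n_mislabeled, n_tested)`` pairs; the second survey
    acts as the reference, so a negative difference means survey ``a`` has
    the lower rate.
    """
    (xa, na), (xb, nb) = a, b
    if na <= 0 or nb <= 0:
        raise ValueError("both surveys need n > 0")
    comp = PeriodComparison(count_a=xa, n_a=na, count_b=xb, n_b=nb)
    table = [[xa, na - xa], [xb, nb - xb]]
    _, comp.p_value = fisher_exact(table, alternative="two-sided")
    lo, hi = confint_proportions_2indep(xa, na, xb, nb, compare="diff",
                                        method="newcomb",
                                        alpha=1 - confidence)
    comp.ci_low_percent, comp.ci_high_percent = 100.0 * lo, 100.0 * hi
    return comp
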