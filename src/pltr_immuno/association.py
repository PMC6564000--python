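"""Univariate genetic association statistics for a case/control cohort.

Crude odds ratios with Woolf (log-normal) confidence intervals and the
Haldane-Anscombe zero-cell correction, per-genotype odds-ratio tables with a
global chi-square / Fisher p-value, the Hardy-Weinberg exact test, and
covariate-adjusted univariate odds ratios from a logistic fit.

Test selection follows the usual small-sample rule: Fisher's exact test when
any expected cell of a 2x2 table is below 5, Pearson chi-square otherwise
(r x c tables always use the chi-square).  The choice is recorded on every
result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .cohort import CohortTable, CohortError
from .glm import fit_logistic, lr_test

Z95 = stats.norm.ppf(0.975)


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 exposure-by-outcome counts.

    ``a`` exposed events, ``b`` exposed non-events, ``c`` unexposed events,
    ``d`` unexposed non-events.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise AssociationError("cell counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise AssociationError("empty 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class AssocResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    n_used: int
    correction_applied: bool = False
    label: str = ""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (ref/ref, ref/alt, alt/alt) per outcome group."""

    events: tuple[int, int, int]
    nonevents: tuple[int, int, int]
    n_missing: int = 0

    def pooled(self) -> tuple[int, int, int]:
        return tuple(int(e + c) for e, c in zip(self.events, self.nonevents))


# ---------------------------------------------------------------------------
# 2x2 odds ratio
# ---------------------------------------------------------------------------

def _choose_test(table: np.ndarray) -> str:
    """Fisher when any expected 2x2 cell < 5, else chi-square."""
    if table.shape == (2, 2):
        rs, cs = table.sum(1), table.sum(0)
        expected = np.outer(rs, cs) / table.sum()
        if (expected < 5).any():
            return "fisher-exact"
    return "chi-square"


def odds_ratio(t: TwoByTwo, correction: bool = False, label: str = "") -> AssocResult:
    """Cross-product odds ratio with Woolf 95% CI.

    With ``correction=True`` and any zero cell, 0.5 is added to all four
    cells (Haldane-Anscombe) before computing.  The p-value comes from
    Fisher's exact test when any expected cell is below 5, else from the
    Pearson chi-square on the uncorrected counts.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    applied = False
    if correction and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        applied = True
    if min(a, b, c, d) == 0:
        raise AssociationError(
            "zero cell makes the odds ratio undefined; pass correction=True "
            "for the Haldane-Anscombe estimate")
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = est * math.exp(-Z95 * se), est * math.exp(Z95 * se)
    tab = t.as_array()
    test = _choose_test(tab)
    if test == "fisher-exact":
        p = fisher_exact(t)
    else:
        _, p = chi_square_test(tab)
    return AssocResult(est, lo, hi, p, test, t.a + t.b + t.c + t.d, applied, label)


def genotype_or_table(g: GenotypeCounts, reference: int = 0):
    """Odds ratios for each non-reference genotype versus the reference.

    ``reference`` indexes the genotype (0 ref/ref, 1 ref/alt, 2 alt/alt).
    Returns ``(results, overall_p, overall_test)``; the overall p comes from
    the 2x3 chi-square over all three genotypes.
    """
    ev, ne = g.events, g.nonevents
    if ev[reference] == 0 or ne[reference] == 0:
        raise AssociationError("reference genotype needs events and non-events")
    labels = ["ref/ref", "ref/alt", "alt/alt"]
    results = []
    for i in range(3):
        if i == reference:
            continue
        t = TwoByTwo(ev[i], ne[i], ev[reference], ne[reference])
        results.append(odds_ratio(t, correction=True,
                                  label=f"{labels[i]} vs {labels[reference]}"))
    tab = np.array([ev, ne], dtype=float)
    keep = tab.sum(0) > 0
    stat, overall_p = chi_square_test(tab[:, keep])
    return results, overall_p, "chi-square"


# ---------------------------------------------------------------------------
# contingency tests
# ---------------------------------------------------------------------------

def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an r x c table."""
    tab = np.asarray(table, dtype=float)
    if tab.sum() <= 0:
        raise AssociationError("empty contingency table")
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        raise AssociationError("degenerate margin (all-zero row or column)")
    stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(stat), float(p)


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sums)."""
    tab = t.as_array()
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        return 1.0
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_test(counts: tuple[int, int, int]) -> tuple[float, bool]:
    """Exact Hardy-Weinberg test on pooled genotype counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed table (plain exact p, no mid-p adjustment).

    Returns ``(p_value, monomorphic_flag)``; a monomorphic marker gives p = 1
    with the flag set.
    """
    n_rr, n_ra, n_aa = (int(c) for c in counts)
    if min(n_rr, n_ra, n_aa) < 0 or n_rr + n_ra + n_aa == 0:
        raise AssociationError("invalid genotype counts")
    n = n_rr + n_ra + n_aa
    n_a = 2 * n_aa + n_ra  # minor-ish allele count (either works, symmetric)
    if n_a == 0 or n_a == 2 * n:
        return 1.0, True
    # P(n_het = h | n, n_a) ~ 2^h * n! * n_a! * (2n-n_a)! / (n_rr! n_ra! n_aa! (2n)!)
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    n_aa_v = (n_a - hets) // 2
    n_rr_v = n - n_aa_v - hets
    logp = (hets * math.log(2.0)
            - gammaln(n_rr_v + 1) - gammaln(hets + 1) - gammaln(n_aa_v + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[np.flatnonzero(hets == n_ra)[0]]
    p = float(prob[prob <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0), False


# ---------------------------------------------------------------------------
# covariate-adjusted univariate odds ratio
# ---------------------------------------------------------------------------

def adjusted_univariate_or(cohort: CohortTable, exposure: str,
                           adjusters: list[str] = ()) -> AssocResult:
    """Odds ratio for a single-column exposure from a logistic fit.

    The exposure must encode to exactly one design column (binary variable or
    an explicit ``:dose`` / ``:dominant`` / ``:recessive`` recode).  The CI is
    Wald on the log-odds scale; the p-value is the likelihood-ratio test of
    the exposure term.  Separation raises with an advisory to fall back on
    the Haldane-corrected crude odds ratio.
    """
    adjusters = list(adjusters)
    full = fit_logistic(cohort, [exposure] + adjusters)
    exp_names = [k for k in full.coefficients
                 if k != "(intercept)" and _term_of(k) == exposure]
    if len(exp_names) != 1:
        raise AssociationError(
            f"exposure {exposure!r} encodes to {len(exp_names)} columns; "
            "use a binary variable or an explicit recode")
    if not full.converged:
        raise AssociationError(
            "logistic fit did not converge (possible separation); use the "
            "Haldane-corrected crude odds_ratio instead")
    reduced = fit_logistic(cohort, adjusters, rows=full.rows)
    p = lr_test(reduced, full)
    b = full.coefficients[exp_names[0]]
    se = full.standard_errors[exp_names[0]]
    return AssocResult(
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - Z95 * se)),
        ci_high=float(np.exp(b + Z95 * se)),
        p_value=p, test="lr-logistic", n_used=full.n, label=exp_names[0])


def _term_of(coef_name: str) -> str:
    return coef_name.split("[", 1)[0]


__all__ = [
    "TwoByTwo", "AssocResult", "GenotypeCounts", "AssociationError",
    "odds_ratio", "genotype_or_table", "chi_square_test", "fisher_exact",
    "hwe_test", "adjusted_univariate_or",
]
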