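"""Maximum-likelihood logistic regression engine.

This module is the numerical core shared by the association, stepwise and
tree-based layers: an IRLS (Newton-Raphson) fitter with per-subject offsets,
deviance / AIC / BIC on the binary-data scale (deviance = -2 loglik), the
likelihood-ratio test for nested fits, and the forward-stepwise model builder
with likelihood-ratio entry/removal at configurable p-value thresholds.

Information criteria are defined on the deviance scale,

    AIC = deviance + 2 p,    BIC = deviance + p log(n),

with p the number of estimated coefficients (offsets are not counted), so a
partially linear tree fit and a plain logistic fit on the same subjects are
directly comparable.

Term syntax
-----------
Model terms are cohort variable names, optionally suffixed with a recode:

``"x"``            dictionary coding (binary/categorical -> reference dummies,
                   genotype -> two genotype dummies, count -> numeric)
``"x:dose"``       allele dose 0/1/2 (the classic additive genetic model)
``"x:dominant"``   1 for het or hom-alt carriers of the alternate allele
``"x:recessive"``  1 for hom-alt only
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .cohort import CohortTable, CohortError

SEPARATION_COEF = 15.0  # |log-odds| beyond this flags (quasi-)separation


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def _parse_term(term: str) -> tuple[str, str | None]:
    if ":" in term:
        name, recode = term.split(":", 1)
        if recode not in {"dose", "dominant", "recessive"}:
            raise CohortError(f"unknown recode {recode!r} in term {term!r}")
        return name, recode
    return term, None


def build_design(cohort: CohortTable, terms: list[str]):
    """Encode ``terms`` into numeric design columns (no intercept).

    Returns ``(X, names, term_cols, rows)`` where ``rows`` is the boolean
    complete-case mask over outcome and all terms, and ``term_cols`` maps each
    term to its column indices in ``X``.
    """
    df = cohort.data
    out_name = cohort.outcome_spec.name
    rows = ~df[out_name].isna()
    for t in terms:
        name, _ = _parse_term(t)
        rows &= ~df[name].isna()
    rows = rows.to_numpy()

    cols, names, term_cols = [], [], {}
    for t in terms:
        name, recode = _parse_term(t)
        spec = cohort.spec(name)
        col = df[name].to_numpy()[rows]
        start = len(cols)
        if recode is not None:
            if spec.coding != "genotype":
                raise CohortError(f"recode {recode!r} requires genotype coding ({name})")
            dose = np.select(
                [col == spec.levels[0], col == spec.levels[1], col == spec.levels[2]],
                [0.0, 1.0, 2.0])
            if recode == "dose":
                cols.append(dose); names.append(f"{name}:dose")
            elif recode == "dominant":
                cols.append((dose >= 1).astype(float)); names.append(f"{name}:dominant")
            else:
                cols.append((dose == 2).astype(float)); names.append(f"{name}:recessive")
        elif spec.coding == "count":
            cols.append(col.astype(float)); names.append(name)
        else:
            for lv in spec.levels:
                if lv == spec.reference_level:
                    continue
                cols.append((col == lv).astype(float))
                names.append(f"{name}[{lv}]")
        term_cols[t] = list(range(start, len(cols)))
    X = np.column_stack(cols) if cols else np.empty((int(rows.sum()), 0))
    return X, names, term_cols, rows


# ---------------------------------------------------------------------------
# IRLS core
# ---------------------------------------------------------------------------

def _deviance(y, eta):
    # -2 loglik for Bernoulli data; stable via softplus
    return 2.0 * float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def irls_logistic(X, y, offset=None, beta0=None, tol=1e-8, max_iter=100):
    """Newton-Raphson for the Bernoulli log-likelihood with optional offset.

    Returns ``(beta, cov, deviance, converged, n_iter)``.  Convergence is an
    infinity-norm on the score below ``tol``; step-halving guards against
    overshoot.  Coefficients beyond ``SEPARATION_COEF`` in absolute value
    leave the fit flagged unconverged (separation advisory).
    """
    n, p = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    eta = X @ beta + off
    dev = _deviance(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad), initial=0.0) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), grad)
        # step-halving if the deviance does not improve
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand + off
            dev_c = _deviance(y, eta_c)
            if dev_c <= dev + 1e-12:
                break
            step *= 0.5
        beta, eta, dev = cand, eta_c, dev_c
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    if p and np.max(np.abs(beta)) > SEPARATION_COEF:
        converged = False
        warnings.warn("possible separation: coefficient beyond +/-15 log-odds",
                      RuntimeWarning, stacklevel=2)
    return beta, cov, dev, converged, it


def fit_intercept_offset(y, offset, max_iter=50, cap=30.0):
    """1-D Newton for an intercept-only logistic fit with offset.

    Used heavily by the tree layer (a leaf effect is exactly this constant).
    Returns ``(c, deviance)``; ``c`` is capped to +/-``cap`` so all-event or
    all-nonevent leaves stay finite.
    """
    y = np.asarray(y, dtype=float)
    off = np.asarray(offset, dtype=float)
    ysum = y.sum()
    c = 0.0
    for _ in range(max_iter):
        mu = expit(off + c)
        g = ysum - mu.sum()
        h = float(np.sum(mu * (1.0 - mu)))
        if h < 1e-12:
            break
        step = g / h
        c += float(np.clip(step, -10.0, 10.0))
        if abs(step) < 1e-10:
            break
        if abs(c) > cap:
            c = float(np.clip(c, -cap, cap))
            break
    return c, _deviance(y, off + c)


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    """A fitted logistic model with deviance-scale information criteria."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    deviance: float
    n: int
    p: int
    converged: bool
    n_iter: int
    terms: tuple[str, ...] = ()
    beta: np.ndarray = field(default=None, repr=False)
    cov: np.ndarray = field(default=None, repr=False)
    rows: np.ndarray = field(default=None, repr=False)
    offset_used: bool = False

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.p

    @property
    def bic(self) -> float:
        return self.deviance + self.p * np.log(self.n)

    def wald_table(self, conf=0.95) -> list[dict]:
        z = stats.norm.ppf(0.5 + conf / 2.0)
        out = []
        with np.errstate(over="ignore"):
            for name in self.coefficients:
                b = self.coefficients[name]
                se = self.standard_errors[name]
                out.append({
                    "term": name, "coef": b, "se": se,
                    "or": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * se)),
                    "ci_high": float(np.exp(b + z * se)),
                    "p_wald": (float(2 * stats.norm.sf(abs(b) / se))
                               if se > 0 else np.nan),
                })
        return out


def fit_logistic(cohort: CohortTable, terms: list[str],
                 offset=None, rows=None) -> GlmFit:
    """Fit outcome ~ intercept + terms on complete cases.

    ``offset`` (full-cohort-length or analysis-length array) is added to the
    linear predictor and not counted as a parameter.  ``rows`` restricts the
    analysis to a boolean subject mask before complete-case filtering.
    """
    X0, names, _, cc = build_design(cohort, list(terms))
    if rows is not None:
        rows = np.asarray(rows, dtype=bool)
        if len(rows) != len(cc):
            raise CohortError("rows mask must have cohort length")
        X0 = X0[rows[cc]]
        cc = cc & rows
    y = cohort.data[cohort.outcome_spec.name].to_numpy()[cc]
    y = (y != cohort.outcome_spec.reference_level).astype(float)
    n = len(y)
    X = np.column_stack([np.ones(n), X0])
    names = ["(intercept)"] + names
    if n < X.shape[1] + 1:
        raise CohortError(f"too few complete cases ({n}) for {X.shape[1]} parameters")
    off = None
    if offset is not None:
        off = np.asarray(offset, dtype=float)
        if len(off) == len(cc):
            off = off[cc]
        elif len(off) != n:
            raise CohortError("offset length matches neither cohort nor analysis set")
    beta, cov, dev, conv, it = irls_logistic(X, y, offset=off)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return GlmFit(
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        deviance=dev, n=n, p=X.shape[1], converged=conv, n_iter=it,
        terms=tuple(terms), beta=beta, cov=cov, rows=cc,
        offset_used=offset is not None,
    )


def lr_test(nested: GlmFit, full: GlmFit) -> float:
    """Likelihood-ratio p-value for ``nested`` within ``full``."""
    if not set(nested.terms) <= set(full.terms):
        raise CohortError("lr_test: models are not nested")
    if nested.n != full.n:
        raise CohortError("lr_test: fits use different subjects")
    df = full.p - nested.p
    if df <= 0:
        return 1.0
    stat = max(nested.deviance - full.deviance, 0.0)
    return float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# forward stepwise with backward removal
# ---------------------------------------------------------------------------

def stepwise_forward(cohort: CohortTable, candidates: list[str],
                     always_in: list[str] = (), p_enter: float = 0.05,
                     p_remove: float = 0.05, prefilter: float = 0.2,
                     max_steps: int = 50):
    """Forward-stepwise logistic model building with LR entry/removal tests.

    Candidates are prefiltered by their LR p-value against the ``always_in``
    base model (< ``prefilter``); at each step the candidate with the smallest
    entry p enters if below ``p_enter`` (ties broken lexicographically), then
    any entered term whose removal p exceeds ``p_remove`` is dropped.  All
    fits share one complete-case analysis set (outcome + always_in + all
    candidates) so every LR test compares the same subjects.

    Returns ``(final_fit, trace)`` where ``trace`` is a list of step records.
    """
    always_in = list(always_in)
    candidates = list(candidates)
    _, _, _, cc = build_design(cohort, always_in + candidates)
    rows = cc

    def fit(terms):
        return fit_logistic(cohort, terms, rows=rows)

    trace: list[dict] = []
    base = fit(always_in)
    kept = []
    for cand in candidates:
        p = lr_test(base, fit(always_in + [cand]))
        trace.append({"action": "prefilter", "term": cand, "p": p,
                      "kept": bool(p < prefilter)})
        if p < prefilter:
            kept.append(cand)
    if not kept:
        trace.append({"action": "note",
                      "term": None, "p": None,
                      "note": "no candidate passed the univariate prefilter"})
        return base, trace

    current = list(always_in)
    cur_fit = base
    pool = list(kept)
    for _ in range(max_steps):
        changed = False
        # entry
        best_term, best_p, best_fit = None, None, None
        for cand in sorted(pool):
            f = fit(current + [cand])
            p = lr_test(cur_fit, f)
            if best_p is None or p < best_p - 1e-15:
                best_term, best_p, best_fit = cand, p, f
        if best_term is not None and best_p < p_enter:
            current.append(best_term)
            pool.remove(best_term)
            cur_fit = best_fit
            trace.append({"action": "enter", "term": best_term, "p": best_p,
                          "aic": cur_fit.aic, "bic": cur_fit.bic})
            changed = True
        # removal (never drop always_in terms)
        while True:
            worst_term, worst_p = None, None
            for term in [t for t in current if t not in always_in]:
                reduced = fit([t2 for t2 in current if t2 != term])
                p = lr_test(reduced, cur_fit)
                if worst_p is None or p > worst_p:
                    worst_term, worst_p = term, p
            if worst_term is not None and worst_p > p_remove:
                current.remove(worst_term)
                pool.append(worst_term)
                cur_fit = fit(current)
                trace.append({"action": "remove", "term": worst_term, "p": worst_p,
                              "aic": cur_fit.aic, "bic": cur_fit.bic})
                changed = True
            else:
                break
        if not changed:
            break
    return cur_fit, trace


__all__ = [
    "GlmFit", "build_design", "irls_logistic", "fit_intercept_offset",
    "fit_logistic", "lr_test", "stepwise_forward", "SEPARATION_COEF",
]
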