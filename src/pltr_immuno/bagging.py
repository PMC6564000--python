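"""Bootstrap-aggregated GPLTR and Deviance Importance Scores (DIS).

Single regression trees are notoriously unstable: a small perturbation of the
cohort can produce a different series of splits.  Bagging refits the whole
partially linear tree pipeline (grow, nested sequence, information-criterion
selection) on bootstrap resamples of the subjects and aggregates, for each
candidate tree variable, the joint-model deviance reductions of the splits it
contributes to each selected tree.  The mean over replicates is the
variable's Deviance Importance Score; variables genuinely associated with the
outcome accumulate large scores, while variables never selected score zero.
The procedure ranks variables by discriminative power — it is a stability
diagnostic, not a prediction engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable
from .gpltr import _Ctx, _fit_gpltr_ctx


class BaggingError(RuntimeError):
    pass


@dataclass
class BagResult:
    """Aggregated importance scores from ``B`` bootstrap GPLTR fits."""

    B: int
    n_failed: int
    dis: dict[str, float]
    selection_freq: dict[str, float]
    seed: int
    stratified: bool = False
    split_counts: dict[str, float] = field(default_factory=dict)


def bag_gpltr(cohort: CohortTable, linear_terms, tree_vars, B: int = 100,
              seed: int = 0, stratified: bool = False,
              criterion: str = "BIC", min_leaf: int | None = None,
              max_depth: int = 5) -> BagResult:
    """Bootstrap-aggregated GPLTR with per-variable deviance importance.

    For each of ``B`` replicates, subjects are resampled with replacement
    (within outcome groups when ``stratified``), the full GPLTR pipeline is
    refit, and each accepted split of the selected tree credits its variable
    with the split's joint-model deviance reduction.  DIS is the per-variable
    mean over successful replicates; replicates whose fit fails are skipped
    and counted, and more than 20% failures aborts.
    """
    if B < 10:
        raise BaggingError("B must be at least 10")
    ctx = _Ctx(cohort, list(linear_terms), list(tree_vars))
    n = ctx.n
    rng = np.random.default_rng(seed)
    if stratified:
        pos = np.arange(n)
        cases, ctrls = pos[ctx.y == 1], pos[ctx.y == 0]
        resamples = [np.concatenate([rng.choice(cases, len(cases)),
                                     rng.choice(ctrls, len(ctrls))])
                     for _ in range(B)]
    else:
        resamples = [rng.integers(0, n, n) for _ in range(B)]

    dis_sum = {v: 0.0 for v in tree_vars}
    sel_count = {v: 0 for v in tree_vars}
    split_count = {v: 0 for v in tree_vars}
    n_failed = 0
    for idx in resamples:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = _fit_gpltr_ctx(ctx, np.sort(idx), criterion=criterion,
                                     min_leaf=min_leaf, max_depth=max_depth)
        except Exception:
            n_failed += 1
            continue
        seen = set()
        for rec in res.selected_records:
            v = rec["variable"]
            dis_sum[v] += max(rec["gain"], 0.0)
            split_count[v] += 1
            seen.add(v)
        for v in seen:
            sel_count[v] += 1
    if n_failed > 0.2 * B:
        raise BaggingError(f"{n_failed}/{B} bootstrap fits failed")
    n_ok = B - n_failed
    return BagResult(
        B=B, n_failed=n_failed,
        dis={v: dis_sum[v] / n_ok for v in tree_vars},
        selection_freq={v: sel_count[v] / n_ok for v in tree_vars},
        split_counts={v: split_count[v] / n_ok for v in tree_vars},
        seed=seed, stratified=stratified)


def rank_variables(r: BagResult) -> list[tuple[str, float, float]]:
    """Variables by descending DIS; ties by selection frequency then name.

    Returns ``(variable, dis, selection_freq)`` tuples.
    """
    if not r.dis:
        raise BaggingError("empty bagging result")
    return sorted(
        ((v, r.dis[v], r.selection_freq[v]) for v in r.dis),
        key=lambda t: (-t[1], -t[2], t[0]))


__all__ = ["BagResult", "BaggingError", "bag_gpltr", "rank_variables"]
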