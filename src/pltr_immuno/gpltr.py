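"""Generalized partially linear tree-based logistic regression (GPLTR).

The model combines a parametric linear part (clinical confounders such as F8
mutation risk class, family history of inhibitors, FVIII product type) with a
binary tree over categorical genetic variables.  Writing ``eta_i = x_i' beta
+ c_{leaf(i)}`` for subject ``i``, the outcome is Bernoulli with probability
``expit(eta_i)``; the leaf constants capture arbitrary high-order interactions
among the tree-part variables while the linear part keeps the confounder
adjustment interpretable.

Fitting proceeds in three stages:

1. :func:`grow_maximal_tree` — an outer loop alternates (i) a joint logistic
   fit of the linear terms plus current leaf indicators, and (ii) a greedy
   CART-style regrow of the tree holding the fitted linear predictor (linear
   part only) fixed as an offset, splitting each node on the rule that
   maximises the deviance reduction, until the joint deviance stabilises.
   Trees are grown to maximal size subject to a minimum leaf count and a
   maximum depth.
2. :func:`forward_nested_sequence` — starting from the root, repeatedly adds
   the maximal-tree split (below a current leaf) with the largest deviance
   decrease, re-fitting the linear part jointly after each accepted split.
   Candidate gains within a sweep are screened with the linear predictor held
   as an offset (a documented approximation); the recorded deviances always
   come from exact joint refits of nested models, so the sequence deviance is
   non-increasing.
3. :func:`select_tree` — picks the sequence member minimising BIC (or AIC),
   ties resolved toward the smaller tree.  The parameter count is the number
   of linear coefficients plus the number of leaves (the intercept is folded
   into the reference leaf), so tree fits and plain logistic fits on the same
   subjects are directly comparable.

Split-rule search space: binary variables offer their single split; genotype
variables offer the two allele-dose-respecting splits (dominant: hom-ref vs
carrier; recessive: hom-alt vs rest); unordered categorical variables with at
most five levels offer every two-set partition.  Missing tree-variable values
are sent to whichever side gives the smaller deviance and the chosen side is
recorded in the rule, so the tree keeps every subject that is complete on the
outcome and the linear terms.

The default minimum leaf size scales with the analysis set as
``max(10, round(0.05 n))`` — ten subjects at the reference cohort size of
125, five percent of larger cohorts (see :func:`default_min_leaf`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSpec
from .glm import GlmFit, build_design, fit_intercept_offset, fit_logistic, irls_logistic

_GAIN_EPS = 1e-9


class GpltrError(ValueError):
    pass


def default_min_leaf(n: int) -> int:
    """Minimum leaf size scaled with the analysis set: max(10, 5% of n).

    A tree can only isolate subgroups larger than the minimum leaf, so the
    default sits clearly below the ~8% granularity implied by the reference
    setting of 10 subjects at n=125 (roughly half of it), while still
    growing with the cohort to keep noise splits in check.
    """
    return max(10, int(round(0.05 * n)))


# ---------------------------------------------------------------------------
# tree data structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitRule:
    """Send a subject left iff its value is in ``left_levels`` (missing
    values go to ``missing_side``)."""

    variable: str
    left_levels: tuple[str, ...]
    missing_side: str = "right"

    def __post_init__(self):
        if self.missing_side not in ("left", "right"):
            raise GpltrError("missing_side must be 'left' or 'right'")
        if not self.left_levels:
            raise GpltrError("left_levels must be nonempty")


@dataclass
class TreeNode:
    id: int
    depth: int
    rule: SplitRule | None = None   # None => leaf
    left: int | None = None
    right: int | None = None
    n: int = 0
    events: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.rule is None


@dataclass
class PLTree:
    """A (possibly fitted) partially linear tree."""

    nodes: list[TreeNode]
    linear_terms: tuple[str, ...] = ()
    joint_fit: GlmFit | None = None

    @property
    def leaves(self) -> list[int]:
        return [nd.id for nd in self.nodes if nd.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def split_variables(self) -> set[str]:
        return {nd.rule.variable for nd in self.nodes if not nd.is_leaf}

    @property
    def depth(self) -> int:
        return max(nd.depth for nd in self.nodes)

    def node(self, nid: int) -> TreeNode:
        for nd in self.nodes:
            if nd.id == nid:
                return nd
        raise KeyError(nid)


@dataclass
class NestedSequence:
    """Forward chain of nested subtrees with joint-fit criteria per member."""

    trees: list[PLTree]
    records: list[dict] = field(default_factory=list)

    @property
    def deviances(self):
        return [r["deviance"] for r in self.records]


# ---------------------------------------------------------------------------
# internal fitting context (plain arrays, bootstrap-friendly)
# ---------------------------------------------------------------------------

class _Ctx:
    """Encoded analysis data for one cohort / variable selection.

    Rows are the complete cases over outcome + linear terms; tree-variable
    missingness is preserved as code -1 and handled by the split rules.
    """

    def __init__(self, cohort: CohortTable, linear_terms, tree_vars):
        if not tree_vars:
            raise GpltrError("tree_vars must be nonempty")
        linear_terms = list(linear_terms)
        X, lin_names, _, rows = build_design(cohort, linear_terms)
        self.rows = rows
        self.linear_terms = tuple(linear_terms)
        self.lin_names = lin_names
        self.X_lin = X
        out = cohort.outcome_spec
        yc = cohort.data[out.name].to_numpy()[rows]
        self.y = (yc != out.reference_level).astype(float)
        self.n = len(self.y)
        self.tree_vars = list(tree_vars)
        self.levels: dict[str, list[str]] = {}
        self.codes: dict[str, np.ndarray] = {}
        self.cands: dict[str, list[tuple[int, ...]]] = {}
        for v in self.tree_vars:
            spec = cohort.spec(v)
            if spec.coding not in ("binary", "categorical", "genotype"):
                raise GpltrError(f"tree variable {v!r} must be categorical-like")
            levels = list(spec.levels)
            col = cohort.data[v].to_numpy()[rows]
            code = np.full(self.n, -1, dtype=np.int8)
            for k, lv in enumerate(levels):
                code[col == lv] = k
            self.levels[v] = levels
            self.codes[v] = code
            self.cands[v] = _candidate_left_sets(spec.coding, len(levels))


def _candidate_left_sets(coding: str, k: int) -> list[tuple[int, ...]]:
    if coding == "binary":
        return [(0,)]
    if coding == "genotype":
        return [(0,), (0, 1)]  # dominant / recessive allele-dose splits
    if k > 5:
        raise GpltrError(f"categorical tree variable with {k} levels (max 5)")
    sets = []
    for size in range(1, k):
        for comb in combinations(range(k), size):
            if 0 in comb:  # fix level 0 on the left to avoid mirror duplicates
                sets.append(comb)
    return sets


@dataclass
class MaximalTreeFit:
    """Maximal tree plus the encoded data needed by later stages."""

    tree: PLTree
    min_leaf: int
    _ctx: _Ctx = field(repr=False)
    _idx: np.ndarray = field(repr=False)
    _node_pos: dict = field(repr=False)


class _View:
    """Positional view of a context for (possibly resampled) subjects."""

    def __init__(self, ctx: _Ctx, idx: np.ndarray):
        self.tree_vars = ctx.tree_vars
        self.levels = ctx.levels
        self.cands = ctx.cands
        self.y = ctx.y[idx]
        self.codes = {v: ctx.codes[v][idx] for v in ctx.tree_vars}


def _joint_fit_view(ctx: _Ctx, idx, leaf_of, leaf_ids, beta0=None):
    """Exact joint fit (intercept + linear + leaf dummies, first leaf ref)."""
    n = len(idx)
    q = 1 + ctx.X_lin.shape[1]
    Z = np.empty((n, q + len(leaf_ids) - 1))
    Z[:, 0] = 1.0
    if ctx.X_lin.shape[1]:
        Z[:, 1:q] = ctx.X_lin[idx]
    names = ["(intercept)"] + list(ctx.lin_names)
    for j, lid in enumerate(leaf_ids[1:]):
        Z[:, q + j] = leaf_of == lid
        names.append(f"leaf[{lid}]")
    y = ctx.y[idx]
    if beta0 is not None and len(beta0) != Z.shape[1]:
        beta0 = None
    beta, cov, dev, conv, it = irls_logistic(Z, y, beta0=beta0)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    fit = GlmFit(
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        deviance=dev, n=n, p=Z.shape[1], converged=conv, n_iter=it,
        terms=ctx.linear_terms, beta=beta, cov=cov)
    offset_lin = Z[:, :q] @ beta[:q]
    return fit, offset_lin


def _best_split(view: _View, sub, off, min_leaf):
    """Best admissible split of node subjects ``sub`` under offset ``off``."""
    y = view.y[sub]
    _, parent_dev = fit_intercept_offset(y, off)
    best = None
    for var in view.tree_vars:
        code = view.codes[var][sub]
        has_missing = bool((code < 0).any())
        for left_set in view.cands[var]:
            base = np.isin(code, left_set)
            for side in (("right", "left") if has_missing else ("right",)):
                m = base | (code < 0) if side == "left" else base
                n_l = int(m.sum())
                if n_l < min_leaf or len(m) - n_l < min_leaf:
                    continue
                _, dev_l = fit_intercept_offset(y[m], off[m])
                _, dev_r = fit_intercept_offset(y[~m], off[~m])
                gain = parent_dev - dev_l - dev_r
                if best is None or gain > best[0] + 1e-12:
                    levels = tuple(view.levels[var][i] for i in left_set)
                    best = (gain, SplitRule(var, levels, side), sub[m], sub[~m])
    if best is None or best[0] <= _GAIN_EPS:
        return None
    return best


def _grow_pass(view: _View, pos, offset_lin, min_leaf, max_depth):
    """One greedy maximal growth with a fixed offset.  Depth-first order so
    node ids are deterministic."""
    nodes: list[TreeNode] = []
    node_pos: dict[int, np.ndarray] = {}

    def make(depth, sub):
        nid = len(nodes)
        nodes.append(TreeNode(id=nid, depth=depth, n=len(sub),
                              events=int(view.y[sub].sum())))
        node_pos[nid] = sub
        return nid

    def split(nid):
        nd = nodes[nid]
        sub = node_pos[nid]
        if nd.depth >= max_depth or len(sub) < 2 * min_leaf:
            return
        found = _best_split(view, sub, offset_lin[sub], min_leaf)
        if found is None:
            return
        _, rule, left_sub, right_sub = found
        nd.rule = rule
        nd.left = make(nd.depth + 1, left_sub)
        split(nd.left)
        nd.right = make(nd.depth + 1, right_sub)
        split(nd.right)

    split(make(0, pos))
    return nodes, node_pos


def _grow_maximal(ctx: _Ctx, idx, min_leaf=None, max_depth=5,
                  tol=1e-6, max_outer=20) -> MaximalTreeFit:
    if min_leaf is None:
        min_leaf = default_min_leaf(len(idx))
    view = _View(ctx, idx)
    pos = np.arange(len(idx))
    leaf_of = np.zeros(len(idx), dtype=np.int64)
    fit, offset_lin = _joint_fit_view(ctx, idx, leaf_of, [0])
    prev_dev = fit.deviance
    nodes = [TreeNode(id=0, depth=0, n=len(idx), events=int(view.y.sum()))]
    node_pos = {0: pos}
    for _ in range(max_outer):
        nodes, node_pos = _grow_pass(view, pos, offset_lin, min_leaf, max_depth)
        leaf_ids = sorted(nd.id for nd in nodes if nd.is_leaf)
        leaf_of = np.zeros(len(idx), dtype=np.int64)
        for lid in leaf_ids:
            leaf_of[node_pos[lid]] = lid
        fit, offset_lin = _joint_fit_view(ctx, idx, leaf_of, leaf_ids)
        if abs(prev_dev - fit.deviance) < tol:
            break
        prev_dev = fit.deviance
    tree = PLTree(nodes=nodes, linear_terms=ctx.linear_terms, joint_fit=fit)
    return MaximalTreeFit(tree=tree, min_leaf=min_leaf,
                          _ctx=ctx, _idx=idx, _node_pos=node_pos)


def grow_maximal_tree(cohort: CohortTable, linear_terms, tree_vars,
                      min_leaf: int | None = None, max_depth: int = 5,
                      tol: float = 1e-6, max_outer: int = 20) -> MaximalTreeFit:
    """Iteratively grow the maximal partially linear tree on a cohort."""
    ctx = _Ctx(cohort, linear_terms, tree_vars)
    return _grow_maximal(ctx, np.arange(ctx.n), min_leaf, max_depth,
                         tol, max_outer)


# ---------------------------------------------------------------------------
# forward nested sequence and selection
# ---------------------------------------------------------------------------

def _subtree(nodes, expanded: set[int]) -> PLTree:
    """Materialise the subtree that expands exactly ``expanded`` node ids."""
    by_id = {nd.id: nd for nd in nodes}
    out = []
    reach = [0]
    while reach:
        nid = reach.pop()
        nd = by_id[nid]
        copy = TreeNode(id=nd.id, depth=nd.depth, n=nd.n, events=nd.events)
        if nid in expanded:
            copy.rule, copy.left, copy.right = nd.rule, nd.left, nd.right
            reach.extend([nd.left, nd.right])
        out.append(copy)
    out.sort(key=lambda nd: nd.id)
    return PLTree(nodes=out)


def forward_nested_sequence(maximal: MaximalTreeFit) -> NestedSequence:
    """Forward chain of nested subtrees of the maximal tree.

    Each step expands the frontier split with the largest offset-screened
    deviance gain, then records the exact joint refit.  Because each member
    nests the previous one and the refits are exact ML, the recorded deviance
    is non-increasing along the chain.
    """
    ctx, idx, node_pos = maximal._ctx, maximal._idx, maximal._node_pos
    nodes = {nd.id: nd for nd in maximal.tree.nodes}
    y = ctx.y[idx]

    expanded: set[int] = set()
    leaf_ids = [0]
    leaf_of = np.zeros(len(idx), dtype=np.int64)
    fit, offset_lin = _joint_fit_view(ctx, idx, leaf_of, leaf_ids)
    t0 = _subtree(maximal.tree.nodes, expanded)
    t0.linear_terms, t0.joint_fit = ctx.linear_terms, fit
    trees = [t0]
    records = [{"step": 0, "node": None, "variable": None, "gain": 0.0,
                "deviance": fit.deviance, "aic": fit.aic, "bic": fit.bic,
                "n_leaves": 1}]
    step = 0
    while True:
        frontier = [nid for nid in leaf_ids if nodes[nid].rule is not None]
        if not frontier:
            break
        best_nid, best_gain = None, -np.inf
        for nid in sorted(frontier):
            nd = nodes[nid]
            sub = node_pos[nid]
            _, dev_p = fit_intercept_offset(y[sub], offset_lin[sub])
            lsub, rsub = node_pos[nd.left], node_pos[nd.right]
            _, dev_l = fit_intercept_offset(y[lsub], offset_lin[lsub])
            _, dev_r = fit_intercept_offset(y[rsub], offset_lin[rsub])
            gain = dev_p - dev_l - dev_r
            if gain > best_gain + 1e-12:
                best_nid, best_gain = nid, gain
        nd = nodes[best_nid]
        expanded.add(best_nid)
        leaf_ids = sorted([lid for lid in leaf_ids if lid != best_nid]
                          + [nd.left, nd.right])
        for lid in (nd.left, nd.right):
            leaf_of[node_pos[lid]] = lid
        prev = fit
        fit, offset_lin = _joint_fit_view(ctx, idx, leaf_of, leaf_ids,
                                          beta0=_warm_start(prev, leaf_ids))
        step += 1
        records.append({"step": step, "node": int(best_nid),
                        "variable": nd.rule.variable,
                        "gain": float(prev.deviance - fit.deviance),
                        "deviance": fit.deviance, "aic": fit.aic,
                        "bic": fit.bic, "n_leaves": len(leaf_ids)})
        t = _subtree(maximal.tree.nodes, expanded)
        t.linear_terms, t.joint_fit = ctx.linear_terms, fit
        trees.append(t)
    return NestedSequence(trees=trees, records=records)


def _warm_start(prev: GlmFit, leaf_ids):
    """Previous coefficients re-aligned to the new leaf-dummy layout (new
    leaves start at zero; the exact refit restores optimality)."""
    base = [k for k in prev.coefficients if not k.startswith("leaf[")]
    new_names = base + [f"leaf[{lid}]" for lid in leaf_ids[1:]]
    return np.array([prev.coefficients.get(nm, 0.0) for nm in new_names])


def select_tree(seq: NestedSequence, criterion: str = "BIC") -> PLTree:
    """Sequence member minimising the criterion; ties go to the smaller tree."""
    key = criterion.lower()
    if key not in ("bic", "aic"):
        raise GpltrError("criterion must be 'BIC' or 'AIC'")
    vals = [r[key] for r in seq.records]
    best = 0
    for i, v in enumerate(vals):
        if v < vals[best] - 1e-9:
            best = i
    return seq.trees[best]


# ---------------------------------------------------------------------------
# top-level fit
# ---------------------------------------------------------------------------

@dataclass
class GpltrResult:
    maximal: PLTree
    sequence: NestedSequence
    optimal: PLTree
    criterion: str
    min_leaf: int
    rows: np.ndarray = field(default=None, repr=False)

    @property
    def selected_records(self) -> list[dict]:
        """Per-split records of the selected tree's prefix (importance input)."""
        k = self.sequence.trees.index(self.optimal)
        return self.sequence.records[1:k + 1]


def fit_gpltr(cohort: CohortTable, linear_terms, tree_vars,
              criterion: str = "BIC", min_leaf: int | None = None,
              max_depth: int = 5, tol: float = 1e-6,
              max_outer: int = 20) -> GpltrResult:
    """Grow, sequence and select the partially linear tree on a cohort."""
    ctx = _Ctx(cohort, linear_terms, tree_vars)
    return _fit_gpltr_ctx(ctx, np.arange(ctx.n), criterion, min_leaf,
                          max_depth, tol, max_outer)


def _fit_gpltr_ctx(ctx: _Ctx, idx, criterion="BIC", min_leaf=None,
                   max_depth=5, tol=1e-6, max_outer=20) -> GpltrResult:
    maximal = _grow_maximal(ctx, idx, min_leaf, max_depth, tol, max_outer)
    seq = forward_nested_sequence(maximal)
    optimal = select_tree(seq, criterion)
    return GpltrResult(maximal=maximal.tree, sequence=seq, optimal=optimal,
                       criterion=criterion.upper(), min_leaf=maximal.min_leaf,
                       rows=ctx.rows)


# ---------------------------------------------------------------------------
# leaf summaries, prediction, rendering
# ---------------------------------------------------------------------------

def assign_leaves(tree: PLTree, cohort: CohortTable, rows=None) -> np.ndarray:
    """Leaf id per subject (analysis rows), applying each node's SplitRule."""
    df = cohort.data if rows is None else cohort.data.loc[rows]
    n = len(df)
    out = np.zeros(n, dtype=np.int64)
    nodes = {nd.id: nd for nd in tree.nodes}
    col_cache: dict[str, np.ndarray] = {}
    active = {0: np.arange(n)}
    for nid in sorted(nodes):
        nd = nodes[nid]
        if nd.is_leaf or nid not in active:
            continue
        sub = active.pop(nid)
        r = nd.rule
        if r.variable not in col_cache:
            col_cache[r.variable] = df[r.variable].to_numpy()
        vals = col_cache[r.variable][sub]
        miss = pd.isna(vals)
        m = np.isin(vals, r.left_levels)
        m = (m | miss) if r.missing_side == "left" else (m & ~miss)
        active[nd.left] = sub[m]
        active[nd.right] = sub[~m]
    for lid, sub in active.items():
        out[sub] = lid
    return out


def leaf_summaries(tree: PLTree, cohort: CohortTable,
                   group_spec: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-leaf (or merged-branch) risk summary.

    Reports n, events, the raw event rate, the covariate-adjusted probability
    (mean fitted probability over member subjects), and the branch-vs-rest
    odds ratio from a logistic fit of the outcome on the branch indicator plus
    the tree's linear terms.  A single-leaf tree has no "rest": error.
    """
    lin = list(tree.linear_terms)
    X, _, _, rows = build_design(cohort, lin)
    leaf_of = assign_leaves(tree, cohort, rows)
    out_spec = cohort.outcome_spec
    y = (cohort.data[out_spec.name].to_numpy()[rows]
         != out_spec.reference_level).astype(float)
    groups = {lid: (group_spec.get(lid, str(lid)) if group_spec else str(lid))
              for lid in tree.leaves}
    labels = sorted(set(groups.values()), key=str)
    if len(labels) < 2:
        raise GpltrError("branch-vs-rest odds ratio undefined for a single "
                         "branch; need at least two leaves/branches")
    fitted = (_fitted_probs(tree, X, leaf_of) if tree.joint_fit is not None
              else np.full(len(y), np.nan))
    recs = []
    for lab in labels:
        member = np.isin(leaf_of, [lid for lid, g in groups.items() if g == lab])
        if member.sum() == 0:
            raise GpltrError(f"empty branch {lab!r}")
        n_g = int(member.sum())
        ev = int(y[member].sum())
        or_, lo, hi = _branch_or(cohort, rows, member, lin)
        adj = (float(np.mean(fitted[member]))
               if tree.joint_fit is not None else float("nan"))
        recs.append({"branch": lab, "n": n_g, "events": ev,
                     "raw_rate": ev / n_g,
                     "adjusted_probability": adj,
                     "or_vs_rest": or_, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(recs)


def _fitted_probs(tree: PLTree, X_lin, leaf_of):
    coefs = tree.joint_fit.coefficients
    eta = np.full(len(leaf_of), coefs["(intercept)"], dtype=float)
    lin_names = [k for k in coefs if k != "(intercept)" and not k.startswith("leaf[")]
    for j, nm in enumerate(lin_names):
        eta += coefs[nm] * X_lin[:, j]
    for k, v in coefs.items():
        if k.startswith("leaf["):
            eta += v * (leaf_of == int(k[5:-1]))
    return 1.0 / (1.0 + np.exp(-eta))


def _branch_or(cohort, rows, member, linear_terms):
    from scipy.stats import norm

    work = cohort.data.loc[rows].copy().reset_index(drop=True)
    work["_branch_"] = np.where(member, "in", "out")
    specs = list(cohort.dictionary) + [
        VariableSpec(name="_branch_", role="linear", coding="binary",
                     levels=("out", "in"))]
    sub = CohortTable(work, specs)
    fit = fit_logistic(sub, ["_branch_"] + list(linear_terms))
    b = fit.coefficients["_branch_[in]"]
    se = fit.standard_errors["_branch_[in]"]
    z = norm.ppf(0.975)
    return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se))


def render_tree(tree: PLTree, format: str = "ascii") -> str:
    """Deterministic serialisation (ascii sketch or lossless JSON)."""
    if format == "json":
        payload = {
            "linear_terms": list(tree.linear_terms),
            "nodes": [_node_dict(nd) for nd in tree.nodes],
        }
        return json.dumps(payload, indent=2, sort_keys=True)
    if format != "ascii":
        raise GpltrError("format must be 'ascii' or 'json'")
    nodes = {nd.id: nd for nd in tree.nodes}
    lines: list[str] = []

    def walk(nid, prefix):
        nd = nodes[nid]
        if nd.is_leaf:
            lines.append(f"{prefix}leaf#{nd.id} n={nd.n} events={nd.events}")
            return
        r = nd.rule
        lines.append(f"{prefix}node#{nd.id} split {r.variable} in "
                     f"{{{', '.join(r.left_levels)}}} (missing->{r.missing_side}) "
                     f"n={nd.n}")
        walk(nd.left, prefix + "  ")
        walk(nd.right, prefix + "  ")

    walk(0, "")
    return "\n".join(lines)


def _node_dict(nd: TreeNode) -> dict:
    d = {"id": nd.id, "depth": nd.depth, "n": nd.n, "events": nd.events}
    if nd.is_leaf:
        d["leaf"] = True
    else:
        d.update({"variable": nd.rule.variable,
                  "left_levels": list(nd.rule.left_levels),
                  "missing_side": nd.rule.missing_side,
                  "left": nd.left, "right": nd.right})
    return d


def parse_tree(serialized: str) -> PLTree:
    """Inverse of ``render_tree(format='json')``."""
    payload = json.loads(serialized)
    nodes = []
    for d in sorted(payload["nodes"], key=lambda x: x["id"]):
        nd = TreeNode(id=d["id"], depth=d["depth"], n=d.get("n", 0),
                      events=d.get("events", 0))
        if not d.get("leaf"):
            nd.rule = SplitRule(d["variable"], tuple(d["left_levels"]),
                                d["missing_side"])
            nd.left, nd.right = d["left"], d["right"]
        nodes.append(nd)
    return PLTree(nodes=nodes, linear_terms=tuple(payload["linear_terms"]))


__all__ = [
    "SplitRule", "TreeNode", "PLTree", "NestedSequence", "MaximalTreeFit",
    "GpltrResult", "GpltrError", "default_min_leaf", "fit_gpltr",
    "grow_maximal_tree", "forward_nested_sequence", "select_tree",
    "leaf_summaries", "assign_leaves", "render_tree", "parse_tree",
]
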