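"""End-to-end study-replication pipeline.

Runs the analysis stages in the order the study design implies — simulate (or
load) a cohort, describe it, univariate genetic association + Hardy-Weinberg
checks, haplotype analysis, stepwise multivariate logistic regression, the
partially linear tree, and bagged variable importance — writing one TSV/JSON
bundle per stage plus a run manifest with seeds, subject counts and
exclusions.  Every stage is a thin wrapper over the library modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (GenotypeCounts, TwoByTwo, adjusted_univariate_or,
                          genotype_or_table, hwe_test, odds_ratio)
from .bagging import bag_gpltr, rank_variables
from .cohort import CohortTable, CohortError, read_cohort, summarize, write_cohort
from .glm import stepwise_forward
from .gpltr import fit_gpltr, leaf_summaries, render_tree
from .haplotype import haplotype_assoc_test
from .simulate import (DEFAULT_LINEAR_TERMS, SimConfig, default_tree_vars,
                       generate_cohort)

logger = logging.getLogger(__name__)

ALL_STAGES = ("describe", "assoc", "hwe", "haplo", "logistic", "gpltr", "bag")


@dataclass
class RunConfig:
    """One pipeline run: input (file pair or simulation), stages, outputs."""

    outdir: str = "pltr_out"
    seed: int = 0
    table: str | None = None
    dictionary: str | None = None
    simulate: dict = field(default_factory=dict)   # SimConfig overrides
    stages: tuple[str, ...] = ALL_STAGES
    eligibility: tuple[str, ...] = ()
    linear_terms: tuple[str, ...] = tuple(DEFAULT_LINEAR_TERMS)
    options: dict = field(default_factory=dict)    # per-stage extras

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def eligibility_filter(cohort: CohortTable, flags: list[str]):
    """Drop subjects failing any requested yes/no eligibility flag.

    A subject failing several flags is attributed to the first failing flag
    in the given order.  Returns ``(filtered_cohort, report)`` with
    per-criterion exclusion counts; removing every subject is fatal.
    """
    if not flags:
        return cohort, {"n_in": cohort.n, "n_out": cohort.n, "excluded": {}}
    keep = np.ones(cohort.n, dtype=bool)
    excluded = {}
    for flag in flags:
        if flag not in cohort.data.columns:
            raise CohortError(f"eligibility flag column {flag!r} absent")
        fails = (cohort.data[flag] != "yes").to_numpy() & keep
        excluded[flag] = int(fails.sum())
        keep &= ~fails
    if not keep.any():
        raise CohortError("eligibility filter removed every subject")
    report = {"n_in": cohort.n, "n_out": int(keep.sum()), "excluded": excluded}
    return cohort.subset(keep), report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_describe(cohort, outdir, **_):
    frames = []
    for s in cohort.dictionary:
        if s.role in ("linear", "tree", "stratum"):
            t = summarize(cohort, s.name)
            t.insert(0, "level", t.index)
            t.insert(0, "variable", s.name)
            frames.append(t.reset_index(drop=True))
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(Path(outdir) / "describe.tsv", sep="\t", index=False)
    return {"n_variables": int(out["variable"].nunique())}


def _genotype_counts(cohort, snp):
    spec = cohort.spec(snp)
    out_spec = cohort.outcome_spec
    col, oc = cohort.data[snp], cohort.data[out_spec.name]
    case = oc != out_spec.reference_level
    ev = tuple(int(((col == lv) & case).sum()) for lv in spec.levels)
    ne = tuple(int(((col == lv) & ~case).sum()) for lv in spec.levels)
    return GenotypeCounts(ev, ne, n_missing=int(col.isna().sum()))


def stage_assoc(cohort, outdir, **_):
    rows = []
    out_spec = cohort.outcome_spec
    case = cohort.data[out_spec.name] != out_spec.reference_level
    for s in cohort.dictionary:
        if s.role != "tree":
            continue
        col = cohort.data[s.name]
        n_missing = int(col.isna().sum())
        if s.coding == "binary":
            exposed = col == s.levels[1]
            t = TwoByTwo(int((exposed & case).sum()), int((exposed & ~case).sum()),
                         int((~exposed & ~col.isna() & case).sum()),
                         int((~exposed & ~col.isna() & ~case).sum()))
            try:
                r = odds_ratio(t, correction=True)
                rows.append({"variable": s.name, "contrast": f"{s.levels[1]} vs {s.levels[0]}",
                             "n_case": t.a, "n_control": t.b, "or": r.estimate,
                             "ci_low": r.ci_low, "ci_high": r.ci_high,
                             "p": r.p_value, "test": r.test,
                             "missing": n_missing})
            except Exception as exc:  # degenerate marker
                rows.append({"variable": s.name, "contrast": "carrier",
                             "note": str(exc), "missing": n_missing})
        elif s.coding == "genotype":
            g = _genotype_counts(cohort, s.name)
            try:
                results, overall_p, test = genotype_or_table(g)
                for r in results:
                    rows.append({"variable": s.name, "contrast": r.label,
                                 "or": r.estimate, "ci_low": r.ci_low,
                                 "ci_high": r.ci_high, "p": overall_p,
                                 "test": test, "missing": n_missing})
            except Exception as exc:
                rows.append({"variable": s.name, "note": str(exc),
                             "missing": n_missing})
    pd.DataFrame(rows).to_csv(Path(outdir) / "assoc_genetic.tsv",
                              sep="\t", index=False)
    return {"n_tests": len(rows)}


def stage_hwe(cohort, outdir, **_):
    rows = []
    for s in cohort.dictionary:
        if s.coding == "genotype":
            g = _genotype_counts(cohort, s.name)
            p, mono = hwe_test(g.pooled())
            rows.append({"snp": s.name, "n_refref": g.pooled()[0],
                         "n_refalt": g.pooled()[1], "n_altalt": g.pooled()[2],
                         "p_hwe": p, "monomorphic": mono})
    pd.DataFrame(rows).to_csv(Path(outdir) / "hwe.tsv", sep="\t", index=False)
    return {"n_snps": len(rows)}


def stage_haplo(cohort, outdir, seed=0, n_perm=1000,
                targets=(("DRB1*15", "DQB1*06"), ("DRB1*04", "DQB1*03")), **_):
    rows = []
    for target in targets:
        r = haplotype_assoc_test(cohort, "DRB1", "DQB1", tuple(target),
                                 n_perm=n_perm, seed=seed)
        rows.append({"haplotype": "-".join(target), "freq_pooled": r.freq_pooled,
                     "freq_case": r.freq_case, "freq_control": r.freq_control,
                     "diff": r.statistic, "p_perm": r.p_value, "n": r.n_used,
                     "n_perm": r.n_perm, "observed": r.target_observed})
    pd.DataFrame(rows).to_csv(Path(outdir) / "haplotype.tsv", sep="\t", index=False)
    return {"n_targets": len(rows)}


def stage_logistic(cohort, outdir, linear_terms=DEFAULT_LINEAR_TERMS, **_):
    candidates = list(linear_terms) + ["blood_group"]
    for s in cohort.dictionary:
        if s.role == "tree":
            candidates.append(s.name if s.coding != "genotype"
                              else f"{s.name}:dominant")
    candidates = [c for c in dict.fromkeys(candidates)
                  if c.split(":")[0] in cohort.data.columns]
    fit, trace = stepwise_forward(cohort, candidates)
    pd.DataFrame(fit.wald_table()).to_csv(Path(outdir) / "logistic_model.tsv",
                                          sep="\t", index=False)
    with open(Path(outdir) / "logistic_trace.json", "w") as fh:
        json.dump({"trace": trace, "aic": fit.aic, "bic": fit.bic,
                   "deviance": fit.deviance, "n": fit.n,
                   "terms": list(fit.terms)}, fh, indent=2)
    return {"aic": fit.aic, "n_terms": len(fit.terms), "n": fit.n}


def stage_gpltr(cohort, outdir, linear_terms=DEFAULT_LINEAR_TERMS,
                criterion="BIC", min_leaf=None, max_depth=5, **_):
    tree_vars = [s.name for s in cohort.dictionary if s.role == "tree"]
    res = fit_gpltr(cohort, list(linear_terms), tree_vars,
                    criterion=criterion, min_leaf=min_leaf, max_depth=max_depth)
    outdir = Path(outdir)
    (outdir / "tree.json").write_text(render_tree(res.optimal, "json"))
    (outdir / "tree.txt").write_text(render_tree(res.optimal, "ascii"))
    pd.DataFrame(res.sequence.records).to_csv(outdir / "model_fit.tsv",
                                              sep="\t", index=False)
    if res.optimal.n_leaves > 1:
        leaf_summaries(res.optimal, cohort).to_csv(
            outdir / "leaf_summaries.tsv", sep="\t", index=False)
    return {"n_leaves": res.optimal.n_leaves,
            "split_variables": sorted(res.optimal.split_variables),
            "aic": res.optimal.joint_fit.aic,
            "bic": res.optimal.joint_fit.bic,
            "min_leaf": res.min_leaf}


def stage_bag(cohort, outdir, linear_terms=DEFAULT_LINEAR_TERMS, B=100,
              seed=0, stratified=False, min_leaf=None, **_):
    tree_vars = [s.name for s in cohort.dictionary if s.role == "tree"]
    r = bag_gpltr(cohort, list(linear_terms), tree_vars, B=B, seed=seed,
                  stratified=stratified, min_leaf=min_leaf)
    ranked = rank_variables(r)
    pd.DataFrame(ranked, columns=["variable", "dis", "selection_freq"]).to_csv(
        Path(outdir) / "dis.tsv", sep="\t", index=False)
    with open(Path(outdir) / "dis.json", "w") as fh:
        json.dump({"B": r.B, "n_failed": r.n_failed, "seed": r.seed,
                   "dis": r.dis, "selection_freq": r.selection_freq}, fh,
                  indent=2)
    return {"top": ranked[0][0], "B": r.B, "n_failed": r.n_failed}


STAGE_FUNCS = {"describe": stage_describe, "assoc": stage_assoc,
               "hwe": stage_hwe, "haplo": stage_haplo,
               "logistic": stage_logistic, "gpltr": stage_gpltr,
               "bag": stage_bag}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": {}}
    if config.table:
        cohort = read_cohort(config.table, config.dictionary)
        manifest["input"] = {"table": config.table, "n": cohort.n}
    else:
        sim = SimConfig(seed=config.seed, **config.simulate)
        cohort, truth = generate_cohort(sim)
        write_cohort(cohort, str(outdir / "cohort.tsv"),
                     str(outdir / "dictionary.yaml"))
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        (outdir / "sim_config.json").write_text(sim.to_json())
        manifest["input"] = {"simulated": True, "n": cohort.n,
                             "sim_seed": sim.seed}
    cohort, report = eligibility_filter(cohort, list(config.eligibility))
    manifest["eligibility"] = report
    opts = dict(config.options)
    for stage in config.stages:
        if stage not in STAGE_FUNCS:
            raise CohortError(f"unknown stage {stage!r}")
        try:
            info = STAGE_FUNCS[stage](
                cohort, outdir, seed=config.seed,
                linear_terms=list(config.linear_terms),
                **opts.get(stage, {}))
            manifest["stages"][stage] = {"status": "ok", **info}
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


__all__ = ["RunConfig", "run_pipeline", "eligibility_filter", "ALL_STAGES"]
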