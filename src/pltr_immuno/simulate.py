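"""Synthetic severe-hemophilia-A cohort generator.

Generates case/control cohorts with the statistical structure the analysis
pipeline assumes, so that every downstream stage (association tests, EM
haplotype analysis, stepwise logistic regression, partially linear trees,
bagging) can be exercised and calibrated without access to patient data:

* HLA-DRB1/DQB1 drawn as two independent haplotypes per subject from a
  haplotype frequency table, which induces realistic linkage disequilibrium
  (e.g. the classic DRB1*15-DQB1*06 association) in the derived per-allele
  carrier indicators;
* biallelic SNPs drawn under Hardy-Weinberg equilibrium (two independent
  allele draws);
* an HMOX1 (GT)n promoter repeat pair with short/medium/long allele classes;
* independent clinical covariates (F8 mutation risk class, 3-level family
  history, FVIII product type, blood group, birth-cohort stratum);
* a partially linear logistic outcome: linear log-odds effects for the
  clinical confounders plus a planted tree-structured interaction over the
  genetic variables, with per-leaf event-probability targets calibrated
  exactly against the clinical-covariate distribution.

The default parameter set emulates the structure of the study cohort this
package is built around: carrier and genotype frequencies follow the
inhibitor-negative reference group of a German severe-HA case/control sample,
the linear log-odds are the adjusted odds ratios of its multivariate model
(4.34 for high-risk F8 mutations, 7.19 for a family history of inhibitors,
3.69 for recombinant product), the baseline corresponds to a 46.4% event
rate, and the planted tree reproduces the reported three-branch risk
stratification (leaf probabilities 0.77 / 0.47 / 0.12).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import CohortTable, VariableSpec, genotype_levels, recode_hmox1


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# default parameters (inhibitor-negative reference population)
# ---------------------------------------------------------------------------

# (DRB1 allele, DQB1 allele) -> haplotype frequency; classic European
# DRB1-DQB1 pairings, allele frequencies back-computed from carrier rates
# of the reference group (carrier = 1 - (1-h)^2).
DEFAULT_HLA_HAPLOTYPES = {
    ("DRB1*01", "DQB1*05"): 0.146,
    ("DRB1*03", "DQB1*02"): 0.067,
    ("DRB1*04", "DQB1*03"): 0.094,
    ("DRB1*07", "DQB1*02"): 0.117,
    ("DRB1*08", "DQB1*04"): 0.066,
    ("DRB1*11", "DQB1*03"): 0.194,
    ("DRB1*13", "DQB1*06"): 0.154,
    ("DRB1*15", "DQB1*06"): 0.117,
    ("DRB1*16", "DQB1*05"): 0.015,
    ("DRB1*X", "DQB1*X"): 0.030,
}

# snp -> (ref allele, alt allele, alt-allele frequency)
DEFAULT_SNPS = {
    "il10_rs1800896": ("G", "A", 0.380),
    "tnf_rs1800629": ("G", "A", 0.171),
    "ctla4_rs3087243": ("A", "G", 0.538),
    "cd32_rs1801274": ("G", "A", 0.570),
    "mapk9_rs4147385": ("C", "T", 0.234),
    "cd86_pro_rs2715267": ("A", "C", 0.266),
    "cd86_ex4_rs2681417": ("A", "G", 0.051),
    "cd86_ex7_rs1129055": ("G", "A", 0.323),
    "cd86_utr_rs2681401": ("G", "T", 0.500),
}

DEFAULT_HMOX1_ALLELE_CLASSES = {"S": 0.34, "M": 0.51, "L": 0.15}

DEFAULT_CLINICAL = {
    "f8_risk": {"low": 0.37, "high": 0.63},
    "family_history": {"ha_no_inh": 0.226, "none": 0.725, "ha_inh": 0.049},
    "product_type": {"plasma": 0.84, "recombinant": 0.16},
    "blood_group": {"O": 0.37, "other": 0.63},
    "birth_cohort": {"pre1978": 0.30, "1978_1995": 0.40, "post1995": 0.30},
}

DEFAULT_LINEAR_EFFECTS = {
    "f8_risk": {"high": math.log(4.34)},
    "family_history": {"none": math.log(1.51), "ha_inh": math.log(7.19)},
    "product_type": {"recombinant": math.log(3.69)},
}

# planted genetic interaction: the three-branch risk stratification
DEFAULT_TREE = {
    "variable": "hla_drb1_15", "left_levels": ["yes"],
    "left": {
        "variable": "il10_rs1800896", "left_levels": ["G/A", "A/A"],
        "left": {"leaf": "high_drb115_il10", "target": 0.77},
        "right": {"leaf": "int_drb115_il10gg", "target": 0.47},
    },
    "right": {
        "variable": "hla_dqb1_02", "left_levels": ["yes"],
        "left": {"leaf": "int_dqb102", "target": 0.47},
        "right": {
            "variable": "cd86_utr_rs2681401", "left_levels": ["G/T", "T/T"],
            "left": {"leaf": "low_cd86", "target": 0.12},
            "right": {"leaf": "int_cd86gg", "target": 0.47},
        },
    },
}

HLA_CARRIER_ALLELES = [
    "DRB1*01", "DRB1*03", "DRB1*04", "DRB1*07", "DRB1*08", "DRB1*11",
    "DRB1*13", "DRB1*15", "DRB1*16",
    "DQB1*02", "DQB1*03", "DQB1*04", "DQB1*05", "DQB1*06",
]


def _carrier_column(allele: str) -> str:
    return "hla_" + allele.replace("DRB1*", "drb1_").replace("DQB1*", "dqb1_")


@dataclass
class SimConfig:
    """Full description of one simulated cohort."""

    n: int = 125
    seed: int = 0
    hla_haplotype_freqs: dict = field(
        default_factory=lambda: dict(DEFAULT_HLA_HAPLOTYPES))
    snp_allele_freqs: dict = field(default_factory=lambda: dict(DEFAULT_SNPS))
    hmox1_class_freqs: dict = field(
        default_factory=lambda: dict(DEFAULT_HMOX1_ALLELE_CLASSES))
    clinical_freqs: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CLINICAL))
    linear_effects: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_LINEAR_EFFECTS))
    tree_spec: dict | None = field(default_factory=lambda: copy.deepcopy(DEFAULT_TREE))
    baseline_log_odds: float = float(logit(0.464))
    missing_rates: dict = field(default_factory=dict)
    well_documented_rate: float = 0.8

    def __post_init__(self):
        tot = sum(self.hla_haplotype_freqs.values())
        if abs(tot - 1.0) > 1e-9:
            raise SimulationError(f"haplotype frequencies sum to {tot}, not 1")
        for name, (_, _, f) in self.snp_allele_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise SimulationError(f"{name}: allele frequency {f} outside [0,1]")
        for var, freqs in self.clinical_freqs.items():
            s = sum(freqs.values())
            if abs(s - 1.0) > 1e-6:
                raise SimulationError(f"{var}: level frequencies sum to {s}")
        for var, rate in self.missing_rates.items():
            if not 0.0 <= rate < 1.0:
                raise SimulationError(f"{var}: missing rate {rate} outside [0,1)")

    def to_json(self) -> str:
        d = asdict(self)
        d["hla_haplotype_freqs"] = {f"{a}|{b}": v for (a, b), v
                                    in self.hla_haplotype_freqs.items()}
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# planted-tree helpers
# ---------------------------------------------------------------------------

def _tree_leaves(node) -> list[dict]:
    if "leaf" in node:
        return [node]
    return _tree_leaves(node["left"]) + _tree_leaves(node["right"])


def planted_variables(config: SimConfig) -> set[str]:
    """Names of the variables the planted tree splits on."""
    out = set()

    def walk(node):
        if "leaf" in node:
            return
        out.add(node["variable"])
        walk(node["left"])
        walk(node["right"])

    if config.tree_spec:
        walk(config.tree_spec)
    return out


def resolve_leaf_offsets(config: SimConfig) -> dict[str, float]:
    """Calibrate per-leaf log-odds offsets against the clinical distribution.

    A leaf specification may give ``offset`` (log-odds, used as-is) or
    ``target`` (a marginal event probability).  Because the planted tree uses
    only genetic variables, which the generator draws independently of the
    clinical covariates, the marginal leaf event rate is the expectation of
    ``expit(baseline + v + c)`` over the finite distribution of linear
    contributions ``v``; the offset ``c`` hitting a target is found by root
    bisection on that expectation.
    """
    if config.tree_spec is None:
        return {}
    # enumerate the linear-contribution distribution
    vals = np.array([0.0])
    probs = np.array([1.0])
    for var, effects in config.linear_effects.items():
        freqs = config.clinical_freqs[var]
        lv_vals = np.array([effects.get(lv, 0.0) for lv in freqs])
        lv_probs = np.array(list(freqs.values()))
        vals = (vals[:, None] + lv_vals[None, :]).ravel()
        probs = (probs[:, None] * lv_probs[None, :]).ravel()

    def marginal_rate(c):
        return float(np.sum(probs * expit(config.baseline_log_odds + vals + c)))

    out = {}
    for leaf in _tree_leaves(config.tree_spec):
        if "offset" in leaf:
            out[leaf["leaf"]] = float(leaf["offset"])
        else:
            t = float(leaf["target"])
            if not 0.0 < t < 1.0:
                raise SimulationError(f"leaf target {t} outside (0,1)")
            out[leaf["leaf"]] = float(brentq(
                lambda c: marginal_rate(c) - t, -25.0, 25.0, xtol=1e-12))
    return out


def _assign_planted(node, df: pd.DataFrame, idx, leaf_of):
    if "leaf" in node:
        leaf_of[idx] = node["leaf"]
        return
    vals = df[node["variable"]].to_numpy()[idx]
    if pd.isna(vals).any():
        raise SimulationError(
            f"planted tree saw missing {node['variable']} (outcome must be "
            "generated before missingness injection)")
    m = np.isin(vals, node["left_levels"])
    _assign_planted(node["left"], df, idx[m], leaf_of)
    _assign_planted(node["right"], df, idx[~m], leaf_of)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw HLA haplotype pairs, HWE SNP genotypes and HMOX1 repeats."""
    n = config.n
    haps = list(config.hla_haplotype_freqs)
    hap_p = np.array([config.hla_haplotype_freqs[h] for h in haps])
    draw1 = rng.choice(len(haps), size=n, p=hap_p)
    draw2 = rng.choice(len(haps), size=n, p=hap_p)
    cols: dict[str, object] = {}
    drb = np.array([haps[i][0] for i in range(len(haps))])
    dqb = np.array([haps[i][1] for i in range(len(haps))])
    cols["DRB1_a1"], cols["DRB1_a2"] = drb[draw1], drb[draw2]
    cols["DQB1_a1"], cols["DQB1_a2"] = dqb[draw1], dqb[draw2]
    for allele in HLA_CARRIER_ALLELES:
        locus = "DRB1" if allele.startswith("DRB1") else "DQB1"
        carrier = ((cols[f"{locus}_a1"] == allele)
                   | (cols[f"{locus}_a2"] == allele))
        cols[_carrier_column(allele)] = np.where(carrier, "yes", "no")
    for snp, (ref, alt, f_alt) in config.snp_allele_freqs.items():
        dose = rng.binomial(1, f_alt, n) + rng.binomial(1, f_alt, n)
        levels = genotype_levels(ref, alt)
        cols[snp] = np.array(levels)[dose]
    # HMOX1: draw an allele class, then a repeat count within the class
    classes = list(config.hmox1_class_freqs)
    cls_p = np.array([config.hmox1_class_freqs[c] for c in classes])
    cls_p = cls_p / cls_p.sum()
    ranges = {"S": (14, 20), "M": (21, 29), "L": (30, 38)}
    for a in ("a1", "a2"):
        cl = rng.choice(len(classes), size=n, p=cls_p)
        reps = np.array([rng.integers(*ranges[classes[c]], endpoint=True)
                         for c in cl])
        cols[f"hmox1_rep_{a}"] = reps.astype(str)
    r1 = cols["hmox1_rep_a1"].astype(int)
    r2 = cols["hmox1_rep_a2"].astype(int)
    c1 = np.array([recode_hmox1(v) for v in r1])
    c2 = np.array([recode_hmox1(v) for v in r2])
    cols["hmox1_class"] = np.array(
        ["".join(sorted((a, b))) for a, b in zip(c1, c2)])
    cols["hmox1_l_carrier"] = np.where((c1 == "L") | (c2 == "L"), "yes", "no")
    return pd.DataFrame(cols)


def simulate_clinical(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n
    cols = {}
    for var, freqs in config.clinical_freqs.items():
        levels = list(freqs)
        p = np.array([freqs[lv] for lv in levels])
        cols[var] = np.array(levels)[rng.choice(len(levels), size=n, p=p)]
    cols["well_documented"] = np.where(
        rng.random(n) < config.well_documented_rate, "yes", "no")
    cols["severe"] = np.full(n, "yes")
    cols["exposure_50d"] = np.full(n, "yes")
    return pd.DataFrame(cols)


def simulate_outcome(config: SimConfig, genotypes: pd.DataFrame,
                     clinical: pd.DataFrame, rng: np.random.Generator):
    """Bernoulli outcome from the partially linear truth model.

    Returns ``(outcome_labels, truth)`` where ``truth`` records each
    subject's planted leaf, linear predictor and event probability.
    """
    n = config.n
    eta = np.full(n, config.baseline_log_odds)
    for var, effects in config.linear_effects.items():
        src = clinical if var in clinical.columns else genotypes
        if var not in src.columns:
            raise SimulationError(f"linear effect on unknown variable {var!r}")
        vals = src[var].to_numpy()
        for lv, b in effects.items():
            eta += b * (vals == lv)
    leaf_of = np.full(n, "root", dtype=object)
    if config.tree_spec is not None:
        offsets = resolve_leaf_offsets(config)
        _assign_planted(config.tree_spec, genotypes, np.arange(n), leaf_of)
        eta += np.array([offsets[l] for l in leaf_of])
    prob = expit(eta)
    y = rng.random(n) < prob
    truth = pd.DataFrame({
        "leaf": leaf_of,
        "linear_predictor": eta,
        "event_probability": prob,
        "outcome": np.where(y, "inh+", "inh-"),
    })
    return np.where(y, "inh+", "inh-"), truth


def build_dictionary(config: SimConfig) -> list[VariableSpec]:
    specs = [
        VariableSpec("subject_id", "id", "count"),
        VariableSpec("inhibitor", "outcome", "binary", ("inh-", "inh+")),
    ]
    clin_roles = {"f8_risk": "linear", "family_history": "linear",
                  "product_type": "linear", "blood_group": "linear",
                  "birth_cohort": "stratum"}
    clin_refs = {"family_history": "ha_no_inh"}
    for var, freqs in config.clinical_freqs.items():
        levels = tuple(freqs)
        coding = "binary" if len(levels) == 2 else "categorical"
        specs.append(VariableSpec(var, clin_roles.get(var, "linear"), coding,
                                  levels, clin_refs.get(var, levels[0])))
    for flag in ("well_documented", "severe", "exposure_50d"):
        specs.append(VariableSpec(flag, "ignore", "binary", ("no", "yes")))
    hla_alleles = sorted({a for pair in config.hla_haplotype_freqs for a in pair})
    for col in ("DRB1_a1", "DRB1_a2", "DQB1_a1", "DQB1_a2"):
        locus = col.split("_")[0]
        levels = tuple(a for a in hla_alleles if a.startswith(locus))
        specs.append(VariableSpec(col, "ignore", "categorical", levels))
    for allele in HLA_CARRIER_ALLELES:
        specs.append(VariableSpec(_carrier_column(allele), "tree", "binary",
                                  ("no", "yes")))
    for snp, (ref, alt, _) in config.snp_allele_freqs.items():
        specs.append(VariableSpec(snp, "tree", "genotype",
                                  ref_allele=ref, alt_allele=alt))
    specs.append(VariableSpec("hmox1_rep_a1", "ignore", "count"))
    specs.append(VariableSpec("hmox1_rep_a2", "ignore", "count"))
    specs.append(VariableSpec("hmox1_class", "ignore", "categorical",
                              ("LL", "LM", "LS", "MM", "MS", "SS")))
    specs.append(VariableSpec("hmox1_l_carrier", "tree", "binary", ("no", "yes")))
    return specs


def generate_cohort(config: SimConfig):
    """Generate a full cohort table plus its per-subject truth record.

    Deterministic given ``config.seed``.  Missingness (``missing_rates``) is
    injected after the outcome is generated, so the truth record always
    reflects complete genotypes.
    """
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    clinical = simulate_clinical(config, rng)
    outcome, truth = simulate_outcome(config, genotypes, clinical, rng)
    df = pd.concat([clinical, genotypes], axis=1)
    df.insert(0, "inhibitor", outcome)
    df.insert(0, "subject_id", [str(i + 1) for i in range(config.n)])
    for var, rate in config.missing_rates.items():
        if var not in df.columns:
            raise SimulationError(f"missing rate for unknown variable {var!r}")
        mask = rng.random(config.n) < rate
        df.loc[mask, var] = np.nan
    cohort = CohortTable(df, build_dictionary(config))
    truth.insert(0, "subject_id", df["subject_id"].to_numpy())
    return cohort, truth


def default_tree_vars(config: SimConfig | None = None) -> list[str]:
    """The full genetic candidate set for the tree part."""
    config = config or SimConfig()
    return ([_carrier_column(a) for a in HLA_CARRIER_ALLELES]
            + list(config.snp_allele_freqs)
            + ["hmox1_l_carrier"])


DEFAULT_LINEAR_TERMS = ["f8_risk", "family_history", "product_type"]


__all__ = [
    "SimConfig", "SimulationError", "simulate_genotypes", "simulate_clinical",
    "simulate_outcome", "generate_cohort", "resolve_leaf_offsets",
    "planted_variables", "build_dictionary", "default_tree_vars",
    "DEFAULT_LINEAR_TERMS", "DEFAULT_TREE", "HLA_CARRIER_ALLELES",
]
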