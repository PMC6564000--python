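"""Cohort data model: typed variable dictionary, validated per-subject table.

A cohort is a rectangular table of subjects crossed with declared variables.
Every analysis column carries a :class:`VariableSpec` describing its role in
the modelling (outcome / linear confounder / tree-part genetic variable /
stratum / id) and its coding (binary, categorical, genotype, count).  Values
are stored as strings (pandas object dtype) with ``NaN`` marking missing; all
numeric encoding happens downstream in the design-matrix builders, so the
table round-trips losslessly through delimited text.

HLA variables are represented as per-allele carrier indicators (present on at
least one chromosome); the raw two-allele columns are kept alongside, with
role ``ignore``, for haplotype analysis.  The HMOX1 (GT)n promoter repeat is
recoded into the short/medium/long classes used in the hemophilia literature
via :func:`recode_hmox1`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ROLES = frozenset({"outcome", "linear", "tree", "stratum", "id", "ignore"})
CODINGS = frozenset({"binary", "categorical", "genotype", "count"})

DEFAULT_MISSING_CODES = ("", "NA", "NaN", "nan", ".")


class CohortError(ValueError):
    """Fatal cohort validation problem (bad dictionary, undeclared level...)."""


def genotype_levels(ref_allele: str, alt_allele: str) -> tuple[str, str, str]:
    """Observable genotype labels for a biallelic SNP, homozygous ref first."""
    return (
        f"{ref_allele}/{ref_allele}",
        f"{ref_allele}/{alt_allele}",
        f"{alt_allele}/{alt_allele}",
    )


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one cohort column.

    Parameters
    ----------
    name
        Column name in the table.
    role
        One of ``outcome``, ``linear``, ``tree``, ``stratum``, ``id``,
        ``ignore``.
    coding
        ``binary`` (two levels), ``categorical`` (explicit levels),
        ``genotype`` (biallelic SNP, three observable levels derived from the
        ref/alt alleles), or ``count`` (nonnegative integer).
    levels
        Declared levels, in order.  For ``genotype`` coding these are derived
        from ``ref_allele``/``alt_allele`` when omitted.
    reference_level
        Baseline level for effect coding; defaults to the first level.
    missing_codes
        Tokens in the raw table that mean "missing".
    """

    name: str
    role: str
    coding: str
    levels: tuple[str, ...] = ()
    reference_level: str | None = None
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise CohortError(f"{self.name}: unknown role {self.role!r}")
        if self.coding not in CODINGS:
            raise CohortError(f"{self.name}: unknown coding {self.coding!r}")
        if self.coding == "genotype":
            if not (self.ref_allele and self.alt_allele):
                raise CohortError(f"{self.name}: genotype coding needs ref/alt alleles")
            expected = genotype_levels(self.ref_allele, self.alt_allele)
            if not self.levels:
                object.__setattr__(self, "levels", expected)
            elif tuple(self.levels) != expected:
                raise CohortError(
                    f"{self.name}: genotype levels must be {expected}, got {self.levels}"
                )
        if self.coding == "binary" and len(self.levels) != 2:
            raise CohortError(f"{self.name}: binary coding needs exactly 2 levels")
        if self.coding == "categorical" and len(self.levels) < 2:
            raise CohortError(f"{self.name}: categorical coding needs >=2 levels")
        if self.coding != "count":
            if self.reference_level is None:
                object.__setattr__(self, "reference_level", self.levels[0])
            elif self.reference_level not in self.levels:
                raise CohortError(
                    f"{self.name}: reference level {self.reference_level!r} "
                    f"not among declared levels {self.levels}"
                )
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "missing_codes", tuple(self.missing_codes))

    def to_dict(self) -> dict:
        d = {"name": self.name, "role": self.role, "coding": self.coding}
        if self.coding == "genotype":
            d["ref_allele"] = self.ref_allele
            d["alt_allele"] = self.alt_allele
        elif self.coding != "count":
            d["levels"] = list(self.levels)
        if self.coding != "count":
            d["reference_level"] = self.reference_level
        d["missing_codes"] = list(self.missing_codes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSpec":
        return cls(
            name=d["name"],
            role=d["role"],
            coding=d["coding"],
            levels=tuple(d.get("levels", ())),
            reference_level=d.get("reference_level"),
            missing_codes=tuple(d.get("missing_codes", DEFAULT_MISSING_CODES)),
            ref_allele=d.get("ref_allele"),
            alt_allele=d.get("alt_allele"),
        )


@dataclass
class CohortTable:
    """Validated subjects-by-variables table with its variable dictionary."""

    data: pd.DataFrame
    dictionary: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    def spec(self, name: str) -> VariableSpec:
        for s in self.dictionary:
            if s.name == name:
                return s
        raise CohortError(f"variable {name!r} not in dictionary")

    def names_with_role(self, role: str) -> list[str]:
        return [s.name for s in self.dictionary if s.role == role]

    @property
    def outcome_spec(self) -> VariableSpec:
        out = self.names_with_role("outcome")
        if len(out) != 1:
            raise CohortError(f"exactly one outcome variable required, found {out}")
        return self.spec(out[0])

    def outcome01(self) -> np.ndarray:
        """Outcome as 0/1 (reference level -> 0).  No missing values allowed."""
        s = self.outcome_spec
        col = self.data[s.name]
        if col.isna().any():
            raise CohortError("outcome has missing values among analysis subjects")
        return (col != s.reference_level).to_numpy(dtype=float)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.data.loc[mask].reset_index(drop=True), self.dictionary)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = [s.name for s in self.dictionary]
        if len(set(names)) != len(names):
            raise CohortError("duplicate variable names in dictionary")
        out = [s for s in self.dictionary if s.role == "outcome"]
        if len(out) != 1:
            raise CohortError(f"exactly one outcome variable required, found {len(out)}")
        if out[0].name not in self.data.columns:
            raise CohortError(f"missing outcome column {out[0].name!r}")
        for s in self.dictionary:
            if s.name not in self.data.columns:
                raise CohortError(f"declared variable {s.name!r} absent from table")
            if s.role == "ignore" or s.coding == "count":
                if s.coding == "count":
                    col = self.data[s.name].dropna()
                    bad = col[~col.astype(str).str.fullmatch(r"\d+")]
                    if len(bad):
                        raise CohortError(
                            f"column {s.name!r}: non-count value {bad.iloc[0]!r} "
                            f"at row {bad.index[0]}"
                        )
                continue
            col = self.data[s.name]
            ok = col.isin(s.levels) | col.isna()
            if not ok.all():
                row = int(np.flatnonzero(~ok.to_numpy())[0])
                raise CohortError(
                    f"column {s.name!r}, row {row}: value {col.iloc[row]!r} is not a "
                    f"declared level of {list(s.levels)} nor a missing code"
                )


# ---------------------------------------------------------------------------
# dictionary and table I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_dictionary(dict_path: str) -> list[VariableSpec]:
    with open(dict_path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict) and "variables" in raw:
        raw = raw["variables"]
    return [VariableSpec.from_dict(d) for d in raw]


def write_dictionary(specs: list[VariableSpec], dict_path: str) -> None:
    with open(dict_path, "w") as fh:
        yaml.safe_dump({"variables": [s.to_dict() for s in specs]}, fh, sort_keys=False)


def read_cohort(table_path: str, dict_path: str) -> CohortTable:
    """Read a delimited cohort table plus its variable dictionary.

    Undeclared columns are kept with role ``ignore`` (a warning is logged);
    a missing outcome column or an undeclared level is fatal.
    """
    specs = read_dictionary(dict_path)
    df = pd.read_csv(
        table_path, sep=_sep_for(table_path), dtype=str,
        keep_default_na=False, na_values=[],
    )
    declared = {s.name for s in specs}
    for col in df.columns:
        if col not in declared:
            logger.warning("column %r undeclared; assigned role=ignore", col)
            specs.append(VariableSpec(
                name=col, role="ignore", coding="categorical",
                levels=("_undeclared_", "_undeclared2_")))
    # map per-variable missing codes to NaN
    for s in specs:
        if s.name in df.columns:
            df[s.name] = df[s.name].where(~df[s.name].isin(s.missing_codes), np.nan)
    return CohortTable(df, specs)


def write_cohort(cohort: CohortTable, table_path: str,
                 dict_path: str | None = None, missing_token: str = "NA") -> None:
    out = cohort.data.fillna(missing_token)
    out.to_csv(table_path, sep=_sep_for(table_path), index=False)
    if dict_path is not None:
        write_dictionary(cohort.dictionary, dict_path)


# ---------------------------------------------------------------------------
# recodes and summaries
# ---------------------------------------------------------------------------

def recode_hmox1(repeat_count: int) -> str:
    """Classify an HMOX1 (GT)n promoter repeat length as S, M or L.

    Fewer than 21 repeats is short (S), 21-29 medium (M) and 30 or more
    long (L).  The boundary count 30 is assigned to L, following the >=30
    convention of the repeat-length literature.
    """
    c = int(repeat_count)
    if c < 0:
        raise ValueError(f"repeat count must be nonnegative, got {repeat_count}")
    if c < 21:
        return "S"
    if c <= 29:
        return "M"
    return "L"


def summarize(cohort: CohortTable, by: str) -> pd.DataFrame:
    """Counts and percentages of ``by`` levels per outcome group.

    Returns one row per declared level plus a ``missing`` row; one count and
    one percentage column per outcome group.  Percentages are over the
    non-missing subjects in each group, mirroring the layout of a typical
    case/control descriptive table.
    """
    spec = cohort.spec(by)
    out_spec = cohort.outcome_spec
    if spec.role == "outcome":
        raise CohortError("summarize: `by` must be a non-outcome variable")
    levels = list(spec.levels) if spec.coding != "count" else sorted(
        cohort.data[by].dropna().unique())
    rows = {}
    for g in out_spec.levels:
        sub = cohort.data.loc[cohort.data[out_spec.name] == g, by]
        n_missing = int(sub.isna().sum())
        n_nonmiss = len(sub) - n_missing
        counts = sub.value_counts()
        rows[(g, "n")] = [int(counts.get(lv, 0)) for lv in levels] + [n_missing]
        rows[(g, "pct")] = [
            (100.0 * counts.get(lv, 0) / n_nonmiss) if n_nonmiss else np.nan
            for lv in levels
        ] + [np.nan]
    idx = levels + ["missing"]
    df = pd.DataFrame(rows, index=idx)
    df.columns = [f"{g}_{k}" for g, k in df.columns]
    return df


__all__ = [
    "VariableSpec", "CohortTable", "CohortError", "genotype_levels",
    "read_cohort", "write_cohort", "read_dictionary", "write_dictionary",
    "recode_hmox1", "summarize",
]
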