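"""Cohort-level statistics: exclusions, correlations, ANOVA with Tukey
correction and compact-letter grouping, and rupture summaries.

Conventions follow the source protocol: follicles that fail to rupture
are excluded from analysis except in 4-MU-treated arms (where failure
to rupture is the treatment effect), simple linear correlations are run
per timepoint, group contrasts use fixed-effects ANOVA with Tukey HSD
at alpha = 0.05, and rupture rates are summarized as percent per
replicate with across-replicate SEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatResult",
    "SchemaError",
    "InsufficientDataError",
    "apply_exclusions",
    "diameter_pressure_correlation",
    "group_comparison",
    "rupture_summary",
]

ALPHA = 0.05


class SchemaError(KeyError):
    """A required column is missing from the cohort table."""


class InsufficientDataError(ValueError):
    """Too few rows to run the requested test."""


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple = ()
    r_squared: float | None = None
    adjustment: str | None = None
    letters: dict = field(default_factory=dict)
    detail: object = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def apply_exclusions(table: pd.DataFrame) -> pd.DataFrame:
    """Flag control follicles that failed to rupture (never drop rows).

    Non-ruptured control rows get ``excluded=True`` with reason
    ``"no_rupture"``; 4-MU-treated rows are never excluded by this rule.
    Returns a copy with ``excluded`` / ``exclusion_reason`` columns.
    """
    for col in ("ruptured", "treatment"):
        if col not in table.columns:
            raise SchemaError(f"missing column {col!r}")
    out = table.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
    if "exclusion_reason" not in out.columns:
        out["exclusion_reason"] = ""
    hit = (~out["ruptured"].astype(bool)) & (out["treatment"] == "control")
    out.loc[hit, "excluded"] = True
    out.loc[hit, "exclusion_reason"] = "no_rupture"
    return out


def diameter_pressure_correlation(table: pd.DataFrame, timepoint_h: float,
                                  diameter_col: str = "diameter_um",
                                  pressure_col: str = "pressure_mmhg"
                                  ) -> StatResult:
    """Simple linear correlation of pressure against diameter at one
    timepoint (excluded rows ignored)."""
    df = table
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df[df["timepoint_h"] == timepoint_h].dropna(
        subset=[diameter_col, pressure_col])
    if len(df) < 3:
        raise InsufficientDataError(
            f"{len(df)} usable rows at timepoint {timepoint_h}; need >= 3")
    res = sps.linregress(df[diameter_col], df[pressure_col])
    return StatResult(test_name="linear_correlation",
                      statistic=float(res.slope), p_value=float(res.pvalue),
                      r_squared=float(res.rvalue**2),
                      groups=(f"timepoint_{timepoint_h}",))


def _compact_letters(groups: list[str], not_different: set[frozenset]
                     ) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not
    significantly different. Insert-and-absorb on groups sorted
    alphabetically (the documented tie-break)."""
    groups = sorted(groups)
    letter_sets: list[set[str]] = []
    for g1 in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g1, g2)) in not_different for g2 in s):
                s.add(g1)
                placed = True
        if not placed:
            letter_sets.append({g1})
    # absorb subsets
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in sorted(s):
            out[g] += letter
    return out


def group_comparison(table: pd.DataFrame, response: str,
                     factors: list[str] | str, design: str | None = None
                     ) -> list[StatResult]:
    """Fixed-effects ANOVA with Tukey-HSD pairwise comparisons.

    Parameters
    ----------
    table : DataFrame
        Cohort table; excluded rows are dropped first.
    response : str
        Response column (e.g. ``"pressure_mmhg"``).
    factors : str or list of str
        One factor -> one-way ANOVA; two -> two-way with interaction.
        Tukey comparisons run over the (combined) factor cells.
    design : {"one_way", "two_way"}, optional
        Inferred from the number of factors when omitted.

    Returns
    -------
    list of StatResult
        One result per ANOVA effect, followed by one ``tukey_hsd``
        result whose ``letters`` give the compact letter display
        (groups sharing a letter do not differ at alpha = 0.05).
    """
    if isinstance(factors, str):
        factors = [factors]
    if design is None:
        design = "one_way" if len(factors) == 1 else "two_way"
    df = table
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df.dropna(subset=[response, *factors]).copy()
    counts = df.groupby(factors, observed=True).size()
    if (counts < 2).any():
        bad = counts[counts < 2]
        raise ValueError(f"design cells with n < 2: {list(bad.index)}")

    df["_y"] = df[response].astype(float)
    terms = " + ".join(f"C(Q('{f}'))" for f in factors)
    if design == "two_way" and len(factors) == 2:
        terms += " + " + ":".join(f"C(Q('{f}'))" for f in factors)
    model = smf.ols(f"_y ~ {terms}", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    results: list[StatResult] = []
    for effect, row in anova.iterrows():
        if effect == "Residual":
            continue
        results.append(StatResult(
            test_name=f"anova[{effect}]", statistic=float(row["F"]),
            p_value=float(row["PR(>F)"]), groups=tuple(factors),
            detail=anova))

    cell = df[factors[0]].astype(str) if len(factors) == 1 else \
        df[factors].astype(str).agg("/".join, axis=1)
    if cell.nunique() < 2:
        raise ValueError("need >= 2 factor cells for pairwise comparison")
    tukey = pairwise_tukeyhsd(df["_y"].to_numpy(), cell.to_numpy(), alpha=ALPHA)
    names = [str(g) for g in tukey.groupsunique]
    not_diff: set[frozenset] = set()
    pairs = list(combinations(names, 2))  # tukeyhsd comparison order
    for (a, b), rej in zip(pairs, tukey.reject):
        if not rej:
            not_diff.add(frozenset((a, b)))
    for n in names:
        not_diff.add(frozenset((n,)))
    letters = _compact_letters(names, not_diff)
    results.append(StatResult(
        test_name="tukey_hsd",
        statistic=float(np.min(tukey.pvalues)),
        p_value=float(np.min(tukey.pvalues)),
        groups=tuple(names), adjustment="tukey", letters=letters,
        detail=tukey))
    return results


def rupture_summary(table: pd.DataFrame, by: str = "treatment",
                    replicate_col: str = "replicate") -> pd.DataFrame:
    """Percent ruptured per group with across-replicate SEM.

    Requires boolean ``ruptured`` and a replicate identifier; the
    percentage is computed within each (group, replicate) and the SEM is
    taken across replicates, mirroring how rupture incidence is
    reported per culture replicate.
    """
    for col in ("ruptured", by, replicate_col):
        if col not in table.columns:
            raise SchemaError(f"missing column {col!r}")
    per_rep = (table.groupby([by, replicate_col], observed=True)["ruptured"]
               .agg(["mean", "size"]).reset_index())
    per_rep["percent"] = 100.0 * per_rep["mean"]

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    out = (per_rep.groupby(by, observed=True)
           .agg(n=("size", "sum"), n_replicates=("percent", "size"),
                percent_ruptured=("percent", "mean"),
                sem=("percent", _sem))
           .reset_index())
    return out
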