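"""Factorial analysis of disc attenuation: 3-way fixed-effects ANOVA.

The design crosses age group (growing vs adult), spinal level (coccygeal,
lumbar, thoracic) and injection status (pre vs post contrast) with the
mean disc attenuation as response.  For balanced designs the classical
sums-of-squares partition is used (all SS types coincide); unbalanced
tables fall back to Type-II sums of squares.  Repeated-measures structure
(the same animal contributes several levels and timepoints) is deliberately
ignored, matching the fixed-effects convention of the original analysis.

Simulation helpers estimate the type-I error and power of the injection
term on synthetic cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaResult",
    "validate_metrics_table",
    "three_way_anova",
    "simulate_rejection_rate",
    "simulate_null_rejection_rate",
]

FACTORS = ("age_group", "level", "injected")

_TERM_NAMES = {
    "C(age_group)": "age_group",
    "C(level)": "level",
    "C(injected)": "injected",
    "C(age_group):C(level)": "age_group:level",
    "C(age_group):C(injected)": "age_group:injected",
    "C(level):C(injected)": "level:injected",
    "C(age_group):C(level):C(injected)": "age_group:level:injected",
    "Residual": "residual",
}


@dataclass
class AnovaResult:
    """Per-term ANOVA table: sum of squares, df, F and p-value.

    ``table`` is indexed by term name (``age_group``, ``level``,
    ``injected``, their interactions, and ``residual``).
    """

    table: pd.DataFrame
    ss_type: int
    n_obs: int
    dropped_terms: tuple[str, ...] = ()

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])

    def f_value(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def __str__(self) -> str:
        lines = [f"3-way ANOVA (type {self.ss_type} SS, n = {self.n_obs})"]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.6g}"))
        if self.dropped_terms:
            lines.append(f"dropped inestimable terms: "
                         f"{', '.join(self.dropped_terms)}")
        return "\n".join(lines)


def validate_metrics_table(table: pd.DataFrame,
                           response: str = "mean_attenuation") -> None:
    """Check factor cardinalities and replication for error df."""
    for col in FACTORS + (response,):
        if col not in table.columns:
            raise ValueError(f"metrics table lacks column {col!r}")
    if len(table) == 0:
        raise ValueError("metrics table is empty")
    n_age = table["age_group"].nunique()
    n_level = table["level"].nunique()
    if n_age > 2 or n_level > 3:
        raise ValueError(
            f"expected <= 2 age groups and <= 3 levels, got {n_age} and {n_level}"
        )
    cells = table.groupby(list(FACTORS), observed=True).size()
    if (cells < 2).all():
        raise ValueError("every design cell has < 2 replicates; "
                         "the residual has no degrees of freedom")


def _is_balanced(table: pd.DataFrame) -> bool:
    counts = table.groupby(list(FACTORS), observed=True).size()
    n_cells = (table["age_group"].nunique() * table["level"].nunique()
               * table["injected"].nunique())
    return len(counts) == n_cells and counts.nunique() == 1


def three_way_anova(table: pd.DataFrame,
                    response: str = "mean_attenuation",
                    ss_type: int | None = None) -> AnovaResult:
    """Full-factorial fixed-effects ANOVA of ``response`` on age group,
    spinal level and injection status.

    ``ss_type=None`` selects the classical (Type I, sequential) partition
    for balanced tables — where all types coincide — and Type II for
    unbalanced ones.  Terms made inestimable by empty cells are dropped
    with a warning.
    """
    validate_metrics_table(table, response)
    df = table.copy()
    df["injected"] = df["injected"].astype(bool)
    df = df.rename(columns={response: "_y"}) if response != "_y" else df

    terms = ["C(age_group)", "C(level)", "C(injected)",
             "C(age_group):C(level)", "C(age_group):C(injected)",
             "C(level):C(injected)",
             "C(age_group):C(level):C(injected)"]
    dropped: list[str] = []

    # empty cells make higher-order interaction contrasts inestimable
    full_cells = (df["age_group"].nunique() * df["level"].nunique()
                  * df["injected"].nunique())
    observed_cells = len(df.groupby(list(FACTORS), observed=True).size())
    if observed_cells < full_cells:
        dropped.append("age_group:level:injected")
        terms.remove("C(age_group):C(level):C(injected)")
        for pair, cols in [("age_group:level", ["age_group", "level"]),
                           ("age_group:injected", ["age_group", "injected"]),
                           ("level:injected", ["level", "injected"])]:
            margin_cells = len(df.groupby(cols, observed=True).size())
            full_margin = df[cols[0]].nunique() * df[cols[1]].nunique()
            if margin_cells < full_margin:
                dropped.append(pair)
                terms.remove(f"C({cols[0]}):C({cols[1]})")
        warnings.warn(
            f"empty design cells: dropped inestimable terms {dropped}",
            stacklevel=2,
        )

    if ss_type is None:
        ss_type = 1 if _is_balanced(df) else 2
    formula = "_y ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        # constant responses yield 0/0 F statistics; report them as NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = sm.stats.anova_lm(fit, typ=ss_type)

    raw = raw.rename(index=_TERM_NAMES)
    out = pd.DataFrame({
        "sum_sq": raw["sum_sq"],
        "df": raw["df"],
        "F": raw.get("F"),
        "p_value": raw["PR(>F)"],
    })
    # clip tiny negative SS from floating-point cancellation
    out["sum_sq"] = out["sum_sq"].clip(lower=0.0)
    return AnovaResult(out, ss_type=ss_type, n_obs=len(df),
                       dropped_terms=tuple(dropped))


# ---------------------------------------------------------------------------
# calibration / power simulation


def _simulated_table(rng: np.random.Generator, n_per_cell: int,
                     injection_effect_sd: float) -> pd.DataFrame:
    ages = ["growing_3mo", "adult_8mo"]
    levels = ["CC5_CC6", "L5_L6", "T12_T13"]
    rows = []
    for a in ages:
        for lv in levels:
            for inj in (False, True):
                y = rng.normal(0.0, 1.0, n_per_cell)
                if inj:
                    y = y + injection_effect_sd
                for v in y:
                    rows.append((a, lv, inj, v))
    return pd.DataFrame(rows, columns=["age_group", "level", "injected",
                                       "mean_attenuation"])


def simulate_rejection_rate(n_per_cell: int, n_reps: int, alpha: float,
                            seed: int = 0,
                            injection_effect_sd: float = 0.0) -> float:
    """Fraction of simulated cohorts whose injection term has p < alpha.

    Responses are unit-variance Gaussian in a balanced 2 x 3 x 2 design;
    ``injection_effect_sd`` shifts the injected cells by that many noise
    SDs.  With the default shift of zero this estimates the type-I error
    of the injection test.
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable estimate")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        tbl = _simulated_table(rng, n_per_cell, injection_effect_sd)
        res = three_way_anova(tbl)
        if res.p_value("injected") < alpha:
            hits += 1
    return hits / n_reps


def simulate_null_rejection_rate(n_per_cell: int, n_reps: int, alpha: float,
                                 seed: int = 0) -> float:
    """Type-I error of the injection term under the global null."""
    return simulate_rejection_rate(n_per_cell, n_reps, alpha, seed,
                                   injection_effect_sd=0.0)
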