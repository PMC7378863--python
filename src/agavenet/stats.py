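"""Balanced two-factor ANOVA and functional-guild abundance comparisons.

Supports the balanced 2 x 2 design of a two-soil, two-season survey.  The
summary-statistics route (:func:`anova2_from_summaries`) reconstructs F
statistics from printed cell means and standard deviations, which is how
published physicochemical tables can be checked without the raw data; the
raw-data route (:func:`anova2_raw`) is the classical decomposition.  On the
same data the two agree to floating-point accuracy.

Functional guilds are genus sets sharing a trait (nitrogen fixation,
denitrification, exopolysaccharide production, ...).  A guild's abundance in
a sample is the summed relative abundance of its member genera; a genus that
carries several traits contributes to each of its guilds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "CellSummary",
    "Anova2Result",
    "anova2_from_summaries",
    "anova2_raw",
    "guild_abundance",
    "compare_guilds",
]


@dataclass(frozen=True)
class CellSummary:
    """Mean, SD and n for one factor-combination cell of a balanced design."""

    level_a: str
    level_b: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("each cell needs n >= 2 observations")
        if self.sd < 0:
            raise ParameterError("sd must be non-negative")


@dataclass(frozen=True)
class Anova2Result:
    F_a: float
    F_b: float
    F_ab: float
    df_effect: int
    df_error: int
    mse: float
    ss: dict

    def p_values(self) -> dict:
        f = sps.f(self.df_effect, self.df_error)
        return {
            "p_a": float(f.sf(self.F_a)),
            "p_b": float(f.sf(self.F_b)),
            "p_ab": float(f.sf(self.F_ab)),
        }


def _result_from_cells(means: np.ndarray, variances: np.ndarray, n: int) -> Anova2Result:
    # means/variances are 2x2 arrays indexed [a, b]; balanced design only
    grand = means.mean()
    a_means = means.mean(axis=1)
    b_means = means.mean(axis=0)
    ss_a = n * 2 * float(((a_means - grand) ** 2).sum())
    ss_b = n * 2 * float(((b_means - grand) ** 2).sum())
    inter = means - a_means[:, None] - b_means[None, :] + grand
    ss_ab = n * float((inter ** 2).sum())
    df_error = 4 * (n - 1)
    ss_error = float(variances.sum()) * (n - 1)
    mse = ss_error / df_error
    if mse == 0:
        # degenerate zero-variance cells: F is 0 for null effects, inf otherwise
        f_a, f_b, f_ab = (np.inf if s > 0 else 0.0 for s in (ss_a, ss_b, ss_ab))
    else:
        f_a, f_b, f_ab = ss_a / mse, ss_b / mse, ss_ab / mse
    return Anova2Result(
        F_a=float(f_a), F_b=float(f_b), F_ab=float(f_ab),
        df_effect=1, df_error=df_error, mse=float(mse),
        ss={"A": ss_a, "B": ss_b, "AB": ss_ab, "error": ss_error},
    )


def anova2_from_summaries(cells: list[CellSummary]) -> Anova2Result:
    """Balanced 2 x 2 two-way ANOVA from cell means and SDs.

    With equal cell size n, the error mean square is the pooled within-cell
    variance (the mean of the four cell variances), and the effect sums of
    squares depend only on the cell means — so printed summary tables fully
    determine the F statistics.
    """
    if len(cells) != 4:
        raise ParameterError("need exactly four cells for a 2x2 design")
    a_levels = sorted({c.level_a for c in cells})
    b_levels = sorted({c.level_b for c in cells})
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ParameterError("cells must cover a complete 2x2 factor grid")
    ns = {c.n for c in cells}
    if len(ns) != 1:
        raise ParameterError("unbalanced design: cell n values differ")
    n = ns.pop()
    means = np.full((2, 2), np.nan)
    variances = np.full((2, 2), np.nan)
    for c in cells:
        i, j = a_levels.index(c.level_a), b_levels.index(c.level_b)
        if not np.isnan(means[i, j]):
            raise ParameterError(f"duplicate cell ({c.level_a}, {c.level_b})")
        means[i, j] = c.mean
        variances[i, j] = c.sd ** 2
    if np.isnan(means).any():
        raise ParameterError("incomplete 2x2 grid")
    return _result_from_cells(means, variances, n)


def anova2_raw(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    log_transform: bool = False,
) -> Anova2Result:
    """Balanced 2 x 2 two-way ANOVA from per-observation values."""
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (len(values) == len(factor_a) == len(factor_b)):
        raise ParameterError("values and factor labels must align")
    if log_transform:
        if np.any(values <= 0):
            raise ParameterError("log transform needs strictly positive values")
        values = np.log(values)
    a_levels = sorted(pd.unique(factor_a))
    b_levels = sorted(pd.unique(factor_b))
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ParameterError("exactly two levels per factor are supported")
    cells = {}
    ns = set()
    for a in a_levels:
        for b in b_levels:
            cell = values[(factor_a == a) & (factor_b == b)]
            if len(cell) < 2:
                raise ParameterError(f"cell ({a}, {b}) missing or has n < 2")
            ns.add(len(cell))
            cells[(a, b)] = cell
    if len(ns) != 1:
        raise ParameterError("unbalanced design: cell sizes differ")
    n = ns.pop()
    # classical balanced decomposition straight from the observations
    grand = values.mean()
    ss_a = 2 * n * sum((values[factor_a == a].mean() - grand) ** 2 for a in a_levels)
    ss_b = 2 * n * sum((values[factor_b == b].mean() - grand) ** 2 for b in b_levels)
    ss_cells = n * sum((c.mean() - grand) ** 2 for c in cells.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_error = sum(float(((c - c.mean()) ** 2).sum()) for c in cells.values())
    df_error = 4 * (n - 1)
    mse = ss_error / df_error
    if mse == 0:
        f_a, f_b, f_ab = (np.inf if s > 1e-12 else 0.0 for s in (ss_a, ss_b, ss_ab))
    else:
        f_a, f_b, f_ab = ss_a / mse, ss_b / mse, ss_ab / mse
    return Anova2Result(
        F_a=float(f_a), F_b=float(f_b), F_ab=float(f_ab),
        df_effect=1, df_error=df_error, mse=float(mse),
        ss={"A": float(ss_a), "B": float(ss_b), "AB": float(ss_ab), "error": float(ss_error)},
    )


def guild_abundance(
    relab: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Sum genus proportions into functional-guild (category) abundances.

    ``traits`` has columns genus/category (an optional class column is passed
    through untouched elsewhere).  A genus holding k categories contributes
    its proportion to all k rows.  Genera absent from the trait table are
    reported, not fatal.
    """
    if traits.empty:
        raise ParameterError("trait table is empty")
    members = traits.groupby("category")["genus"].apply(list)
    rows = {}
    for cat, genera in members.items():
        present = [g for g in genera if g in relab.index]
        rows[cat] = relab.loc[present].sum(axis=0) if present else pd.Series(0.0, index=relab.columns)
    guilds = pd.DataFrame(rows).T.sort_index()
    guilds.index.name = "category"
    mapped = set(traits["genus"])
    unmapped = [g for g in relab.index if g not in mapped]
    report = {
        "n_unmapped_genera": len(unmapped),
        "unmapped_genera": unmapped,
        "unmapped_fraction": float(relab.loc[unmapped].sum(axis=0).mean()) if unmapped else 0.0,
    }
    return guilds, report


def compare_guilds(
    guilds: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: tuple[str, str] = ("soil_type", "season"),
    alpha: float = 0.05,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-guild two-way ANOVA across the study factors.

    Returns one row per category with F and p for each factor and their
    interaction, plus Benjamini-Hochberg adjusted q-values (computed per
    effect across categories) and a significance flag at ``alpha``.
    """
    fa, fb = factors
    meta = metadata.loc[guilds.columns]
    rows = []
    for cat in guilds.index:
        res = anova2_raw(
            guilds.loc[cat].to_numpy(), meta[fa].to_numpy(), meta[fb].to_numpy(),
            log_transform=log_transform,
        )
        p = res.p_values()
        rows.append(
            {
                "category": cat,
                f"F_{fa}": res.F_a, f"F_{fb}": res.F_b, "F_interaction": res.F_ab,
                f"p_{fa}": p["p_a"], f"p_{fb}": p["p_b"], "p_interaction": p["p_ab"],
            }
        )
    table = pd.DataFrame(rows).set_index("category")
    for eff in (fa, fb, "interaction"):
        table[f"q_{eff}"] = _bh_adjust(table[f"p_{eff}"].to_numpy())
        table[f"significant_{eff}"] = table[f"q_{eff}"] <= alpha
    return table


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
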