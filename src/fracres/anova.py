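"""Balanced cell-mean design and the inferential layer.

The raw gene-level table is unbalanced (categories hold very different
numbers of genes), so inference runs on cell means: for every (low-level
category, expression bin) the mean retention index over member genes.
With the default 18-term scheme this gives a perfectly balanced 36-row
design — 6 low-level terms per high-level category (GOf) crossed with
2 expression bins (ExpQ) — on which a two-way Type II ANOVA with partial
eta squared and a Tukey HSD over GOf are computed.

On this balanced design Type I, II and III sums of squares coincide; the
Type II model-comparison definition is used (each main effect adjusted
for the other, the interaction adjusted for both).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import optimize
from scipy import stats

from .errors import ValidationError
from .expression import HIGH_EXP, LOW_EXP
from .ontology import FunctionalScheme

logger = logging.getLogger(__name__)

BINS = (HIGH_EXP, LOW_EXP)
ANOVA_TERMS = ("GOf", "ExpQ", "GOf:ExpQ", "Residual")

#: relative tolerance for sum-of-squares non-negativity / balance checks
SS_RTOL = 1e-8


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------

def build_design(
    records: pd.DataFrame,
    scheme: FunctionalScheme | None = None,
) -> pd.DataFrame:
    """Collapse gene records to the balanced cell-mean design.

    One row per (high_code GOf, low_code, bin ExpQ) with the arithmetic
    mean retention index and the member-gene count.  When ``scheme`` is
    given the design must cover every scheme term in both bins; any empty
    cell is an error naming the cells.
    """
    required = {"retention_index", "high_code", "low_code", "bin"}
    if not required.issubset(records.columns):
        raise ValidationError(f"gene records need columns {sorted(required)}")
    grouped = (
        records.groupby(["high_code", "low_code", "bin"], sort=True)
        .agg(mean_retention=("retention_index", "mean"), n_genes=("retention_index", "size"))
        .reset_index()
        .rename(columns={"high_code": "GOf", "low_code": "term", "bin": "ExpQ"})
    )
    if scheme is not None:
        expected = {
            (e.high_code, e.low_code, b) for e in scheme.entries for b in BINS
        }
    else:
        expected = {
            (h, l, b)
            for (h, l) in grouped[["GOf", "term"]].itertuples(index=False, name=None)
            for b in BINS
        }
    have = set(grouped[["GOf", "term", "ExpQ"]].itertuples(index=False, name=None))
    empty = sorted(expected - have)
    if empty:
        raise ValidationError(
            "design is incomplete; empty (GOf, term, ExpQ) cells: "
            + ", ".join(map(str, empty))
        )
    grouped = grouped.sort_values(["GOf", "term", "ExpQ"], kind="mergesort").reset_index(
        drop=True
    )
    return grouped[["GOf", "term", "ExpQ", "mean_retention", "n_genes"]]


def split_regulation_response(design: pd.DataFrame) -> pd.DataFrame:
    """Recode GOf with 4 levels: Z3 terms Z31–Z33 (regulation) become Z3R
    and Z34–Z36 (response to stimulus) become Z3S.

    Supports the alternative reading of the factor structure in which the
    regulation and response halves of Z3 are separate levels (GOf df 3).
    """
    out = design.copy()
    z3 = out["GOf"] == "Z3"
    sub = out.loc[z3, "term"].str[:3].isin({"Z31", "Z32", "Z33"})
    out.loc[z3, "GOf"] = np.where(sub, "Z3R", "Z3S")
    return out


# ---------------------------------------------------------------------------
# Two-way Type II ANOVA with partial eta squared
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-term ANOVA table: sum_sq, df, mean_sq, F_value, p_value,
    partial_eta_sq, indexed by GOf, ExpQ, GOf:ExpQ, Residual."""

    table: pd.DataFrame

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    @property
    def residual_ss(self) -> float:
        return float(self.table.loc["Residual", "sum_sq"])

    @property
    def residual_df(self) -> float:
        return float(self.table.loc["Residual", "df"])


def partial_eta_squared(ss_effect: float, ss_residual: float) -> float:
    """Effect size of one ANOVA term: SS_effect / (SS_effect + SS_residual).

    Returns NaN (flagged missing) when both sums of squares are zero.
    """
    if ss_effect < 0 or ss_residual < 0:
        raise ValidationError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_residual == 0:
        logger.warning("partial eta squared undefined: both sums of squares are zero")
        return float("nan")
    return ss_effect / (ss_effect + ss_residual)


def anova_type2(design: pd.DataFrame, gof_levels: int = 3) -> AnovaResult:
    """Two-way Type II ANOVA of mean retention on GOf x ExpQ.

    ``gof_levels=4`` first recodes GOf via
    :func:`split_regulation_response` (regulation vs response halves of
    Z3 as separate levels).  Fits are delegated to statsmodels OLS /
    anova_lm; negative sums of squares beyond numerical tolerance and
    rank-deficient designs are rejected.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if gof_levels == 4:
        design = split_regulation_response(design)
    elif gof_levels != 3:
        raise ValidationError("gof_levels must be 3 or 4")
    for col in ("GOf", "ExpQ", "mean_retention"):
        if col not in design.columns:
            raise ValidationError(f"design table lacks column {col!r}")
    n_gof = design["GOf"].nunique()
    n_bin = design["ExpQ"].nunique()
    if n_gof < 2 or n_bin < 2:
        raise ValidationError("both factors need at least two levels")

    model = smf.ols("mean_retention ~ C(GOf) * C(ExpQ)", data=design).fit()
    expected_rank = n_gof * n_bin
    if model.df_model + 1 < expected_rank:
        raise ValidationError("rank-deficient design (empty or aliased cells)")
    if model.df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    raw = anova_lm(model, typ=2)

    scale = float((design["mean_retention"] ** 2).sum()) or 1.0
    rename = {"C(GOf)": "GOf", "C(ExpQ)": "ExpQ", "C(GOf):C(ExpQ)": "GOf:ExpQ"}
    table = raw.rename(index=rename).reindex(list(ANOVA_TERMS))
    ss = table["sum_sq"].to_numpy()
    if (ss < -SS_RTOL * scale).any():
        raise ValidationError("negative sum of squares beyond numerical tolerance")
    # sums of squares within rounding noise of zero are exactly zero
    ss = np.where(np.abs(ss) < SS_RTOL * scale, 0.0, ss)
    table["sum_sq"] = np.clip(ss, 0.0, None)
    table["mean_sq"] = table["sum_sq"] / table["df"]
    ss_res = table.loc["Residual", "sum_sq"]
    # a term with SS 0 in a zero-residual table is a null effect, not missing
    table["partial_eta_sq"] = [
        np.nan
        if t == "Residual"
        else (
            0.0
            if table.loc[t, "sum_sq"] == 0 and ss_res == 0
            else partial_eta_squared(table.loc[t, "sum_sq"], ss_res)
        )
        for t in table.index
    ]
    table = table.rename(columns={"F": "F_value", "PR(>F)": "p_value"})
    # a constant response has F = 0/0; report 0 with p = 1 (no evidence)
    zero = (table["sum_sq"] == 0) & (table.index != "Residual")
    if ss_res == 0:
        table.loc[zero, ["F_value", "p_value"]] = [0.0, 1.0]
    return AnovaResult(
        table=table[["sum_sq", "df", "mean_sq", "F_value", "p_value", "partial_eta_sq"]]
    )


def significance_code(p: float) -> str:
    """R-style significance code for a p-value."""
    if np.isnan(p):
        return ""
    for cut, code in ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, ".")):
        if p <= cut:
            return code
    return ""


def render_anova(result: AnovaResult, title: str = "Anova Table (Type II tests)") -> str:
    """Readable ANOVA table with partial eta squared and signif. codes."""
    lines = [title, f"{'':10s}{'Partial eta^2':>14s}{'Sum Sq':>10s}{'Df':>5s}{'F value':>10s}  Pr(>F)"]
    for term in result.table.index:
        row = result.table.loc[term]
        eta = "" if np.isnan(row["partial_eta_sq"]) else f"{row['partial_eta_sq']:.5f}"
        f_val = "" if np.isnan(row["F_value"]) else f"{row['F_value']:.4f}"
        p_val = ""
        if not np.isnan(row["p_value"]):
            p_val = f"{row['p_value']:.5g} {significance_code(row['p_value'])}"
        lines.append(
            f"{term:10s}{eta:>14s}{row['sum_sq']:>10.4f}{int(row['df']):>5d}{f_val:>10s}  {p_val}"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Studentized range distribution (vectorized quadrature)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _sr_nodes(df: float, n_outer: int = 64, n_inner: int = 96):
    """Quadrature nodes shared by all survival-function evaluations at one
    residual df: outer over the scaled chi variable s = sqrt(chi2_df/df),
    inner over the standard normal z."""
    s_lo = math.sqrt(stats.chi2.ppf(1e-13, df) / df)
    s_hi = math.sqrt(stats.chi2.isf(1e-13, df) / df)
    xs, ws = leggauss(n_outer)
    s = 0.5 * (s_hi - s_lo) * xs + 0.5 * (s_hi + s_lo)
    ws = ws * 0.5 * (s_hi - s_lo)
    log_g = (
        (df / 2) * math.log(df / 2)
        - math.lgamma(df / 2)
        + math.log(2.0)
        + (df - 1) * np.log(s)
        - df * s * s / 2
    )
    outer_w = ws * np.exp(log_g)
    xz, wz = leggauss(n_inner)
    z = 9.0 * xz
    inner_w = 9.0 * wz * stats.norm.pdf(z)
    Phi = stats.norm.cdf(z)
    return s, outer_w, z, inner_w, Phi


def studentized_range_sf(q, k: int, df: float):
    """P(Q > q) for the studentized range of ``k`` means with ``df``
    residual degrees of freedom.

    Vectorized Gauss–Legendre evaluation of the classical double
    integral; agrees with scipy.stats.studentized_range to ~1e-10 while
    being fast enough for simulation loops.
    """
    if k < 2 or df <= 0:
        raise ValidationError("studentized range needs k >= 2 and df > 0")
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.ones_like(q_arr)
    pos = q_arr > 0
    if pos.any():
        s, outer_w, z, inner_w, Phi = _sr_nodes(float(df))
        qs = q_arr[pos][:, None, None] * s[None, :, None]
        a = Phi[None, None, :] - stats.norm.cdf(z[None, None, :] - qs)
        inner = k * np.einsum("j,qsj->qs", inner_w, np.clip(a, 0.0, 1.0) ** (k - 1))
        cdf = np.einsum("s,qs->q", outer_w, inner)
        out[pos] = np.clip(1.0 - cdf, 0.0, 1.0)
    if np.isscalar(q) or np.ndim(q) == 0:
        return float(out[0])
    return out


@lru_cache(maxsize=64)
def studentized_range_crit(conf_level: float, k: int, df: float) -> float:
    """Upper critical value q such that P(Q > q) = 1 - conf_level."""
    alpha = 1.0 - conf_level
    return float(
        optimize.brentq(lambda q: studentized_range_sf(q, k, df) - alpha, 1e-8, 400.0)
    )


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def tukey_hsd(
    values: Sequence[float] | np.ndarray | pd.Series,
    groups: Sequence | np.ndarray | pd.Series,
    conf_level: float = 0.95,
    ms_resid: float | None = None,
    df_resid: float | None = None,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """All-pairs Tukey honest-significant-difference comparisons.

    For every pair of group levels: the difference of group means, a
    ``conf_level`` studentized-range confidence interval, and the
    familywise-adjusted p-value.  By default the error variance is the
    pooled within-group mean square (one-way residual, df = N - k); pass
    ``ms_resid``/``df_resid`` to use a richer model's residual (e.g. the
    two-way design residual, as :func:`tukey_from_design` does).
    Unequal group sizes use the Tukey–Kramer standard error.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValidationError("values and groups must align")
    levels, inverse = np.unique(g, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValidationError("Tukey HSD needs at least two factor levels")
    ns = np.bincount(inverse)
    means = np.bincount(inverse, weights=y) / ns
    if ms_resid is None or df_resid is None:
        if ms_resid is not None or df_resid is not None:
            raise ValidationError("pass both ms_resid and df_resid, or neither")
        df_resid = float(len(y) - k)
        if df_resid <= 0:
            raise ValidationError("zero residual degrees of freedom")
        ms_resid = float(np.sum((y - means[inverse]) ** 2) / df_resid)
    if df_resid <= 0:
        raise ValidationError("zero residual degrees of freedom")

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    est = np.array([means[j] - means[i] for i, j in pairs])
    se_diff = np.array(
        [math.sqrt(ms_resid * (1.0 / ns[i] + 1.0 / ns[j])) for i, j in pairs]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        q_stat = np.where(se_diff > 0, np.abs(est) * math.sqrt(2.0) / se_diff, np.inf)
    p_adj = np.where(
        np.isfinite(q_stat), studentized_range_sf(np.where(np.isfinite(q_stat), q_stat, 0.0), k, df_resid), 0.0
    )
    p_adj = np.where(np.abs(est) == 0, 1.0, p_adj)

    out = pd.DataFrame(
        {
            "group1": [levels[i] for i, j in pairs],
            "group2": [levels[j] for i, j in pairs],
            "estimate": est,
            "p_adjusted": np.clip(p_adj, 0.0, 1.0),
        }
    )
    if compute_ci:
        q_crit = studentized_range_crit(conf_level, k, float(df_resid))
        half = q_crit / math.sqrt(2.0) * se_diff
        out.insert(3, "ci_low", est - half)
        out.insert(4, "ci_high", est + half)
    return out


def tukey_from_design(
    design: pd.DataFrame,
    conf_level: float = 0.95,
    gof_levels: int = 3,
    use_model_residual: bool = True,
) -> pd.DataFrame:
    """Tukey HSD across high-level categories on the cell-mean design.

    Groups the design rows by GOf (12 rows per level for the default
    scheme).  With ``use_model_residual`` (default) the error variance is
    the two-way model's residual mean square, mirroring Tukey intervals
    computed from a fitted factorial model; otherwise the one-way pooled
    within-group variance is used.
    """
    if gof_levels == 4:
        design = split_regulation_response(design)
    ms = dfr = None
    if use_model_residual:
        res = anova_type2(design, gof_levels=3 if gof_levels != 4 else 4)
        if res.residual_df <= 0:
            raise ValidationError("zero residual degrees of freedom")
        ms = res.table.loc["Residual", "mean_sq"]
        dfr = res.residual_df
    return tukey_hsd(
        design["mean_retention"],
        design["GOf"],
        conf_level=conf_level,
        ms_resid=ms,
        df_resid=dfr,
    )
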