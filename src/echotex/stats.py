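"""Group comparisons and the echotexture-trait correlation screen.

The screen computes, per group of birds (and optionally pooled over all
birds), the Pearson product-moment correlation between every echotexture
variable (plane x {MPI, MPH}) and every trait, together with the
least-squares regression line y = a + b*x.  Two-tailed p-values come from
the t transform t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom; no
multiple-testing correction is applied (an optional Benjamini-Hochberg
column can be annotated as an extension).  Candidate bookkeeping follows
the study design: possible = planes x echo variables x traits x groups.

Correlation magnitudes carry conventional verbal strength labels
(slight < 0.2 <= low < 0.4 <= moderate < 0.7 <= high < 0.9 <= very high);
band edges are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "ScreenTable",
    "ScreenResult",
    "AnovaResult",
    "pearson_with_regression",
    "count_candidates",
    "correlation_screen",
    "strength_label",
    "screen_percentage",
    "format_regression_equation",
    "evaluate_regression",
    "anova_oneway_tukey",
    "anova_twoway_lsd",
    "compact_letter_display",
    "DEFAULT_STRENGTH_BANDS",
    "SCREEN_COLUMNS",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pearson correlation with regression line
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """One (echotexture variable, trait) correlation with its fitted line."""

    x_name: str
    y_name: str
    r: float
    p: float
    slope: float
    intercept: float
    n: int
    group: str = "POOLED"

    @property
    def equation(self) -> str:
        return format_regression_equation(self.intercept, self.slope)


def _pearson_core(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """r, p, slope, intercept from the textbook product-moment formulas."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    xd, yd = x - xm, y - ym
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    sxy = float(xd @ yd)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance: correlation undefined for constant input")
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - r * r <= 0.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    return r, p, float(slope), float(intercept)


def pearson_with_regression(
    x: Sequence[float], y: Sequence[float],
    x_name: str = "x", y_name: str = "y", group: str = "POOLED",
) -> CorrelationResult:
    """Pearson r with two-tailed p (t transform, n-2 df) and the LS line.

    The fitted line always passes through the sample means.  Raises for
    unequal lengths, n < 3, or a constant input vector.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    r, p, slope, intercept = _pearson_core(x, y)
    return CorrelationResult(x_name=x_name, y_name=y_name, r=r, p=p,
                             slope=slope, intercept=intercept, n=x.size, group=group)


def _pearson_block(X: np.ndarray, Y: np.ndarray):
    """Vectorized all-pairs Pearson between columns of X (n x p) and Y (n x q).

    Returns (r, p, slope, intercept) arrays of shape (p, q); pairs involving
    a constant column come back as NaN.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    syy = np.einsum("ij,ij->j", Yc, Yc)
    sxy = Xc.T @ Yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r = sxy / np.sqrt(np.outer(sxx, syy))
        slope = sxy / sxx[:, None]
    r = np.clip(r, -1.0, 1.0)
    r[np.outer(sxx == 0, np.ones_like(syy, dtype=bool))] = np.nan
    r[np.outer(np.ones_like(sxx, dtype=bool), syy == 0)] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(1.0 - r * r <= 0.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    intercept = Y.mean(axis=0)[None, :] - slope * X.mean(axis=0)[:, None]
    return r, p, slope, intercept


# ---------------------------------------------------------------------------
# Bookkeeping and formatting
# ---------------------------------------------------------------------------

def count_candidates(n_planes: int, n_echo_vars: int, n_traits: int, n_groups: int) -> int:
    """Number of candidate correlations: planes x echo variables x traits x groups."""
    counts = (n_planes, n_echo_vars, n_traits, n_groups)
    if any(c < 1 for c in counts):
        raise ValueError(f"all counts must be >= 1, got {counts}")
    return int(np.prod(counts))


def screen_percentage(significant: int, possible: int) -> float:
    """Share of significant candidates, in percent rounded to one decimal."""
    if not 0 <= significant <= possible:
        raise ValueError(f"need 0 <= significant <= possible, got {significant}/{possible}")
    return round(100.0 * significant / possible, 1)


DEFAULT_STRENGTH_BANDS: tuple[tuple[float, str], ...] = (
    (0.2, "slight"), (0.4, "low"), (0.7, "moderate"), (0.9, "high"),
)
_TOP_LABEL = "very high"


def strength_label(
    r: float,
    bands: tuple[tuple[float, str], ...] = DEFAULT_STRENGTH_BANDS,
    top_label: str = _TOP_LABEL,
) -> str:
    """Verbal strength of |r|: slight/low/moderate/high/very high by default."""
    a = abs(float(r))
    if a > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    for edge, label in bands:
        if a < edge:
            return label
    return top_label


def _fmt_coef(v: float) -> str:
    # two decimals, extended until the first significant digit shows for
    # magnitudes below 0.01 (so a slope of 0.007 prints as 0.007, not 0.01)
    d = 2
    while d < 8 and v != 0 and abs(v) < 0.95 * 10.0 ** (-d):
        d += 1
    return f"{v:.{d}f}"


def format_regression_equation(intercept: float, slope: float) -> str:
    """Render ``y = a + bx`` with ASCII signs and two-decimal coefficients."""
    sign = "-" if slope < 0 else "+"
    return f"y = {_fmt_coef(intercept)} {sign} {_fmt_coef(abs(slope))}x"


def evaluate_regression(intercept: float, slope: float, x: float) -> float:
    """Value of the fitted line y = intercept + slope * x at ``x``."""
    return intercept + slope * x


# ---------------------------------------------------------------------------
# The correlation screen
# ---------------------------------------------------------------------------

SCREEN_COLUMNS = ("group", "input_variable", "output_variable", "r", "p_value",
                  "slope", "intercept", "n", "equation", "strength_label")


@dataclass
class ScreenTable:
    """One screen scope (within-group or pooled): retained rows and counts."""

    results: pd.DataFrame            # significant rows, SCREEN_COLUMNS layout
    possible: int                    # candidate count from the study design
    significant: int
    percentage: float                # 100 * significant / possible, 1 decimal
    n_tested: int                    # pairs actually testable (non-constant)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)


@dataclass
class ScreenResult:
    """Within-group screen plus, when requested, the pooled screen."""

    within: ScreenTable
    pooled: ScreenTable | None
    alpha: float


def _echo_wide(echo: pd.DataFrame) -> pd.DataFrame:
    """Long (bird, plane, mpi, mph) records -> one row per bird, 8 columns."""
    long = echo.melt(id_vars=["bird_id", "group", "plane"],
                     value_vars=["mpi", "mph"], var_name="stat")
    long["variable"] = long["plane"] + "-" + long["stat"].str.upper()
    wide = long.pivot_table(index=["bird_id", "group"], columns="variable",
                            values="value", aggfunc="first")
    return wide.reset_index()


def _screen_one(
    merged: pd.DataFrame, echo_vars: list[str], trait_cols: list[str],
    group_label: str, alpha: float,
) -> tuple[list[dict], int, list[tuple[str, str, str]]]:
    X = merged[echo_vars].to_numpy(dtype=np.float64)
    Y = merged[trait_cols].to_numpy(dtype=np.float64)
    n = X.shape[0]
    r, p, slope, intercept = _pearson_block(X, Y)
    rows: list[dict] = []
    skipped: list[tuple[str, str, str]] = []
    n_tested = 0
    for i, xv in enumerate(echo_vars):
        for j, tv in enumerate(trait_cols):
            if np.isnan(r[i, j]):
                skipped.append((group_label, xv, tv))
                continue
            n_tested += 1
            if p[i, j] < alpha:
                rows.append({
                    "group": group_label, "input_variable": xv,
                    "output_variable": tv, "r": float(r[i, j]),
                    "p_value": float(p[i, j]), "slope": float(slope[i, j]),
                    "intercept": float(intercept[i, j]), "n": n,
                    "equation": format_regression_equation(float(intercept[i, j]),
                                                           float(slope[i, j])),
                    "strength_label": strength_label(float(r[i, j])),
                })
    if skipped:
        logger.info("screen %s: skipped %d constant pair(s)", group_label, len(skipped))
    return rows, n_tested, skipped


def correlation_screen(
    echo: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = 0.05,
    pooled: bool = True,
    n_traits_bookkeeping: int | None = None,
    bh_annotation: bool = False,
) -> ScreenResult:
    """Screen every (echotexture variable, trait) pair for correlation.

    ``echo`` is a long table (bird_id, group, plane, mpi, mph); ``traits``
    has bird_id, group and one numeric column per trait.  Within-group
    correlations are always computed; the pooled screen (all birds, group
    structure ignored) is added when ``pooled``.  Pairs with a constant
    vector are skipped with a logged notice.  ``n_traits_bookkeeping``
    fixes the trait count used for the possible-candidate denominator
    (defaults to the number of trait columns).

    When ``bh_annotation`` is set, a ``p_bh`` Benjamini-Hochberg column is
    added to the retained rows — an extension beyond the raw-alpha screen.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    wide = _echo_wide(echo)
    echo_birds = set(wide["bird_id"])
    trait_birds = set(traits["bird_id"])
    if echo_birds != trait_birds:
        only_e = sorted(echo_birds - trait_birds)
        only_t = sorted(trait_birds - echo_birds)
        raise ValueError(
            f"bird_ids do not match: only in echotexture table {only_e}; "
            f"only in trait table {only_t}"
        )
    trait_cols = [c for c in traits.columns if c not in ("bird_id", "group")]
    echo_vars = [c for c in wide.columns if c not in ("bird_id", "group")]
    n_planes = len({v.split("-")[0] for v in echo_vars})
    n_vars = len({v.split("-")[1] for v in echo_vars})
    n_traits = n_traits_bookkeeping if n_traits_bookkeeping is not None else len(trait_cols)
    merged = wide.merge(traits.drop(columns=["group"]), on="bird_id", validate="1:1")

    groups = sorted(merged["group"].unique())
    for g in groups:
        if (merged["group"] == g).sum() < 3:
            raise ValueError(f"group {g} has fewer than 3 birds")

    within_rows: list[dict] = []
    within_tested = 0
    within_skipped: list[tuple[str, str, str]] = []
    for g in groups:
        sub = merged[merged["group"] == g]
        rows, n_tested, skipped = _screen_one(sub, echo_vars, trait_cols, g, alpha)
        within_rows += rows
        within_tested += n_tested
        within_skipped += skipped
    within = _make_table(within_rows, within_tested, within_skipped,
                         count_candidates(n_planes, n_vars, n_traits, len(groups)),
                         bh_annotation)

    pooled_table = None
    if pooled:
        rows, n_tested, skipped = _screen_one(merged, echo_vars, trait_cols,
                                              "POOLED", alpha)
        pooled_table = _make_table(rows, n_tested, skipped,
                                   count_candidates(n_planes, n_vars, n_traits, 1),
                                   bh_annotation)
    return ScreenResult(within=within, pooled=pooled_table, alpha=alpha)


def _make_table(rows, n_tested, skipped, possible, bh_annotation) -> ScreenTable:
    df = pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))
    if bh_annotation and len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_bh"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["group", "input_variable", "output_variable"],
                        kind="mergesort").reset_index(drop=True)
    significant = len(df)
    return ScreenTable(results=df, possible=possible, significant=significant,
                       percentage=screen_percentage(significant, possible),
                       n_tested=n_tested, skipped=list(skipped))


# ---------------------------------------------------------------------------
# ANOVA with post-hoc letters
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """F tests per factor with pairwise post-hoc comparisons and letters."""

    factors: tuple[str, ...]
    f: dict
    p: dict
    df_resid: float
    ms_resid: float
    pairwise: pd.DataFrame      # factor, level_a, level_b, diff, p_value, significant
    letters: dict               # factor -> {level: letters}
    method: str                 # "tukey" or "lsd"
    alpha: float


def compact_letter_display(
    levels: Sequence[str],
    means: Mapping[str, float],
    significant: Mapping[frozenset, bool],
) -> dict[str, str]:
    """Assign letters so that levels sharing a letter are non-significant.

    Insert-and-absorb algorithm: start from one column holding every level;
    each significant pair splits any column containing both; redundant
    columns are absorbed.  Letters are ordered by descending column-best
    mean, so the highest-mean level carries 'a'.
    """
    columns: list[set[str]] = [set(levels)]
    for pair, is_sig in significant.items():
        if not is_sig:
            continue
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            new_a, new_b = col - {b}, col - {a}
            for new in (new_a, new_b):
                if not any(new <= other for other in columns):
                    columns.append(new)
    columns = [c for c in columns if c]
    columns.sort(key=lambda c: -max(means[l] for l in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {l: "" for l in levels}
    for letter, col in zip(alphabet, columns):
        for l in col:
            out[l] += letter
    return {l: "".join(sorted(s)) for l, s in out.items()}


def _oneway_ss(samples: Mapping[str, np.ndarray]) -> tuple[float, float, int, int]:
    all_vals = np.concatenate(list(samples.values()))
    grand = all_vals.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in samples.values())
    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in samples.values())
    dfb = len(samples) - 1
    dfw = all_vals.size - len(samples)
    return float(ssb), float(ssw), dfb, dfw


def _f_p(ss_effect: float, df_effect: int, ss_resid: float, df_resid: int,
         tol: float = 1e-12) -> tuple[float, float]:
    if ss_resid <= tol:
        if ss_effect <= tol:
            return 0.0, 1.0          # all observations identical
        return float("inf"), 0.0
    f = (ss_effect / df_effect) / (ss_resid / df_resid)
    return float(f), float(sps.f.sf(f, df_effect, df_resid))


def anova_oneway_tukey(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    factor: str = "group",
) -> AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letters.

    ``samples`` maps level name -> observations (each n >= 2, >= 2 levels).
    A fully constant data set yields F = 0, p = 1 and a shared letter.
    """
    samples = {k: np.asarray(v, dtype=np.float64) for k, v in samples.items()}
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {k} needs n >= 2, got {v.size}")
    levels = list(samples)
    ssb, ssw, dfb, dfw = _oneway_ss(samples)
    f, p = _f_p(ssb, dfb, ssw, dfw)

    means = {k: float(v.mean()) for k, v in samples.items()}
    pair_rows = []
    sig: dict[frozenset, bool] = {}
    if ssw > 1e-12:
        hsd = sps.tukey_hsd(*samples.values())
        pmat = hsd.pvalue
    else:
        pmat = None
    for i, a in enumerate(levels):
        for j in range(i + 1, len(levels)):
            b = levels[j]
            if pmat is not None:
                pv = float(pmat[i, j])
            else:
                pv = 1.0 if means[a] == means[b] else 0.0
            pair_rows.append({"factor": factor, "level_a": a, "level_b": b,
                              "diff": means[a] - means[b], "p_value": pv,
                              "significant": pv < alpha})
            sig[frozenset((a, b))] = pv < alpha
    letters = compact_letter_display(levels, means, sig)
    return AnovaResult(
        factors=(factor,), f={factor: f}, p={factor: p},
        df_resid=dfw, ms_resid=ssw / dfw if dfw else float("nan"),
        pairwise=pd.DataFrame(pair_rows), letters={factor: letters},
        method="tukey", alpha=alpha,
    )


def _lsd_pairs(
    df: pd.DataFrame, value: str, factor: str, levels: Sequence[str],
    ms_resid: float, df_resid: float, alpha: float,
) -> tuple[list[dict], dict[str, str]]:
    means = {l: float(df.loc[df[factor] == l, value].mean()) for l in levels}
    counts = {l: int((df[factor] == l).sum()) for l in levels}
    rows = []
    sig: dict[frozenset, bool] = {}
    for i, a in enumerate(levels):
        for j in range(i + 1, len(levels)):
            b = levels[j]
            diff = means[a] - means[b]
            se = np.sqrt(ms_resid * (1.0 / counts[a] + 1.0 / counts[b]))
            if se == 0:
                pv = 1.0 if diff == 0 else 0.0
            else:
                t = diff / se
                pv = float(2.0 * sps.t.sf(abs(t), df_resid))
            rows.append({"factor": factor, "level_a": a, "level_b": b,
                         "diff": diff, "p_value": pv, "significant": pv < alpha})
            sig[frozenset((a, b))] = pv < alpha
    return rows, compact_letter_display(levels, means, sig)


def anova_twoway_lsd(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "group",
    factor_b: str = "plane",
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-way additive ANOVA (main effects only) with LSD pairwise tests.

    Every factor_a x factor_b cell must be non-empty.  LSD comparisons are
    unadjusted t-tests on the marginal means using the residual mean square
    of the additive fit.  When one factor has a single level, the model
    reduces to a one-way ANOVA on the other factor (with LSD post hoc).
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    levels_a = sorted(data[factor_a].unique())
    levels_b = sorted(data[factor_b].unique())
    for la in levels_a:
        for lb in levels_b:
            if ((data[factor_a] == la) & (data[factor_b] == lb)).sum() == 0:
                raise ValueError(f"empty cell: {factor_a}={la!r}, {factor_b}={lb!r}")

    if len(levels_a) < 2 or len(levels_b) < 2:
        # degenerate: single-level factor drops out of the model
        if len(levels_a) < 2 and len(levels_b) < 2:
            raise ValueError("both factors need >= 2 levels")
        keep = factor_a if len(levels_a) >= 2 else factor_b
        samples = {l: data.loc[data[keep] == l, value].to_numpy(dtype=np.float64)
                   for l in sorted(data[keep].unique())}
        ssb, ssw, dfb, dfw = _oneway_ss(samples)
        f, p = _f_p(ssb, dfb, ssw, dfw)
        ms_resid = ssw / dfw if dfw else float("nan")
        rows, letters = _lsd_pairs(data, value, keep, list(samples), ms_resid, dfw, alpha)
        return AnovaResult(factors=(keep,), f={keep: f}, p={keep: p},
                           df_resid=dfw, ms_resid=ms_resid,
                           pairwise=pd.DataFrame(rows), letters={keep: letters},
                           method="lsd", alpha=alpha)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    work = pd.DataFrame({"_y": data[value].to_numpy(dtype=np.float64),
                         "_a": data[factor_a].astype(str).to_numpy(),
                         "_b": data[factor_b].astype(str).to_numpy()})
    fit = smf.ols("_y ~ C(_a) + C(_b)", data=work).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ss_a = float(table.loc["C(_a)", "sum_sq"])
    ss_b = float(table.loc["C(_b)", "sum_sq"])
    ss_r = float(table.loc["Residual", "sum_sq"])
    df_a = int(table.loc["C(_a)", "df"])
    df_b = int(table.loc["C(_b)", "df"])
    df_r = int(table.loc["Residual", "df"])
    f_a, p_a = _f_p(ss_a, df_a, ss_r, df_r)
    f_b, p_b = _f_p(ss_b, df_b, ss_r, df_r)
    ms_resid = ss_r / df_r if df_r else 0.0

    rows_a, letters_a = _lsd_pairs(data, value, factor_a, levels_a, ms_resid, df_r, alpha)
    rows_b, letters_b = _lsd_pairs(data, value, factor_b, levels_b, ms_resid, df_r, alpha)
    return AnovaResult(
        factors=(factor_a, factor_b),
        f={factor_a: f_a, factor_b: f_b},
        p={factor_a: p_a, factor_b: p_b},
        df_resid=df_r, ms_resid=ms_resid,
        pairwise=pd.DataFrame(rows_a + rows_b),
        letters={factor_a: letters_a, factor_b: letters_b},
        method="lsd", alpha=alpha,
    )
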