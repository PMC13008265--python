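"""Statistical layer: growth-curve fits, condition comparisons, septation χ².

Doubling times come from nonlinear least-squares fits of a logistic model
to replicate OD600 curves; condition effects on per-cell geometry are
tested by one-way ANOVA with post-hoc comparisons against a reference
condition; septation indices are compared by an overall r×2 χ² on raw
counts followed, when significant, by pairwise 2×2 χ² tests versus the
wild-type reference with Bonferroni adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .synth import logistic_od

#: significance tiers as printed in figure legends
SIGNIFICANCE_TIERS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.04, "*"))


def significance_tier(p: float) -> str:
    for cut, stars in SIGNIFICANCE_TIERS:
        if p < cut:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthFit:
    """Logistic fit of one replicate growth curve."""

    replicate: int | str
    k: float  # min^-1
    doubling_time: float  # ln(2)/k, min
    od0: float
    od_max: float
    r_squared: float
    n_points: int
    flagged: str | None = None


def fit_growth(
    time_min: np.ndarray, od: np.ndarray, replicate: int | str = 1
) -> GrowthFit:
    """Fit OD(t) = od_max·od0·e^{kt}/(od_max + od0(e^{kt}−1)) to one curve.

    k is initialized from a log-linear regression over the early phase
    (OD below half its final level); doubling time is ln(2)/k.  A fitted
    k ≤ 0 is returned flagged as non-growing rather than raised.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(od, dtype=float)
    if len(t) < 20:
        raise ValueError(f"need >= 20 time points, got {len(t)}")
    if y.max() <= 0:
        raise ValueError("OD values must be positive")

    # log-linear early phase for k0 (noise can push single readings to
    # zero or below; only positive points inform the log fit)
    pos = y > 0
    early = pos & (y < max(y[pos].max() / 2, y[pos][0] * 1.5))
    if early.sum() >= 3:
        k0 = float(np.polyfit(t[early], np.log(y[early]), 1)[0])
    else:
        k0 = float(np.polyfit(t[pos], np.log(y[pos]), 1)[0])
    k0 = max(k0, 1e-5)
    p0 = (k0, max(float(y[pos][0]), 1e-4), float(y.max()) * 1.05)

    try:
        popt, _ = optimize.curve_fit(
            lambda tt, k, od0, od_max: logistic_od(tt, k, od0, od_max),
            t, y, p0=p0, maxfev=20000,
            bounds=((1e-8, 1e-8, 1e-8), (np.inf, np.inf, np.inf)),
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"growth fit failed to converge (init k0={k0:.4g}, od0={p0[1]:.3g}, "
            f"od_max={p0[2]:.3g}): {exc}"
        ) from exc
    k, od0, od_max = (float(v) for v in popt)
    resid = y - logistic_od(t, k, od0, od_max)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    flagged = "non_growing" if k <= 1e-7 else None
    return GrowthFit(
        replicate=replicate, k=k, doubling_time=math.log(2) / k,
        od0=od0, od_max=od_max, r_squared=r2, n_points=len(t), flagged=flagged,
    )


def fit_growth_table(curves: pd.DataFrame) -> pd.DataFrame:
    """Fit every replicate in a (time_min, replicate, od) table; one row per
    replicate plus the condition summary mean ± SD of doubling time."""
    fits = [
        fit_growth(g["time_min"].to_numpy(), g["od"].to_numpy(), replicate=rep)
        for rep, g in curves.groupby("replicate")
    ]
    df = pd.DataFrame([f.__dict__ for f in fits])
    df.attrs["doubling_time_mean"] = float(df["doubling_time"].mean())
    df.attrs["doubling_time_sd"] = float(df["doubling_time"].std(ddof=1)) if len(df) > 1 else 0.0
    return df


# ---------------------------------------------------------------------------
# condition comparisons
# ---------------------------------------------------------------------------

def t_test(group_a, group_b) -> tuple[float, float, float]:
    """Unpaired two-tailed t test; returns (t, df, p)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(len(a) + len(b) - 2), float(res.pvalue)


def compare_conditions(
    values_by_condition: dict[str, np.ndarray], reference: str
) -> dict:
    """One-way ANOVA across conditions plus post-hoc tests vs the reference.

    Post-hoc comparisons are Bonferroni-adjusted unpaired t tests of each
    non-reference condition against the reference, reported with the tiered
    asterisks used in figure legends (ns, *p<0.04, **p<0.01, ***p<0.001,
    ****p<0.0001).
    """
    if reference not in values_by_condition:
        raise KeyError(f"reference condition {reference!r} not in data")
    groups = {k: np.asarray(list(v), dtype=float) for k, v in values_by_condition.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    for name, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"condition {name!r} has n < 2")

    arrays = list(groups.values())
    if all(np.ptp(g) == 0 for g in arrays) and len({g[0] for g in arrays}) == 1:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = (float(v) for v in sps.f_oneway(*arrays))

    others = [k for k in groups if k != reference]
    m = len(others)
    posthoc = []
    for name in others:
        t, df, praw = t_test(groups[name], groups[reference])
        padj = min(praw * m, 1.0)
        posthoc.append(dict(
            condition=name, reference=reference, t=t, df=df,
            p_raw=praw, p_adjusted=padj, tier=significance_tier(padj),
        ))
    return dict(
        anova_F=f_stat,
        anova_p=p,
        df_between=len(groups) - 1,
        df_within=sum(len(g) for g in arrays) - len(groups),
        posthoc=pd.DataFrame(posthoc),
    )


# ---------------------------------------------------------------------------
# septation index
# ---------------------------------------------------------------------------

@dataclass
class SeptationResult:
    chi2: float
    df: int
    p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def septation_tests(
    counts: pd.DataFrame, reference: str = "WT", alpha: float = 0.05,
    yates: bool = False,
) -> SeptationResult:
    """χ² procedure on a septated/unseptated count table.

    ``counts`` needs columns genotype, septated, unseptated.  An overall
    r×2 χ² on raw counts is run first; only if it is significant at
    ``alpha`` are pairwise 2×2 χ² tests of each mutant against the
    reference performed, Bonferroni-adjusted.  Continuity correction is off
    by default (``yates`` enables it).
    """
    req = {"genotype", "septated", "unseptated"}
    if not req.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(req)}")
    tbl = counts.set_index("genotype")[["septated", "unseptated"]].astype(int)
    if (tbl.sum(axis=1) < 1).any():
        raise ValueError("every genotype needs at least one counted cell")
    obs = tbl.to_numpy()
    _check_expected(obs)
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=yates)

    pairwise = pd.DataFrame()
    if p < alpha and reference in tbl.index:
        rows = []
        others = [g for g in tbl.index if g != reference]
        m = len(others)
        for g in others:
            sub = tbl.loc[[g, reference]].to_numpy()
            _check_expected(sub)
            c2, praw, d, _ = sps.chi2_contingency(sub, correction=yates)
            padj = min(praw * m, 1.0)
            rows.append(dict(
                genotype=g, chi2=float(c2), df=int(d), p_raw=float(praw),
                p_adjusted=padj, tier=significance_tier(padj),
            ))
        pairwise = pd.DataFrame(rows)
    return SeptationResult(chi2=float(chi2), df=int(df), p=float(p), pairwise=pairwise)


def _check_expected(obs: np.ndarray) -> None:
    exp = sps.contingency.expected_freq(obs)
    if np.any(exp == 0):
        raise ValueError(
            "a cell of the contingency table has expected count 0; merge "
            "categories before testing"
        )
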